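"""Discrete Helfrich mechanics of the spine membrane.

The spine outline is a closed 2D polyline (``MembraneMesh``) whose vertices
move overdamped under the negative gradient of the Helfrich free energy

    E = P*Omega + tau*L + 2*kappa * sum_k H_k^2 ds_k,

where ``Omega`` is the enclosed area, ``L`` the contour length and ``H_k`` a
per-vertex mean-curvature estimate (turning angle over mean adjacent edge
length).  Two contiguous vertex stretches are pinned: the postsynaptic
density (PSD) at height ``h_psd`` and the neck at ``h_neck``; pinned
vertices feel forces but do not move.

All lengths are in micrometres, forces in piconewtons, energies in pN*um.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from shapely.geometry import Polygon as _ShapelyPolygon

FREE, PSD, NECK = 0, 1, 2
_ROLE_NAMES = {FREE: "free", PSD: "psd", NECK: "neck"}
_ROLE_CODES = {v: k for k, v in _ROLE_NAMES.items()}


class InvalidMeshError(ValueError):
    """Mesh violates a structural invariant (too few / coincident vertices...)."""


class TimeStepError(RuntimeError):
    """A single Euler step produced a displacement larger than d_max."""


class ConvergenceError(RuntimeError):
    """Relaxation did not reach the requested tolerance."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


@dataclass
class MechanicalParams:
    """Membrane material constants and integrator settings.

    P : pressure difference, pN/um^2 (energy per area)
    tau : line tension, pN
    kappa : bending modulus, pN*um
    zeta : force-to-velocity mobility, um/(pN*s)
    d_min / d_max : remeshing bounds on edge length, um
    dt : Euler time step, s
    """

    P: float = 8.0
    tau: float = 5.0
    kappa: float = 0.02
    zeta: float = 0.05
    d_min: float = 0.018
    d_max: float = 0.054
    dt: float = 0.1

    def __post_init__(self) -> None:
        if self.zeta <= 0:
            raise ValueError("zeta must be positive")
        if not (0 < self.d_min < self.d_max):
            raise ValueError("need 0 < d_min < d_max")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.kappa < 0 or self.tau < 0:
            raise ValueError("kappa and tau must be non-negative")


@dataclass
class MembraneMesh:
    """Closed counter-clockwise polyline with pinned PSD and neck stretches.

    ``roles[k]`` is FREE, PSD or NECK; PSD vertices sit at ``y == h_psd``,
    neck vertices at ``y == h_neck``, and each pinned set occupies a
    cyclically contiguous index range.
    """

    vertices: np.ndarray
    roles: np.ndarray
    h_psd: float
    h_neck: float

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.roles = np.asarray(self.roles, dtype=np.int8)

    @property
    def n(self) -> int:
        return len(self.vertices)

    @property
    def psd_indices(self) -> np.ndarray:
        return np.flatnonzero(self.roles == PSD)

    @property
    def neck_indices(self) -> np.ndarray:
        return np.flatnonzero(self.roles == NECK)

    @property
    def free_mask(self) -> np.ndarray:
        return self.roles == FREE

    def copy(self) -> "MembraneMesh":
        return MembraneMesh(self.vertices.copy(), self.roles.copy(),
                            self.h_psd, self.h_neck)

    def validate(self, check_spacing: bool = False,
                 params: MechanicalParams | None = None,
                 check_simple: bool = False) -> None:
        if self.n < 3:
            raise InvalidMeshError(f"mesh needs >= 3 vertices, got {self.n}")
        if len(self.roles) != self.n:
            raise InvalidMeshError("roles length does not match vertex count")
        if not np.all(np.isfinite(self.vertices)):
            raise InvalidMeshError("non-finite vertex coordinates")
        edges = np.roll(self.vertices, -1, axis=0) - self.vertices
        lens = np.hypot(edges[:, 0], edges[:, 1])
        if np.any(lens < 1e-12):
            raise InvalidMeshError("coincident consecutive vertices")
        psd = self.psd_indices
        if psd.size and np.abs(self.vertices[psd, 1] - self.h_psd).max() > 1e-8:
            raise InvalidMeshError("PSD vertices off h_psd")
        neck = self.neck_indices
        if neck.size and np.abs(self.vertices[neck, 1] - self.h_neck).max() > 1e-8:
            raise InvalidMeshError("neck vertices off h_neck")
        if check_spacing:
            assert params is not None
            if lens.min() < params.d_min - 1e-12 or lens.max() > params.d_max + 1e-12:
                raise InvalidMeshError("edge length outside [d_min, d_max]")
        if check_simple and not self.is_simple():
            raise InvalidMeshError("polygon self-intersects")

    def is_simple(self) -> bool:
        return _ShapelyPolygon(self.vertices).is_valid


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def signed_area(mesh: MembraneMesh) -> float:
    x, y = mesh.vertices[:, 0], mesh.vertices[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def enclosed_area(mesh: MembraneMesh) -> float:
    """Area enclosed by the closed contour (shoelace formula), um^2."""
    mesh.validate()
    return abs(signed_area(mesh))


def boundary_length(mesh: MembraneMesh) -> float:
    """Total contour length including the closing edge, um."""
    mesh.validate()
    edges = np.roll(mesh.vertices, -1, axis=0) - mesh.vertices
    return float(np.hypot(edges[:, 0], edges[:, 1]).sum())


def _edge_vectors(v: np.ndarray):
    """Outgoing edges e_k = x_{k+1} - x_k and their lengths."""
    e = np.roll(v, -1, axis=0) - v
    el = np.hypot(e[:, 0], e[:, 1])
    return e, el


def _turning_angles(v: np.ndarray):
    """Signed exterior (turning) angle at each vertex, with edge data."""
    e, el = _edge_vectors(v)
    u = np.roll(e, 1, axis=0)          # incoming edge at vertex k
    ul = np.roll(el, 1)
    cross = u[:, 0] * e[:, 1] - u[:, 1] * e[:, 0]
    dot = u[:, 0] * e[:, 0] + u[:, 1] * e[:, 1]
    theta = np.arctan2(cross, dot)
    return theta, u, ul, e, el


def discrete_curvature(mesh: MembraneMesh) -> np.ndarray:
    """Per-vertex curvature: turning angle over mean adjacent edge length.

    Converges to 1/r on a sampled circle of radius r.  Sign follows the
    contour orientation; a counter-clockwise convex contour is positive.
    """
    mesh.validate()
    theta, _, ul, _, el = _turning_angles(mesh.vertices)
    ds = 0.5 * (ul + el)
    return theta / ds


def membrane_energy(mesh: MembraneMesh, params: MechanicalParams) -> float:
    """Discrete Helfrich free energy P*Omega + tau*L + 2*kappa*sum H^2 ds."""
    mesh.validate()
    theta, _, ul, _, el = _turning_angles(mesh.vertices)
    ds = 0.5 * (ul + el)
    bend = float(np.sum((theta / ds) ** 2 * ds))
    return (params.P * enclosed_area(mesh)
            + params.tau * boundary_length(mesh)
            + 2.0 * params.kappa * bend)


def _perp(w: np.ndarray) -> np.ndarray:
    out = np.empty_like(w)
    out[:, 0] = -w[:, 1]
    out[:, 1] = w[:, 0]
    return out


def membrane_force(mesh: MembraneMesh, params: MechanicalParams) -> np.ndarray:
    """Per-vertex force -dE/dx^k (pN), analytic gradient of the discrete energy.

    Forces on PSD/neck vertices are reported too; the integrator simply
    never moves them.
    """
    mesh.validate()
    v = mesh.vertices
    theta, u, ul, e, el = _turning_angles(v)
    grad = np.zeros_like(v)

    # pressure term: P * |A|, d|A|/dx_k = sign(A)/2 * (y_{k+1}-y_{k-1}, x_{k-1}-x_{k+1})
    s = np.sign(signed_area(mesh)) or 1.0
    nxt = np.roll(v, -1, axis=0)
    prv = np.roll(v, 1, axis=0)
    grad[:, 0] += params.P * s * 0.5 * (nxt[:, 1] - prv[:, 1])
    grad[:, 1] += params.P * s * 0.5 * (prv[:, 0] - nxt[:, 0])

    # tension term: dL/dx_k = u_hat - e_hat (incoming minus outgoing unit edge)
    uhat = u / ul[:, None]
    ehat = e / el[:, None]
    grad += params.tau * (uhat - ehat)

    # bending term: E_b = 2 kappa sum_j theta_j^2 / l_j, l_j = (|u_j|+|e_j|)/2
    lmean = 0.5 * (ul + el)
    a = theta / lmean                      # dE/dtheta_j / (4 kappa) = a_j / 2 ... folded below
    b = (theta / lmean) ** 2
    pu = _perp(u) / (ul ** 2)[:, None]     # d theta_j / d x_{j-1}
    pe = _perp(e) / (el ** 2)[:, None]     # d theta_j / d x_{j+1}

    gb = np.zeros_like(v)
    # j = k term
    gb += 2.0 * a[:, None] * (-pu - pe) - b[:, None] * 0.5 * (uhat - ehat)
    # j = k+1 term (vertex k is x_{j-1} of joint j)
    gb += np.roll(2.0 * a[:, None] * pu + b[:, None] * 0.5 * uhat, -1, axis=0)
    # j = k-1 term (vertex k is x_{j+1} of joint j)
    gb += np.roll(2.0 * a[:, None] * pe - b[:, None] * 0.5 * ehat, 1, axis=0)
    grad += 2.0 * params.kappa * gb

    return -grad


def step_vertices(mesh: MembraneMesh, total_force: np.ndarray,
                  params: MechanicalParams, do_remesh: bool = True) -> MembraneMesh:
    """Explicit Euler step x += zeta * F * dt on free vertices; pins stay put."""
    total_force = np.asarray(total_force, dtype=float)
    if total_force.shape != mesh.vertices.shape:
        raise ValueError("force array shape does not match vertex count")
    disp = params.zeta * total_force * params.dt
    mag = np.hypot(disp[:, 0], disp[:, 1])
    free = mesh.free_mask
    if np.any(mag[free] > params.d_max):
        raise TimeStepError(
            f"max displacement {mag[free].max():.3g} um exceeds d_max="
            f"{params.d_max}; reduce dt")
    out = mesh.copy()
    out.vertices[free] += disp[free]
    if do_remesh:
        out = remesh(out, params)
    return out


def remesh(mesh: MembraneMesh, params: MechanicalParams) -> MembraneMesh:
    """Enforce edge lengths in [d_min, d_max] by midpoint merges and splits.

    Merging a free vertex into a pinned one keeps the pinned position; a
    pair of pinned vertices is never merged.  Split midpoints inherit a
    pinned role only when both edge endpoints share it (which keeps the
    pinned height exact).
    """
    e, el = _edge_vectors(mesh.vertices)
    if el.min() >= params.d_min and el.max() <= params.d_max:
        return mesh
    verts = list(map(tuple, mesh.vertices))
    roles = list(mesh.roles)
    for _ in range(10 * max(len(verts), 4)):
        n = len(verts)
        changed = False
        # merge pass
        for k in range(n):
            if len(verts) <= 3:
                break
            j = (k + 1) % len(verts)
            if k >= len(verts) or j >= len(verts):
                break
            p, q = np.array(verts[k]), np.array(verts[j])
            if np.hypot(*(q - p)) < params.d_min:
                rk, rj = roles[k], roles[j]
                if rk != FREE and rj != FREE:
                    continue  # pins win: never delete a pinned vertex
                if rk != FREE:
                    del verts[j]; del roles[j]
                elif rj != FREE:
                    del verts[k]; del roles[k]
                else:
                    verts[k] = tuple(0.5 * (p + q))
                    del verts[j]; del roles[j]
                changed = True
                break
        if changed:
            continue
        # split pass
        for k in range(len(verts)):
            j = (k + 1) % len(verts)
            p, q = np.array(verts[k]), np.array(verts[j])
            if np.hypot(*(q - p)) > params.d_max:
                role = roles[k] if roles[k] == roles[j] else FREE
                verts.insert(k + 1, tuple(0.5 * (p + q)))
                roles.insert(k + 1, role)
                changed = True
                break
        if not changed:
            break
    return MembraneMesh(np.array(verts), np.array(roles, dtype=np.int8),
                        mesh.h_psd, mesh.h_neck)


def relax_to_rest(mesh: MembraneMesh, params: MechanicalParams,
                  tol: float | None = None,
                  max_iter: int = 5000) -> MembraneMesh:
    """Find the zero-actin resting shape: the constrained minimum of the
    Helfrich energy with PSD/neck vertices held fixed.

    The discrete energy is indifferent to how vertices are spaced along the
    contour (a reparametrisation mode), so the minimisation adds a weak
    edge-length spring that keeps the spacing uniform without biasing the
    shape, and convergence is measured on the displacement one Euler step
    would produce *along the membrane normal*: ``zeta*dt*|F.n| < tol`` (um)
    at every free vertex.  Tangential sliding is mesh maintenance, not a
    shape change.  L-BFGS with the analytic gradient, interleaved with
    remeshing, reaches the same fixed point as Euler descent orders of
    magnitude faster.

    The spring is weakened geometrically between rounds; if the spacing can
    only be held with a spring whose residual bias exceeds ``tol``, the
    best shape within ``10*tol`` is returned (beyond that a
    ``ConvergenceError`` is raised).
    """
    from scipy.optimize import minimize

    if tol is None:
        # default displacement tolerance scales with the mobility so the
        # same residual force quality is demanded for any zeta*dt
        tol = 4e-3 * params.zeta * params.dt
    m = mesh.copy()
    resid = np.inf
    w_scale = 1.0
    best: tuple | None = None
    bad_rounds = 0
    for outer in range(60):
        free = np.flatnonzero(m.free_mask)
        if free.size == 0:
            return m
        base = m.vertices.copy()
        roles = m.roles.copy()
        _, el0 = _edge_vectors(base)
        l_target = float(el0.mean())
        # adaptive continuation: strong spring first (uniform spacing), then
        # weaken it geometrically so its residual normal bias leaves the
        # converged shape; if a weaker spring lets the spacing collapse,
        # back off and stop weakening
        w_spring = 10.0 * (params.tau + 1e-3) / l_target * w_scale

        def unpack(x):
            v = base.copy()
            v[free] = x.reshape(-1, 2)
            return MembraneMesh(v, roles, m.h_psd, m.h_neck)

        def fun(x):
            trial = unpack(x)
            e, el = _edge_vectors(trial.vertices)
            if el.min() < 1e-9:
                return 1e12, np.zeros_like(x)
            en = membrane_energy(trial, params)
            # penalise non-uniform spacing only: deviation from the current
            # mean edge length, so uniform growth/shrinkage is spring-free
            lm = float(el.mean())
            en += w_spring * float(np.sum((el - lm) ** 2))
            g = -membrane_force(trial, params)
            # d l_k/d x_k = -e_hat_k, d l_{k-1}/d x_k = +e_hat_{k-1};
            # the d(mean)/dx part cancels because sum(el - lm) = 0
            coef = 2.0 * w_spring * (el - lm)
            ce = coef[:, None] * (e / el[:, None])
            g += np.roll(ce, 1, axis=0) - ce
            return en, g[free].ravel()

        res = minimize(fun, base[free].ravel(), jac=True, method="L-BFGS-B",
                       options={"maxiter": max_iter, "ftol": 1e-15,
                                "gtol": 1e-12})
        trial = unpack(res.x)
        f = membrane_force(trial, params)
        e, el = _edge_vectors(trial.vertices)
        u, ul = np.roll(e, 1, axis=0), np.roll(el, 1)
        tang = e / el[:, None] + u / ul[:, None]
        tang /= np.maximum(np.hypot(tang[:, 0], tang[:, 1]), 1e-12)[:, None]
        fnorm = np.abs(f[:, 0] * -tang[:, 1] + f[:, 1] * tang[:, 0])
        fnorm[~trial.free_mask] = 0.0
        resid = params.zeta * params.dt * float(fnorm.max())
        spacing_ok = (el.min() >= 0.9 * params.d_min
                      and el.max() <= 1.1 * params.d_max)
        if spacing_ok:
            bad_rounds = 0
            if resid < tol:
                return trial
            if best is None or resid < best[0]:
                best = (resid, trial.copy())
            m = remesh(trial, params)
            w_scale *= 0.25
        else:
            # spring too weak to hold the spacing: restore and back off
            bad_rounds += 1
            w_scale = min(w_scale * 8.0, 1.0)
            m = remesh(best[1].copy() if best is not None else m, params)
            if bad_rounds >= 6:
                break
    if best is not None and best[0] < 10.0 * tol:
        return best[1]
    raise ConvergenceError(
        f"relaxation did not reach tol={tol}", resid)


# ---------------------------------------------------------------------------
# construction and I/O
# ---------------------------------------------------------------------------

def _circle_through(p1, p2, p3):
    """Centre and radius of the circle through three points."""
    ax, ay = p1
    bx, by = p2
    cx, cy = p3
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    ux = ((ax ** 2 + ay ** 2) * (by - cy) + (bx ** 2 + by ** 2) * (cy - ay)
          + (cx ** 2 + cy ** 2) * (ay - by)) / d
    uy = ((ax ** 2 + ay ** 2) * (cx - bx) + (bx ** 2 + by ** 2) * (ax - cx)
          + (cx ** 2 + cy ** 2) * (bx - ax)) / d
    r = float(np.hypot(ax - ux, ay - uy))
    return (ux, uy), r


def stadium_mesh(h_psd: float = 0.55, h_neck: float = 0.0,
                 psd_width: float = 0.40, neck_width: float = 0.15,
                 bulge: float = 0.38, spacing: float = 0.035) -> MembraneMesh:
    """Seed polygon spanning neck (bottom) to PSD (top) with bulging flanks.

    Counter-clockwise: neck left-to-right along y=h_neck, right flank up a
    circular arc through the mid-height bulge, PSD right-to-left along
    y=h_psd, left flank back down (mirror image).
    """
    ym = 0.5 * (h_neck + h_psd)
    (cx, cy), r = _circle_through((neck_width / 2, h_neck), (bulge, ym),
                                  (psd_width / 2, h_psd))

    def seg(p, q, include_end=False):
        p, q = np.array(p, float), np.array(q, float)
        n = max(int(np.ceil(np.hypot(*(q - p)) / spacing)), 1)
        ts = np.linspace(0, 1, n + 1)
        if not include_end:
            ts = ts[:-1]
        return p[None, :] + ts[:, None] * (q - p)[None, :]

    def arc(p, q, centre, radius, flip=False):
        a0 = np.arctan2(p[1] - centre[1], p[0] - centre[0])
        a1 = np.arctan2(q[1] - centre[1], q[0] - centre[0])
        if not flip and a1 < a0:
            a1 += 2 * np.pi
        if flip and a1 > a0:
            a1 -= 2 * np.pi
        n = max(int(np.ceil(abs(a1 - a0) * radius / spacing)), 2)
        ang = np.linspace(a0, a1, n + 1)[1:-1]
        return np.stack([centre[0] + radius * np.cos(ang),
                         centre[1] + radius * np.sin(ang)], axis=1)

    neck = seg((-neck_width / 2, h_neck), (neck_width / 2, h_neck),
               include_end=True)
    right = arc((neck_width / 2, h_neck), (psd_width / 2, h_psd), (cx, cy), r)
    psd = seg((psd_width / 2, h_psd), (-psd_width / 2, h_psd),
              include_end=True)
    left = arc((-psd_width / 2, h_psd), (-neck_width / 2, h_neck),
               (-cx, cy), r)

    verts = np.vstack([neck, right, psd, left])
    roles = np.concatenate([
        np.full(len(neck), NECK), np.full(len(right), FREE),
        np.full(len(psd), PSD), np.full(len(left), FREE)]).astype(np.int8)
    mesh = MembraneMesh(verts, roles, h_psd=h_psd, h_neck=h_neck)
    if signed_area(mesh) < 0:
        mesh = MembraneMesh(verts[::-1].copy(), roles[::-1].copy(),
                            h_psd, h_neck)
    mesh.validate()
    return mesh


def circle_mesh(radius: float, n: int = 128, centre=(0.0, 0.0)) -> MembraneMesh:
    """Unpinned regular n-gon (handy for analytic checks)."""
    ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
    verts = np.stack([centre[0] + radius * np.cos(ang),
                      centre[1] + radius * np.sin(ang)], axis=1)
    return MembraneMesh(verts, np.zeros(n, dtype=np.int8),
                        h_psd=np.inf, h_neck=-np.inf)


def equilibrium_radius(params: MechanicalParams) -> float:
    """Positive root of P r^3 + tau r^2 - 2 kappa = 0 (free-circle rest radius)."""
    roots = np.roots([params.P, params.tau, 0.0, -2.0 * params.kappa])
    real = roots[np.abs(roots.imag) < 1e-9].real
    pos = real[real > 0]
    if pos.size != 1:
        raise ValueError("no unique positive equilibrium radius")
    return float(pos[0])


def mesh_to_frame(mesh: MembraneMesh):
    import pandas as pd

    return pd.DataFrame({
        "index": np.arange(mesh.n),
        "x_um": mesh.vertices[:, 0],
        "y_um": mesh.vertices[:, 1],
        "role": [_ROLE_NAMES[int(r)] for r in mesh.roles],
    })


def write_mesh_csv(mesh: MembraneMesh, path) -> None:
    mesh_to_frame(mesh).to_csv(path, index=False)


def read_mesh_csv(path) -> MembraneMesh:
    import pandas as pd

    df = pd.read_csv(path)
    verts = df[["x_um", "y_um"]].to_numpy(float)
    roles = np.array([_ROLE_CODES[r] for r in df["role"]], dtype=np.int8)
    psd = verts[roles == PSD, 1]
    neck = verts[roles == NECK, 1]
    return MembraneMesh(verts, roles,
                        h_psd=float(psd[0]) if psd.size else np.inf,
                        h_neck=float(neck[0]) if neck.size else -np.inf)
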