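"""Stochastic actin polymerization foci.

Each focus is a cluster of branched filaments nucleated near the PSD.  Every
filament carries an uncapped barbed (+) end — capping the barbed end removes
the filament from the simulation — and a minus (-) end that is either capped
(freshly branch-born) or uncapped (eligible for severing).  The number of
barbed ends B = n_minus_capped + n_minus_uncapped sets both the pushing
force on the membrane (a Gaussian kernel around the nucleation point) and
the polymerization-event count per time step.

All rates are constant except branching, which carries the force feedback

    gamma_branch = phi * k_on * delta * a
                   * exp(-|F_mem| * delta / (kB*T * B)) / B,

a Brownian-ratchet-style slowdown of the treadmilling velocity under
membrane load shared by the B barbed ends of the focus.  The non-feedback
control model freezes |F_mem| = 7 pN and B = 4 inside this formula, making
the branching rate a constant.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from shapely.geometry import Point, Polygon as _ShapelyPolygon

from .membrane import MembraneMesh

#: constants of the non-feedback (constant-branching-rate) control model:
#: membrane force at the likely nucleation sites of the resting shape, and
#: the mean barbed-end count of force-clamped Monte-Carlo runs
NONFEEDBACK_F_PN = 7.0
NONFEEDBACK_B = 4


class ExtinctFocusError(ValueError):
    """Operation on a focus with zero barbed ends."""


@dataclass(frozen=True)
class Focus:
    """One polymerization focus with filament minus-end bookkeeping."""

    id: int
    X_n: tuple[float, float]
    n_minus_capped: int = 1
    n_minus_uncapped: int = 0
    birth_time: float = 0.0

    @property
    def B(self) -> int:
        """Barbed-end count; the focus is extinct when it reaches zero."""
        return self.n_minus_capped + self.n_minus_uncapped

    @property
    def extinct(self) -> bool:
        return self.B == 0

    def __post_init__(self):
        if self.n_minus_capped < 0 or self.n_minus_uncapped < 0:
            raise ValueError("negative filament count")


@dataclass
class ActinRates:
    """Event rates (1/s) and polymerization constants.

    gamma_f : focus nucleation rate
    gamma_cap : barbed-end capping (filament removal)
    gamma_uncap : minus-end uncapping
    gamma_sever : removal of filaments with uncapped minus end
    phi : branching amplitude, 1/um
    k_on : assembly rate, 1/(uM*s)
    delta : actin monomer length, um
    a : profilin-ATP-actin concentration, uM
    kBT : thermal energy, pN*um
    dt : time step, s (per-event probabilities are rate*dt)
    """

    gamma_f: float = 0.3
    gamma_cap: float = 0.5
    gamma_uncap: float = 0.05
    gamma_sever: float = 0.5
    phi: float = 151.0
    k_on: float = 11.6
    delta: float = 0.0027
    a: float = 1.0
    kBT: float = 0.004114
    dt: float = 0.1

    def __post_init__(self):
        for name in ("gamma_f", "gamma_cap", "gamma_uncap", "gamma_sever",
                     "phi", "k_on", "delta", "a", "kBT", "dt"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def poly_coeff(self) -> float:
        """phi*k_on*delta*a, the zero-force branching scale (1/s)."""
        return self.phi * self.k_on * self.delta * self.a


@dataclass
class KernelParams:
    """Gaussian force kernel: amplitude alpha (pN*um), width sigma (um),
    and the maximum span of the branched network from its nucleation point
    (um), which bounds how far the tracked kernel centre can follow the
    membrane."""

    amplitude: float = 1.2
    sigma: float = 0.2
    reach: float = 0.45

    def __post_init__(self):
        if self.sigma <= 0 or self.amplitude <= 0:
            raise ValueError("sigma and amplitude must be positive")
        if self.reach <= 0:
            raise ValueError("reach must be positive")

    def weight(self, r):
        return (self.amplitude / (self.sigma * np.sqrt(2.0 * np.pi))
                * np.exp(-np.square(r) / (2.0 * self.sigma ** 2)))


def branching_rate(B: int, F_mem_mag: float, rates: ActinRates,
                   feedback: bool = True) -> float:
    """Per-filament branching rate (1/s), Brownian-ratchet force feedback.

    With ``feedback=False`` the force and barbed-end count inside the
    formula are frozen at 7 pN and 4 regardless of the arguments, so the
    rate is one constant for the whole run.
    """
    if B < 1:
        raise ExtinctFocusError("branching rate undefined for extinct focus")
    if F_mem_mag < 0:
        raise ValueError("force magnitude must be non-negative")
    if not feedback:
        F_mem_mag, B = NONFEEDBACK_F_PN, NONFEEDBACK_B
    return (rates.poly_coeff
            * np.exp(-F_mem_mag * rates.delta / (rates.kBT * B)) / B)


def step_focus(focus: Focus, F_mem_mag: float, rates: ActinRates,
               rng: np.random.Generator, feedback: bool = True):
    """Advance one focus by one time step.

    Every barbed end polymerizes once (the returned event count is B before
    any update).  Each filament then independently branches (new filament,
    minus end capped), caps its barbed end (removed), uncaps its minus end
    (if capped) or is severed (if its minus end is uncapped), with
    probabilities rate*dt drawn from the pre-update counts.

    Returns ``(focus, polymerization_events, event_counts)`` with
    ``event_counts`` a dict of branch/cap/uncap/sever tallies.
    """
    if focus.extinct:
        raise ExtinctFocusError("cannot step an extinct focus")
    p_br = branching_rate(focus.B, F_mem_mag, rates, feedback) * rates.dt
    p_cap = rates.gamma_cap * rates.dt
    p_uncap = rates.gamma_uncap * rates.dt
    p_sever = rates.gamma_sever * rates.dt
    if p_br > 1 or p_cap + p_uncap > 1 or p_cap + p_sever > 1:
        raise ValueError("per-step event probability exceeds 1; reduce dt")

    poly_events = focus.B
    n_mc, n_mu = focus.n_minus_capped, focus.n_minus_uncapped
    branches = int(rng.binomial(focus.B, p_br)) if p_br > 0 else 0
    # minus-capped filaments: barbed-cap, minus-uncap, or persist
    cap_mc, uncap, _ = rng.multinomial(n_mc, [p_cap, p_uncap,
                                              1 - p_cap - p_uncap])
    # minus-uncapped filaments: barbed-cap, sever, or persist
    cap_mu, sever, _ = rng.multinomial(n_mu, [p_cap, p_sever,
                                              1 - p_cap - p_sever])
    new = replace(focus,
                  n_minus_capped=n_mc + branches - int(cap_mc) - int(uncap),
                  n_minus_uncapped=n_mu + int(uncap) - int(cap_mu) - int(sever))
    counts = {"branch": branches, "cap": int(cap_mc + cap_mu),
              "uncap": int(uncap), "sever": int(sever)}
    return new, poly_events, counts


def maybe_nucleate(mesh: MembraneMesh, rates: ActinRates,
                   rng: np.random.Generator, focus_id: int = 0,
                   time: float = 0.0, offset_scale: float = 0.2):
    """With probability gamma_f*dt, nucleate a new focus close to the PSD.

    The nucleation point is drawn uniformly along the PSD segment and
    offset into the spine interior by a half-Gaussian perpendicular
    displacement (scale ``offset_scale`` um), rejected until it falls
    inside the contour.  Returns the new single-filament focus or None.
    """
    if rng.random() >= rates.gamma_f * rates.dt:
        return None
    mesh.validate()
    psd = mesh.psd_indices
    if psd.size == 0:
        return None
    poly = _ShapelyPolygon(mesh.vertices)
    xs = mesh.vertices[psd, 0]
    x_lo, x_hi = xs.min(), xs.max()
    for _ in range(200):
        x = rng.uniform(x_lo, x_hi)
        y = mesh.h_psd - abs(rng.normal(0.0, offset_scale))
        if poly.contains(Point(x, y)):
            return Focus(id=focus_id, X_n=(x, y), n_minus_capped=1,
                         n_minus_uncapped=0, birth_time=time)
    return None


def contact_point(focus: Focus, mesh: MembraneMesh,
                  reach: float = 0.45) -> np.ndarray:
    """Kernel centre X_c: the membrane vertex closest to the nucleation
    point, i.e. the filament network's contact point, which tracks the
    wall as it deforms.

    The branched network spans at most ``reach`` um (filaments are a few
    hundred nm long), so if the wall has been pushed farther than that the
    centre stops at ``reach`` along the line to the contact — the push on
    a wall beyond the network's span decays with the kernel tail instead
    of following it indefinitely.
    """
    xn = np.asarray(focus.X_n)
    d = mesh.vertices - xn
    k = int(np.argmin(np.hypot(d[:, 0], d[:, 1])))
    vec = mesh.vertices[k] - xn
    dist = float(np.hypot(vec[0], vec[1]))
    if dist <= reach or dist == 0.0:
        return mesh.vertices[k]
    return xn + vec * (reach / dist)


def actin_force(focus: Focus, mesh: MembraneMesh, kp: KernelParams,
                X_c=None) -> np.ndarray:
    """Per-vertex pushing force of one focus.

    Vertex k feels W(|x_k - X_c|) * B along the unit vector from the
    nucleation point X_n to the vertex.  ``X_c`` is the kernel centre; by
    default it tracks the membrane contact point (vertex nearest X_n), so
    the push stays on the wall the network abuts however far the contour
    deforms; pass ``X_c=focus.X_n`` for a static kernel.  A vertex exactly
    on X_n gets zero.
    """
    out = np.zeros_like(mesh.vertices)
    if focus.B == 0:
        return out
    if X_c is None:
        X_c = contact_point(focus, mesh, reach=kp.reach)
    dc = mesh.vertices - np.asarray(X_c)
    w = kp.weight(np.hypot(dc[:, 0], dc[:, 1])) * focus.B
    d = mesh.vertices - np.asarray(focus.X_n)
    r = np.hypot(d[:, 0], d[:, 1])
    ok = r > 1e-12
    out[ok] = (w[ok] / r[ok])[:, None] * d[ok]
    return out


def kernel_weights(focus: Focus, mesh: MembraneMesh, kp: KernelParams,
                   X_c=None) -> np.ndarray:
    """Normalized Gaussian weights of a focus over the mesh vertices,
    centred on ``X_c`` (default: the tracked membrane contact point)."""
    if X_c is None:
        X_c = contact_point(focus, mesh, reach=kp.reach)
    d = mesh.vertices - np.asarray(X_c)
    w = kp.weight(np.hypot(d[:, 0], d[:, 1]))
    s = w.sum()
    if s < 1e-300:
        return np.zeros(mesh.n)
    return w / s


def local_membrane_force(focus: Focus, mesh: MembraneMesh,
                         mem_forces: np.ndarray, kp: KernelParams,
                         mode: str = "magnitude", X_c=None) -> float:
    """|F_mem^i| entering the branching-rate feedback (pN).

    ``magnitude`` (default): kernel-weighted mean of the per-vertex force
    magnitudes — the load the membrane patch around the focus exerts,
    matching the ~7 pN scale of the resting shape near the PSD that the
    constant-rate control model is anchored to.  ``net``: norm of the
    weighted vector sum (opposing forces cancel).  ``nearest``: force
    magnitude at the kernel-nearest vertex.  Far from the membrane (all
    weights ~ 0) every mode returns 0.
    """
    mags = np.hypot(mem_forces[:, 0], mem_forces[:, 1])
    if mode == "nearest":
        d = mesh.vertices - np.asarray(focus.X_n)
        r = np.hypot(d[:, 0], d[:, 1])
        if r.min() > 6.0 * kp.sigma:
            return 0.0
        return float(mags[np.argmin(r)])
    w = kernel_weights(focus, mesh, kp, X_c=X_c)
    if mode == "magnitude":
        return float(w @ mags)
    if mode == "net":
        tot = w @ mem_forces
        return float(np.hypot(tot[0], tot[1]))
    raise ValueError(f"unknown mode {mode!r}")
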