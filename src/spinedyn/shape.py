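"""Circular-statistics shape descriptors of a spine head.

From the spine-neck centre, rays are traced every 15 degrees; the distances
to the head outline, dROI(theta), are fitted by a truncated Fourier series
(trigonometric interpolation on the 2n sample angles), insignificant terms
are pruned one by one (standardized coefficient < 0.1, F-test at level
0.1), and the retained series R(theta) = S + D(theta) + O(theta) is split
into

    S : the constant term A_0 — overall spine size (mean neck-to-boundary
        distance),
    D : the odd harmonics — directional selectivity, the tendency of the
        head to tilt towards one direction,
    O : the even harmonics — orientational selectivity, elongation along
        one or more axes.

D is reported as the mean of |D(theta)| in percent of S; O as the mean of
|dO/dtheta| over half a period in percent of S per radian (the derivative
reading is what gives "per radian" units; the literal |O(theta)| reading is
available via ``o_derivative=False``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _sstats
from shapely.geometry import LineString, Point, Polygon as _ShapelyPolygon

from .membrane import NECK, MembraneMesh

DEFAULT_HARMONICS = 12


@dataclass
class ROIPolygon:
    """Spine-head outline with the neck centre as the ray origin."""

    points: np.ndarray
    neck_center: np.ndarray
    neck_limits: np.ndarray | None = None

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        self.neck_center = np.asarray(self.neck_center, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")
        if len(self.points) < 3:
            raise ValueError("polygon needs at least 3 points")
        if not np.all(np.isfinite(self.neck_center)):
            raise ValueError("neck_center must be finite")

    def shapely(self) -> _ShapelyPolygon:
        return _ShapelyPolygon(self.points)


@dataclass
class PeriodicFit:
    """Truncated Fourier fit of dROI on the 2n regular sample angles.

    ``A[k]`` holds A_0..A_n, ``B[k]`` holds B_k with B[0] and B[n] fixed at
    zero (they do not exist in the series).  ``retained_A``/``retained_B``
    flag the terms surviving the pruning; discarded terms reconstruct as
    exactly zero.
    """

    n: int
    A: np.ndarray
    B: np.ndarray
    retained_A: np.ndarray = field(default=None)
    retained_B: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.retained_A is None:
            self.retained_A = np.ones(self.n + 1, dtype=bool)
        if self.retained_B is None:
            self.retained_B = np.zeros(self.n + 1, dtype=bool)
            self.retained_B[1:self.n] = True

    @property
    def angles(self) -> np.ndarray:
        """Sample angles theta_i = (i-1)*pi/n for i = 1..2n."""
        return np.arange(2 * self.n) * np.pi / self.n

    def __call__(self, theta) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        out = np.zeros_like(theta)
        for k in range(self.n + 1):
            if self.retained_A[k] and self.A[k] != 0.0:
                out = out + self.A[k] * np.cos(k * theta)
            if self.retained_B[k] and self.B[k] != 0.0:
                out = out + self.B[k] * np.sin(k * theta)
        return out


@dataclass
class ShapeDescriptors:
    S: float        # length units of the input
    D: float        # % of S
    O: float        # % of S per radian


def sample_dROI(roi: ROIPolygon, n: int = DEFAULT_HARMONICS) -> np.ndarray:
    """Distances from the neck centre to the outline along 2n rays.

    Ray i points at theta_i = (i-1)*pi/n counter-clockwise from +x.  When a
    ray crosses the outline more than once the farthest intersection is
    used (the outer membrane of the head); a ray that misses entirely
    records 0.
    """
    if not np.all(np.isfinite(roi.neck_center)):
        raise ValueError("neck_center must be finite")
    pts = roi.points
    c = roi.neck_center
    reach = 4.0 * (np.abs(pts - c).max() + 1.0)
    ring = LineString(np.vstack([pts, pts[:1]]))
    out = np.zeros(2 * n)
    for i in range(2 * n):
        th = i * np.pi / n
        far = c + reach * np.array([np.cos(th), np.sin(th)])
        hit = ring.intersection(LineString([c, far]))
        if hit.is_empty:
            continue
        dmax = 0.0
        geoms = getattr(hit, "geoms", [hit])
        for g in geoms:
            coords = np.asarray(g.coords)
            d = np.hypot(coords[:, 0] - c[0], coords[:, 1] - c[1]).max()
            dmax = max(dmax, d)
        out[i] = dmax
    return out


def fit_fourier(dROI: np.ndarray, n: int = DEFAULT_HARMONICS) -> PeriodicFit:
    """Exact trigonometric interpolation of the 2n samples.

    A_0 and A_n carry the 1/2n normalization, interior terms 1/n; before
    pruning the reconstruction reproduces dROI at every sample angle to
    machine precision.
    """
    d = np.asarray(dROI, dtype=float)
    if d.shape != (2 * n,):
        raise ValueError(f"expected {2 * n} samples, got {d.shape}")
    th = np.arange(2 * n) * np.pi / n
    A = np.zeros(n + 1)
    B = np.zeros(n + 1)
    A[0] = d.sum() / (2 * n)
    A[n] = (d * np.cos(n * th)).sum() / (2 * n)
    for k in range(1, n):
        A[k] = (d * np.cos(k * th)).sum() / n
        B[k] = (d * np.sin(k * th)).sum() / n
    return PeriodicFit(n=n, A=A, B=B)


def _design_columns(n: int):
    """(label, column) pairs of the trigonometric regressors, A_0 first."""
    th = np.arange(2 * n) * np.pi / n
    cols = [(("A", 0), np.ones(2 * n))]
    for k in range(1, n + 1):
        cols.append((("A", k), np.cos(k * th)))
        if k < n:
            cols.append((("B", k), np.sin(k * th)))
    return cols


def prune_terms(fit: PeriodicFit, dROI: np.ndarray,
                alpha_level: float = 0.1,
                coef_threshold: float = 0.1) -> PeriodicFit:
    """Drop weak harmonics one by one.

    Candidates are the retained non-constant terms whose standardized
    coefficient (coefficient scaled by regressor-to-data standard-deviation
    ratio) is below ``coef_threshold``; the weakest is dropped first, and
    the drop is kept only if an extra-sum-of-squares F-test against the
    current model is non-significant at ``alpha_level``.  A significant
    term is locked in and never reconsidered.  A_0 is always kept.
    """
    d = np.asarray(dROI, dtype=float)
    n = fit.n
    sd_d = d.std()
    cols = dict(_design_columns(n))
    out = PeriodicFit(n=n, A=fit.A.copy(), B=fit.B.copy(),
                      retained_A=fit.retained_A.copy(),
                      retained_B=fit.retained_B.copy())
    if sd_d < 1e-14:            # flat dROI: constant-only model
        out.retained_A[1:] = False
        out.retained_B[:] = False
        return out

    eps = 1e-9 * float(np.sum((d - d.mean()) ** 2) + 1e-30)
    locked: set = set()

    def active_terms():
        terms = []
        for k in range(1, n + 1):
            if out.retained_A[k]:
                terms.append(("A", k))
            if k < n and out.retained_B[k]:
                terms.append(("B", k))
        return terms

    def rss_of(terms):
        X = np.column_stack([cols[("A", 0)]] + [cols[t] for t in terms])
        beta, *_ = np.linalg.lstsq(X, d, rcond=None)
        r = d - X @ beta
        return float(r @ r), X.shape[1]

    while True:
        cands = []
        for t in active_terms():
            if t in locked:
                continue
            coef = out.A[t[1]] if t[0] == "A" else out.B[t[1]]
            std_coef = coef * cols[t].std() / sd_d
            if abs(std_coef) < coef_threshold:
                cands.append((abs(std_coef), t))
        if not cands:
            return out
        _, term = min(cands)
        current = active_terms()
        rss_c, p_c = rss_of(current)
        rss_r, p_r = rss_of([t for t in current if t != term])
        df2 = 2 * n - p_c
        if df2 <= 0 or rss_c < eps:
            # saturated (interpolating) current model: its variance
            # estimate is 0/0, so judge the drop against the restricted
            # model's own residual variance instead
            df2r = 2 * n - p_r
            if rss_r < eps or df2r <= 0:
                significant = False
            else:
                F = (rss_r - rss_c) / (rss_r / df2r)
                significant = _sstats.f.sf(F, 1, df2r) < alpha_level
        else:
            F = (rss_r - rss_c) / (rss_c / df2)
            significant = _sstats.f.sf(F, 1, df2) < alpha_level
        if significant:
            locked.add(term)
        else:
            if term[0] == "A":
                out.retained_A[term[1]] = False
            else:
                out.retained_B[term[1]] = False


def split_SDO(fit: PeriodicFit):
    """Split the pruned fit into S (constant), D (odd harmonics) and O
    (even harmonics); returns ``(S, D(theta), O(theta))`` with the two
    callables evaluating only retained terms."""
    n = fit.n

    def part(parity):
        ks = [k for k in range(1, n + 1) if k % 2 == parity]

        def f(theta):
            theta = np.asarray(theta, dtype=float)
            out = np.zeros_like(theta)
            for k in ks:
                if fit.retained_A[k]:
                    out = out + fit.A[k] * np.cos(k * theta)
                if k < n and fit.retained_B[k]:
                    out = out + fit.B[k] * np.sin(k * theta)
            return out

        def df(theta):
            theta = np.asarray(theta, dtype=float)
            out = np.zeros_like(theta)
            for k in ks:
                if fit.retained_A[k]:
                    out = out - k * fit.A[k] * np.sin(k * theta)
                if k < n and fit.retained_B[k]:
                    out = out + k * fit.B[k] * np.cos(k * theta)
            return out

        f.derivative = df
        return f

    return float(fit.A[0]), part(1), part(0)


def integrate_descriptors(S: float, Dfun, Ofun, nodes: int = 4096,
                          o_derivative: bool = True) -> ShapeDescriptors:
    """Average the selectivity functions into the scalar descriptors.

    D = (1/2pi) Int_0^2pi |D(theta)| dtheta * 100/S  (percent of S)
    O = (1/pi)  Int_0^pi |dO/dtheta| dtheta * 100/S  (percent of S per rad)

    Trapezoidal quadrature on ``nodes`` points (>= 2048).  If ``Ofun`` has
    no analytic ``.derivative``, a spectral-accuracy finite difference on
    the dense grid is used.  ``o_derivative=False`` integrates |O(theta)|
    itself instead.
    """
    if S <= 0:
        raise ValueError("S must be positive")
    nodes = max(int(nodes), 2048)
    thD = np.linspace(0.0, 2.0 * np.pi, nodes)
    D = np.trapezoid(np.abs(Dfun(thD)), thD) / (2.0 * np.pi) * 100.0 / S
    thO = np.linspace(0.0, np.pi, nodes)
    if o_derivative:
        dO = getattr(Ofun, "derivative", None)
        vals = dO(thO) if dO is not None else np.gradient(Ofun(thO), thO)
    else:
        vals = Ofun(thO)
    O = np.trapezoid(np.abs(vals), thO) / np.pi * 100.0 / S
    return ShapeDescriptors(S=float(S), D=float(D), O=float(O))


def descriptors_from_polygon(roi: ROIPolygon, n: int = DEFAULT_HARMONICS,
                             alpha_level: float = 0.1,
                             o_derivative: bool = True) -> ShapeDescriptors:
    """Full pipeline: ray sampling, Fourier fit, pruning, S/D/O split and
    integration."""
    d = sample_dROI(roi, n)
    fit = prune_terms(fit_fourier(d, n), d, alpha_level=alpha_level)
    S, Dfun, Ofun = split_SDO(fit)
    return integrate_descriptors(S, Dfun, Ofun, o_derivative=o_derivative)


def mesh_to_roi(mesh: MembraneMesh) -> ROIPolygon:
    """View a simulation snapshot as an ROI: the contour with the neck
    midpoint as neck centre."""
    neck = mesh.vertices[mesh.roles == NECK]
    if len(neck):
        centre = np.array([0.5 * (neck[:, 0].min() + neck[:, 0].max()),
                           mesh.h_neck])
        limits = np.array([neck[neck[:, 0].argmin()],
                           neck[neck[:, 0].argmax()]])
    else:
        centre = mesh.vertices.mean(axis=0)
        limits = None
    return ROIPolygon(points=mesh.vertices.copy(), neck_center=centre,
                      neck_limits=limits)


def descriptor_series(snapshots, n: int = DEFAULT_HARMONICS,
                      alpha_level: float = 0.1):
    """S, D, O (and polygon area) for a sequence of mesh snapshots.

    Returns a pandas DataFrame with one row per snapshot.
    """
    import pandas as pd

    from .membrane import enclosed_area

    rows = []
    for i, mesh in enumerate(snapshots):
        roi = mesh_to_roi(mesh)
        sd = descriptors_from_polygon(roi, n=n, alpha_level=alpha_level)
        rows.append({"frame": i, "area": enclosed_area(mesh),
                     "S": sd.S, "D": sd.D, "O": sd.O})
    return pd.DataFrame(rows)
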