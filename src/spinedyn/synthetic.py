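"""Synthetic fixtures: ROI polygons with known descriptors, surrogate time
series for the noise classifiers, and power-law samples for the avalanche
estimators.

Every generator is deterministic under a fixed seed, and each output's
ground truth is known analytically from its spec, so the analysis modules
can be tested end to end without microscopy data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .shape import ROIPolygon


@dataclass
class SyntheticShapeSpec:
    """Star-shaped polygon r(theta) about the neck centre.

    ``harmonics`` maps k -> (cos amplitude, sin amplitude); the radial
    function is r(theta) = base_radius + sum_k a_k cos(k theta)
    + b_k sin(k theta), which makes the true Fourier content of dROI known
    exactly.
    """

    base_radius: float = 1.0
    harmonics: dict = field(default_factory=dict)
    resolution: int = 256
    neck_center: tuple = (0.0, 0.0)

    def r(self, theta):
        theta = np.asarray(theta, float)
        out = np.full_like(theta, self.base_radius)
        for k, (a, b) in self.harmonics.items():
            out = out + a * np.cos(k * theta) + b * np.sin(k * theta)
        return out


def make_polygon(spec: SyntheticShapeSpec) -> ROIPolygon:
    """Polygonize the radial function about the neck centre."""
    if spec.resolution < 64:
        raise ValueError("resolution must be at least 64")
    th = np.linspace(0.0, 2.0 * np.pi, spec.resolution, endpoint=False)
    r = spec.r(th)
    if np.any(r <= 0):
        raise ValueError("radial function must be positive everywhere")
    c = np.asarray(spec.neck_center, float)
    pts = np.stack([c[0] + r * np.cos(th), c[1] + r * np.sin(th)], axis=1)
    return ROIPolygon(points=pts, neck_center=c.copy())


@dataclass
class SurrogateSeriesSpec:
    """Surrogate scalar series: white noise, random walk, AR(1) or
    fractionally integrated (ARFIMA-type) noise."""

    kind: str = "white"
    n: int = 1000
    sigma: float = 1.0
    phi: float = 0.0            # AR(1) coefficient (ar1/arfima kinds)
    theta: float = 0.0          # MA(1) coefficient (arfima kind)
    d: float = 0.0              # fractional integration order (arfima)
    seed: int = 0

    def __post_init__(self):
        if self.kind not in {"white", "random_walk", "ar1", "arfima"}:
            raise ValueError(f"unknown series kind {self.kind!r}")
        if self.n < 30:
            raise ValueError("n must be at least 30")
        if self.kind == "arfima" and not (0.0 <= self.d < 0.5):
            raise ValueError("arfima requires 0 <= d < 0.5")


def fractional_integration_weights(d: float, n: int) -> np.ndarray:
    """Binomial weights psi_j of (1-L)^{-d}, j = 0..n-1."""
    w = np.empty(n)
    w[0] = 1.0
    for j in range(1, n):
        w[j] = w[j - 1] * (j - 1.0 + d) / j
    return w


def make_series(spec: SurrogateSeriesSpec, burn: int = 500) -> np.ndarray:
    """Generate the surrogate series (seeded).

    ``random_walk`` is by construction the cumulative sum of the ``white``
    series drawn with the same seed/sigma/n.  The ``arfima`` kind applies
    the truncated (1-L)^{-d} weights to ARMA(phi, theta) innovations and
    discards a burn-in so the start-up transient is gone.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "white":
        return rng.normal(0.0, spec.sigma, spec.n)
    if spec.kind == "random_walk":
        return np.cumsum(rng.normal(0.0, spec.sigma, spec.n))
    e = rng.normal(0.0, spec.sigma, spec.n + burn)
    w = lfilter([1.0, spec.theta], [1.0, -spec.phi], e)
    if spec.kind == "ar1":
        return w[burn:]
    psi = fractional_integration_weights(spec.d, spec.n + burn)
    x = lfilter(psi, [1.0], w)
    return x[burn:]


def sample_power_law(alpha: float, x_min: float, n: int,
                     seed: int | np.random.Generator = 0) -> np.ndarray:
    """Inverse-transform samples of a continuous power law p(x) ~ x^-alpha
    on [x_min, inf): x = x_min * (1 - u)^(-1/(alpha-1))."""
    if alpha <= 1:
        raise ValueError("alpha must exceed 1")
    if x_min <= 0:
        raise ValueError("x_min must be positive")
    rng = seed if hasattr(seed, "random") else np.random.default_rng(seed)
    u = rng.random(n)
    return x_min * (1.0 - u) ** (-1.0 / (alpha - 1.0))
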