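"""Avalanche statistics and power-law exponents of actin polymerization.

The total barbed-end count across foci rises from and returns to zero in
bursts.  A maximal run of strictly positive counts is an *avalanche*: its
duration is the run length (steps, also reported in seconds), its size the
summed barbed-end count over the run (= polymerization events, since every
barbed end adds one monomer per step), and eta the quiet gap to the
previous avalanche.  In the feedback model the size and lifetime
distributions follow power laws whose exponents are estimated with the
discrete-sample continuous MLE

    alpha = 1 + n / sum(ln(x_i / x_min)),   se = (alpha - 1) / sqrt(n),

the standard closed form for a Pareto tail.  The non-feedback control
produces visibly curved log-log distributions, which the linearity screen
(R^2 of the log-log binned fit) picks up.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .timeseries import fit_arfima


@dataclass
class Avalanche:
    start_step: int
    duration_steps: int
    size: int
    eta_prev: int | None        # gap (steps) since the previous avalanche
    truncated: bool = False     # touches the start or end of the record

    def duration_seconds(self, dt: float) -> float:
        return self.duration_steps * dt


@dataclass
class PowerLawFit:
    exponent: float
    x_min: float
    n_tail: int

    @property
    def se(self) -> float:
        return (self.exponent - 1.0) / np.sqrt(self.n_tail)


def extract_avalanches(total_B) -> list[Avalanche]:
    """Maximal runs of nonzero total barbed ends, with sizes, durations and
    inter-avalanche gaps; runs touching either end of the record are
    flagged truncated."""
    b = np.asarray(total_B)
    if b.ndim != 1:
        raise ValueError("total_B must be one-dimensional")
    if np.any(b < 0):
        raise ValueError("total_B must be non-negative")
    n = len(b)
    active = b > 0
    if not active.any():
        return []
    edges = np.diff(active.astype(np.int8))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)     # exclusive
    if active[0]:
        starts.insert(0, 0)
    if active[-1]:
        ends.append(n)
    out = []
    prev_end = None
    for s, e in zip(starts, ends):
        out.append(Avalanche(
            start_step=int(s), duration_steps=int(e - s),
            size=int(b[s:e].sum()),
            eta_prev=None if prev_end is None else int(s - prev_end),
            truncated=(s == 0 or e == n)))
        prev_end = e
    return out


def newman_mle(samples, x_min: float) -> PowerLawFit:
    """Continuous power-law exponent MLE for the tail x >= x_min."""
    x = np.asarray(samples, float)
    if x_min <= 0:
        raise ValueError("x_min must be positive")
    if np.any(x < x_min):
        raise ValueError("all samples must be >= x_min")
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 tail samples")
    s = float(np.log(x / x_min).sum())
    if s <= 0:
        raise ValueError("all samples equal x_min: exponent diverges")
    return PowerLawFit(exponent=1.0 + n / s, x_min=float(x_min), n_tail=n)


def select_xmin_ks(samples, x_min_grid=None) -> float:
    """Kolmogorov-Smirnov scan for the power-law cutoff x_min.

    For every candidate cutoff the tail exponent is fitted by the MLE and
    the KS distance between the fitted Pareto CDF and the empirical tail
    CDF is computed; the cutoff minimizing the distance is returned
    (candidates leaving fewer than 10 tail samples are skipped).
    """
    x = np.sort(np.asarray(samples, float))
    if x_min_grid is None:
        x_min_grid = np.unique(x)[:-9]
    best = None
    for xm in x_min_grid:
        tail = x[x >= xm]
        n = len(tail)
        if n < 10:
            continue
        s = float(np.log(tail / xm).sum())
        if s <= 0:
            continue
        alpha = 1.0 + n / s
        emp = np.arange(1, n + 1) / n
        model = 1.0 - (tail / xm) ** (1.0 - alpha)
        ks = float(np.abs(emp - model).max())
        if best is None or ks < best[0]:
            best = (ks, float(xm))
    if best is None:
        raise ValueError("no viable x_min candidate")
    return best[1]


def loglog_distribution(samples, n_bins: int = 20):
    """Logarithmically binned probability density (per unit x).

    Returns (bin centres, densities); empty bins are dropped.
    """
    x = np.asarray(samples, float)
    if x.size == 0:
        raise ValueError("no samples")
    if np.any(x <= 0):
        raise ValueError("samples must be positive")
    lo, hi = x.min(), x.max()
    if lo == hi:
        return np.array([lo]), np.array([1.0 / max(lo * 1e-6, 1e-12)])
    edges = np.geomspace(lo, hi * (1 + 1e-12), n_bins + 1)
    counts, edges = np.histogram(x, bins=edges)
    widths = np.diff(edges)
    dens = counts / (x.size * widths)
    centres = np.sqrt(edges[:-1] * edges[1:])
    keep = counts > 0
    return centres[keep], dens[keep]


def loglog_linearity(samples, n_bins: int = 20, min_count: int = 10):
    """R^2 of a straight-line fit to the log-log binned density: the screen
    separating power-law (feedback) from curved (non-feedback) spectra.

    Bins holding fewer than ``min_count`` samples are excluded — their
    Poisson scatter is strongly asymmetric on the log scale and would bias
    both the slope and the R^2.
    """
    x = np.asarray(samples, float)
    if x.size == 0:
        raise ValueError("no samples")
    lo, hi = x.min(), x.max()
    edges = np.geomspace(lo, hi * (1 + 1e-12), n_bins + 1)
    counts, edges = np.histogram(x, bins=edges)
    dens = counts / (x.size * np.diff(edges))
    cx = np.sqrt(edges[:-1] * edges[1:])
    keep = counts >= min_count
    cx, cy = cx[keep], dens[keep]
    if len(cx) < 3:
        raise ValueError("too few occupied bins for a linearity screen")
    lx, ly = np.log10(cx), np.log10(cy)
    slope, intercept = np.polyfit(lx, ly, 1)
    pred = slope * lx + intercept
    ss_res = float(np.sum((ly - pred) ** 2))
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return r2, slope


@dataclass
class CriticalityReport:
    n_avalanches: int
    size_fit: PowerLawFit
    lifetime_fit: PowerLawFit
    size_r2: float
    lifetime_r2: float
    mean_alpha: float | None        # mean ARFIMA 1/f exponent of the runs
    two_minus_alpha: float | None
    low_count_warning: bool


def pooled_avalanches(trajectories, include_truncated: bool = False):
    """All avalanches of the given trajectories (total-B series) pooled."""
    pooled = []
    for traj in trajectories:
        b = getattr(traj, "total_B", traj)
        for av in extract_avalanches(b):
            if include_truncated or not av.truncated:
                pooled.append(av)
    return pooled


def criticality_report(trajectories, x_min: float | str | None = None,
                       sampled_series: list | None = None
                       ) -> CriticalityReport:
    """Pooled avalanche exponents of replicate runs, the log-log linearity
    screens, and (when 10-s-sampled area series are supplied) the
    2 - alpha consistency check against the mean ARFIMA 1/f exponent.

    ``x_min`` may be a number (fixed cutoff), ``"ks"`` (KS-scan selection
    per tail) or None (minimum observed value).
    """
    pooled = pooled_avalanches(trajectories)
    if not pooled:
        raise ValueError("no avalanches in the supplied trajectories")
    sizes = np.array([a.size for a in pooled], float)
    lifes = np.array([a.duration_steps for a in pooled], float)

    def fit(vals):
        if x_min == "ks":
            xm = select_xmin_ks(vals)
        elif x_min is None:
            xm = vals.min()
        else:
            xm = float(x_min)
        return newman_mle(vals[vals >= xm], xm)

    sfit = fit(sizes)
    lfit = fit(lifes)
    try:
        s_r2, _ = loglog_linearity(sizes)
        l_r2, _ = loglog_linearity(lifes)
    except ValueError:          # too few samples for the screen
        s_r2 = l_r2 = float("nan")
    mean_alpha = None
    consistency = None
    if sampled_series:
        alphas = [2.0 * fit_arfima(s).d_frac for s in sampled_series]
        mean_alpha = float(np.mean(alphas))
        consistency = 2.0 - mean_alpha
    return CriticalityReport(
        n_avalanches=len(pooled), size_fit=sfit, lifetime_fit=lfit,
        size_r2=s_r2, lifetime_r2=l_r2, mean_alpha=mean_alpha,
        two_minus_alpha=consistency, low_count_warning=len(pooled) < 100)
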