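"""Tendency and 1/f-noise analysis of spine-area time series.

Two pipelines:

* ARIMA tendency classification — all eight ARIMA(p,d,q) orders with
  p,d,q in {0,1} are fitted by maximum likelihood; the lowest-AIC model
  whose residuals are stationary (augmented Dickey-Fuller, p < 0.01) and
  free of ACF/PACF spikes in the first ten lags is selected and labelled
  (WN white noise, RW random walk, AR mean-reverting, ES exponential
  smoothing).

* the Wagenmakers-style 1/f test — 1/f noise sits between white noise
  (spectral exponent alpha = 0, ARIMA d = 0) and a random walk (alpha = 2,
  d = 1), so fractional d is estimated by an ARFIMA(1,d,1) fit; the series
  is called 1/f if d is significantly above zero and the ARFIMA AIC beats
  an ARIMA(1,0,1)'s.  The spectral exponent follows as alpha = 2d.

The ARFIMA(1,d,1) estimator is an approximate (conditional-sum-of-squares)
Gaussian MLE: the demeaned series is fractionally differenced with the
binomial weights of (1-L)^d truncated at min(N, 100) lags, and an
ARMA(1,1) CSS likelihood is maximized jointly over (d, ar1, ma1).  The
competing ARIMA(1,0,1) AIC for the 1/f decision is computed with the same
likelihood machinery so the comparison is on one scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize as _opt, signal as _signal, stats as _sstats
from statsmodels.tsa.arima.model import ARIMA as _SmARIMA
from statsmodels.tsa.stattools import acf as _sm_acf, adfuller as _adfuller
from statsmodels.tsa.stattools import pacf as _sm_pacf

ORDER_LABELS = {(0, 0, 0): "WN", (0, 1, 0): "RW",
                (1, 0, 0): "AR", (0, 1, 1): "ES"}


def cv(series) -> float:
    """Coefficient of variation std/mean (population std)."""
    x = np.asarray(series, float)
    m = x.mean()
    if m == 0:
        raise ValueError("cv undefined for zero-mean series")
    return float(x.std() / m)


def pearson(x, y) -> float:
    """Pearson linear correlation coefficient."""
    return float(_sstats.pearsonr(np.asarray(x, float),
                                  np.asarray(y, float)).statistic)


# ---------------------------------------------------------------------------
# ARIMA tendency classification
# ---------------------------------------------------------------------------

@dataclass
class ArimaFit:
    order: tuple
    ar: float | None
    ma: float | None
    intercept: float | None
    aic: float
    residuals: np.ndarray
    converged: bool = True

    @property
    def label(self) -> str:
        return ORDER_LABELS.get(self.order, str(self.order))


def fit_arima(series, order) -> ArimaFit:
    """Maximum-likelihood ARIMA(p,d,q) fit (statsmodels), with an intercept
    for d = 0 models; AIC counts every estimated parameter including the
    innovation variance."""
    x = np.asarray(series, float)
    if len(x) < 20:
        raise ValueError("series too short for ARIMA fitting (need >= 20)")
    if not np.all(np.isfinite(x)):
        raise ValueError("series must be finite")
    if x.std() < 1e-14:
        raise ValueError("degenerate constant series")
    p, d, q = order
    model = _SmARIMA(x, order=order, trend="c" if d == 0 else "n")
    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit()
        params = res.params
        conv = bool(getattr(res, "mle_retvals", {}).get("converged", True))
        return ArimaFit(
            order=tuple(order),
            ar=float(params[res.param_names.index("ar.L1")]) if p else None,
            ma=float(params[res.param_names.index("ma.L1")]) if q else None,
            intercept=(float(params[res.param_names.index("const")])
                       if d == 0 else None),
            aic=float(res.aic),
            residuals=np.asarray(res.resid)[d:],
            converged=conv)
    except (np.linalg.LinAlgError, ValueError) as err:
        raise RuntimeError(f"ARIMA{tuple(order)} failed: {err}") from err


@dataclass
class ArimaSelection:
    best: ArimaFit
    label: str
    residual_warning: bool
    candidates: list = field(default_factory=list)


def _residuals_clean(resid, adf_p: float = 0.01, n_lags: int = 10) -> bool:
    """Stationary residuals without ACF/PACF spikes in the first lags."""
    r = np.asarray(resid, float)
    if r.std() < 1e-14:
        return False
    try:
        p = adf_test(r)
    except ValueError:
        return False
    if p >= adf_p:
        return False
    lags = min(n_lags, len(r) // 2 - 1)
    band = 1.96 / np.sqrt(len(r))
    a = _sm_acf(r, nlags=lags, fft=True)[1:]
    pa = _sm_pacf(r, nlags=lags, method="ywm")[1:]
    return bool(np.all(np.abs(a) <= band) and np.all(np.abs(pa) <= band))


def _fit_orders(series, orders):
    fits = []
    for order in orders:
        try:
            f = fit_arima(series, order)
        except (RuntimeError, ValueError):
            continue
        if f.converged and np.isfinite(f.aic):
            fits.append(f)
    return fits


def select_arima(series) -> ArimaSelection:
    """Two-stage tendency selection in the auto-ARIMA spirit.

    Stage 1: the differencing order d in {0, 1} is fixed by a KPSS
    unit-root pretest (d = 1 if stationarity is rejected at 0.05), then the
    four (p, q) candidates at that d compete by AIC.  Stage 2 (only if the
    winner's residuals are non-stationary by ADF or show ACF/PACF spikes
    beyond the 95% band in the first ten lags): all eight orders compete by
    AIC among residual-clean fits.  If nothing is clean the overall AIC
    minimum is returned flagged with ``residual_warning``.
    """
    x = np.asarray(series, float)
    import warnings

    from statsmodels.tsa.stattools import kpss as _kpss

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            kpss_p = float(_kpss(x, regression="c", nlags="auto")[1])
        except (ValueError, OverflowError):
            kpss_p = 0.0
    d = 1 if kpss_p < 0.05 else 0
    stage1 = _fit_orders(x, [(p, d, q) for p in (0, 1) for q in (0, 1)])
    if stage1:
        best = min(stage1, key=lambda f: f.aic)
        if _residuals_clean(best.residuals):
            return ArimaSelection(best=best, label=best.label,
                                  residual_warning=False, candidates=stage1)
    fits = _fit_orders(x, [(p, d_, q) for p in (0, 1) for d_ in (0, 1)
                           for q in (0, 1)])
    if not fits:
        raise RuntimeError("no ARIMA candidate converged")
    clean = [f for f in fits if _residuals_clean(f.residuals)]
    if clean:
        best = min(clean, key=lambda f: f.aic)
        return ArimaSelection(best=best, label=best.label,
                              residual_warning=False, candidates=fits)
    best = min(fits, key=lambda f: f.aic)
    return ArimaSelection(best=best, label=best.label,
                          residual_warning=True, candidates=fits)


def adf_test(series, lag: int = 0) -> float:
    """Augmented Dickey-Fuller p-value, trend regression, fixed lag."""
    x = np.asarray(series, float)
    if len(x) < 10:
        raise ValueError("series too short for the ADF test")
    if x.std() < 1e-14:
        raise ValueError("ADF undefined for a constant series")
    return float(_adfuller(x, maxlag=lag, regression="ct", autolag=None)[1])


def acf_with_bands(series, frac_lags: float = 0.1):
    """Sample autocorrelation for lags 0..floor(frac_lags*N) together with
    the white-noise 95% band +-1.96/sqrt(N)."""
    x = np.asarray(series, float)
    if len(x) < 20:
        raise ValueError("series too short")
    if x.std() < 1e-14:
        raise ValueError("zero-variance series")
    n_lags = max(int(np.floor(frac_lags * len(x))), 1)
    vals = _sm_acf(x, nlags=n_lags, fft=True)
    return vals, 1.96 / np.sqrt(len(x))


# ---------------------------------------------------------------------------
# ARFIMA(1,d,1) and the 1/f decision
# ---------------------------------------------------------------------------

MAX_FRACDIFF_LAGS = 100


def fracdiff_weights(d: float, n: int) -> np.ndarray:
    """Binomial expansion weights of (1-L)^d, pi_0..pi_{n-1}."""
    w = np.empty(n)
    w[0] = 1.0
    for j in range(1, n):
        w[j] = w[j - 1] * (j - 1.0 - d) / j
    return w


def _css_loglik(x: np.ndarray, d: float, ar: float, ma: float) -> float:
    """Gaussian conditional-sum-of-squares log-likelihood of ARFIMA(1,d,1)
    for the demeaned series ``x`` (sigma^2 profiled out)."""
    n = len(x)
    w = _signal.lfilter(fracdiff_weights(d, min(n, MAX_FRACDIFF_LAGS)),
                        [1.0], x)
    e = _signal.lfilter([1.0, -ar], [1.0, ma], w)
    s2 = float(e @ e) / n
    if not np.isfinite(s2) or s2 <= 0:
        return -np.inf
    return -0.5 * n * (np.log(2.0 * np.pi * s2) + 1.0)


@dataclass
class ArfimaFit:
    d_frac: float
    ar1: float
    ma1: float
    aic: float
    d_se: float
    loglik: float
    n: int
    residual_adf_p: float | None = None


def _fit_css(x: np.ndarray, with_d: bool):
    """Maximize the CSS likelihood over (d, ar, ma) or (ar, ma) at d=0."""
    bounds_arma = [(-0.985, 0.985), (-0.985, 0.985)]
    best = None
    starts = ([(dd, p0, q0) for dd in (0.05, 0.25, 0.4)
               for p0, q0 in ((0.2, 0.0), (-0.2, 0.2))] if with_d
              else [(0.0, p0, q0) for p0, q0 in
                    ((0.2, 0.0), (-0.2, 0.2), (0.6, -0.3))])
    for d0, p0, q0 in starts:
        if with_d:
            fun = lambda th: -_css_loglik(x, th[0], th[1], th[2])
            x0, bounds = [d0, p0, q0], [(0.0, 0.4999)] + bounds_arma
        else:
            fun = lambda th: -_css_loglik(x, 0.0, th[0], th[1])
            x0, bounds = [p0, q0], bounds_arma
        res = _opt.minimize(fun, x0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    return best


def fit_arfima(series) -> ArfimaFit:
    """Approximate ML fit of ARFIMA(1,d,1); see the module docstring.

    The standard error of d comes from the observed information (numerical
    Hessian of the CSS log-likelihood at the optimum), falling back to the
    asymptotic sqrt(6/(pi^2 N)) when the Hessian is not positive definite.
    """
    x = np.asarray(series, float)
    if len(x) < 60:
        raise ValueError("series too short for ARFIMA fitting (need >= 60)")
    if not np.all(np.isfinite(x)):
        raise ValueError("series must be finite")
    if x.std() < 1e-14:
        raise ValueError("degenerate constant series")
    xc = x - x.mean()
    res = _fit_css(xc, with_d=True)
    if not np.isfinite(res.fun):
        raise RuntimeError("ARFIMA CSS optimization failed")
    d, ar, ma = res.x
    ll = -float(res.fun)
    # observed information for se(d)
    se = np.sqrt(6.0 / (np.pi ** 2 * len(x)))
    h = 1e-4

    def nll(th):
        return -_css_loglik(xc, th[0], th[1], th[2])

    try:
        k = 3
        H = np.zeros((k, k))
        for i in range(k):
            for j in range(i, k):
                ei = np.eye(k)[i] * h
                ej = np.eye(k)[j] * h
                H[i, j] = H[j, i] = (
                    nll(res.x + ei + ej) - nll(res.x + ei - ej)
                    - nll(res.x - ei + ej) + nll(res.x - ei - ej)
                ) / (4 * h * h)
        cov = np.linalg.inv(H)
        if cov[0, 0] > 0:
            se = float(np.sqrt(cov[0, 0]))
    except np.linalg.LinAlgError:
        pass
    # parameters: d, ar, ma, mean, sigma^2
    aic = 2.0 * 5 - 2.0 * ll
    return ArfimaFit(d_frac=float(d), ar1=float(ar), ma1=float(ma),
                     aic=float(aic), d_se=se, loglik=ll, n=len(x))


def fit_arma101_css(series) -> ArfimaFit:
    """ARIMA(1,0,1) fitted with the same CSS likelihood (d fixed at 0),
    giving an AIC directly comparable to :func:`fit_arfima`'s."""
    x = np.asarray(series, float)
    xc = x - x.mean()
    res = _fit_css(xc, with_d=False)
    ll = -float(res.fun)
    # parameters: ar, ma, mean, sigma^2
    return ArfimaFit(d_frac=0.0, ar1=float(res.x[0]), ma1=float(res.x[1]),
                     aic=2.0 * 4 - 2.0 * ll, d_se=np.nan, loglik=ll,
                     n=len(x))


@dataclass
class NoiseVerdict:
    is_one_over_f: bool
    alpha: float
    d_frac: float
    d_se: float
    aic_arfima: float
    aic_arima101: float
    arfima: ArfimaFit
    arima101: ArfimaFit


def detect_one_over_f(series, significance: float = 0.05) -> NoiseVerdict:
    """1/f decision: d significantly > 0 (one-sided z-test) AND the
    ARFIMA(1,d,1) AIC below the ARIMA(1,0,1) AIC.  alpha = 2d.

    Residuals of both fits are ADF-tested and the p-values attached to the
    returned fit objects.
    """
    x = np.asarray(series, float)
    arf = fit_arfima(x)
    arma = fit_arma101_css(x)
    z_crit = _sstats.norm.ppf(1.0 - significance)
    d_significant = arf.d_frac / arf.d_se > z_crit
    preferred = arf.aic < arma.aic
    for f in (arf, arma):
        xc = x - x.mean()
        w = _signal.lfilter(
            fracdiff_weights(f.d_frac, min(len(x), MAX_FRACDIFF_LAGS)),
            [1.0], xc)
        resid = _signal.lfilter([1.0, -f.ar1], [1.0, f.ma1], w)
        try:
            f.residual_adf_p = adf_test(resid)
        except ValueError:
            f.residual_adf_p = None
    return NoiseVerdict(is_one_over_f=bool(d_significant and preferred),
                        alpha=2.0 * arf.d_frac, d_frac=arf.d_frac,
                        d_se=arf.d_se, aic_arfima=arf.aic,
                        aic_arima101=arma.aic, arfima=arf, arima101=arma)
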