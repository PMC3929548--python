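"""Vector-autoregression estimation and time-domain Granger causality.

The estimator follows the classical covariance route: lagged covariance
matrices Gamma(k) = E[w_t w_{t-k}^T] are estimated with the biased (1/T)
normalization, regression coefficients solve the block-Toeplitz Yule-Walker
system, the regression order is chosen by BIC, and Granger causality (GC)
is the log-ratio of residual variances between the auto regression (AR,
excluding the candidate driver) and the joint regression (JR, including
it):

    F_{y->x} = ln( var(eps_x | AR) / var(eps_x | JR) ).

For m > 2 channels the conditional GC F_{j->i} compares the full
m-channel joint fit against the (m-1)-channel fit that omits channel j,
so influences mediated entirely by the remaining channels yield F = 0.
Under the null of no coupling, T * F_hat is asymptotically chi^2 with p
degrees of freedom (p = regression order), which provides the
significance threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats


class EstimationError(RuntimeError):
    """Degenerate input or unrecoverable numerical failure."""


@dataclass
class TimeSeriesSet:
    """Uniformly sampled multichannel series; data is (T, m)."""

    data: np.ndarray
    fs: float = 1.0  # kHz
    channel_labels: Optional[Sequence] = None

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.ndim != 2:
            raise EstimationError("data must be a (T, m) array")
        if self.channel_labels is None:
            self.channel_labels = list(range(self.data.shape[1]))

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


@dataclass
class VarModelFit:
    order: int
    coefficients: np.ndarray        # (p, m, m), lag-u block maps x_{t-u} -> x_t
    residuals: np.ndarray           # (T - p, m)
    noise_cov: np.ndarray           # (m, m) residual sample covariance
    excluded_channel: Optional[int] = None
    bic: float = float("nan")
    channel_labels: Optional[Sequence] = None


@dataclass
class GcMatrix:
    """values[j, i] = F_{j->i}; diagonal is identically zero."""

    values: np.ndarray
    order: int
    n_samples: int
    mode: str = "voltage"
    conditional: bool = True
    bic_curve: Optional[np.ndarray] = None

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    def offdiag_values(self) -> np.ndarray:
        m = self.n_channels
        return self.values[~np.eye(m, dtype=bool)]


# ---------------------------------------------------------------------------

def demean(series) -> TimeSeriesSet:
    """Subtract each channel's sample mean; flags constant channels."""
    ts = series if isinstance(series, TimeSeriesSet) else TimeSeriesSet(series)
    if ts.n_samples < 2:
        raise EstimationError("need at least two samples")
    sd = ts.data.std(axis=0)
    if np.any(sd == 0):
        bad = np.where(sd == 0)[0].tolist()
        raise EstimationError(f"constant channel(s) {bad}: GC undefined")
    out = ts.data - ts.data.mean(axis=0)
    return TimeSeriesSet(out, fs=ts.fs, channel_labels=list(ts.channel_labels))


def estimate_covariances(series, max_lag: int) -> np.ndarray:
    """Lagged covariances Gamma(k) = E[w_t w_{t-k}^T], k = 0..max_lag,
    with the biased 1/T normalization (guarantees a PSD block-Toeplitz
    system).  Returns an array of shape (max_lag+1, m, m)."""
    ts = series if isinstance(series, TimeSeriesSet) else TimeSeriesSet(series)
    X = ts.data
    T, m = X.shape
    if max_lag >= T:
        raise EstimationError("max_lag must be smaller than the series length")
    G = np.empty((max_lag + 1, m, m))
    for k in range(max_lag + 1):
        G[k] = X[k:].T @ X[: T - k] / T
    G[0] = 0.5 * (G[0] + G[0].T)
    return G


def _yule_walker_solve(G: np.ndarray, p: int) -> np.ndarray:
    """Solve the order-p block Yule-Walker system built from Gamma(0..p).

    Returns coefficients A of shape (p, m, m) satisfying
    Gamma(v) = sum_u A_u Gamma(v-u), v = 1..p.  Ill-conditioned systems get
    one documented ridge retry before failing.
    """
    m = G.shape[1]
    R = np.empty((m * p, m * p))
    for u in range(p):
        for v in range(p):
            k = v - u
            R[u * m:(u + 1) * m, v * m:(v + 1) * m] = G[k] if k >= 0 else G[-k].T
    C = np.concatenate([G[v + 1].T for v in range(p)], axis=0)  # (mp, m)
    try:
        sol = np.linalg.solve(R, C)
        if not np.all(np.isfinite(sol)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        jitter = 1e-8 * np.trace(R) / (m * p)
        warnings.warn("singular Yule-Walker system; retrying with ridge "
                      f"jitter {jitter:.3e}", RuntimeWarning, stacklevel=2)
        try:
            sol = np.linalg.solve(R + jitter * np.eye(m * p), C)
        except np.linalg.LinAlgError as exc:
            raise EstimationError("Yule-Walker system is singular") from exc
        if not np.all(np.isfinite(sol)):
            raise EstimationError("Yule-Walker solution is non-finite")
    # sol stacks A_u^T blocks; A[u] = sol[u*m:(u+1)*m].T
    return np.stack([sol[u * m:(u + 1) * m].T for u in range(p)])


def _yw_implied_noise_cov(G: np.ndarray, A: np.ndarray) -> np.ndarray:
    """Residual covariance implied by the Yule-Walker identity
    Sigma = Gamma(0) - sum_u A_u Gamma(u)^T (used for fast BIC scans)."""
    S = G[0].copy()
    for u in range(A.shape[0]):
        S -= A[u] @ G[u + 1].T
    return 0.5 * (S + S.T)


def _residual_pass(X: np.ndarray, A: np.ndarray) -> np.ndarray:
    p = A.shape[0]
    T = X.shape[0]
    E = X[p:].copy()
    for u in range(p):
        E -= X[p - 1 - u:T - 1 - u] @ A[u].T
    return E


def fit_var_yule_walker(series, order: int,
                        exclude: Optional[int] = None) -> VarModelFit:
    """Fit a VAR(order) by Yule-Walker; optionally drop one channel first
    (the conditional AR model that omits the candidate driver)."""
    if order < 1:
        raise EstimationError("order must be >= 1")
    ts = demean(series)
    X = ts.data
    labels = list(ts.channel_labels)
    if exclude is not None:
        keep = [c for c in range(X.shape[1]) if c != exclude]
        if not keep:
            raise EstimationError("cannot exclude the only channel")
        X = X[:, keep]
        labels = [labels[c] for c in keep]
    T, m = X.shape
    if T <= m * order + 1:
        raise EstimationError("series too short for the requested order")
    G = estimate_covariances(TimeSeriesSet(X, fs=ts.fs), order)
    A = _yule_walker_solve(G, order)
    E = _residual_pass(X, A)
    Sigma = E.T @ E / E.shape[0]
    Tp = T - order
    sign, logdet = np.linalg.slogdet(Sigma)
    bic = (logdet if sign > 0 else np.inf) + order * m * m * np.log(Tp) / Tp
    return VarModelFit(order=order, coefficients=A, residuals=E,
                       noise_cov=Sigma, excluded_channel=exclude, bic=bic,
                       channel_labels=labels)


def select_order_bic(series, max_order: int = 30):
    """BIC order selection for the full joint VAR.

    BIC(p) = ln det Sigma_p + p m^2 ln(T')/T' with T' = T - p; the noise
    covariance in the scan comes from the Yule-Walker identity (no residual
    pass per order).  Returns ``(p_star, bic_curve)``; ties break toward
    smaller p.
    """
    if max_order < 1:
        raise EstimationError("max_order must be >= 1")
    ts = demean(series)
    X = ts.data
    T, m = X.shape
    if T <= m * max_order + 1:
        raise EstimationError("series too short for max_order")
    G = estimate_covariances(ts, max_order)
    bic = np.full(max_order, np.inf)
    for p in range(1, max_order + 1):
        try:
            A = _yule_walker_solve(G[: p + 1], p)
        except EstimationError:
            continue
        Sigma = _yw_implied_noise_cov(G[: p + 1], A)
        sign, logdet = np.linalg.slogdet(Sigma)
        if sign <= 0:
            continue
        Tp = T - p
        bic[p - 1] = logdet + p * m * m * np.log(Tp) / Tp
    if not np.any(np.isfinite(bic)):
        raise EstimationError("all candidate orders produced singular fits")
    p_star = int(np.argmin(bic)) + 1
    return p_star, bic


_NEG_CLIP = 1e-10


def _gc_from_vars(var_ar: float, var_jr: float) -> float:
    if var_jr <= 0 or var_ar <= 0:
        raise EstimationError("zero residual variance: degenerate channel")
    f = float(np.log(var_ar / var_jr))
    if f < 0:
        if f > -_NEG_CLIP:
            f = 0.0
        else:
            warnings.warn(f"negative GC estimate {f:.3e} clipped to 0 "
                          "(model misspecification?)", RuntimeWarning,
                          stacklevel=3)
            f = 0.0
    return f


def pairwise_gc(x, y, order: int):
    """Bivariate GC between two equal-length channels.

    Returns ``(F_yx, F_xy)``: the GC from y to x and from x to y, each the
    log-ratio of AR to JR residual variances at the given order.
    """
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if x.shape != y.shape:
        raise EstimationError("x and y must have equal length")
    ar_x = fit_var_yule_walker(x[:, None], order)
    ar_y = fit_var_yule_walker(y[:, None], order)
    jr = fit_var_yule_walker(np.column_stack([x, y]), order)
    F_yx = _gc_from_vars(ar_x.noise_cov[0, 0], jr.noise_cov[0, 0])
    F_xy = _gc_from_vars(ar_y.noise_cov[0, 0], jr.noise_cov[1, 1])
    return F_yx, F_xy


def conditional_gc_matrix(series, order: Optional[int] = None,
                          max_order: int = 30, mode: str = "voltage"):
    """Conditional GC for all ordered channel pairs.

    One full m-channel joint fit supplies the JR residual variances; for
    each candidate driver j a fresh (m-1)-channel fit excluding j supplies
    the conditional AR variances, and

        F[j, i] = ln( sigma^2_{AR, i | -j} / sigma^2_{JR, i} ).

    If ``order`` is None it is selected once by BIC on the full model and
    reused for every conditional fit.  Returns ``(GcMatrix, VarModelFit)``
    with the full joint fit (whose residuals feed the STC diagnostics).
    """
    ts = demean(series)
    m = ts.n_channels
    if m < 2:
        raise EstimationError("need at least two channels")
    bic_curve = None
    if order is None:
        order, bic_curve = select_order_bic(ts, max_order)
    full = fit_var_yule_walker(ts, order)
    sig_jr = np.diag(full.noise_cov)
    F = np.zeros((m, m))
    for j in range(m):
        sub = fit_var_yule_walker(ts, order, exclude=j)
        keep = [c for c in range(m) if c != j]
        sig_ar = np.diag(sub.noise_cov)
        for pos, i in enumerate(keep):
            F[j, i] = _gc_from_vars(sig_ar[pos], sig_jr[i])
    gc = GcMatrix(values=F, order=order, n_samples=ts.n_samples, mode=mode,
                  conditional=True, bic_curve=bic_curve)
    return gc, full


def gc_significance_threshold(gc: GcMatrix, alpha: float = 0.01,
                              bonferroni: bool = False) -> float:
    """GC threshold from the asymptotic null T*F ~ chi^2_p.

    With ``bonferroni`` the level is divided by the m(m-1) ordered pairs.
    """
    if not 0 < alpha < 1:
        raise EstimationError("alpha must lie in (0, 1)")
    a = alpha
    if bonferroni:
        m = gc.n_channels
        a = alpha / (m * (m - 1))
    return float(stats.chi2.ppf(1 - a, df=gc.order) / gc.n_samples)


def gc_standard_error(F: float, order: int, n_samples: int) -> float:
    """Asymptotic standard error of a GC estimate: T*F_hat is (non)central
    chi^2 with p dof and noncentrality T*F, so
    SD(F_hat) = sqrt(2p + 4*T*F) / T."""
    return float(np.sqrt(2 * order + 4 * n_samples * max(F, 0.0)) / n_samples)
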