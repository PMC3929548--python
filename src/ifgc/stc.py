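"""Spike-triggered correlation (STC) diagnostics.

These operations explain *why* voltage-based Granger causality recovers
synaptic wiring in integrate-and-fire networks:

* the STC of a raw voltage on a neighbour's spikes is contaminated by the
  voltage autocorrelation and shows spurious positive-lag structure in the
  unconnected direction;
* the STC of the *whitened* regression residual is not — the firing-reset
  dynamics concentrate residual energy into delta-like pulses at the
  neuron's own spike samples, so the residual STC is proportional to the
  residual cross-correlation sequence, which in turn determines the GC;
* because the postsynaptic conductance jump is proportional to the
  coupling strength S, the residual cross-correlations scale linearly in S
  and the GC scales quadratically (F ~ c * S^2 for small S).

Significance of an STC feature is assessed against a circular spike-time
shuffle null: the same number of triggers, uniformly rotated, destroys any
spike-locked structure while preserving both marginals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats as _sstats

from .vargc import (EstimationError, VarModelFit, TimeSeriesSet,
                    estimate_covariances, fit_var_yule_walker)


@dataclass
class StcCurve:
    """Lag-indexed spike-triggered average of a zero-mean signal."""

    lags: np.ndarray              # ms, symmetric about 0
    values: np.ndarray
    n_triggers: int
    trigger_neuron: int = -1
    signal_neuron: int = -1
    # null envelopes from circular shuffles (None if n_shuffles == 0)
    pointwise_band: Optional[np.ndarray] = None   # per-lag 99% of |STC|
    simultaneous_band: float = float("nan")       # 99% of max-over-lags |STC|
    meta: dict = field(default_factory=dict)

    def positive_lag_mask(self) -> np.ndarray:
        return self.lags > 0

    def exceeds_pointwise(self) -> np.ndarray:
        if self.pointwise_band is None:
            raise EstimationError("no null band: rerun with n_shuffles > 0")
        return np.abs(self.values) > self.pointwise_band


@dataclass
class CouplingScan:
    """GC measured across a sweep of coupling strengths S."""

    strengths: np.ndarray
    gc_values: np.ndarray
    fitted_exponent: float = float("nan")
    fitted_coefficient: float = float("nan")

    def __post_init__(self):
        s = np.asarray(self.strengths, float)
        if np.any(s <= 0) or np.any(np.diff(s) <= 0):
            raise EstimationError("strengths must be positive and increasing")
        self.strengths = s
        self.gc_values = np.asarray(self.gc_values, float)


# ---------------------------------------------------------------------------

def _triggered_mean(signal: np.ndarray, trig_idx: np.ndarray,
                    lag_samples: np.ndarray) -> np.ndarray:
    return signal[trig_idx[:, None] + lag_samples[None, :]].mean(axis=0)


def _shuffle_bands(signal, trig_idx, lag_samples, n_shuffles, rng):
    """Pointwise and simultaneous 99% envelopes from circular trigger shifts."""
    n = len(signal)
    lo, hi = -lag_samples[0], n - lag_samples[-1]
    span = hi - lo
    absmax = np.empty(n_shuffles)
    curves = np.empty((n_shuffles, len(lag_samples)))
    for s in range(n_shuffles):
        shift = rng.integers(1, span)
        idx = lo + (trig_idx - lo + shift) % span
        c = _triggered_mean(signal, idx, lag_samples)
        curves[s] = c
        absmax[s] = np.max(np.abs(c))
    pointwise = np.quantile(np.abs(curves), 0.99, axis=0)
    simultaneous = float(np.quantile(absmax, 0.99))
    return pointwise, simultaneous


def spike_triggered_correlation(signal, spike_times_ms, lag_window_ms=50.0,
                                fs=1.0, n_shuffles=0, rng=None,
                                trigger_neuron=-1, signal_neuron=-1,
                                sample_offset=0) -> StcCurve:
    """STC(t) = mean over spikes T_k of signal(T_k + t), lag grid symmetric
    about zero at the sampling resolution (nearest-sample lookup).

    ``signal`` must be zero-mean (it is demeaned defensively here).  Spikes
    whose lag window leaves the recording are dropped.  ``sample_offset``
    shifts spike-to-sample mapping for signals that start later than t=0
    (e.g. residual streams missing the first p samples).
    """
    x = np.asarray(signal, float).ravel()
    x = x - x.mean()
    L = int(round(lag_window_ms * fs))
    lag_samples = np.arange(-L, L + 1)
    idx = np.round(np.asarray(spike_times_ms, float) * fs).astype(int)
    idx = idx - sample_offset
    ok = (idx + lag_samples[0] >= 0) & (idx + lag_samples[-1] < len(x))
    idx = idx[ok]
    if len(idx) == 0:
        raise EstimationError("no retained trigger spikes in the recording")
    values = _triggered_mean(x, idx, lag_samples)
    curve = StcCurve(lags=lag_samples / fs, values=values, n_triggers=len(idx),
                     trigger_neuron=trigger_neuron, signal_neuron=signal_neuron)
    if n_shuffles > 0:
        rng = np.random.default_rng(rng)
        pw, sim = _shuffle_bands(x, idx, lag_samples, n_shuffles, rng)
        curve.pointwise_band = pw
        curve.simultaneous_band = sim
    return curve


def residual_stc(fit: VarModelFit, spike_times_ms, lag_window_ms=50.0,
                 fs=1.0, channel=0, n_shuffles=0, rng=None,
                 trigger_neuron=-1) -> StcCurve:
    """STC of a whitened residual channel triggered on another neuron's
    spikes.  The residual stream starts p samples into the recording, which
    is accounted for when mapping spike times to residual indices."""
    curve = spike_triggered_correlation(
        fit.residuals[:, channel], spike_times_ms, lag_window_ms, fs,
        n_shuffles=n_shuffles, rng=rng, trigger_neuron=trigger_neuron,
        signal_neuron=channel, sample_offset=fit.order)
    curve.meta["residual"] = True
    curve.meta["order"] = fit.order
    return curve


# ---------------------------------------------------------------------------

def _residual_cross_cov(eps: np.ndarray, eta: np.ndarray, p: int):
    """c_k = cov(eps_t, eta_{t-k}) for k = 1..p (biased normalization)."""
    T = len(eps)
    e = eps - eps.mean()
    h = eta - eta.mean()
    return np.array([e[k:] @ h[:T - k] / T for k in range(1, p + 1)])


def approx_regression_coefficients(eps, eta, order: int) -> dict:
    """Whitened-residual approximation of the joint-regression coefficients.

    For the bivariate JR models written on the AR residual streams eps (of
    x) and eta (of y), the cross coefficients are approximately the
    normalized residual cross-covariances,

        b_k ~= cov(eps_t, eta_{t-k}) / var(eta),
        d_k ~= cov(eta_t, eps_{t-k}) / var(eps),

    because whitened residuals have (near-)diagonal lagged covariance.
    Returns the approximations together with the exactly fitted JR
    coefficients on the stacked residual pair for comparison.
    """
    eps = np.asarray(eps, float).ravel()
    eta = np.asarray(eta, float).ravel()
    if eps.shape != eta.shape:
        raise EstimationError("residual streams must have equal length")
    ve, vh = eps.var(), eta.var()
    if ve == 0 or vh == 0:
        raise EstimationError("zero-variance residual stream")
    b_approx = _residual_cross_cov(eps, eta, order) / vh
    d_approx = _residual_cross_cov(eta, eps, order) / ve
    jr = fit_var_yule_walker(np.column_stack([eps, eta]), order)
    return {
        "lags": np.arange(1, order + 1),
        "b_approx": b_approx, "d_approx": d_approx,
        # exact JR cross coefficients: eps-row loading on lagged eta and v.v.
        "b_fit": jr.coefficients[:, 0, 1].copy(),
        "d_fit": jr.coefficients[:, 1, 0].copy(),
        "var_eps": ve, "var_eta": vh,
    }


def gc_from_residual_crosscorr(eps, eta, order: int):
    """GC approximated from the residual cross-correlation sequence:

        F_{y->x} ~= sum_k cov(eps_t, eta_{t-k})^2 / (var(eps) var(eta))

    (the leading term of -ln(1 - sum rho_k^2)), and symmetrically for
    F_{x->y}.  Useful as a consistency check against the directly
    estimated GC."""
    eps = np.asarray(eps, float).ravel()
    eta = np.asarray(eta, float).ravel()
    ve, vh = eps.var(), eta.var()
    if ve == 0 or vh == 0:
        raise EstimationError("zero-variance residual stream")
    c_yx = _residual_cross_cov(eps, eta, order)
    c_xy = _residual_cross_cov(eta, eps, order)
    F_yx = float(np.sum(c_yx ** 2) / (ve * vh))
    F_xy = float(np.sum(c_xy ** 2) / (ve * vh))
    return F_yx, F_xy


def delta_residual_check(fit: VarModelFit, spikes, fs=1.0) -> dict:
    """Quantify the delta-like, spike-locked structure of the residuals.

    For each channel, reports the fraction of residual energy carried by
    samples containing one of that neuron's own spikes, against the
    fraction of time those samples occupy.  Firing-reset dynamics make the
    energy fraction far exceed the time fraction; white noise with random
    trigger times gives energy fraction ~= time fraction.
    """
    E = fit.residuals
    n_res, m = E.shape
    report = {"channels": []}
    for i in range(m):
        st = np.asarray(spikes[i], float)
        idx = np.round(st * fs).astype(int) - fit.order
        idx = idx[(idx >= 0) & (idx < n_res)]
        total = float(np.sum(E[:, i] ** 2))
        if len(idx) == 0 or total == 0:
            report["channels"].append({
                "channel": i, "n_spike_samples": 0, "degenerate": True,
                "energy_fraction": float("nan"), "time_fraction": 0.0})
            continue
        idx = np.unique(idx)
        energy = float(np.sum(E[idx, i] ** 2))
        report["channels"].append({
            "channel": i, "n_spike_samples": int(len(idx)),
            "degenerate": False,
            "energy_fraction": energy / total,
            "time_fraction": len(idx) / n_res,
        })
    return report


def fit_gc_coupling_law(scan: CouplingScan) -> CouplingScan:
    """Least-squares slope of log(GC) versus log(S).

    The delta-residual mechanism predicts GC ~ c * S^2 for small coupling,
    i.e. slope ~ 2.  Nonpositive GC values are excluded with a warning;
    fewer than three usable points is an error.
    """
    s, f = scan.strengths, scan.gc_values
    ok = f > 0
    if not ok.all():
        warnings.warn(f"excluding {int((~ok).sum())} nonpositive GC value(s) "
                      "from the log-log fit", RuntimeWarning, stacklevel=2)
    if ok.sum() < 3:
        raise EstimationError("need >= 3 positive GC values for the power-law fit")
    res = _sstats.linregress(np.log(s[ok]), np.log(f[ok]))
    scan.fitted_exponent = float(res.slope)
    scan.fitted_coefficient = float(np.exp(res.intercept))
    return scan
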