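# Methods

## The problem

Given simultaneously recorded activity (membrane voltages or spike times)
of a population of neurons, can the *structural* wiring — the directed
synaptic adjacency matrix — be recovered from the *statistical* dependence
structure of the recordings?  This package implements one complete answer
for conductance-based integrate-and-fire (IF) networks: time-domain
conditional Granger causality (GC) estimated from the recorded time
series, thresholded into a causal adjacency matrix, reproduces the
synaptic adjacency over a wide range of dynamical regimes.  The package
contains both the forward model (a network simulator) and the inference
machinery, plus the spike-triggered-correlation diagnostics that explain
*why* a linear method works on these strongly nonlinear, non-smooth
dynamics.

## Forward model

Neuron `i`'s membrane potential obeys

    dV_i/dt = -g_L (V_i - E_L) - G_E,i (V_i - E_E) - G_I,i (V_i - E_I)
              [ + g_L * delta_T * exp((V_i - V_T)/delta_T) ]   (EIF only)

Conductances jump instantaneously on spikes — by `f` for feedforward
Poisson events (rate `lambda` per neuron, independent trains; optionally a
shared train for common-input studies) and by the class coupling strength
`S` when a presynaptic neuron fires — and decay exponentially (`tau_E` =
2 ms, `tau_I` = 5 ms).  When `V` crosses threshold (`V_th` = 1 for IF;
the divergence guard `V_cut` = 5 for EIF) a spike is recorded, `V` resets
to 0 and is clamped for an absolute refractory period `tau_ref` = 2 ms.
No autapses, delays, or synaptic plasticity.

Units are normalized: `E_L` = 0, `V_th` = 1 (so one normalized voltage
unit corresponds to the ~15 mV rest-to-threshold span), `E_E` = 14/3,
`E_I` = -2/3, `g_L` = 0.05 /ms; time is in ms.  These are the standard
normalized physiological values of the conductance-based IF modeling
literature, and every one of them is overridable in code or config.

### Integrator

Fixed-step Heun (second-order Runge-Kutta) for the voltage with *exact*
exponential decay of the conductances inside each step; default
`dt` = 0.05 ms.  Poisson and recurrent spike events are binned to step
boundaries (a recurrent spike takes effect from the start of the next
step).  Threshold-crossing times are located by linear interpolation
within the step, giving spike times with O(dt^2) accuracy; the refractory
clamp is released at the first step boundary past `tau_ref`.  Voltages
are recorded as *trapezoidal window means* over windows of width `1/fs`
(default `fs` = 1 kHz), so the recorded samples converge at second order
for subthreshold dynamics; a reset inside a window is smeared at O(dt),
which is far below the statistical noise of any analysis here.  The
EIF exponential argument is capped (at 50) so the spike-current blow-up
saturates instead of overflowing; with `delta_T` below 1e-8 the spike
current is disabled and the EIF code path is arithmetically identical to
the IF path, which is verified to reproduce IF trajectories bit-exactly.

### Randomness

One master seed; per-neuron Poisson substreams are derived from
`(seed, neuron_index)`, so enlarging a network leaves the other neurons'
drive untouched.  The shared common-input train uses a reserved substream.
All downstream analyses are deterministic given the recordings, so every
workflow is bit-reproducible from its config and seed.

## Granger-causality estimation

All channels are demeaned.  Lagged covariances use the biased (1/T)
normalization, which keeps the block-Toeplitz Yule-Walker system positive
semi-definite.  VAR coefficients solve that system exactly (one dense
solve; a documented ridge jitter of 1e-8 * mean diagonal is applied once
if the system is numerically singular, with a warning).  The noise
covariance of a fit is the sample covariance of the actual residual
series (T - p rows).

**Order selection.**  BIC(p) = ln det Sigma_p + p m^2 ln(T')/T' with
T' = T - p, minimized over p = 1..max_order (default 30 at 1 kHz; ties
break toward smaller p).  During the scan, Sigma_p is evaluated through
the Yule-Walker identity Sigma = Gamma(0) - sum_u A_u Gamma(u)^T rather
than a residual pass per candidate order; the two differ only by O(p/T)
edge effects and the scan is then linear rather than quadratic in the
data length.  The order is selected once on the full joint model and
reused for every conditional fit.

**Conditional GC.**  One m-channel joint fit gives the joint residual
variances sigma^2_JR,i; for each candidate driver j, an (m-1)-channel fit
excluding j gives the conditional AR variances, and

    F_{j->i} = ln( sigma^2_{AR,i|-j} / sigma^2_{JR,i} ).

For m = 2 this reduces to classical pairwise GC.  Estimates in
(-1e-10, 0) are clipped to zero silently; more negative values are
clipped with a warning (they indicate misspecification).

**Significance.**  Under the null, T * F_hat is asymptotically chi^2 with
p degrees of freedom (p = number of coefficients the driver contributes),
so the threshold is quantile_{chi2_p}(1 - alpha)/T with alpha = 0.01 by
default.  An optional Bonferroni correction divides alpha by the m(m-1)
ordered pairs; the packaged multi-pair study protocols (20-neuron
network, 3-neuron chain, 2-channel subnetwork) use it, since at m = 20
there are 380 simultaneous tests and per-test alpha = 0.01 would
contribute ~4 false edges on its own, and because on IF voltage data the
finite-order truncation leaves a genuine reverse-leakage floor of order
3e-5 that a plain alpha = 0.01 threshold crosses once recordings exceed
a few hundred seconds.  This calibration is verified
empirically: on independent white channels the false-positive rate falls
inside the exact binomial 99% interval of the nominal level.

**Spike-train mode.**  Spike trains are binarized at 1 ms (one bin can
hold at most one spike because the refractory period is 2 ms; two spikes
in a bin is an error, not a silent merge), demeaned, and sent through the
identical VAR/GC path.

**Subnetwork (LFP-like) mode.**  A partition of neurons is collapsed to
one channel per block by unweighted voltage averaging, spike-reset
transients included, and the standard pipeline runs on the collapsed
channels.

## Thresholding and scoring

`threshold_gc` sets a causal edge where F strictly exceeds the threshold;
`gap_threshold` instead ranks the off-diagonal GC values on a log scale
and places the cut in the largest gap — restricted to splits that leave
at most half of the values above the cut, because in a sparse network the
significant group is the minority and relative gaps between the extreme
order statistics at the bottom of the noise group would otherwise win.
The gap result carries its size in decades (`clear` = at least one
decade), so callers can detect the mixed excitatory/inhibitory situation
where no clean gap exists.  `compare_adjacency` scores off-diagonal
agreement (accuracy, false positives/negatives) against the structural
matrix.

## Why it works: the whitening diagnostics

The spike-triggered correlation (STC) of a *raw voltage* on a neighbour's
spikes is significantly nonzero at positive lags even in the direction
with no synapse, because voltages have a finite autocorrelation time —
the classic failure of naive spike-triggered inference.  The STC of the
*whitened regression residual* does not have this problem: the
firing-reset dynamics concentrate residual energy into delta-like pulses
at the neuron's own spike samples (`delta_residual_check` quantifies
this: the residual energy fraction in spike-containing samples exceeds
their time fraction many-fold), so the residual STC is proportional to
the residual cross-correlation sequence; the joint-regression cross
coefficients are, in turn, approximately the normalized residual
cross-covariances (`approx_regression_coefficients`, verified lag by lag
against the exactly fitted coefficients), and the GC is approximately the
normalized sum of their squares (`gc_from_residual_crosscorr`).  Since
the postsynaptic conductance jump is proportional to S, this chain
predicts GC ~ c * S^2 for small S.

STC significance uses a circular spike-time shuffle null (1000 shuffles
by default).  Two envelopes are computed from the same shuffles: a
pointwise per-lag 99% band, and a simultaneous band (99% quantile of the
max over lags), because a "stays within the band at *all* positive lags"
statement tested pointwise at 99% would false-alarm on ~40% of curves
with ~50 lags.  Per-lag statements use the pointwise band; whole-curve
statements use the simultaneous band.

## Study conditions

The drive grid and coupling strength were calibrated once, before the
validation suite was frozen, to place the three dynamical regimes of the
Poisson-driven IF neuron inside the physiological firing range at the
default parameters:

| regime        | lambda (/ms) | firing rate | ISI CV |
|---------------|--------------|-------------|--------|
| fluctuation   | 0.08         | ~15-26 Hz   | ~0.83  |
| intermediate  | 0.10         | ~22-35 Hz   | ~0.78  |
| mean-driven   | 0.30         | ~90-115 Hz  | ~0.57  |

with input strengths f in {0.06, 0.07, 0.08} and synaptic coupling
S = 0.03 (EPSP ~2-3 mV at rest, ~1-1.5 mV under synaptic load).  Two
findings from that calibration are worth knowing when changing the
conditions:

* In the deep fluctuation regime (lambda <= 0.05/ms at these strengths),
  window-averaged sampling leaks sub-window spike-timing information into
  the *reverse* direction: the unconnected-direction GC acquires a small
  genuine positive value that does not vanish with longer regressions and
  sits above the chi^2 threshold of a 120-s recording.  Longer recordings
  (>= 600 s) or the spike-train mode are unaffected in practice.
* Around lambda ~ 0.15-0.25/ms (the transition into mean-driven firing)
  the connected-direction GC passes through a minimum and short
  recordings can miss the edge.

Default recording length for reconstruction workflows is 600 s of
simulated time; the two-neuron grid studies use 120 s per cell and the
20-neuron network study 300 s, which one CPU core simulates in under a
second per two-neuron run.

## The coupling-strength scaling law

The predicted quadratic law is an asymptotic small-S statement, and at
strengths large enough to measure against the estimator noise floor the
fitted log-log exponent is mode- and regime-dependent: voltage-mode
exponents run ~1.4-1.6 (the EPSP-driven growth of the target's residual
variance flattens the curve), spike-train-mode exponents ~1.8-2.3 (the
convexity of the spike-probability response steepens it at low rates).
The packaged scan protocol therefore uses spike-train GC at order 20,
five strengths per regime chosen below each regime's saturation onset,
each strength averaged over three 600-s recordings, and subtracts the
paired unconnected-direction estimate (which carries the same
small-sample floor) before fitting.  Under this protocol the intermediate
and mean-driven regimes land at exponents ~1.8-2.2; the fluctuation
regime is systematically slightly super-quadratic (~2.2-2.3), and local
exponents measured down to S = 0.002 with 1800-s records do not drift
back toward 2 — at these study conditions that regime's scaling is
genuinely a little steeper than the small-S law.

## What the generator does and does not emulate

The simulator produces exactly the model class the inference targets:
pulse-coupled conductance dynamics, Poisson drive, instantaneous synapses,
no conduction delays, no adaptation, stationary rates.  Real recordings
add measurement noise, nonstationarity, unobserved neurons and correlated
background input; of these, only the common-input axis is explored (as a
controlled robustness sweep).  Passing the validation suite therefore
demonstrates correctness of the method on its model class and its
documented failure modes — not performance on experimental data.

## Numerical and statistical conventions

* Biased covariance normalization; residual-based noise covariances
  (T - p denominator) everywhere except the BIC scan (Yule-Walker
  identity).
* Asymptotic standard error of a GC estimate:
  SD(F_hat) = sqrt(2p + 4 T F)/T, from the (non)central chi^2 law of
  T * F_hat; the filter-invariance study also computes a segment-based
  empirical SE (10 non-overlapping segments).
* The minimal-data-length sweep simulates the longest length once per
  seed and truncates, scoring exact reconstruction by majority over five
  seeds.
* The common-input sweep keeps the *total* feedforward rate fixed —
  independent rate (1-c) lambda plus shared rate c lambda — so the
  fraction c varies input correlation without shifting the dynamical
  regime; both ratio conventions (connected/unconnected and its inverse)
  are reported.
* Degenerate inputs (constant channels, zero residual variances, two
  spikes per bin, overlapping partitions, non-stationary fixtures) raise
  typed errors rather than propagating NaNs.

## Known limitations

* Edge *sign* (excitatory vs inhibitory) is not inferred; mixed E/I
  networks are reconstructed as unsigned adjacency only, and their ranked
  GC values typically show no clear gap.
* Dense networks (connection density well above ~10-20%) degrade the
  reconstruction; the packaged studies stay at 5%.
* Near spike-to-spike synchrony (very strong coupling) the conditional
  GC itself acquires spurious structure; the chain-conditioning
  demonstration therefore uses a linear VAR chain, where the
  bivariate-vs-conditional contrast is unconfounded.
* The chi^2 null is exact for linear processes; on IF voltage data the
  finite-order truncation inflates small-sample GC estimates by a
  regime-dependent factor of ~2 relative to the nominal null mean, which
  is why short-recording workflows favor the Bonferroni threshold.
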