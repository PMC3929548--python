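# ifgc — Granger-causality reconstruction of integrate-and-fire networks

`ifgc` asks and answers a structure-from-function question: given only the
recorded activity of a population of neurons — membrane voltages, or even
just spike times — can the directed *synaptic* wiring be recovered?  It
provides, in one package:

* a fast simulator for conductance-based integrate-and-fire networks
  (standard IF, exponential IF, and mixed excitatory/inhibitory variants)
  under Poisson drive, with full seed-level reproducibility;
* a time-domain conditional Granger-causality (GC) estimator
  (Yule-Walker VAR fits, BIC order selection, chi-squared significance
  thresholds, ranked-GC gap thresholds);
* the spike-triggered-correlation diagnostics that explain *why* a linear
  method recovers nonlinear pulse-coupled wiring — residual whitening,
  coefficient approximations, and the quadratic GC-vs-coupling law;
* end-to-end reconstruction workflows with accuracy scoring, spike-train
  and subnetwork (LFP-like) modes, and robustness sweeps over recording
  length and common input.

It is intended for computational neuroscientists studying the mapping
between causal (functional) and structural connectivity, and as a
reference implementation for benchmarking other network-inference
methods on a ground-truth forward model.

## The method in brief

For channels $x_t, y_t$ (zero mean), compare the autoregression of $x$
on its own past with the joint regression that adds $y$'s past:

$$F_{y \to x} = \ln \frac{\operatorname{var}(\varepsilon_x^{AR})}{\operatorname{var}(\varepsilon_x^{JR})} \ge 0 ,$$

and conditionally for $m > 2$ channels: $F_{j \to i}$ compares the full
$m$-channel joint fit against the fit that omits channel $j$, so
influences mediated by the remaining channels drop out.  Coefficients are
estimated by solving the block-Toeplitz Yule-Walker system built from the
lagged covariances, the order $p$ is chosen by BIC, and under the null
$T \hat F$ is asymptotically $\chi^2_p$, which yields the significance
threshold $F_{th}$.  Thresholding $\hat F_{j\to i} > F_{th}$ gives the
causal adjacency matrix, which is compared entry-by-entry with the
structural one.  For the conductance-based IF model, the firing-reset
dynamics give the regression residuals a delta-like, spike-locked
structure; this makes the whitened-residual cross-correlations track the
synaptic couplings, and the GC grows quadratically with the coupling
strength $S$ — the mechanism, and its diagnostics, live in `ifgc.stc`.

## Worked example

```python
import numpy as np
from ifgc import netsim, pipeline

net = netsim.two_neuron_network()          # neuron 1 -> neuron 2, S = 0.03
par = netsim.NeuronParams()
drive = netsim.DriveSpec(rate=0.1, strength=0.07, seed=1)
rec = netsim.simulate(net, par, drive, duration=120_000.0)   # 120 s at 1 kHz
print("firing rates (Hz):", np.round(rec.firing_rates() * 1000, 1))

out = pipeline.reconstruct(rec, structural=net.adjacency)
gc = out["gc"]
print("selected order p:", gc.order)
print("GC matrix F[j,i] (row = driver):")
print(np.array2string(gc.values, precision=6))
print("chi2 threshold:", f"{out['threshold']:.2e}")
print("causal adjacency:")
print(out["causal"].matrix)
print("accuracy vs structure:", out["report"].accuracy)
```

prints

```
firing rates (Hz): [25.8 29.9]
selected order p: 4
GC matrix F[j,i] (row = driver):
[[0.000000e+00 1.439287e-04]
 [1.628121e-05 0.000000e+00]]
chi2 threshold: 1.11e-04
causal adjacency:
[[0 1]
 [0 0]]
accuracy vs structure: 1.0
```

Reading it: both neurons fire at ~26-30 Hz in the intermediate
(irregular-firing) regime.  The GC from neuron 1 to neuron 2
(1.4e-4) exceeds the chi-squared threshold (1.1e-4) while the reverse
direction (1.6e-5) does not, so the thresholded causal adjacency contains
exactly the one true synapse: the wiring is reconstructed perfectly from
120 s of voltage data, with no knowledge of the model parameters.

The same analysis runs from the shell:

```bash
ifgc simulate --config examples/two_neuron.yaml --out run/
ifgc gc --series run/voltages.txt --out run/gc/
ifgc reconstruct --config examples/two_neuron.yaml --out run/rec/
```

## Package layout

| module          | contents                                                          |
|-----------------|-------------------------------------------------------------------|
| `ifgc.netsim`   | IF/EIF/E-I network simulation, Poisson drive, random networks     |
| `ifgc.vargc`    | Yule-Walker VAR fits, BIC, pairwise & conditional GC, thresholds  |
| `ifgc.stc`      | spike-triggered correlations, whitening diagnostics, coupling law |
| `ifgc.pipeline` | thresholding, scoring, spike/subnetwork modes, robustness sweeps  |
| `ifgc.io`       | text formats for recordings/spikes/configs, run manifests         |
| `ifgc.fixtures` | stationary VAR fixtures with analytic GC (ground-truth oracles)   |
| `ifgc.studies`  | predefined end-to-end study protocols                             |
| `ifgc.cli`      | umbrella `ifgc` command                                           |

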