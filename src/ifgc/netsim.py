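"""Conductance-based integrate-and-fire network simulation.

Implements pulse-coupled networks of leaky integrate-and-fire (IF) and
exponential integrate-and-fire (EIF) point neurons under independent
homogeneous Poisson drive, with optional excitatory/inhibitory populations
and an optional shared ("common") Poisson train.  Membrane voltage of
neuron ``i`` obeys

    dV_i/dt = -g_L (V_i - E_L) - G_E,i (V_i - E_E) - G_I,i (V_i - E_I)
              [+ g_L * delta_T * exp((V_i - V_T)/delta_T)   (EIF only)]

between events; synaptic conductances jump instantaneously on presynaptic
or feedforward spikes and decay exponentially with time constants tau_E /
tau_I.  On threshold crossing the spike time is located by linear
interpolation within the step, the voltage is reset and clamped for an
absolute refractory period.  Voltages are recorded as means over sampling
windows of width 1/fs.

All voltages are in normalized units (resting potential 0, firing
threshold 1); time is in milliseconds, rates in 1/ms, fs in kHz.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
from numba import njit


#: Poisson input rates (1/ms) representative of the three dynamical regimes
#: of the Poisson-driven IF neuron at the default parameters: highly
#: fluctuating / intermediate / mean-driven (nearly periodic) firing.
REGIME_RATES = {"fluctuation": 0.08, "intermediate": 0.1, "mean_driven": 0.3}

#: Input-strength grid paired with REGIME_RATES for drive-parameter scans.
GRID_STRENGTHS = (0.06, 0.07, 0.08)

#: Default synaptic coupling (EPSP ~ 2-3 mV at rest, ~1-1.5 mV under load).
DEFAULT_COUPLING = 0.03


class ParameterError(ValueError):
    """Invalid model/drive/run parameter."""


class SimulationError(RuntimeError):
    """Numerical failure during integration (non-finite state)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class NetworkSpec:
    """Directed network of n_exc excitatory followed by n_inh inhibitory neurons.

    ``adjacency[j, i] == 1`` means neuron ``j`` is presynaptic to neuron ``i``.
    Coupling strengths are per connection class, named target-source:
    ``S_ie`` is the strength of excitatory-to-inhibitory synapses.  All
    strengths are nonnegative conductance jumps; the sign of the effect is
    carried by the reversal potentials.
    """

    n_exc: int
    n_inh: int = 0
    adjacency: Optional[np.ndarray] = None
    S_ee: float = 0.03
    S_ie: float = 0.03
    S_ei: float = 0.03
    S_ii: float = 0.03
    model_kind: str = "IF"

    def __post_init__(self):
        if self.n_exc < 0 or self.n_inh < 0:
            raise ParameterError("population sizes must be nonnegative")
        n = self.n_exc + self.n_inh
        if n < 1:
            raise ParameterError("network must contain at least one neuron")
        if self.model_kind not in ("IF", "EIF"):
            raise ParameterError(f"unknown model_kind {self.model_kind!r}")
        for name in ("S_ee", "S_ie", "S_ei", "S_ii"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.adjacency is None:
            self.adjacency = np.zeros((n, n), dtype=np.int8)
        else:
            A = np.asarray(self.adjacency)
            if A.shape != (n, n):
                raise ParameterError(f"adjacency must be {n}x{n}, got {A.shape}")
            if not np.isin(A, (0, 1)).all():
                raise ParameterError("adjacency entries must be 0 or 1")
            if np.diag(A).any():
                raise ParameterError("autapses (diagonal entries) are not allowed")
            self.adjacency = A.astype(np.int8)

    @property
    def n_neurons(self) -> int:
        return self.n_exc + self.n_inh

    def is_inhibitory(self) -> np.ndarray:
        """Boolean mask, True for inhibitory neurons (the last n_inh indices)."""
        mask = np.zeros(self.n_neurons, dtype=bool)
        mask[self.n_exc:] = True
        return mask

    def coupling_matrix(self) -> np.ndarray:
        """Per-edge conductance jumps C[j, i] applied to neuron i when j fires."""
        inh = self.is_inhibitory()
        C = np.zeros((self.n_neurons, self.n_neurons))
        for j in range(self.n_neurons):
            if inh[j]:
                row = np.where(inh, self.S_ii, self.S_ei)
            else:
                row = np.where(inh, self.S_ie, self.S_ee)
            C[j] = row * self.adjacency[j]
        return C


@dataclass
class NeuronParams:
    """Single-neuron parameters, normalized units (E_L = 0, V_th = 1).

    Defaults follow the normalized-unit convention standard in
    conductance-based IF network modeling; all are overridable.
    """

    g_L: float = 0.05       # leak conductance, 1/ms
    E_L: float = 0.0        # leak reversal
    E_E: float = 14.0 / 3.0  # excitatory reversal
    E_I: float = -2.0 / 3.0  # inhibitory reversal
    V_th: float = 1.0       # firing threshold (IF)
    V_reset: float = 0.0
    tau_E: float = 2.0      # ms
    tau_I: float = 5.0      # ms
    tau_ref: float = 2.0    # ms, absolute refractory period
    delta_T: float = 0.35   # EIF slope factor
    V_T: float = 1.0        # EIF spike-initiation threshold
    V_cut: float = 5.0      # EIF numerical divergence cutoff

    def __post_init__(self):
        if not (self.E_I < self.E_L < self.V_th < self.E_E):
            raise ParameterError("reversal potentials must satisfy E_I < E_L < V_th < E_E")
        if min(self.tau_E, self.tau_I, self.tau_ref) <= 0:
            raise ParameterError("time constants must be positive")
        if self.delta_T < 0:
            raise ParameterError("delta_T must be >= 0")
        if self.V_cut <= self.V_th:
            raise ParameterError("V_cut must exceed V_th")


@dataclass
class DriveSpec:
    """Feedforward Poisson drive: independent per-neuron trains plus an
    optional shared train delivered identically to targeted neurons."""

    rate: float = 0.1          # 1/ms, independent train per neuron
    strength: float = 0.07     # conductance jump per event
    common_rate: float = 0.0   # 1/ms, shared train
    common_strength: float = 0.1
    common_targets: Optional[Sequence[int]] = None  # None -> all neurons
    seed: int = 0

    def __post_init__(self):
        if self.rate < 0 or self.common_rate < 0:
            raise ParameterError("Poisson rates must be >= 0")
        if self.strength < 0 or self.common_strength < 0:
            raise ParameterError("input strengths must be >= 0")


@dataclass
class SimulationRecord:
    """Sampled voltages, spike times and full provenance of one run."""

    voltages: np.ndarray          # (n_samples, n_neurons), window means
    spikes: list                  # per-neuron ascending spike times, ms
    fs: float                     # kHz
    dt: float                     # ms
    duration: float               # ms
    provenance: dict = field(default_factory=dict)

    @property
    def n_neurons(self) -> int:
        return self.voltages.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Sample-window center times in ms."""
        return (np.arange(self.voltages.shape[0]) + 0.5) / self.fs

    def firing_rates(self) -> np.ndarray:
        """Per-neuron firing rate in spikes/ms."""
        return np.array([len(s) for s in self.spikes]) / self.duration


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def generate_random_network(n_exc, n_inh=0, density=0.05,
                            coupling_strengths=None, seed=0,
                            model_kind="IF") -> NetworkSpec:
    """Erdos-Renyi directed network: each off-diagonal entry is 1 with
    probability ``density``; no autapses.  Reproducible from ``seed``."""
    if n_exc < 0 or n_inh < 0:
        raise ParameterError("population sizes must be nonnegative")
    if not 0.0 <= density <= 1.0:
        raise ParameterError("density must lie in [0, 1]")
    n = n_exc + n_inh
    if n < 2:
        raise ParameterError("need at least two neurons")
    rng = np.random.default_rng(seed)
    A = (rng.random((n, n)) < density).astype(np.int8)
    np.fill_diagonal(A, 0)
    kwargs = dict(coupling_strengths or {})
    return NetworkSpec(n_exc=n_exc, n_inh=n_inh, adjacency=A,
                       model_kind=model_kind, **kwargs)


def two_neuron_network(S=0.03, model_kind="IF") -> NetworkSpec:
    """Two excitatory neurons with a single synapse 1 -> 2 (0-based 0 -> 1)."""
    A = np.zeros((2, 2), dtype=np.int8)
    A[0, 1] = 1
    return NetworkSpec(n_exc=2, adjacency=A, S_ee=S, model_kind=model_kind)


def sample_poisson_trains(drive: DriveSpec, n_neurons: int, duration: float,
                          seed: Optional[int] = None):
    """Independent homogeneous Poisson event times per neuron plus the shared
    common-train events copied into every targeted neuron's list.

    Returns ``(events, strengths)``: per-neuron ascending event-time arrays
    and matching per-event conductance jumps.  Per-neuron substreams are
    derived from (seed, neuron index) so adding a neuron does not perturb
    the others' drive.
    """
    if duration <= 0:
        raise ParameterError("duration must be positive")
    seed = drive.seed if seed is None else seed
    events, strengths = [], []
    for i in range(n_neurons):
        rng = np.random.default_rng([int(seed), i])
        k = rng.poisson(drive.rate * duration)
        t = np.sort(rng.random(k)) * duration
        events.append(t)
        strengths.append(np.full(k, drive.strength))
    if drive.common_rate > 0:
        rng = np.random.default_rng([int(seed), 999_999_937])
        k = rng.poisson(drive.common_rate * duration)
        tc = np.sort(rng.random(k)) * duration
        targets = (range(n_neurons) if drive.common_targets is None
                   else drive.common_targets)
        for i in targets:
            t = np.concatenate([events[i], tc])
            s = np.concatenate([strengths[i], np.full(k, drive.common_strength)])
            order = np.argsort(t, kind="stable")
            events[i], strengths[i] = t[order], s[order]
    return events, strengths


def common_input_fraction(drive: DriveSpec) -> float:
    """Fraction of feedforward events that come from the shared train,
    lambda_c / (lambda + lambda_c)."""
    tot = drive.rate + drive.common_rate
    if tot <= 0:
        raise ParameterError("rate + common_rate must be positive")
    return drive.common_rate / tot


@njit(cache=True)
def _integrate_kernel(n_steps, dt, n, C, is_inh,
                      g_L, E_L, E_E, E_I, V_th, V_reset,
                      tau_E, tau_I, tau_ref, eif, delta_T, V_T, V_cut,
                      ev_ptr, ev_step, ev_jump,
                      steps_per_window, n_windows, v0,
                      volt_out, spike_t, spike_n):
    """Fixed-step integration loop.  Events and recurrent spikes are binned to
    step boundaries; voltage uses Heun's method with exact exponential
    conductance decay inside the step.  Returns (n_spikes, status)."""
    V = v0.copy()
    GE = np.zeros(n)
    GI = np.zeros(n)
    ref_until = np.full(n, -1.0)
    ev_pos = ev_ptr[:n].copy()
    dE = np.exp(-dt / tau_E)
    dI = np.exp(-dt / tau_I)
    thr = V_cut if eif else V_th
    n_sp = 0
    acc = np.zeros(n)
    win = 0
    in_win = 0
    fired = np.empty(n, np.int64)
    for k in range(n_steps):
        t0 = k * dt
        t1 = t0 + dt
        # feedforward events binned to the start of this step
        for i in range(n):
            p = ev_pos[i]
            while p < ev_ptr[i + 1] and ev_step[p] == k:
                GE[i] += ev_jump[p]
                p += 1
            ev_pos[i] = p
        nf = 0
        for i in range(n):
            gE0, gI0 = GE[i], GI[i]
            gE1, gI1 = gE0 * dE, gI0 * dI
            v_start = V[i]
            if t0 < ref_until[i]:
                # clamped; released at the first step boundary past tau_ref
                V[i] = V_reset
                v_start = V_reset
            else:
                v = V[i]
                k1 = -g_L * (v - E_L) - gE0 * (v - E_E) - gI0 * (v - E_I)
                if eif:
                    a = (v - V_T) / delta_T
                    if a > 50.0:
                        a = 50.0
                    k1 += g_L * delta_T * np.exp(a)
                ve = v + dt * k1
                k2 = -g_L * (ve - E_L) - gE1 * (ve - E_E) - gI1 * (ve - E_I)
                if eif:
                    a = (ve - V_T) / delta_T
                    if a > 50.0:
                        a = 50.0
                    k2 += g_L * delta_T * np.exp(a)
                vn = v + 0.5 * dt * (k1 + k2)
                if vn >= thr:
                    # linear interpolation of the crossing time in the step
                    ts = t0 + dt * (thr - v) / (vn - v)
                    if ts > t1:
                        ts = t1
                    spike_t[n_sp] = ts
                    spike_n[n_sp] = i
                    n_sp += 1
                    ref_until[i] = ts + tau_ref
                    fired[nf] = i
                    nf += 1
                    vn = V_reset
                elif not np.isfinite(vn):
                    return n_sp, 1
                V[i] = vn
            GE[i] = gE1
            GI[i] = gI1
            # trapezoidal window accumulation (continuous V between resets)
            acc[i] += 0.5 * (v_start + V[i])
        # recurrent spikes take effect from the start of the next step
        for f in range(nf):
            j = fired[f]
            sj = is_inh[j]
            for i in range(n):
                c = C[j, i]
                if c > 0.0:
                    if sj:
                        GI[i] += c
                    else:
                        GE[i] += c
        in_win += 1
        if in_win == steps_per_window:
            if win < n_windows:
                for i in range(n):
                    volt_out[win, i] = acc[i] / steps_per_window
            win += 1
            in_win = 0
            for i in range(n):
                acc[i] = 0.0
    return n_sp, 0


def simulate(network: NetworkSpec, params: NeuronParams, drive: DriveSpec,
             duration: float, dt: float = 0.05, fs: float = 1.0,
             v0: Optional[np.ndarray] = None,
             events: Optional[tuple] = None) -> SimulationRecord:
    """Simulate the network and record window-averaged voltages and spikes.

    Parameters
    ----------
    duration : total simulated time in ms.
    dt : integration step in ms (must resolve tau_E: dt <= tau_E/10).
    fs : sampling rate in kHz; each sample is the voltage averaged over a
        window of 1/fs ms (fs*dt <= 1 so a window holds >= 1 step).
    v0 : optional initial voltages (defaults to E_L).
    events : optional pre-sampled ``(event_times, event_jumps)`` per neuron,
        as returned by :func:`sample_poisson_trains`; if omitted they are
        sampled from ``drive``.
    """
    n = network.n_neurons
    if dt > params.tau_E / 10 + 1e-12:
        raise ParameterError("dt must satisfy dt <= tau_E/10")
    if fs * dt > 1 + 1e-12:
        raise ParameterError("fs*dt must be <= 1")
    if duration < 1.0 / fs:
        raise ParameterError("duration shorter than one sampling window")
    steps_per_window = int(round(1.0 / (fs * dt)))
    n_windows = int(np.floor(duration * fs))
    n_steps = n_windows * steps_per_window

    if events is None:
        events = sample_poisson_trains(drive, n, duration)
    ev_times, ev_jumps = events
    ev_ptr = np.zeros(n + 1, dtype=np.int64)
    for i in range(n):
        ev_ptr[i + 1] = ev_ptr[i] + len(ev_times[i])
    ev_step = np.empty(ev_ptr[-1], dtype=np.int64)
    ev_jump = np.empty(ev_ptr[-1])
    for i in range(n):
        s = np.floor(np.asarray(ev_times[i]) / dt).astype(np.int64)
        ev_step[ev_ptr[i]:ev_ptr[i + 1]] = np.clip(s, 0, n_steps - 1)
        ev_jump[ev_ptr[i]:ev_ptr[i + 1]] = ev_jumps[i]

    max_spikes = n * (int(duration / params.tau_ref) + 2)
    spike_t = np.empty(max_spikes)
    spike_n = np.empty(max_spikes, dtype=np.int64)
    volt = np.empty((n_windows, n))
    v_init = np.full(n, params.E_L) if v0 is None else np.asarray(v0, float).copy()
    if v_init.shape != (n,):
        raise ParameterError("v0 must have one entry per neuron")

    eif = network.model_kind == "EIF" and params.delta_T > 1e-8
    n_sp, status = _integrate_kernel(
        n_steps, float(dt), n, network.coupling_matrix(),
        network.is_inhibitory(), params.g_L, params.E_L, params.E_E,
        params.E_I, params.V_th, params.V_reset, params.tau_E, params.tau_I,
        params.tau_ref, eif, params.delta_T, params.V_T, params.V_cut,
        ev_ptr, ev_step, ev_jump, steps_per_window, n_windows, v_init,
        volt, spike_t, spike_n)
    if status != 0:
        raise SimulationError("non-finite membrane voltage encountered; "
                              "reduce dt or check parameters")
    spikes = [spike_t[:n_sp][spike_n[:n_sp] == i].copy() for i in range(n)]
    prov = {
        "network": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                    for k, v in asdict(network).items()},
        "params": asdict(params),
        "drive": {k: (list(v) if isinstance(v, (list, tuple)) else v)
                  for k, v in asdict(drive).items()},
        "duration": duration, "dt": dt, "fs": fs, "seed": drive.seed,
    }
    return SimulationRecord(voltages=volt, spikes=spikes, fs=fs, dt=dt,
                            duration=float(n_windows / fs), provenance=prov)


def isi_cv(spike_times: np.ndarray) -> float:
    """Coefficient of variation of interspike intervals (NaN if < 3 spikes)."""
    if len(spike_times) < 3:
        return float("nan")
    isi = np.diff(spike_times)
    return float(np.std(isi) / np.mean(isi))
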