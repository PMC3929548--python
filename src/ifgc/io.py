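"""Text formats, configuration and run manifests.

All artifacts are plain text with ``#``-prefixed metadata headers carrying
a format-version tag.  Times are milliseconds, sampling rates kHz,
voltages normalized units.  Neuron indices are 1-based in files (matching
the usual neuron numbering convention) and 0-based in memory; conversion
is confined to the readers/writers here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import netsim
from .netsim import DriveSpec, NetworkSpec, NeuronParams, ParameterError
from .vargc import TimeSeriesSet

TIMESERIES_TAG = "ifgc-timeseries v1"
SPIKES_TAG = "ifgc-spikes v1"


class FormatError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# time-series tables
# ---------------------------------------------------------------------------

def write_timeseries(ts: TimeSeriesSet, path) -> None:
    """Columnar text table (default) or, for a ``.npz`` suffix, a binary
    array container better suited to long recordings."""
    path = Path(path)
    if path.suffix == ".npz":
        np.savez_compressed(path, format=TIMESERIES_TAG, data=ts.data,
                            fs_khz=float(ts.fs),
                            labels=np.array([str(c) for c in
                                             ts.channel_labels]))
        return
    header = (f"{TIMESERIES_TAG}\n"
              f"fs_khz = {float(ts.fs)!r}\n"
              f"n_channels = {ts.n_channels}\n"
              "columns: time_ms " +
              " ".join(f"ch{lab}" for lab in ts.channel_labels))
    t = (np.arange(ts.n_samples) + 0.5) / ts.fs
    np.savetxt(path, np.column_stack([t, ts.data]), fmt="%.17g",
               header=header, comments="# ")


def _read_header(path, tag):
    meta, n_header = {}, 0
    with open(path) as fh:
        first = fh.readline()
        if not first:
            raise FormatError(f"{path}: empty file")
        if first.strip() != f"# {tag}":
            raise FormatError(f"{path}: missing or unknown format tag "
                              f"(expected '# {tag}')")
        n_header = 1
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            body = line[1:].strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
    return meta, n_header

def read_timeseries(path) -> TimeSeriesSet:
    """Inverse of :func:`write_timeseries`; round-trips values and fs
    exactly.  Malformed rows are reported with line and column numbers."""
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as z:
            if str(z["format"]) != TIMESERIES_TAG:
                raise FormatError(f"{path}: unknown container format "
                                  f"{z['format']!r}")
            return TimeSeriesSet(z["data"], fs=float(z["fs_khz"]),
                                 channel_labels=list(z["labels"]))
    meta, n_header = _read_header(path, TIMESERIES_TAG)
    if "fs_khz" not in meta:
        raise FormatError(f"{path}: header lacks fs_khz")
    fs = float(meta["fs_khz"])
    try:
        arr = np.loadtxt(path, comments="#", ndmin=2)
    except ValueError:
        # slow diagnostic pass to locate the offending cell
        with open(path) as fh:
            width = None
            for ln, line in enumerate(fh, start=1):
                if line.startswith("#") or not line.strip():
                    continue
                cells = line.split()
                if width is None:
                    width = len(cells)
                elif len(cells) != width:
                    raise FormatError(f"{path}:{ln}: ragged row "
                                      f"({len(cells)} != {width} columns)")
                for col, c in enumerate(cells, start=1):
                    try:
                        float(c)
                    except ValueError:
                        raise FormatError(f"{path}:{ln}: column {col}: "
                                          f"non-numeric value {c!r}") from None
        raise FormatError(f"{path}: unparseable numeric table")
    if arr.size == 0:
        raise FormatError(f"{path}: no data rows")
    t = arr[:, 0]
    if np.any(np.diff(t) <= 0):
        bad = int(np.argmax(np.diff(t) <= 0)) + 2
        raise FormatError(f"{path}: time column not strictly increasing "
                          f"at data row {bad}")
    return TimeSeriesSet(arr[:, 1:], fs=fs)


# ---------------------------------------------------------------------------
# spike event lists
# ---------------------------------------------------------------------------

def write_spikes(spikes, path) -> None:
    """Event list ``neuron_index spike_time_ms`` (1-based indices), time
    ascending within each neuron and globally merged."""
    path = Path(path)
    rows = []
    for i, st in enumerate(spikes):
        for t in np.asarray(st, float):
            rows.append((t, i + 1))
    rows.sort()
    with open(path, "w") as fh:
        fh.write(f"# {SPIKES_TAG}\n# n_neurons = {len(spikes)}\n")
        for t, i in rows:
            fh.write(f"{i} {float(t)!r}\n")


def read_spikes(path, n_neurons: Optional[int] = None):
    """Inverse of :func:`write_spikes`: per-neuron ascending spike times."""
    path = Path(path)
    meta, _ = _read_header(path, SPIKES_TAG)
    n = int(meta.get("n_neurons", n_neurons or 0))
    if n_neurons is not None:
        n = n_neurons
    if n <= 0:
        raise FormatError(f"{path}: neuron count undeclared")
    spikes = [[] for _ in range(n)]
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.split()
            if len(parts) != 2:
                raise FormatError(f"{path}:{ln}: expected 'index time_ms'")
            try:
                i, t = int(parts[0]), float(parts[1])
            except ValueError:
                raise FormatError(f"{path}:{ln}: non-numeric entry") from None
            if not 1 <= i <= n:
                raise FormatError(f"{path}:{ln}: neuron index {i} outside 1..{n}")
            if t < 0:
                raise FormatError(f"{path}:{ln}: negative spike time")
            spikes[i - 1].append(t)
    out = []
    for i, st in enumerate(spikes):
        a = np.asarray(st, float)
        if np.any(np.diff(a) < 0):
            raise FormatError(f"{path}: spike times of neuron {i + 1} "
                              "not nondecreasing")
        out.append(a)
    return out


def read_adjacency(path, n_neurons: Optional[int] = None) -> np.ndarray:
    """Dense 0/1 matrix (whitespace table) or edge list ('src dst' 1-based
    per line, requires ``n_neurons``)."""
    path = Path(path)
    arr = np.loadtxt(path, comments="#", ndmin=2)
    if arr.shape[1] == 2 and (n_neurons is not None
                              and arr.shape[0] != n_neurons):
        A = np.zeros((n_neurons, n_neurons), dtype=np.int8)
        for src, dst in arr.astype(int):
            if not (1 <= src <= n_neurons and 1 <= dst <= n_neurons):
                raise FormatError(f"{path}: edge ({src}, {dst}) out of range")
            A[src - 1, dst - 1] = 1
        return A
    if arr.shape[0] != arr.shape[1]:
        raise FormatError(f"{path}: adjacency must be square "
                          "(or pass n_neurons for an edge list)")
    return arr.astype(np.int8)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

_SCHEMA = {
    "network": {"n_exc", "n_inh", "density", "adjacency_file", "edges",
                "s_ee", "s_ie", "s_ei", "s_ii", "model_kind", "seed"},
    "neuron": {"g_l", "e_l", "e_e", "e_i", "v_th", "v_reset", "tau_e",
               "tau_i", "tau_ref", "delta_t", "v_t", "v_cut"},
    "drive": {"rate", "strength", "common_rate", "common_strength",
              "common_targets"},
    "run": {"duration_ms", "dt_ms", "fs_khz", "seed"},
    "gc": {"order", "max_order", "alpha", "bonferroni", "mode", "fs_bin_khz"},
    "pipeline": {"threshold_method", "partition"},
}


@dataclass
class RunConfig:
    network: NetworkSpec
    neuron: NeuronParams
    drive: DriveSpec
    run: dict = field(default_factory=dict)
    gc: dict = field(default_factory=dict)
    pipeline: dict = field(default_factory=dict)


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration.

    Unknown sections or keys are rejected; every field is range-checked by
    the domain-type constructors before any compute starts.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise FormatError(f"{path}: top level must be a mapping")
    for section, content in raw.items():
        if section not in _SCHEMA:
            raise FormatError(f"{path}: unknown section {section!r}")
        if content is None:
            continue
        unknown = set(content) - _SCHEMA[section]
        if unknown:
            raise FormatError(f"{path}: unknown key(s) {sorted(unknown)} "
                              f"in section {section!r}")
    net_raw = dict(raw.get("network") or {})
    n_exc = int(net_raw.get("n_exc", 2))
    n_inh = int(net_raw.get("n_inh", 0))
    n = n_exc + n_inh
    if "adjacency_file" in net_raw:
        A = read_adjacency(path.parent / net_raw["adjacency_file"], n)
    elif "edges" in net_raw:
        A = np.zeros((n, n), dtype=np.int8)
        for src, dst in net_raw["edges"]:
            A[int(src) - 1, int(dst) - 1] = 1
    elif "density" in net_raw:
        A = netsim.generate_random_network(
            n_exc, n_inh, float(net_raw["density"]),
            seed=int(net_raw.get("seed", 0))).adjacency
    else:
        raise FormatError(f"{path}: network needs density, edges or "
                          "adjacency_file")
    try:
        network = NetworkSpec(
            n_exc=n_exc, n_inh=n_inh, adjacency=A,
            S_ee=float(net_raw.get("s_ee", 0.03)),
            S_ie=float(net_raw.get("s_ie", 0.03)),
            S_ei=float(net_raw.get("s_ei", 0.03)),
            S_ii=float(net_raw.get("s_ii", 0.03)),
            model_kind=str(net_raw.get("model_kind", "IF")))
        rename = {"g_l": "g_L", "e_l": "E_L", "e_e": "E_E", "e_i": "E_I",
                  "v_th": "V_th", "v_reset": "V_reset", "tau_e": "tau_E",
                  "tau_i": "tau_I", "tau_ref": "tau_ref",
                  "delta_t": "delta_T", "v_t": "V_T", "v_cut": "V_cut"}
        neuron = NeuronParams(**{rename[k]: float(v)
                                 for k, v in (raw.get("neuron") or {}).items()})
        drive_raw = dict(raw.get("drive") or {})
        run = dict(raw.get("run") or {})
        drive = DriveSpec(rate=float(drive_raw.get("rate", 0.1)),
                          strength=float(drive_raw.get("strength", 0.07)),
                          common_rate=float(drive_raw.get("common_rate", 0.0)),
                          common_strength=float(
                              drive_raw.get("common_strength", 0.1)),
                          common_targets=drive_raw.get("common_targets"),
                          seed=int(run.get("seed", 0)))
    except (ParameterError, TypeError, ValueError) as exc:
        raise FormatError(f"{path}: invalid parameter: {exc}") from exc
    return RunConfig(network=network, neuron=neuron, drive=drive, run=run,
                     gc=dict(raw.get("gc") or {}),
                     pipeline=dict(raw.get("pipeline") or {}))


def write_manifest(path, provenance: dict) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        return str(o)
    with open(path, "w") as fh:
        json.dump({"format": "ifgc-manifest v1", **provenance}, fh,
                  indent=2, default=default)


def write_gc_matrix(gc, path, labels=None) -> None:
    """GC matrix as a delimited table with a header row of channel labels."""
    m = gc.values.shape[0]
    labels = labels or [str(i + 1) for i in range(m)]
    header = (f"ifgc-gcmatrix v1\norder = {gc.order}\n"
              f"n_samples = {gc.n_samples}\nmode = {gc.mode}\n"
              "columns: " + " ".join(labels))
    np.savetxt(path, gc.values, fmt="%.10e", header=header, comments="# ")
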