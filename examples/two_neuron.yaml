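# Unidirectional two-neuron network (neuron 1 -> neuron 2), intermediate
# drive regime.  All values are overridable on the command line.
network:
  n_exc: 2
  edges: [[1, 2]]     # 1-based: presynaptic 1 -> postsynaptic 2
  s_ee: 0.03
  model_kind: IF
drive:
  rate: 0.1           # Poisson rate per neuron, 1/ms
  strength: 0.07      # conductance jump per event
run:
  duration_ms: 120000
  dt_ms: 0.05
  fs_khz: 1.0
  seed: 1
gc:
  max_order: 30
  alpha: 0.01
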