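# Example configuration: every section is optional and every key mirrors a
# dataclass field (NetworkConfig / NeuronParams / SynapseParams /
# SimProtocol / SynthConfig / analysis defaults).

network:
  N: 50
  pConn: 0.13
  WMaxNonNMDA: 0.15      # nS
  WMaxNMDA: 0.1          # nS (ramps reduce this toward 0)
  gCANMax: 2.0           # nS

neuron:
  gNaP: 2.8              # nS
  gTonic: 0.25           # nS
  mg_mM: 2.0             # NMDA Mg2+ block; 0 disables

synapse:
  tauNMDA: 20.0          # ms
  tauNonNMDA: 5.0        # ms

protocol:
  kind: nmda_ramp
  ramp_start: 0.1        # nS
  ramp_end: 0.0
  ramp_stages: 6
  stage_ms: 65000.0
  settle_ms: 5000.0
  warmup_ms: 5000.0

analysis:
  bin_ms: 20.0
  threshold: 10.0        # spikes/(s·neuron)
  min_bins: 5
  chi_bin_ms: 50.0
  min_spikes: 3
  hf_cut: 95.0
  window_s: 120.0

synth:
  n_units: 30
  duration_s: 1800.0
  burst_rate_hz: 0.25
  tonic_rate_hz: 0.3
  blocks:
    - label: baseline
      duration_s: 600.0
    - label: ne
      duration_s: 600.0
      overrides: {burst_rate_hz: 0.4, spikes_per_burst_mean: 12.0,
                  timing_center: -0.05}
    - label: apv
      duration_s: 600.0
      overrides: {burst_rate_hz: 0.45, spikes_per_burst_mean: 6.0,
                  participation: 0.75}
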