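# Frozen framework-default neuron constants, one block per current.
# These are the package defaults (framework-derived and calibrated; see
# docs/methods.md); edit a copy and load it with load_neuron_params().

membrane:
  C: 21.0          # pF
  gL: 2.8          # nS (heterogeneous in networks)
  EL: -66.0        # mV
  gTonic: 0.25     # nS
  Esyn: 0.0        # mV

ina:
  gNa: 28.0        # nS
  ENa: 50.0        # mV
  theta_m: -34.0   # mV
  sigma_m: -5.0    # mV

ik:
  gK: 11.2         # nS
  EK: -85.0        # mV
  theta_n: -29.0   # mV
  sigma_n: -4.0    # mV
  tau_n_max: 10.0  # ms

inap:
  gNaP: 2.8        # nS (heterogeneous in networks)
  theta_mp: -40.0  # mV
  sigma_mp: -6.0   # mV
  theta_hp: -48.0  # mV
  sigma_hp: 6.0    # mV
  tau_hp_max: 10000.0  # ms

ica:
  gCa: 0.7         # nS
  ECa: 150.0       # mV
  theta_mc: -27.5  # mV
  sigma_mc: -5.7   # mV
  tau_mc: 0.5      # ms
  theta_hc: -52.4  # mV
  sigma_hc: 5.2    # mV
  tau_hc: 18.0     # ms

ican:
  gCAN: 1.0        # nS (heterogeneous in networks)
  ECAN: 0.0        # mV
  KCAN: 0.74       # µM
  nCAN: 2.0        # Hill coefficient

calcium:
  tauCa: 150.0     # ms
  alphaCa: 1.6e-3  # µM/fC
  CaMin: 0.05      # µM

nmda_block:
  mg_mM: 2.0       # mM; 0 disables the Jahr-Stevens factor
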