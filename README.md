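# prebotc

Conductance-based simulation of the preBötzinger complex (preBötC) — the
medullary network that generates the inspiratory breathing rhythm — together
with the spike-train analysis pipeline used on sorted multi-electrode-array
(MEA) recordings of that network.

**For whom:** computational and systems neurophysiologists studying
respiratory rhythmogenesis, neuromodulation (norepinephrine, NMDAR
blockade) and population-burst dynamics, who need either (a) a fast,
reproducible in silico preBötC network in which the *source* of
intracellular Ca²⁺ is an experimental knob, or (b) a tested implementation
of the standard MEA burst/synchrony/participation/transmission analyses
that runs on any `(unit, spike time)` table.

## The model

Each of N = 100 neurons is a Hodgkin–Huxley-style single compartment:

C dV/dt = −I_Na − I_K − I_NaP − I_Ca − I_CAN − I_leak − I_tonic − I_nonNMDA − I_NMDA

with Butera-style spiking and persistent-sodium kinetics (slow inactivation
h_NaP paces bursts), a Hill-activated calcium-dependent cation current
I_CAN = ḡ_CAN·Ca²/(Ca² + K²)·(V − E_CAN) that amplifies bursts, and
jump-and-decay excitatory synapses with fast non-NMDA (τ = 5 ms) and slow
NMDA (τ = 20 ms) components on a random directed graph (p = 0.13,
per-edge weights U(0, W_max)).  Intracellular calcium is one pool,

dCa/dt = −α_Ca (P_ICa·I_Ca + P_nonNMDAca·I_nonNMDA + P_NMDAca·I_NMDA) − (Ca − Ca_min)/τ_Ca,

and the routing triple selects the **CaV**, **CaK** or **CaN** variant
(calcium exclusively from voltage-gated channels, non-NMDA synapses, or
NMDA synapses).  Routing touches only the calcium balance — membrane
currents are identical across variants.  Integration is exponential Euler
at Δt = 0.025 ms in a numba kernel; spikes are −35 mV upward crossings.

The analysis side implements: population activity in spikes/(s·neuron) on
20 ms bins; threshold-crossing burst detection (default 10 spikes/(s·neuron),
runs must exceed 5 bins); the Golomb-style synchrony score
χ = √(Var_t X̄ / mean_i Var_t x_i) on 50 ms bins; burst-peak-aligned,
duration-normalized spike timing; per-unit participation (≥ 3 spikes per
cycle) with high-fidelity (> 95%) / low-fidelity / silent classes and
condition transitions; and preBötC→XII burst matching (500–750 ms growing
tolerance) with normalized input–output ratios.

A synthetic raster generator (`prebotc.synth`) emulates the statistical
structure of the recordings — rhythmic bursts, programmable per-unit
participation, tonic firing, condition blocks — with complete ground
truth, so every stage is testable without data downloads.

## Worked example

```python
import dataclasses
from prebotc import (NetworkConfig, SimProtocol, SynapseParams,
                     build_network, run_nmda_ramp)
from prebotc.simulate import ramp_summary

net = build_network(NetworkConfig(N=50, seed=2, gCANMax=2.0, WMaxNMDA=0.1),
                    variant="can", synapse=SynapseParams(tauNMDA=20.0))
proto = SimProtocol(kind="nmda_ramp", ramp_start=0.1, ramp_end=0.0,
                    ramp_stages=6, stage_ms=65000.0, settle_ms=5000.0,
                    warmup_ms=5000.0, seed=2)
summary = ramp_summary(run_nmda_ramp(net, proto))
print(summary[["WMaxNMDA", "frequency_med_hz", "amplitude_med", "chi"]]
      .round(3).to_string(index=False))
```

prints (CaN variant, ḡ_CAN = 2 nS, NMDA weight bound ramped 0.1 → 0 nS):

```
 WMaxNMDA  frequency_med_hz  amplitude_med    chi
     0.10             0.157           77.0  0.867
     0.08             0.174           68.0  0.847
     0.06             0.197           51.0  0.824
     0.04             0.218           48.0  0.793
     0.02             0.238           43.5  0.751
     0.00             0.250           40.0  0.697
```

Reading it: as NMDAR weights are withdrawn from the elevated
(norepinephrine-like) state, burst **frequency rises** (0.16 → 0.25 Hz),
burst **amplitude falls** (77 → 40 spikes/(s·neuron)) and network
**synchrony χ falls** (0.87 → 0.70) — the signature of NMDAR-routed
calcium driving ICAN-dependent burst amplification.  Repeating the same
ramp in the CaV or CaK variant, or with τ_NMDA shortened to 5 ms, leaves
frequency and amplitude nearly flat.

The same pipeline runs from the shell:

```bash
prebotc simulate --variant can --protocol ramp --seed 2 --out runs/ramp
prebotc synth --seed 1 --out runs/synth
prebotc analyze-raster --raster runs/synth/raster.csv --duration 600 --out runs/analysis
prebotc validate --seed 1 --out runs/validate
```

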