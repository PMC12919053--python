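# Methods

## Scope

`prebotc` couples two things that are usually studied together but coded
separately: an in silico preBötzinger-complex (preBötC) network in which
NMDAR-routed synaptic calcium drives ICAN-dependent burst amplification,
and the spike-train analysis pipeline applied to sorted multi-electrode
(MEA) recordings of such networks — population-burst detection, the χ
synchrony score, burst-aligned spike timing, per-unit participation and
fidelity, and preBötC→XII transmission.  A synthetic raster generator with
full ground truth stands in for recordings, so the entire analysis chain is
testable offline.

## Single-neuron model

Each neuron is a single compartment with

I<sub>Na</sub> (spike-generating, instantaneous m∞³ activation, 1−n
inactivation), I<sub>K</sub> (delayed rectifier, n⁴), I<sub>NaP</sub>
(persistent sodium, instantaneous activation, slow inactivation h<sub>NaP</sub>
with τ up to 10 s), I<sub>Ca</sub> (voltage-gated calcium), I<sub>CAN</sub>
(calcium-activated nonspecific cation), leak, a tonic excitatory
conductance, and two dynamic excitatory synaptic currents: fast non-NMDA
(τ = 5 ms) and slow NMDA (τ = 20 ms).

The spiking/INaP kinetics follow the classic preBötC framework lineage
(Butera-style model 1; gNa = 28 nS, gK = 11.2 nS, gNaP ≈ 2.8 nS,
C = 21 pF), extended with the ICa/ICAN/calcium-pool structure of the
Jasinski/Rubin family (K<sub>CAN</sub> = 0.74 µM).  Beyond that framework
level the remaining constants are calibrated defaults, exposed in
configuration (a frozen copy ships as
`prebotc/data/framework_defaults.yaml`) and stamped into run metadata.  The calibration was done
once, during model construction, to place the network in the reported
operating regime (rhythmic 0.15–0.5 Hz population bursts, silent or
sparsely tonic interburst activity, burst amplitudes of tens of
spikes/(s·neuron)):

| parameter | default | units | why |
|---|---|---|---|
| EL | −66 | mV | with gTonic = 0.25 nS puts most cells just below burst threshold |
| gTonic | 0.25 | nS | network-wide excitability; > ~0.4 tips the net tonic |
| gL, gNaP | N(2.8, 0.28), N(2.8, 0.56), truncated ≥ 0 | nS | heterogeneity: mixture of silent cells, conditional bursters and pacemakers |
| gCa | 0.7 | nS | gives the CaV routing variant a calcium supply comparable to the synaptic variants |
| αCa | 1.6·10⁻³ | µM/fC | sets in-burst Ca ≈ 0.3–1.7 µM in the CaN variant at WMax,NMDA = 0.1 nS |
| τCa | 150 | ms | calcium tracks within-burst structure but outlives single spikes |
| CaMin | 0.05 | µM | resting level; ICAN ≈ 4·10⁻³ activated at rest |
| KCAN, nCAN | 0.74 µM, 2 | — | saturating Hill activation; slope 2 (cooperative, TRPM4-like) |
| Mg²⁺ | 2.0 | mM | Jahr–Stevens voltage-dependent NMDA block (see below) |

Two deliberate deviations from the most common framework choices, both
config-reversible:

* **NMDA Mg²⁺ block on by default.**  Without the block, the direct
  depolarization carried by the slow NMDA conductance dominates network
  excitability, and every routing variant — not just CaN — responds
  strongly to the NMDA weight.  With a Jahr–Stevens block
  (1/(1 + [Mg]/3.57·e^(−0.062V)), [Mg] = 2 mM) the NMDA current's direct
  voltage role is strongly suppressed at interburst potentials while its
  calcium role survives, which is exactly the separation the three-variant
  experiment (CaV/CaK/CaN) is about.  Set `mg_mM = 0` for the pure
  conductance·gate·driving-force form.
* **ICAN Hill slope 2 rather than ≈ 1.**  A cooperative activation curve
  discriminates the calcium levels reached with slow (τ = 20 ms) versus
  fast (τ = 5 ms) NMDA kinetics; slope-1 activation is nearly linear below
  K<sub>CAN</sub> and blurs that contrast.  TRPM4-like channels are
  reported with Hill slopes ≥ 2.

## Calcium routing

Intracellular calcium is one first-order pool:

dCa/dt = −αCa·(P<sub>ICa</sub>·I<sub>Ca</sub> + P<sub>nonNMDAca</sub>·I<sub>nonNMDA</sub> + P<sub>NMDAca</sub>·I<sub>NMDA</sub>) − (Ca − Ca<sub>min</sub>)/τ<sub>Ca</sub>

with the routing triple (P<sub>ICa</sub>, P<sub>nonNMDAca</sub>,
P<sub>NMDAca</sub>) equal to (1,0,0), (0,1,0), (0,0,1) for the CaV, CaK and
CaN variants.  Routing enters *only* this equation; the membrane currents
are bit-identical across variants (enforced by a test that clamps calcium
by setting αCa ≈ 0 and checks identical voltage trajectories).

## Network

N = 100 neurons (sweep/ramp experiments in this repository run N = 50; see
"Problem sizes"), directed Erdős–Rényi connectivity with p = 0.13, no
self-connections.  Both receptor weights live on one shared adjacency and
are drawn per edge as U(0, WMax): WMax = 0.15 nS (non-NMDA) and 0.05 nS
(NMDA) statically, with NMDA swept over [0, 0.1] nS in experiments.
gCAN ~ U(0, ḡCAN) per neuron.  One root seed spawns separate child streams
for topology, per-neuron parameters, and each weight matrix, so rescaling
a bound never perturbs the topology.

Synapses are jump-and-decay: a presynaptic spike adds the connection
weight to the postsynaptic summed gate (linear superposition, no
saturation, instantaneous rise); gates decay exponentially.  A
dual-exponential rise is deliberately out of scope — the kinetic
experiment of interest manipulates only the decay constant.

## Integration

Fixed-step exponential Euler, Δt = 0.025 ms.  V and the gating variables
advance with state-frozen relaxation factors; calcium and synaptic gates
use exact exponential decay plus forcing, which keeps all gates in [0, 1]
by construction.  Voltage-dependent steady states and per-step decay
factors are tabulated on a 0.02 mV grid and linearly interpolated inside a
numba kernel.  A spike is an upward crossing of −35 mV with re-arming
below −40 mV (hysteresis avoids double counts on threshold dither).  Spikes propagate to postsynaptic
gates at the step they occur.

Validation: exponential Euler is exact on the passive membrane (matches
the closed form to machine precision); a quiescent neuron matches a
classical 4th-order Runge–Kutta reference at Δt/10 to < 0.05 mV over 2 s;
a repetitively spiking neuron shows the expected first-order phase drift
(~0.35 ms per spike at Δt = 0.025 ms, ten times smaller at Δt/10) with
firing rate preserved to a few percent.  Initial conditions are V = EL,
gates at steady state, Ca = CaMin, synaptic gates 0; a 5 s warm-up is
discarded.

## Protocols

* **fixed** — one condition, one summary.
* **nmda_ramp** — the in-silico analogue of progressive NMDAR blockade
  from a noradrenergic-like elevated state: initialize at
  WMax,NMDA = 0.1 nS and reduce linearly to 0 in piecewise-constant stages
  (library default 11 stages × 20 s; the experiments in this repository
  use 6 stages × 90 s with the first 5 s of each stage discarded).  State
  carries across stages.
* **sweep** — grid over (ḡCAN, WMax,NMDA) with per-point burst/synchrony
  summaries; per-point divergences are recorded and skipped.

## Analysis definitions

* **Population activity**: spikes of all units binned at 20 ms, divided by
  bin width and unit count → spikes/(s·neuron); half-open bins anchored at
  t = 0; a trailing partial bin is dropped.
* **Burst detection**: onset at an upward crossing of the threshold
  (default 10 spikes/(s·neuron)), termination at the next downward
  crossing; runs must strictly exceed 5 bins; runs touching
  a record boundary are dropped; the peak is the maximum of a centered
  3-bin boxcar-smoothed signal within the run, with amplitude reported
  from the raw signal at that bin.
* **Burst frequency**: inverse inter-peak intervals.  Stage summaries
  report both the mean and the median of the instantaneous frequencies
  (and of peak amplitudes).  At the scaled-down N = 50 used here the
  rhythm occasionally produces a small doublet burst; a single short
  interval then dominates the mean of 1/interval, so trend statistics in
  this repository use the median columns.  At larger N the two coincide.
* **χ synchrony**: 50 ms binned counts x_i(t);
  χ = sqrt(Var_t[X̄] / mean_i Var_t[x_i]) (population variances).  χ = 1
  for identical trains and ≈ 1/√N for independent ones.  All-constant
  rasters give a missing value with a warning, never a number.
* **Burst-aligned timing**: spikes inside onset→termination map to
  (t − t_peak)/duration (negative = early); inter-burst spikes are
  excluded.  Peak action-potential density time = arg-max of a Gaussian
  KDE (Silverman bandwidth), ties broken toward the earliest time; mean
  firing time = arithmetic mean.
* **Participation**: a unit participates in a cycle when it fires ≥ 3
  spikes inside the burst window (half-open at termination).  Percent
  participation over the analysis window (default: last 120 s of a
  condition); > 95% ⇒ high fidelity, exactly 95% ⇒ low fidelity (the
  source leaves the boundary open; strict ">" chosen), participation 0 ⇒
  silent.  Cycle skipping = 100 − participation.
* **Transmission**: preBötC and XII burst-start times matched within a
  tolerance grown from 500 ms in 50 ms steps up to 750 ms while the
  assignment stays one-to-one (nearest-in-time; earlier event on exact
  tie; if no tolerance is conflict-free the 750 ms assignment is used with
  duplicate claims beyond the nearest left unmatched).  Amplitudes are
  normalized by their own analysis-window means before
  IO_n = BA_XII/BA_preBötC; unmatched cycles get IO_n = 0, making IO
  invariant to rescaling either raw series.

## Synthetic data

The generator emulates the statistical structure the analyses consume,
not biophysics: bursts from a jittered renewal process (default 0.25 Hz,
CV 0.15, duration 0.5 ± 0.05 s), Bernoulli per-unit participation,
Poisson-above-minimum in-burst spike counts placed by a truncated Gaussian
in normalized burst time, homogeneous Poisson tonic firing between bursts,
and ordered condition blocks with per-block overrides (a noradrenergic-like
block raises burst rate and in-burst firing; an NMDAR-blockade-like block
lowers counts and participation).  Everything is reproducible per seed and
every spike is traceable to a burst or the tonic process.

What passing recovery tests shows: the pipeline measures what it claims to
measure on data with exactly the assumed structure.  What it does not
show: robustness to sorting errors, electrode drift, bursts with
non-Gaussian timing profiles, or sighs — real-recording features the
generator deliberately omits.

One measurement subtlety the generator exposes: detected burst windows
(threshold crossings) sit slightly inside the programmed windows, so
participation measured against detected windows can undercount a unit
whose few spikes fall in the outermost tails.  Recovery tests therefore
check participation against the programmed windows (exact) and detected
windows (approximate).

## Problem sizes

Simulation experiments in the tests and the acceptance script run N = 50
networks, 6-stage ramps with 60 s analyzed per stage, and 1–3 seeds;
these sizes give stable trend statistics for this model family while
keeping a full run on a single CPU in the tens of minutes.  The library
defaults remain at full scale (N = 100, 11 stages).

## Known limitations

* The exact published equation set (supplementary material) is not
  reproduced; defaults are framework-derived and calibrated as described.
  Anyone holding the original constants can drop them into
  `NeuronParams`/`NetworkConfig` unchanged.
* Single-compartment, purely excitatory network: no inhibition, no sigh
  mechanism, no spatial structure.
* The instantaneous-frequency mean is heavy-tailed at small N (see
  above); median columns are provided.
* The χ denominator uses population variance; for very short records the
  sample-variance convention differs by T/(T−1).
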