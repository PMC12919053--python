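"""Network integration and the simulation protocols.

Integration is fixed-step exponential Euler (default Δt = 0.025 ms): V and
the voltage-gated variables are advanced with state-frozen relaxation
factors, calcium and the synaptic gates with exact exponential decay plus
forcing.  A spike is registered when V crosses −35 mV from below; the
detector re-arms once V falls back below −40 mV, so a trace dithering
around threshold counts a single spike.  Spikes propagate to postsynaptic
gates at the step they occur.

Three protocols are provided: a fixed condition, a staged NMDA-weight ramp
(the in-silico analogue of progressive NMDAR blockade), and a 2-D
(gCANMax, WMaxNMDA) parameter sweep summarized through the burst and
synchrony metrics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import _kernel
from .conductance import NeuronParams, steady_gates
from .network import NetworkConfig, NetworkModel, build_network, scale_nmda_weights
from .raster import SpikeRaster

__all__ = ["SimProtocol", "SimResult", "integrate", "detect_spikes",
           "run_nmda_ramp", "run_sweep", "SimulationError"]


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SimProtocol:
    """Integration and protocol settings (times in ms)."""

    duration_ms: float = 60000.0
    dt_ms: float = 0.025
    warmup_ms: float = 5000.0          # discarded transient before t = 0
    record: tuple = ("V", "Cai", "ICAN", "hNaP")
    record_every_ms: float = 1.0
    kind: str = "fixed"                # fixed | nmda_ramp | sweep
    # nmda_ramp settings
    ramp_start: float = 0.1            # nS
    ramp_end: float = 0.0              # nS
    ramp_stages: int = 11
    stage_ms: float = 20000.0
    settle_ms: float = 5000.0          # discarded at the head of each stage
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt_ms <= 0 or self.duration_ms < self.dt_ms:
            raise ValueError("need dt > 0 and duration >= dt")
        if not self.ramp_start >= self.ramp_end >= 0:
            raise ValueError("ramp requires start >= end >= 0")
        if self.kind not in ("fixed", "nmda_ramp", "sweep"):
            raise ValueError(f"unknown protocol kind {self.kind!r}")


@dataclass
class SimResult:
    """Raster plus population-averaged traces and per-stage bookkeeping."""

    raster: SpikeRaster
    traces: pd.DataFrame               # time_s + mean_V/mean_Cai/mean_ICAN/mean_hNaP
    protocol: SimProtocol
    stages: pd.DataFrame | None = None  # stage, WMaxNMDA, t0_s, t1_s, analysis_t0_s

    def stage_raster(self, stage: int) -> SpikeRaster:
        """Raster restricted to one ramp stage's analysis window."""
        row = self.stages.iloc[stage]
        return self.raster.restrict(row.analysis_t0_s, row.t1_s)


class _NetState:
    """Mutable per-neuron state vectors handed to the kernel."""

    def __init__(self, model: NetworkModel):
        p = model.base
        n = model.N
        h_nap, gate = steady_gates(p.EL, p)
        self.V = np.full(n, p.EL, dtype=np.float64)
        self.n = np.full(n, gate[0], dtype=np.float64)
        self.hp = np.full(n, h_nap, dtype=np.float64)
        self.mc = np.full(n, gate[1], dtype=np.float64)
        self.hc = np.full(n, gate[2], dtype=np.float64)
        self.ca = np.full(n, p.CaMin, dtype=np.float64)
        self.sN = np.zeros(n)
        self.sNN = np.zeros(n)
        self.armed = np.ones(n, dtype=np.bool_)


def _run_block(model: NetworkModel, state: _NetState, duration_ms: float,
               dt: float, rec_every: int, tables: dict):
    """Advance the network by one block; returns (spike df ms, trace arrays)."""
    p = model.base
    syn = model.synapse
    r = model.routing
    n_steps = int(round(duration_ms / dt))
    n_rec = (n_steps + rec_every - 1) // rec_every
    trV, trCa, trCAN, trH = (np.empty(n_rec) for _ in range(4))
    cap = int(model.N * duration_ms * 0.12) + 1000
    sp_steps = np.empty(cap, dtype=np.int64)
    sp_units = np.empty(cap, dtype=np.int32)
    err = np.zeros(2, dtype=np.int64)

    n_sp, status = _kernel.run_stage(
        state.V, state.n, state.hp, state.mc, state.hc, state.ca,
        state.sN, state.sNN, state.armed,
        model.gL, model.gNaP, model.gCAN,
        np.ascontiguousarray(model.WNMDA.T * syn.increment),
        np.ascontiguousarray(model.WnonNMDA.T * syn.increment),
        n_steps, dt,
        p.C, p.gNa, p.gK, p.gCa, p.gTonic,
        p.ENa, p.EK, p.ECa, p.EL, p.Esyn, p.ECAN,
        p.KCAN, p.nCAN, p.tauCa, p.alphaCa, p.CaMin,
        r.PICa, r.PnonNMDAca, r.PNMDAca,
        math.exp(-dt / syn.tauNMDA), math.exp(-dt / syn.tauNonNMDA),
        math.exp(-dt / p.tauCa), math.exp(-dt / p.tau_mc),
        math.exp(-dt / p.tau_hc),
        _kernel.V_GRID_MIN, 1.0 / _kernel.V_GRID_STEP,
        tables["minf3"], tables["ninf"], tables["ndec"], tables["hpinf"],
        tables["hpdec"], tables["mpinf"], tables["mcinf"], tables["hcinf"],
        tables["mgb"], p.mg_mM > 0,
        -35.0, -40.0,
        sp_steps, sp_units,
        rec_every, trV, trCa, trCAN, trH,
        err,
    )
    if status == 1:
        raise SimulationError(
            f"divergence at step {err[0]} (t = {err[0] * dt:.3f} ms), "
            f"neuron {err[1]}")
    if status == 2:
        raise SimulationError(f"spike buffer overflow at step {err[0]}")
    times_ms = sp_steps[:n_sp] * dt
    units = sp_units[:n_sp]
    return units, times_ms, (trV, trCa, trCAN, trH)


def _assemble(model, protocol, units, times_ms, traces, t_offset_ms=0.0,
              duration_ms=None):
    duration_ms = duration_ms if duration_ms is not None else protocol.duration_ms
    spikes = []
    for i in range(model.N):
        sel = units == i
        spikes.append(np.sort(times_ms[sel]) / 1e3)
    raster = SpikeRaster(list(range(model.N)), spikes, duration_ms / 1e3,
                         provenance="simulated")
    trV, trCa, trCAN, trH = traces
    t = (np.arange(trV.size) * protocol.record_every_ms + t_offset_ms) / 1e3
    df = pd.DataFrame({"time_s": t, "mean_V": trV, "mean_Cai": trCa,
                       "mean_ICAN": trCAN, "mean_hNaP": trH})
    return raster, df


def integrate(model: NetworkModel, protocol: SimProtocol) -> SimResult:
    """Run a fixed-condition simulation; warm-up is run and discarded."""
    model.validate()
    dt = protocol.dt_ms
    rec_every = max(1, int(round(protocol.record_every_ms / dt)))
    tables = _kernel.build_tables(model.base, dt)
    state = _NetState(model)
    if protocol.warmup_ms > 0:
        _run_block(model, state, protocol.warmup_ms, dt, rec_every, tables)
    units, times_ms, traces = _run_block(
        model, state, protocol.duration_ms, dt, rec_every, tables)
    raster, df = _assemble(model, protocol, units, times_ms, traces)
    return SimResult(raster=raster, traces=df, protocol=protocol)


def run_nmda_ramp(model: NetworkModel, protocol: SimProtocol) -> SimResult:
    """Staged reduction of the NMDA weight bound from ramp_start to ramp_end.

    Stage weight bounds are linearly spaced (inclusive of both endpoints);
    network state carries over between stages and the first ``settle_ms``
    of each stage is excluded from the per-stage analysis window.
    """
    if protocol.kind != "nmda_ramp":
        raise ValueError("protocol.kind must be 'nmda_ramp'")
    model.validate()
    dt = protocol.dt_ms
    rec_every = max(1, int(round(protocol.record_every_ms / dt)))
    tables = _kernel.build_tables(model.base, dt)
    state = _NetState(model)
    if protocol.warmup_ms > 0:
        w0 = scale_nmda_weights(model, new_wmax=protocol.ramp_start) \
            if model.config.WMaxNMDA > 0 else model
        _run_block(w0, state, protocol.warmup_ms, dt, rec_every, tables)

    stage_w = np.linspace(protocol.ramp_start, protocol.ramp_end,
                          protocol.ramp_stages)
    all_units, all_times, trace_frames, stage_rows = [], [], [], []
    t0 = 0.0
    for s, w in enumerate(stage_w):
        staged = scale_nmda_weights(model, new_wmax=float(w)) \
            if model.config.WMaxNMDA > 0 else model
        units, times_ms, traces = _run_block(
            staged, state, protocol.stage_ms, dt, rec_every, tables)
        all_units.append(units)
        all_times.append(times_ms + t0)
        _, df = _assemble(model, protocol, units, times_ms, traces,
                          t_offset_ms=t0, duration_ms=protocol.stage_ms)
        trace_frames.append(df)
        stage_rows.append({
            "stage": s, "WMaxNMDA": float(w), "t0_s": t0 / 1e3,
            "t1_s": (t0 + protocol.stage_ms) / 1e3,
            "analysis_t0_s": (t0 + protocol.settle_ms) / 1e3,
        })
        t0 += protocol.stage_ms

    units = np.concatenate(all_units) if all_units else np.empty(0, int)
    times = np.concatenate(all_times) if all_times else np.empty(0)
    spikes = [np.sort(times[units == i]) / 1e3 for i in range(model.N)]
    raster = SpikeRaster(list(range(model.N)), spikes, t0 / 1e3,
                         provenance="simulated")
    return SimResult(raster=raster, traces=pd.concat(trace_frames,
                                                     ignore_index=True),
                     protocol=protocol, stages=pd.DataFrame(stage_rows))


def summarize_stage(raster: SpikeRaster, *, bin_ms: float = 20.0,
                    threshold: float = 10.0, min_bins: int = 5,
                    chi_bin_ms: float = 50.0) -> dict:
    """Burst amplitude/frequency and synchrony for one analysis window."""
    from .bursts import bin_population_activity, burst_summary, detect_bursts
    from .synchrony import synchrony_score

    act = bin_population_activity(raster, bin_ms)
    bursts = detect_bursts(act, threshold=threshold, min_bins=min_bins)
    summ = burst_summary(bursts)
    chi = synchrony_score(raster, chi_bin_ms)
    # median summaries are reported alongside the means: at scaled-down
    # network sizes occasional burst doublets make the mean of 1/interval
    # heavy-tailed, and the median is the robust stage statistic
    return {"burst_count": summ["n_bursts"],
            "amplitude": summ["mean_peak_amplitude"],
            "frequency_hz": summ["mean_frequency_hz"],
            "amplitude_med": summ["median_peak_amplitude"],
            "frequency_med_hz": summ["median_frequency_hz"],
            "chi": chi.chi}


def ramp_summary(result: SimResult, **metric_kw) -> pd.DataFrame:
    """Per-stage burst/synchrony summary table for a ramp result."""
    rows = []
    for s in range(len(result.stages)):
        row = dict(result.stages.iloc[s])
        row.update(summarize_stage(result.stage_raster(s), **metric_kw))
        rows.append(row)
    return pd.DataFrame(rows)


def run_sweep(config: NetworkConfig, gcan_grid, wnmda_grid, *,
              variant: str = "can", base: NeuronParams | None = None,
              synapse=None, point_duration_ms: float = 60000.0,
              dt_ms: float = 0.025, warmup_ms: float = 5000.0,
              seed: int | None = None, **metric_kw) -> pd.DataFrame:
    """2-D (gCANMax, WMaxNMDA) sweep summarized per grid point.

    Each gCANMax column rebuilds the network (gCAN draws depend on the
    bound); WMaxNMDA points rescale the same network's NMDA matrix so the
    topology is matched along each column.  Divergent points are recorded
    with NaN summaries and the sweep continues.
    """
    gcan_grid = np.atleast_1d(np.asarray(gcan_grid, float))
    wnmda_grid = np.atleast_1d(np.asarray(wnmda_grid, float))
    if gcan_grid.size == 0 or wnmda_grid.size == 0:
        raise ValueError("sweep grids must be non-empty")
    seed = config.seed if seed is None else seed
    rows = []
    for g in gcan_grid:
        cfg = replace(config, gCANMax=float(g),
                      WMaxNMDA=max(wnmda_grid.max(), 1e-12), seed=seed)
        net = build_network(cfg, variant=variant, base=base, synapse=synapse)
        for w in wnmda_grid:
            point = scale_nmda_weights(net, new_wmax=float(w))
            proto = SimProtocol(duration_ms=point_duration_ms, dt_ms=dt_ms,
                                warmup_ms=warmup_ms, seed=seed)
            row = {"gCANMax": float(g), "WMaxNMDA": float(w), "seed": seed,
                   "diverged": False}
            try:
                res = integrate(point, proto)
                row.update(summarize_stage(res.raster, **metric_kw))
            except SimulationError as exc:
                row.update({"diverged": True, "error": str(exc),
                            "burst_count": np.nan, "amplitude": np.nan,
                            "frequency_hz": np.nan, "chi": np.nan})
            rows.append(row)
    return pd.DataFrame(rows)


def detect_spikes(v: np.ndarray, dt_ms: float, threshold: float = -35.0,
                  rearm: float = -40.0) -> np.ndarray:
    """Spike times (ms) from a uniformly sampled voltage trace.

    A spike is an upward crossing of ``threshold``; the detector re-arms
    only after the trace falls below ``rearm``.
    """
    v = np.asarray(v, float)
    times = []
    armed = v[0] < threshold
    for i in range(1, v.size):
        if armed and v[i] >= threshold:
            times.append(i * dt_ms)
            armed = False
        elif not armed and v[i] < rearm:
            armed = True
    return np.asarray(times)
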