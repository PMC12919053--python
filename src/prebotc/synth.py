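"""Synthetic MEA-like spike rasters and paired burst-event tables.

The generator emulates the statistical structure of sorted multi-electrode
recordings from a rhythmically bursting inspiratory network so that every
analysis stage can be exercised against known ground truth:

* rhythmic population bursts from a jittered renewal process
  (rate ~0.2–0.5 Hz, Gaussian inter-burst-interval jitter),
* per-unit Bernoulli burst participation with programmable probabilities,
* heterogeneous in-burst spike counts (Poisson above an enforceable
  minimum) placed by a truncated-Gaussian timing profile inside the burst,
* homogeneous-Poisson tonic firing between bursts, and
* ordered condition blocks (e.g. baseline / NE-like / APV-like) that
  override rates, counts and participation per block.

Everything is deterministic per seed, and the emitted ground truth records
the programmed burst windows, participation indicators and spike counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .raster import SpikeRaster
from .transmission import BurstEventTable

__all__ = ["SynthConfig", "ConditionBlock", "SynthGroundTruth",
           "generate_raster", "generate_paired_events", "PairedEventConfig"]


@dataclass(frozen=True)
class ConditionBlock:
    """One condition block: a label, a duration and parameter overrides."""

    label: str
    duration_s: float
    overrides: dict = field(default_factory=dict)


@dataclass(frozen=True)
class SynthConfig:
    """Ground-truth parameters of the synthetic recording.

    Defaults mirror a baseline-like slice regime: ~0.25 Hz network bursts
    of ~0.5 s, units participating in 90% of cycles with ~9 in-burst
    spikes, and sparse tonic activity between bursts.
    """

    n_units: int = 30
    duration_s: float = 600.0
    burst_rate_hz: float = 0.25
    ibi_cv: float = 0.15                  # inter-burst-interval jitter
    burst_duration_s: float = 0.5
    burst_duration_sd_s: float = 0.05
    participation: float | tuple = 0.9    # scalar or per-unit vector
    spikes_per_burst_mean: float = 9.0
    min_spikes: int = 3                   # enforced when participating
    timing_center: float = 0.0            # fraction of duration, vs. peak
    timing_spread: float = 0.18           # fraction of burst duration
    peak_frac: float = 0.5                # peak position within the burst
    tonic_rate_hz: float = 0.3            # per unit, between bursts
    blocks: tuple = ()                    # ConditionBlock overrides

    def __post_init__(self) -> None:
        # accept plain mappings for blocks (e.g. loaded from YAML)
        if self.blocks and isinstance(self.blocks[0], dict):
            object.__setattr__(self, "blocks", tuple(
                ConditionBlock(**b) for b in self.blocks))
        if self.duration_s <= 0 or self.n_units < 1:
            raise ValueError("need positive duration and >= 1 unit")
        for name in ("burst_rate_hz", "tonic_rate_hz", "spikes_per_burst_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        p = np.atleast_1d(np.asarray(self.participation, float))
        if ((p < 0) | (p > 1)).any():
            raise ValueError("participation probabilities must lie in [0, 1]")
        if self.burst_rate_hz > 0 and \
                self.burst_duration_s >= 1.0 / self.burst_rate_hz:
            raise ValueError("burst duration must be shorter than the "
                             "mean inter-burst interval")

    def participation_vector(self) -> np.ndarray:
        p = np.atleast_1d(np.asarray(self.participation, float))
        if p.size == 1:
            return np.full(self.n_units, float(p[0]))
        if p.size != self.n_units:
            raise ValueError("participation vector length must equal n_units")
        return p


@dataclass
class SynthGroundTruth:
    """Programmed structure behind a synthetic raster."""

    bursts: pd.DataFrame          # onset_s, peak_s, termination_s, block
    participation: np.ndarray     # bool (units, bursts)
    spike_counts: np.ndarray      # int  (units, bursts)
    participation_prob: np.ndarray
    blocks: pd.DataFrame          # label, t0_s, t1_s
    config: SynthConfig

    def burst_series(self):
        """Programmed burst windows as a BurstSeries (e.g. for counting
        in-burst spikes against the exact generator windows)."""
        from .bursts import BurstSeries
        df = self.bursts[["onset_s", "termination_s", "peak_s"]].copy()
        df["peak_amplitude"] = np.nan
        return BurstSeries(bursts=df, threshold=np.nan, min_bins=0,
                           bin_ms=np.nan)


def _truncnorm(rng, lo, hi, loc, scale, size):
    """Rejection-sampled truncated normal (loc/scale in the open interval)."""
    if scale <= 0:
        return np.full(size, np.clip(loc, lo, hi))
    out = rng.normal(loc, scale, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(loc, scale, int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def _block_bursts(cfg: SynthConfig, rng, t0: float, t1: float, label: str):
    """Burst windows for one block from the jittered renewal process."""
    rows = []
    if cfg.burst_rate_hz <= 0:
        return rows
    mean_ibi = 1.0 / cfg.burst_rate_hz
    sd_ibi = cfg.ibi_cv * mean_ibi
    t = t0 + float(_truncnorm(rng, cfg.burst_duration_s, 2 * mean_ibi,
                              mean_ibi, sd_ibi, 1)[0])
    while True:
        dur = float(_truncnorm(rng, 0.05, 3 * cfg.burst_duration_s,
                               cfg.burst_duration_s, cfg.burst_duration_sd_s,
                               1)[0])
        onset = t - cfg.peak_frac * dur
        term = onset + dur
        if term >= t1:
            break
        if onset > t0:
            rows.append({"onset_s": onset, "peak_s": t, "termination_s": term,
                         "block": label})
        gap = float(_truncnorm(rng, dur, 3 * mean_ibi, mean_ibi, sd_ibi, 1)[0])
        t += gap
    return rows


def generate_raster(config: SynthConfig, seed: int = 0
                    ) -> tuple[SpikeRaster, SynthGroundTruth]:
    """Generate a raster plus its ground truth, deterministically per seed."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EA]))
    blocks = list(config.blocks) or [ConditionBlock("baseline",
                                                    config.duration_s)]
    total = sum(b.duration_s for b in blocks)

    burst_rows, block_rows, block_cfgs = [], [], []
    t0 = 0.0
    for blk in blocks:
        bcfg = replace(config, **blk.overrides) if blk.overrides else config
        block_cfgs.append(bcfg)
        burst_rows += _block_bursts(bcfg, rng, t0, t0 + blk.duration_s,
                                    blk.label)
        block_rows.append({"label": blk.label, "t0_s": t0,
                           "t1_s": t0 + blk.duration_s})
        t0 += blk.duration_s
    bursts = pd.DataFrame(burst_rows, columns=["onset_s", "peak_s",
                                               "termination_s", "block"])
    block_df = pd.DataFrame(block_rows)
    n_b = len(bursts)
    label_cfg = {b.label: c for b, c in zip(blocks, block_cfgs)}

    part = np.zeros((config.n_units, n_b), dtype=bool)
    counts = np.zeros((config.n_units, n_b), dtype=int)
    spikes = [[] for _ in range(config.n_units)]

    for b in range(n_b):
        row = bursts.iloc[b]
        bcfg = label_cfg[row.block]
        pvec = bcfg.participation_vector()
        dur = row.termination_s - row.onset_s
        active = rng.random(config.n_units) < pvec
        part[:, b] = active
        extra_mean = max(bcfg.spikes_per_burst_mean - bcfg.min_spikes, 0.0)
        for i in np.flatnonzero(active):
            k = bcfg.min_spikes + rng.poisson(extra_mean)
            counts[i, b] = k
            center = row.peak_s + bcfg.timing_center * dur
            t_sp = _truncnorm(rng, row.onset_s, row.termination_s - 1e-9,
                              center, bcfg.timing_spread * dur, k)
            spikes[i].append(t_sp)

    # tonic firing between bursts, block-wise rates
    for blk_row, bcfg in zip(block_rows, block_cfgs):
        if bcfg.tonic_rate_hz <= 0:
            continue
        b0, b1 = blk_row["t0_s"], blk_row["t1_s"]
        span = b1 - b0
        for i in range(config.n_units):
            n_tonic = rng.poisson(bcfg.tonic_rate_hz * span)
            t_sp = rng.uniform(b0, b1, n_tonic)
            inside = np.zeros(n_tonic, dtype=bool)
            for _, br in bursts.iterrows():
                inside |= (t_sp >= br.onset_s) & (t_sp < br.termination_s)
            spikes[i].append(t_sp[~inside])

    trains = [np.sort(np.concatenate(s)) if s else np.empty(0)
              for s in spikes]
    raster = SpikeRaster(list(range(config.n_units)), trains, total,
                         provenance="synthetic")
    truth = SynthGroundTruth(bursts=bursts, participation=part,
                             spike_counts=counts,
                             participation_prob=config.participation_vector(),
                             blocks=block_df, config=config)
    return raster, truth


@dataclass(frozen=True)
class PairedEventConfig:
    """Scenario for the transmission analysis generator."""

    n_cycles: int = 100
    cycle_period_s: float = 4.0
    period_cv: float = 0.1
    transmission_prob: float = 0.8
    latency_mean_s: float = 0.1          # XII start lag after preBötC start
    latency_sd_s: float = 0.05           # truncated to [0, 0.45] s so a
                                         # transmitted event stays inside the
                                         # 500 ms base matching tolerance
    pre_amp_mean: float = 1.0
    pre_amp_cv: float = 0.2
    xii_amp_mean: float = 1.0
    xii_amp_cv: float = 0.2

    def __post_init__(self) -> None:
        if not 0 <= self.transmission_prob <= 1:
            raise ValueError("transmission_prob must lie in [0, 1]")
        if not 0 <= self.latency_mean_s <= 0.75:
            raise ValueError("latency must lie within the 0-750 ms window")


def generate_paired_events(config: PairedEventConfig, seed: int = 0):
    """Paired (preBötC, XII) burst-event tables with known transmission.

    Returns ``(pre, xii, truth)`` where truth maps each preBötC cycle to
    its programmed XII event index (−1 for failures).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x10]))
    gaps = _truncnorm(rng, 1.0, 3 * config.cycle_period_s,
                      config.cycle_period_s,
                      config.period_cv * config.cycle_period_s,
                      config.n_cycles)
    pre_t = np.cumsum(gaps)
    pre_a = np.abs(rng.normal(config.pre_amp_mean,
                              config.pre_amp_cv * config.pre_amp_mean,
                              config.n_cycles)) + 1e-6
    transmitted = rng.random(config.n_cycles) < config.transmission_prob
    lat = _truncnorm(rng, 0.0, 0.45, config.latency_mean_s,
                     config.latency_sd_s, config.n_cycles)
    xii_t = pre_t[transmitted] + lat[transmitted]
    xii_a = np.abs(rng.normal(config.xii_amp_mean,
                              config.xii_amp_cv * config.xii_amp_mean,
                              int(transmitted.sum()))) + 1e-6
    order = np.argsort(xii_t)
    truth = np.full(config.n_cycles, -1, dtype=int)
    # map each transmitted cycle to its position in the time-sorted XII table
    pos = np.empty(order.size, dtype=int)
    pos[order] = np.arange(order.size)
    truth[np.flatnonzero(transmitted)] = pos
    pre = BurstEventTable(pre_t, pre_a)
    xii = BurstEventTable(xii_t[order], xii_a[order])
    return pre, xii, truth
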