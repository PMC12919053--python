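"""Per-unit burst-cycle participation and fidelity bookkeeping.

A unit "participates" in a network burst when it fires at least
``min_spikes`` (default 3) action potentials inside the burst window.
Percent participation is the percentage of bursts in an analysis window
meeting that rule; units above 95% are high-fidelity (HF), active units at
or below 95% low-fidelity (LF), and units participating in no burst are
silent.  Cycle skipping is the complement of participation.  Transitions
between condition blocks (recruitment, silencing, LF↔HF) are tabulated
from per-condition metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bursts import BurstSeries
from .raster import SpikeRaster

__all__ = ["UnitBurstMatrix", "count_in_burst_spikes", "participation_metrics",
           "condition_transitions"]


@dataclass
class UnitBurstMatrix:
    """Units × bursts in-burst spike counts plus the burst windows used."""

    counts: pd.DataFrame      # index unit_id, one column per burst
    bursts: pd.DataFrame      # onset_s, termination_s, peak_s per column
    condition: str = ""

    @property
    def n_bursts(self) -> int:
        return self.counts.shape[1]


def count_in_burst_spikes(raster: SpikeRaster, bursts: BurstSeries,
                          condition: str = "") -> UnitBurstMatrix:
    """Count spikes per unit inside each burst's [onset, termination) window."""
    b = bursts.bursts
    onsets = b["onset_s"].to_numpy()
    terms = b["termination_s"].to_numpy()
    if len(b) > 1 and (onsets[1:] < terms[:-1]).any():
        raise ValueError("burst windows overlap")
    mat = np.empty((raster.n_units, len(b)), dtype=int)
    for i, s in enumerate(raster.spikes):
        # half-open window: spikes exactly at termination belong to no burst
        mat[i] = np.searchsorted(s, terms, side="left") - \
            np.searchsorted(s, onsets, side="left")
    counts = pd.DataFrame(mat, index=pd.Index(raster.unit_ids, name="unit_id"))
    return UnitBurstMatrix(counts=counts, bursts=b.reset_index(drop=True),
                           condition=condition)


def participation_metrics(matrix: UnitBurstMatrix, min_spikes: int = 3,
                          hf_cut: float = 95.0) -> pd.DataFrame:
    """Per-unit participation, fidelity class and in-burst firing stats.

    Returns a DataFrame indexed by unit with columns: participation_pct,
    fidelity (HF/LF/silent), skip_pct, mean_spikes_per_burst and
    mean_inburst_rate_hz (both over participated bursts only; NaN for
    silent units).  HF is strict (> ``hf_cut``); exactly 95% is LF.
    """
    if matrix.n_bursts < 1:
        raise ValueError("no bursts in the analysis window")
    counts = matrix.counts.to_numpy()
    durations = (matrix.bursts["termination_s"]
                 - matrix.bursts["onset_s"]).to_numpy()
    took_part = counts >= min_spikes
    participation = 100.0 * took_part.mean(axis=1)

    mean_spikes = np.full(counts.shape[0], np.nan)
    mean_rate = np.full(counts.shape[0], np.nan)
    for i in range(counts.shape[0]):
        sel = took_part[i]
        if sel.any():
            mean_spikes[i] = counts[i, sel].mean()
            mean_rate[i] = (counts[i, sel] / durations[sel]).mean()

    fid = np.where(participation == 0.0, "silent",
                   np.where(participation > hf_cut, "HF", "LF"))
    return pd.DataFrame({
        "participation_pct": participation,
        "fidelity": fid,
        "skip_pct": 100.0 - participation,
        "mean_spikes_per_burst": mean_spikes,
        "mean_inburst_rate_hz": mean_rate,
    }, index=matrix.counts.index)


def condition_transitions(metrics_by_condition: dict) -> dict:
    """Fidelity trajectories across an ordered set of condition blocks.

    ``metrics_by_condition`` maps condition label → the DataFrame from
    :func:`participation_metrics`; insertion order defines the block
    order.  Counts are tallied between consecutive blocks: ``recruited``
    (silent → active), ``silenced`` (active → silent), ``lf_to_hf`` and
    ``hf_to_lf``.  Returns the counts per block pair plus a per-unit label
    table.
    """
    labels = list(metrics_by_condition)
    if len(labels) < 2:
        raise ValueError("need at least two condition blocks")
    base_idx = metrics_by_condition[labels[0]].index
    for lab in labels[1:]:
        idx = metrics_by_condition[lab].index
        if not base_idx.equals(idx):
            missing = base_idx.symmetric_difference(idx).tolist()
            raise ValueError(f"unit sets differ across conditions: {missing}")

    per_unit = pd.DataFrame(
        {lab: metrics_by_condition[lab]["fidelity"] for lab in labels})
    pair_counts = {}
    for a, b in zip(labels[:-1], labels[1:]):
        fa, fb = per_unit[a], per_unit[b]
        pair_counts[(a, b)] = {
            "recruited": int(((fa == "silent") & (fb != "silent")).sum()),
            "silenced": int(((fa != "silent") & (fb == "silent")).sum()),
            "lf_to_hf": int(((fa == "LF") & (fb == "HF")).sum()),
            "hf_to_lf": int(((fa == "HF") & (fb == "LF")).sum()),
        }
    return {"transitions": pair_counts, "per_unit": per_unit}
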