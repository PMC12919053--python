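"""Spike-raster container shared by the simulator, the synthetic generator
and the analysis stages.

Canonical time unit is seconds.  CSV round-trip uses two columns
(unit_id, spike_time_s) so sorted MEA spike trains can be loaded directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SpikeRaster"]


@dataclass
class SpikeRaster:
    """Unit-indexed spike-time lists with total duration and provenance."""

    unit_ids: list
    spikes: list                 # list of 1-D float arrays, seconds, sorted
    duration: float              # seconds
    provenance: str = "recorded"  # simulated | synthetic | recorded

    def __post_init__(self) -> None:
        if len(self.unit_ids) != len(self.spikes):
            raise ValueError("unit_ids and spikes must have equal length")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        self.spikes = [np.asarray(s, dtype=float) for s in self.spikes]
        for uid, s in zip(self.unit_ids, self.spikes):
            if s.size and (s.min() < 0 or s.max() > self.duration):
                raise ValueError(f"unit {uid}: spike times outside [0, duration]")
            if s.size > 1 and (np.diff(s) < 0).any():
                raise ValueError(f"unit {uid}: spike times must be sorted")

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    @property
    def n_spikes(self) -> int:
        return int(sum(s.size for s in self.spikes))

    def restrict(self, t0: float, t1: float) -> "SpikeRaster":
        """Sub-raster on [t0, t1), re-zeroed at t0."""
        if not 0 <= t0 < t1 <= self.duration:
            raise ValueError("window must lie inside the record")
        out = [s[(s >= t0) & (s < t1)] - t0 for s in self.spikes]
        return SpikeRaster(list(self.unit_ids), out, t1 - t0, self.provenance)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [(uid, t) for uid, s in zip(self.unit_ids, self.spikes) for t in s]
        return pd.DataFrame(rows, columns=["unit_id", "spike_time_s"])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, duration: float,
                       unit_ids=None, provenance: str = "recorded",
                       time_unit: str = "s") -> "SpikeRaster":
        """Build from a (unit_id, spike_time) table.

        ``unit_ids`` may list units explicitly so that silent units (no
        spikes in the table) are retained.
        """
        scale = {"s": 1.0, "ms": 1e-3}[time_unit]
        col = "spike_time_s" if "spike_time_s" in df.columns else (
            "spike_time_ms" if "spike_time_ms" in df.columns else "spike_time")
        if unit_ids is None:
            unit_ids = sorted(df["unit_id"].unique().tolist())
        groups = {uid: np.sort(g[col].to_numpy(dtype=float) * scale)
                  for uid, g in df.groupby("unit_id")}
        spikes = [groups.get(uid, np.empty(0)) for uid in unit_ids]
        return cls(list(unit_ids), spikes, duration, provenance)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, duration: float, **kw) -> "SpikeRaster":
        return cls.from_dataframe(pd.read_csv(path), duration, **kw)

    def concatenate(self, other: "SpikeRaster") -> "SpikeRaster":
        """Append another raster (same units) after this one in time."""
        if list(other.unit_ids) != list(self.unit_ids):
            raise ValueError("unit ids differ")
        sp = [np.concatenate([a, b + self.duration])
              for a, b in zip(self.spikes, other.spikes)]
        return SpikeRaster(list(self.unit_ids), sp,
                           self.duration + other.duration, self.provenance)
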