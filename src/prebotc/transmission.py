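"""PreBötC → hypoglossal (XII) transmission analysis.

Paired burst-event tables — start times and integrated amplitudes for the
rhythm-generating network and the downstream motor pool — are matched by
start-time proximity: the correspondence tolerance starts at 500 ms and
grows (50 ms steps, up to 750 ms) while the assignment stays one-to-one.
For each preBötC cycle n the input–output ratio is

    IO_n = BA_XII(n) / BA_preBötC(n)

on amplitudes normalized to their own analysis-window means; cycles with
no corresponding XII burst get IO_n = 0.  Transmission is the percentage
of preBötC cycles with a matched XII burst.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["BurstEventTable", "TransmissionResult", "match_bursts", "io_ratios"]


@dataclass
class BurstEventTable:
    """Burst start times (s) and integrated amplitudes for one network."""

    times: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.amplitudes = np.asarray(self.amplitudes, float)
        if self.times.shape != self.amplitudes.shape:
            raise ValueError("times and amplitudes must have equal length")
        if self.times.size > 1 and (np.diff(self.times) < 0).any():
            raise ValueError("burst times must be sorted")
        if (self.amplitudes <= 0).any():
            raise ValueError("amplitudes must be positive")

    def __len__(self) -> int:
        return self.times.size

    @classmethod
    def from_csv(cls, path) -> "BurstEventTable":
        df = pd.read_csv(path)
        return cls(df["start_time_s"].to_numpy(), df["amplitude"].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame({"start_time_s": self.times,
                      "amplitude": self.amplitudes}).to_csv(path, index=False)


@dataclass
class TransmissionResult:
    cycles: pd.DataFrame       # per preBötC cycle
    transmission_pct: float
    mean_io: float
    tolerance_ms: float

    def heatmap_row(self, max_cycles: int = 25) -> np.ndarray:
        """Up to ``max_cycles`` consecutive IO_n values, NaN-padded."""
        io = self.cycles["io"].to_numpy()[:max_cycles]
        row = np.full(max_cycles, np.nan)
        row[:io.size] = io
        return row


def _assign(pre_t: np.ndarray, xii_t: np.ndarray, tol_s: float):
    """Nearest-in-time assignment within tolerance; returns (match, conflict).

    ``match[n]`` is the XII index for preBötC cycle n or −1.  A conflict is
    any XII event claimed by more than one cycle; conflicts are resolved by
    keeping the nearest claimant (earlier cycle on an exact tie).
    """
    match = np.full(pre_t.size, -1, dtype=int)
    if xii_t.size:
        for n, t in enumerate(pre_t):
            j = int(np.searchsorted(xii_t, t))
            best, best_d = -1, tol_s
            for cand in (j - 1, j):
                if 0 <= cand < xii_t.size:
                    d = abs(xii_t[cand] - t)
                    if d < best_d or (d == best_d and best == -1):
                        best, best_d = cand, d
            match[n] = best
    conflict = False
    for j in set(match[match >= 0].tolist()):
        claimants = np.flatnonzero(match == j)
        if claimants.size > 1:
            conflict = True
            d = np.abs(pre_t[claimants] - xii_t[j])
            keep = claimants[int(np.argmin(d))]   # earliest wins exact ties
            for c in claimants:
                if c != keep:
                    match[c] = -1
    return match, conflict


def match_bursts(pre: BurstEventTable, xii: BurstEventTable,
                 window_ms: tuple[float, float] = (500.0, 750.0),
                 step_ms: float = 50.0) -> tuple[np.ndarray, float]:
    """Correspondence matching between the two burst series.

    The tolerance is maximized over ``window_ms`` in ``step_ms`` increments
    subject to the assignment staying one-to-one; if no tolerance in the
    range is conflict-free, the upper bound is used and duplicate claims
    beyond the nearest are left unmatched.  Returns (match array, tolerance
    used in ms).
    """
    lo, hi = window_ms
    tols = np.arange(lo, hi + step_ms / 2, step_ms)
    chosen, chosen_tol = None, None
    for tol in tols:
        match, conflict = _assign(pre.times, xii.times, tol / 1e3)
        if not conflict:
            chosen, chosen_tol = match, tol      # keep the largest clean one
    if chosen is None:
        chosen, _ = _assign(pre.times, xii.times, hi / 1e3)
        chosen_tol = hi
    return chosen, float(chosen_tol)


def io_ratios(pre: BurstEventTable, xii: BurstEventTable,
              match: np.ndarray | None = None,
              window: tuple[float, float] | None = None,
              tolerance_ms: float | None = None) -> TransmissionResult:
    """Cycle-wise I/O ratios and the transmission percentage.

    Both amplitude series are normalized by their own mean over the
    analysis window (all events when ``window`` is None), making every
    IO_n invariant to rescaling either network's raw amplitudes.
    """
    if match is None:
        match, tolerance_ms = match_bursts(pre, xii)
    in_win = np.ones(len(pre), bool)
    xii_in_win = np.ones(len(xii), bool)
    if window is not None:
        t0, t1 = window
        in_win = (pre.times >= t0) & (pre.times < t1)
        xii_in_win = (xii.times >= t0) & (xii.times < t1)
    if not in_win.any():
        raise ValueError("no preBötC cycles in the analysis window")
    pre_mean = pre.amplitudes[in_win].mean()
    if not xii_in_win.any():
        raise ValueError("no XII events in the analysis window to normalize by")
    xii_mean = xii.amplitudes[xii_in_win].mean()

    rows = []
    for n in np.flatnonzero(in_win):
        j = match[n]
        ba_pre = pre.amplitudes[n] / pre_mean
        if j >= 0:
            io = (xii.amplitudes[j] / xii_mean) / ba_pre
        else:
            io = 0.0                    # unmatched cycle: BA_XII assigned 0
        rows.append({"cycle": n, "pre_time_s": pre.times[n],
                     "xii_index": int(j), "matched": bool(j >= 0),
                     "ba_pre_norm": ba_pre,
                     "ba_xii_norm": (xii.amplitudes[j] / xii_mean
                                     if j >= 0 else 0.0),
                     "io": io})
    cycles = pd.DataFrame(rows)
    matched = cycles["matched"].sum()
    return TransmissionResult(
        cycles=cycles,
        transmission_pct=100.0 * matched / len(cycles),
        mean_io=float(cycles["io"].mean()),
        tolerance_ms=float(tolerance_ms) if tolerance_ms else np.nan)
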