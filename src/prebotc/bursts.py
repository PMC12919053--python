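"""Population-activity signal and network-burst detection.

Spike rasters are reduced to a binned population firing rate — total
spikes per 20 ms bin divided by the number of units, in spikes/(s·neuron).
A network burst is a maximal supra-threshold run of bins: onset where the
rate crosses the threshold (default 10 spikes/(s·neuron)) from below,
termination at the subsequent downward crossing, with runs required to
exceed a minimum duration (default five bins) to exclude spurious events.
The burst peak is the time of maximal smoothed activity inside the run;
peak amplitude is reported from the raw (unsmoothed) signal at that bin.
Instantaneous burst frequency is the inverse of the peak-to-peak interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster import SpikeRaster

__all__ = ["PopulationActivity", "BurstSeries", "bin_population_activity",
           "detect_bursts", "burst_summary"]


@dataclass
class PopulationActivity:
    """Binned network firing rate in spikes/(s·neuron)."""

    bin_ms: float
    t: np.ndarray          # bin start times, s
    rate: np.ndarray       # spikes/(s·neuron) per bin
    n_units: int

    def spike_counts(self) -> np.ndarray:
        """Integer spike count per bin implied by the rate."""
        return np.rint(self.rate * (self.bin_ms / 1e3) * self.n_units)


@dataclass
class BurstSeries:
    """Detected network bursts plus the detector settings used."""

    bursts: pd.DataFrame   # onset_s, termination_s, peak_s, peak_amplitude
    threshold: float
    min_bins: int
    bin_ms: float

    def __len__(self) -> int:
        return len(self.bursts)

    @property
    def peak_times(self) -> np.ndarray:
        return self.bursts["peak_s"].to_numpy()


def bin_population_activity(raster: SpikeRaster, bin_ms: float = 20.0
                            ) -> PopulationActivity:
    """Bin all spikes into half-open [t, t+bin) bins, normalized per unit.

    A trailing partial bin is dropped so every reported rate covers a full
    bin width.
    """
    if raster.n_units == 0:
        raise ValueError("raster has no units")
    if bin_ms <= 0:
        raise ValueError("bin width must be positive")
    bw_s = bin_ms / 1e3
    n_bins = int(np.floor(raster.duration / bw_s + 1e-9))
    if n_bins < 1:
        raise ValueError("record shorter than one bin")
    edges = np.arange(n_bins + 1) * bw_s
    all_spikes = (np.concatenate(raster.spikes) if raster.n_spikes
                  else np.empty(0))
    counts, _ = np.histogram(all_spikes, bins=edges)
    # np.histogram closes the last bin; restore the half-open convention
    n_at_end = int(np.sum(all_spikes == edges[-1]))
    counts[-1] -= n_at_end
    rate = counts / (bw_s * raster.n_units)
    return PopulationActivity(bin_ms=bin_ms, t=edges[:-1], rate=rate,
                              n_units=raster.n_units)


def _smooth(x: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return x
    kernel = np.ones(width) / width
    return np.convolve(x, kernel, mode="same")


def detect_bursts(activity: PopulationActivity, threshold: float = 10.0,
                  min_bins: int = 5, smooth_bins: int = 3,
                  strict_min: bool = True) -> BurstSeries:
    """Threshold-crossing burst detection on the population activity.

    ``strict_min`` keeps only runs strictly longer than ``min_bins``
    ("exceed a minimum duration"); set False for >=.  Runs touching either
    record boundary lack a genuine crossing and are dropped.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if min_bins < 1:
        raise ValueError("min_bins must be >= 1")
    rate = activity.rate
    bw_s = activity.bin_ms / 1e3
    above = rate > threshold
    smoothed = _smooth(rate, smooth_bins)

    # maximal runs of supra-threshold bins
    padded = np.concatenate([[False], above, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)          # exclusive

    rows = []
    for s, e in zip(starts, ends):
        if s == 0 or e == rate.size:        # no onset / unterminated
            continue
        length = e - s
        if (length <= min_bins) if strict_min else (length < min_bins):
            continue
        peak_idx = s + int(np.argmax(smoothed[s:e]))
        rows.append({
            "onset_s": activity.t[s],
            "termination_s": activity.t[e - 1] + bw_s,
            "peak_s": activity.t[peak_idx] + 0.5 * bw_s,
            "peak_amplitude": float(rate[peak_idx]),
        })
    df = pd.DataFrame(rows, columns=["onset_s", "termination_s", "peak_s",
                                     "peak_amplitude"])
    return BurstSeries(bursts=df, threshold=threshold, min_bins=min_bins,
                       bin_ms=activity.bin_ms)


def burst_summary(series: BurstSeries,
                  window: tuple[float, float] | None = None) -> dict:
    """Mean peak amplitude and mean instantaneous frequency over a window.

    Frequency needs at least two bursts; with fewer it is reported as NaN
    (missing), never zero.
    """
    df = series.bursts
    if window is not None:
        t0, t1 = window
        df = df[(df["peak_s"] >= t0) & (df["peak_s"] < t1)]
    n = len(df)
    amp = float(df["peak_amplitude"].mean()) if n else np.nan
    amp_med = float(df["peak_amplitude"].median()) if n else np.nan
    if n >= 2:
        intervals = np.diff(df["peak_s"].to_numpy())
        freq = float(np.mean(1.0 / intervals))
        freq_med = float(np.median(1.0 / intervals))
    else:
        freq = freq_med = np.nan
    return {"n_bursts": n, "mean_peak_amplitude": amp,
            "mean_frequency_hz": freq,
            "median_peak_amplitude": amp_med,
            "median_frequency_hz": freq_med}
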