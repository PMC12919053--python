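"""Population-activity binning and burst-detector behavior."""

import numpy as np
import pytest

from prebotc import (PopulationActivity, SpikeRaster, bin_population_activity,
                     burst_summary, detect_bursts)


def _activity(rate, bin_ms=20.0, n_units=10):
    rate = np.asarray(rate, float)
    return PopulationActivity(bin_ms=bin_ms,
                              t=np.arange(rate.size) * bin_ms / 1e3,
                              rate=rate, n_units=n_units)


def test_empty_raster_bins_to_zero():
    r = SpikeRaster(list(range(10)), [np.empty(0)] * 10, 10.0)
    act = bin_population_activity(r, 20.0)
    assert (act.rate == 0).all()
    assert act.rate.size == 500


def test_printed_rate_definition():
    """100 units firing one spike each inside a single 20 ms bin give
    100 / (0.02 s * 100 units) = 50 spikes/(s·neuron)."""
    spikes = [np.array([1.005 + 1e-4 * i]) for i in range(100)]
    r = SpikeRaster(list(range(100)), spikes, 2.0)
    act = bin_population_activity(r, 20.0)
    b = int(1.0 / 0.02)
    assert act.rate[b] == pytest.approx(50.0)
    assert act.rate.sum() == pytest.approx(50.0)


def test_rate_normalization_independent_of_binwidth():
    rng = np.random.default_rng(0)
    r = SpikeRaster([0, 1], [np.sort(rng.uniform(0, 100, 2000)) for _ in "01"],
                    100.0)
    a20 = bin_population_activity(r, 20.0)
    a40 = bin_population_activity(r, 40.0)
    assert a20.rate.mean() == pytest.approx(a40.rate.mean(), rel=0.01)


def test_spike_conservation():
    rng = np.random.default_rng(1)
    r = SpikeRaster([0, 1, 2], [np.sort(rng.uniform(0, 10, 77)),
                                np.sort(rng.uniform(0, 10, 33)),
                                np.empty(0)], 10.0)
    act = bin_population_activity(r, 20.0)
    total = act.rate.sum() * 0.02 * 3
    assert total == pytest.approx(110)


def test_rectangular_pulse_detected():
    rate = np.zeros(50)
    rate[10:16] = 20.0          # 6 bins above threshold
    series = detect_bursts(_activity(rate), threshold=10.0, min_bins=5)
    assert len(series) == 1
    b = series.bursts.iloc[0]
    assert b.onset_s == pytest.approx(0.200)
    assert b.termination_s == pytest.approx(0.320)
    assert b.peak_amplitude == pytest.approx(20.0)
    assert b.onset_s < b.peak_s <= b.termination_s


def test_short_pulse_rejected_by_min_duration():
    rate = np.zeros(50)
    rate[10:14] = 20.0          # 4 bins: below the >5-bin rule
    assert len(detect_bursts(_activity(rate))) == 0
    rate5 = np.zeros(50)
    rate5[10:15] = 20.0         # exactly 5 bins: "exceed" is strict
    assert len(detect_bursts(_activity(rate5))) == 0
    assert len(detect_bursts(_activity(rate5), strict_min=False)) == 1


def test_subthreshold_activity_yields_no_bursts():
    assert len(detect_bursts(_activity(np.full(100, 5.0)))) == 0


def test_unterminated_final_run_dropped():
    rate = np.zeros(40)
    rate[30:] = 20.0
    assert len(detect_bursts(_activity(rate))) == 0


def test_detector_matches_run_length_oracle_exactly():
    """Randomized profiles against a brute-force run-length oracle."""
    rng = np.random.default_rng(42)
    for _ in range(50):
        n = rng.integers(60, 200)
        rate = rng.choice([0.0, 4.0, 12.0, 25.0, 60.0], size=n,
                          p=[0.35, 0.2, 0.2, 0.15, 0.1])
        act = _activity(rate)
        got = detect_bursts(act, threshold=10.0, min_bins=5, smooth_bins=3)

        # oracle: explicit scan for maximal runs of rate > threshold
        expected = []
        i = 0
        while i < n:
            if rate[i] > 10.0:
                j = i
                while j < n and rate[j] > 10.0:
                    j += 1
                if i > 0 and j < n and (j - i) > 5:
                    kernel = np.convolve(rate, np.ones(3) / 3, mode="same")
                    peak = i + int(np.argmax(kernel[i:j]))
                    expected.append((i * 0.02, j * 0.02,
                                     peak * 0.02 + 0.01, rate[peak]))
                i = j
            else:
                i += 1
        assert len(got) == len(expected)
        for row, (on, off, pk, amp) in zip(got.bursts.itertuples(), expected):
            assert row.onset_s == pytest.approx(on)
            assert row.termination_s == pytest.approx(off)
            assert row.peak_s == pytest.approx(pk)
            assert row.peak_amplitude == pytest.approx(amp)


def test_burst_summary_frequency_arithmetic():
    import pandas as pd
    from prebotc.bursts import BurstSeries
    rows = [{"onset_s": p - 0.2, "termination_s": p + 0.2, "peak_s": p,
             "peak_amplitude": 30.0} for p in (0.5, 1.5, 3.5)]
    series = BurstSeries(pd.DataFrame(rows), 10.0, 5, 20.0)
    s = burst_summary(series)
    assert s["n_bursts"] == 3
    assert s["mean_frequency_hz"] == pytest.approx((1.0 + 0.5) / 2)
    assert s["mean_peak_amplitude"] == pytest.approx(30.0)

    single = BurstSeries(pd.DataFrame(rows[:1]), 10.0, 5, 20.0)
    s1 = burst_summary(single)
    assert s1["n_bursts"] == 1
    assert np.isnan(s1["mean_frequency_hz"])      # missing, not zero
    assert s1["mean_peak_amplitude"] == pytest.approx(30.0)


def test_end_to_end_on_programmed_bursts(regular_burst_raster):
    raster, peaks = regular_burst_raster
    act = bin_population_activity(raster, 20.0)
    series = detect_bursts(act, threshold=10.0, min_bins=5)
    assert len(series) == len(peaks)
    assert np.allclose(series.peak_times, peaks, atol=0.15)
    s = burst_summary(series)
    assert s["mean_frequency_hz"] == pytest.approx(0.25, rel=0.05)
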