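"""χ synchrony score and burst-aligned timing statistics."""

import numpy as np
import pandas as pd
import pytest

from prebotc import (SpikeRaster, align_spikes_to_bursts, synchrony_score,
                     timing_summaries)
from prebotc.bursts import BurstSeries
from prebotc.synchrony import TimingDistribution


def _poisson_raster(n_units, duration, rate, seed):
    rng = np.random.default_rng(seed)
    spikes = [np.sort(rng.uniform(0, duration, rng.poisson(rate * duration)))
              for _ in range(n_units)]
    return SpikeRaster(list(range(n_units)), spikes, duration)


def test_identical_trains_have_unit_chi():
    rng = np.random.default_rng(0)
    train = np.sort(rng.uniform(0, 60, 300))
    r = SpikeRaster(list(range(8)), [train.copy() for _ in range(8)], 60.0)
    assert synchrony_score(r).chi == pytest.approx(1.0)


def test_single_unit_chi_is_one():
    r = _poisson_raster(1, 120.0, 5.0, seed=3)
    assert synchrony_score(r).chi == pytest.approx(1.0)


def test_independent_poisson_chi_scales_as_inverse_sqrt_n():
    """For N iid units Var(mean) = sigma^2/N, so chi ~ 1/sqrt(N)."""
    r = _poisson_raster(100, 600.0, 5.0, seed=11)
    chi = synchrony_score(r).chi
    assert chi == pytest.approx(0.1, rel=0.3)


def test_chi_invariant_under_relabeling_and_duplication():
    r = _poisson_raster(20, 120.0, 4.0, seed=5)
    chi = synchrony_score(r).chi
    perm = np.random.default_rng(0).permutation(20)
    r_perm = SpikeRaster([r.unit_ids[i] for i in perm],
                         [r.spikes[i] for i in perm], r.duration)
    assert synchrony_score(r_perm).chi == pytest.approx(chi)
    r_dup = SpikeRaster(list(range(40)), r.spikes + r.spikes, r.duration)
    assert synchrony_score(r_dup).chi == pytest.approx(chi)


def test_chi_decreases_along_jitter_ladder():
    """Independent jitter added to a shared burst template lowers chi."""
    rng = np.random.default_rng(42)
    template = np.sort(rng.uniform(0, 300, 900))
    chis = []
    for jitter in (0.0, 0.05, 0.2, 0.8):
        spikes = [np.sort(np.clip(template + rng.normal(0, jitter,
                                                        template.size),
                                  0, 300)) for _ in range(30)]
        chis.append(synchrony_score(
            SpikeRaster(list(range(30)), spikes, 300.0)).chi)
    assert all(a > b for a, b in zip(chis, chis[1:]))


def test_constant_units_give_missing_chi():
    r = SpikeRaster([0, 1], [np.empty(0), np.empty(0)], 10.0)
    with pytest.warns(UserWarning):
        assert np.isnan(synchrony_score(r).chi)


def _series(peaks, half=0.5):
    rows = [{"onset_s": p - half, "termination_s": p + half, "peak_s": p,
             "peak_amplitude": 30.0} for p in peaks]
    return BurstSeries(pd.DataFrame(rows), 10.0, 5, 20.0)


def test_alignment_normalization():
    bursts = _series([2.0, 6.0])       # duration 1 s, peak centered
    spikes = [np.array([2.0, 5.5, 6.5 - 1e-9]),   # at peak, onset, ~term
              np.array([3.5])]                     # outside every burst
    r = SpikeRaster([0, 1], spikes, 10.0)
    dist = align_spikes_to_bursts(r, bursts)
    got = np.sort(dist.rel_times)
    assert np.allclose(got, [-0.5, 0.0, 0.5], atol=1e-6)
    assert (dist.table["unit_id"] == 0).all()     # unit 1 excluded


def test_uniform_spikes_centered_peak_mean_near_zero():
    rng = np.random.default_rng(1)
    bursts = _series(np.arange(2.0, 118.0, 4.0))
    spikes = [np.sort(np.concatenate(
        [rng.uniform(p - 0.5, p + 0.5, 8) for p in bursts.peak_times]))
        for _ in range(10)]
    r = SpikeRaster(list(range(10)), spikes, 120.0)
    dist = align_spikes_to_bursts(r, bursts)
    s = timing_summaries(dist)
    assert abs(s["mean_firing_time"]) < 0.03


def test_timing_summary_point_mass_and_tie_break():
    point = TimingDistribution(pd.DataFrame(
        {"unit_id": [0, 0], "burst": [0, 1], "rel_time": [0.0, 0.0]}), 2)
    s = timing_summaries(point)
    assert s["peak_density_time"] == 0.0
    assert s["mean_firing_time"] == 0.0

    # two equal point masses: mean 0, density argmax ties to earlier time
    rel = np.array([-0.2] * 50 + [0.2] * 50)
    bimodal = TimingDistribution(pd.DataFrame(
        {"unit_id": 0, "burst": np.arange(100), "rel_time": rel}), 100)
    grid = np.linspace(-0.5, 0.5, 501)
    s = timing_summaries(bimodal, grid=grid)
    assert s["mean_firing_time"] == pytest.approx(0.0)
    assert s["peak_density_time"] == pytest.approx(-0.2, abs=0.02)


def test_gaussian_cloud_recovered():
    rng = np.random.default_rng(2)
    rel = rng.normal(-0.1, 0.05, 4000)
    dist = TimingDistribution(pd.DataFrame(
        {"unit_id": 0, "burst": 0, "rel_time": rel}), 1)
    s = timing_summaries(dist)
    assert s["peak_density_time"] == pytest.approx(-0.1, abs=0.02)
    assert s["mean_firing_time"] == pytest.approx(-0.1, abs=0.01)


def test_time_shift_equivariance():
    rng = np.random.default_rng(3)
    peaks = np.arange(2.0, 58.0, 4.0)
    spikes = [np.sort(np.concatenate(
        [p + rng.normal(-0.05, 0.1, 6).clip(-0.45, 0.45) for p in peaks]))
        for _ in range(5)]
    r = SpikeRaster(list(range(5)), spikes, 60.0)
    b = _series(peaks)
    s0 = timing_summaries(align_spikes_to_bursts(r, b))
    shift = 1.7
    r2 = SpikeRaster(list(range(5)), [s + shift for s in spikes], 62.0)
    b2 = _series(peaks + shift)
    s1 = timing_summaries(align_spikes_to_bursts(r2, b2))
    assert s0["mean_firing_time"] == pytest.approx(s1["mean_firing_time"])
    assert s0["peak_density_time"] == pytest.approx(s1["peak_density_time"])


def test_empty_distribution_gives_missing_summaries():
    empty = TimingDistribution(
        pd.DataFrame(columns=["unit_id", "burst", "rel_time"]), 0)
    s = timing_summaries(empty)
    assert np.isnan(s["peak_density_time"]) and np.isnan(s["mean_firing_time"])
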