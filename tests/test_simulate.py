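"""Network integrator: exactness on linear membranes, agreement with a
high-accuracy reference, spike detection, protocols and determinism."""

import numpy as np
import pytest

from prebotc import (HeterogeneitySpec, NetworkConfig, NeuronParams,
                     SimProtocol, build_network, detect_spikes, integrate,
                     run_nmda_ramp, run_sweep)
from prebotc import _kernel
from prebotc.simulate import _NetState, _run_block


def _single_neuron_net(base, gcan=0.0):
    cfg = NetworkConfig(N=1, pConn=0.0, seed=0, gCANMax=gcan,
                        gL_het=HeterogeneitySpec("normal", base.gL, 0.0),
                        gNaP_het=HeterogeneitySpec("normal", base.gNaP, 0.0))
    return build_network(cfg, variant="can", base=base)


def _run_single(base, duration_ms, dt=0.025, rec=0.025):
    net = _single_neuron_net(base)
    proto = SimProtocol(duration_ms=duration_ms, dt_ms=dt, warmup_ms=0,
                        record_every_ms=rec, seed=0)
    return integrate(net, proto)


def test_passive_membrane_matches_closed_form():
    """With only leak, V(t) relaxes to EL with tau = C/gL; exponential
    Euler is exact on this linear problem."""
    p = NeuronParams(gNa=0, gNaP=0, gK=0, gCa=0, gCAN=0, gTonic=0,
                     gL=2.8, EL=-60.0)
    net = _single_neuron_net(p)
    state = _NetState(net)
    state.V[:] = -80.0
    tables = _kernel.build_tables(p, 0.025)
    _, _, traces = _run_block(net, state, 50.0, 0.025, 1, tables)
    v = traces[0]
    t = (np.arange(v.size) + 1) * 0.025
    closed = -60.0 + (-80.0 + 60.0) * np.exp(-t / (p.C / p.gL))
    assert np.max(np.abs(v - closed)) / 20.0 < 1e-3


def test_subthreshold_trajectory_matches_rk4_reference(
        rk4_subthreshold_reference):
    """A quiescent neuron's relaxation agrees with 4th-order RK at dt/10."""
    p, _, y = rk4_subthreshold_reference
    res = _run_single(p, 2000.0)
    v_ref = y[:, 0][10::10]
    v_got = res.traces.mean_V.to_numpy()
    n = min(v_ref.size, v_got.size)
    assert np.max(np.abs(v_got[:n] - v_ref[:n])) < 0.05


def test_spiking_trajectory_tracks_rk4_reference(rk4_spiking_reference):
    """Repetitive spiking shows the expected first-order phase drift:
    close early agreement at dt, near-exact agreement at dt/10."""
    p, _, y = rk4_spiking_reference
    ref_spikes = detect_spikes(y[:, 0], 0.0025)

    got = _run_single(p, 2000.0)
    spikes = detect_spikes(got.traces.mean_V.to_numpy(), 0.025)
    assert abs(len(spikes) - len(ref_spikes)) / len(ref_spikes) < 0.10
    assert abs(spikes[0] - ref_spikes[0]) < 0.3

    fine = _run_single(p, 2000.0, dt=0.0025, rec=0.0025)
    fine_spikes = detect_spikes(fine.traces.mean_V.to_numpy(), 0.0025)
    assert abs(len(fine_spikes) - len(ref_spikes)) <= 2
    assert np.max(np.abs(fine_spikes[:5] - ref_spikes[:5])) < 0.2


def test_detect_spikes_hysteresis():
    assert detect_spikes(np.full(100, -60.0), 1.0).size == 0
    # one clean action potential
    v = np.full(100, -60.0)
    v[40:45] = [-30.0, 10.0, -10.0, -50.0, -60.0]
    assert detect_spikes(v, 1.0).size == 1
    # dither around threshold without falling below the re-arm level
    v2 = np.full(100, -60.0)
    v2[40:50] = [-30, -37, -34, -38, -33, -39, -36, -34, -50, -60]
    assert detect_spikes(v2, 1.0).size == 1
    # falling below -40 re-arms
    v3 = np.full(100, -60.0)
    v3[40:46] = [-30, -45, -30, -45, -30, -60]
    assert detect_spikes(v3, 1.0).size == 3


def test_network_determinism():
    cfg = NetworkConfig(N=20, seed=4, gCANMax=1.0)
    proto = SimProtocol(duration_ms=5000.0, warmup_ms=1000.0, seed=4)
    r1 = integrate(build_network(cfg), proto)
    r2 = integrate(build_network(cfg), proto)
    assert r1.raster.n_spikes == r2.raster.n_spikes
    for a, b in zip(r1.raster.spikes, r2.raster.spikes):
        assert np.array_equal(a, b)
    assert np.array_equal(r1.traces.mean_Cai, r2.traces.mean_Cai)


def test_routing_neutral_at_membrane_when_calcium_inert():
    """With alphaCa ~ 0, Cai stays at CaMin for every routing, so CaV, CaK
    and CaN must produce identical voltage trajectories and rasters."""
    base = NeuronParams(alphaCa=1e-300)
    cfg = NetworkConfig(N=15, seed=3, gCANMax=2.0)
    proto = SimProtocol(duration_ms=4000.0, warmup_ms=500.0, seed=3)
    results = [integrate(build_network(cfg, variant=v, base=base), proto)
               for v in ("cav", "cak", "can")]
    for other in results[1:]:
        assert np.array_equal(results[0].traces.mean_V, other.traces.mean_V)
        for a, b in zip(results[0].raster.spikes, other.raster.spikes):
            assert np.array_equal(a, b)


def test_spike_times_inside_record_and_sorted():
    cfg = NetworkConfig(N=20, seed=1, gCANMax=1.5)
    res = integrate(build_network(cfg),
                    SimProtocol(duration_ms=8000.0, warmup_ms=1000.0, seed=1))
    assert res.raster.n_spikes > 0
    for s in res.raster.spikes:
        if s.size:
            assert 0 <= s.min() and s.max() <= res.raster.duration
            assert (np.diff(s) >= 0).all()


def test_ramp_bookkeeping_and_fixed_equivalence():
    cfg = NetworkConfig(N=10, seed=2, gCANMax=1.0, WMaxNMDA=0.1)
    net = build_network(cfg)
    proto = SimProtocol(kind="nmda_ramp", ramp_start=0.1, ramp_end=0.0,
                        ramp_stages=5, stage_ms=2000.0, settle_ms=500.0,
                        warmup_ms=500.0, seed=2)
    res = run_nmda_ramp(net, proto)
    assert np.allclose(res.stages["WMaxNMDA"],
                       np.linspace(0.1, 0.0, 5))
    assert np.allclose(np.diff(res.stages["t0_s"]), 2.0)
    assert res.raster.duration == pytest.approx(10.0)

    # a ramp with start == end is the fixed protocol in disguise
    flat = SimProtocol(kind="nmda_ramp", ramp_start=0.1, ramp_end=0.1,
                       ramp_stages=2, stage_ms=1000.0, settle_ms=0.0,
                       warmup_ms=500.0, seed=2)
    fixed = SimProtocol(duration_ms=2000.0, warmup_ms=500.0, seed=2)
    r_flat = run_nmda_ramp(net, flat)
    r_fixed = integrate(net, fixed)
    assert r_flat.raster.n_spikes == r_fixed.raster.n_spikes


def test_sweep_single_point_equals_fixed_run():
    cfg = NetworkConfig(N=15, seed=6)
    table = run_sweep(cfg, [1.0], [0.05], point_duration_ms=5000.0,
                      warmup_ms=1000.0, seed=6)
    assert len(table) == 1
    assert not table.iloc[0]["diverged"]
    assert {"gCANMax", "WMaxNMDA", "amplitude", "frequency_hz",
            "chi"} <= set(table.columns)


def test_divergence_reported_with_location():
    from prebotc import SimulationError
    # absurd tonic drive forces V out of range
    p = NeuronParams(gTonic=1e5, Esyn=500.0)
    net = _single_neuron_net(p)
    with pytest.raises(SimulationError, match="divergence"):
        integrate(net, SimProtocol(duration_ms=1000.0, warmup_ms=0, seed=0))


def test_invalid_protocol_rejected():
    with pytest.raises(ValueError):
        SimProtocol(dt_ms=0.0)
    with pytest.raises(ValueError):
        SimProtocol(ramp_start=0.0, ramp_end=0.1)
    with pytest.raises(ValueError):
        SimProtocol(kind="bogus")
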