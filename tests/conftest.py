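import numpy as np
import pytest

from prebotc import (NeuronParams, SpikeRaster, SynapseParams, initial_state,
                     reference_integrate)
from prebotc.conductance import variant_fractions


@pytest.fixture
def regular_burst_raster():
    """20 units firing 10 spikes in every ~0.55 s burst, bursts every 4 s.

    Spike offsets are denser near the burst center and per-unit shifts
    spread the population uniformly across 20 ms bins, so the population
    rate clears the default 10 spikes/(s·neuron) threshold contiguously
    and peaks near the programmed peak (deterministic raster).
    """
    duration = 120.0
    peaks = np.arange(2.0, duration - 2.0, 4.0)
    offsets = np.array([-0.27, -0.19, -0.12, -0.06, -0.02,
                        0.02, 0.06, 0.12, 0.19, 0.27])
    spikes = []
    for u in range(20):
        t = np.concatenate([p + offsets + u * 0.002 for p in peaks])
        spikes.append(np.sort(t))
    return SpikeRaster(list(range(20)), spikes, duration,
                       provenance="synthetic"), peaks


#: isolated-neuron parameter sets used for integrator validation
SUBTHRESHOLD_PARAMS = NeuronParams(EL=-66.0, gTonic=0.1, gNaP=1.0, gCAN=0.0)
SPIKING_PARAMS = NeuronParams(EL=-58.0, gTonic=0.0, gCAN=0.0)


@pytest.fixture(scope="session")
def rk4_subthreshold_reference():
    """4th-order reference trajectory (dt = 0.0025 ms, 2 s), quiescent cell."""
    p = SUBTHRESHOLD_PARAMS
    t, y = reference_integrate(p, variant_fractions("can"), SynapseParams(),
                               initial_state(p), 2000.0, 0.0025)
    return p, t, y


@pytest.fixture(scope="session")
def rk4_spiking_reference():
    """4th-order reference trajectory (dt = 0.0025 ms, 2 s), spiking cell."""
    p = SPIKING_PARAMS
    t, y = reference_integrate(p, variant_fractions("can"), SynapseParams(),
                               initial_state(p), 2000.0, 0.0025)
    return p, t, y


@pytest.fixture(scope="session")
def ramp_tables():
    """Matched-seed NMDA-ramp summaries for all variants (the expensive
    shared fixture behind the in silico trend tests)."""
    from prebotc.experiments import nmda_ramp_experiment
    seeds = (1, 2, 3)
    tables = {}
    for tag, (variant, tau) in {
        "can": ("can", 20.0), "cav": ("cav", 20.0),
        "cak": ("cak", 20.0), "can_tau5": ("can", 5.0),
    }.items():
        tables[tag] = [nmda_ramp_experiment(s, variant, tau) for s in seeds]
    return tables
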