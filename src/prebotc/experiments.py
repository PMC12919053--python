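"""Canonical scaled-down in silico experiments.

These are the study conditions used by the test suite and the acceptance
script: N = 50 networks (half the library default, for single-CPU
runtimes), ḡCAN = 2 nS, a 6-stage NMDA-weight ramp from 0.1 nS to 0 with
85 s analyzed per stage after a 5 s settle, and matched seeds across the
CaV/CaK/CaN variants and the fast-NMDA-decay control.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .conductance import NeuronParams, SynapseParams
from .network import NetworkConfig, build_network
from .simulate import SimProtocol, ramp_summary, run_nmda_ramp

__all__ = ["nmda_ramp_experiment", "seed_averaged_profile"]

RAMP_STAGES = 6
STAGE_MS = 90000.0
SETTLE_MS = 5000.0


def nmda_ramp_experiment(seed: int, variant: str = "can",
                         tau_nmda: float = 20.0, n: int = 50,
                         gcan_max: float = 2.0,
                         base: NeuronParams | None = None) -> pd.DataFrame:
    """One staged NMDA-weight ramp; returns the per-stage summary table.

    Columns include stage, WMaxNMDA, mean and median burst amplitude and
    instantaneous frequency, and the synchrony score χ.
    """
    cfg = NetworkConfig(N=n, seed=seed, gCANMax=gcan_max, WMaxNMDA=0.1)
    net = build_network(cfg, variant=variant, base=base,
                        synapse=SynapseParams(tauNMDA=tau_nmda))
    proto = SimProtocol(kind="nmda_ramp", ramp_start=0.1, ramp_end=0.0,
                        ramp_stages=RAMP_STAGES, stage_ms=STAGE_MS,
                        settle_ms=SETTLE_MS, warmup_ms=5000.0, seed=seed)
    return ramp_summary(run_nmda_ramp(net, proto))


def seed_averaged_profile(tables: list[pd.DataFrame], column: str
                          ) -> np.ndarray:
    """Average a per-stage column across matched-seed ramp tables."""
    return np.mean([t[column].to_numpy() for t in tables], axis=0)
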