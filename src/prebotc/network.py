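"""Random heterogeneous network construction.

The network is a directed Erdős–Rényi graph of excitatory neurons.  Each
existing connection carries both receptor components — a fast non-NMDA
weight and an NMDA weight — drawn independently per edge from uniform
distributions on [0, WMax].  Heterogeneity across neurons enters through
normally distributed leak (gL) and persistent-sodium (gNaP) conductances
(redrawn while negative) and a uniformly distributed ICAN conductance
gCAN ~ U(0, gCANMax).

Reproducibility: one root seed spawns independent child streams for
topology, per-neuron parameters and weights, so rescaling a weight bound
never perturbs the topology draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .conductance import CaRouting, NeuronParams, SynapseParams, variant_fractions

__all__ = ["HeterogeneitySpec", "NetworkConfig", "NetworkModel", "build_network",
           "scale_nmda_weights"]


@dataclass(frozen=True)
class HeterogeneitySpec:
    """Distribution of one per-neuron parameter (currently 'normal' only)."""

    distribution: str = "normal"
    loc: float = 0.0
    scale: float = 0.0

    def draw(self, rng: np.random.Generator, n: int) -> tuple[np.ndarray, int]:
        """Draw ``n`` non-negative values; returns (values, redraw count)."""
        if self.distribution != "normal":
            raise ValueError(
                f"unsupported heterogeneity distribution {self.distribution!r}")
        vals = rng.normal(self.loc, self.scale, size=n)
        redraws = 0
        neg = vals < 0
        while neg.any():
            redraws += int(neg.sum())
            vals[neg] = rng.normal(self.loc, self.scale, size=int(neg.sum()))
            neg = vals < 0
        return vals, redraws


@dataclass(frozen=True)
class NetworkConfig:
    """Network-level construction parameters.

    ``WMaxNMDA`` defaults to the static operating point (0.05 nS); ramp and
    sweep protocols explore the [0, 0.1] nS range around it.
    """

    N: int = 100
    pConn: float = 0.13
    WMaxNonNMDA: float = 0.15     # nS
    WMaxNMDA: float = 0.05        # nS
    gCANMax: float = 1.0          # nS
    gL_het: HeterogeneitySpec = field(
        default_factory=lambda: HeterogeneitySpec("normal", 2.8, 0.28))
    gNaP_het: HeterogeneitySpec = field(
        default_factory=lambda: HeterogeneitySpec("normal", 2.8, 0.56))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if not 0.0 <= self.pConn <= 1.0:
            raise ValueError("pConn must lie in [0, 1]")
        if min(self.WMaxNonNMDA, self.WMaxNMDA, self.gCANMax) < 0:
            raise ValueError("weight and conductance bounds must be >= 0")


@dataclass
class NetworkModel:
    """A realized network: parameter vectors plus weight matrices.

    ``W[i, j]`` is the weight of the connection from presynaptic neuron
    ``j`` onto postsynaptic neuron ``i``.  Both receptor matrices share one
    adjacency; weights are zero exactly off the adjacency and there are no
    self-connections.
    """

    base: NeuronParams
    gL: np.ndarray
    gNaP: np.ndarray
    gCAN: np.ndarray
    adjacency: np.ndarray          # bool (N, N)
    WnonNMDA: np.ndarray           # nS (N, N)
    WNMDA: np.ndarray              # nS (N, N)
    routing: CaRouting
    synapse: SynapseParams
    config: NetworkConfig
    variant: str = "can"
    redraws: int = 0

    @property
    def N(self) -> int:
        return self.adjacency.shape[0]

    def validate(self) -> None:
        a = self.adjacency
        if np.diag(a).any():
            raise ValueError("self-connections are not allowed")
        for W, bound in ((self.WnonNMDA, self.config.WMaxNonNMDA),
                         (self.WNMDA, None)):
            if (W[~a] != 0).any():
                raise ValueError("weights must be zero off the adjacency")
            if (W < 0).any():
                raise ValueError("weights must be >= 0")
            if bound is not None and (W > bound + 1e-12).any():
                raise ValueError("weight exceeds its configured bound")

    def with_variant(self, variant: str) -> "NetworkModel":
        return replace(self, routing=variant_fractions(variant),
                       variant=variant.lower())

    def to_json(self, path) -> None:
        """Serialize the realized network (parameters, adjacency, both
        weight matrices, config echo) to one JSON archive for exact
        re-runs."""
        import dataclasses as dc
        import json
        payload = {
            "variant": self.variant,
            "redraws": self.redraws,
            "base": dc.asdict(self.base),
            "synapse": dc.asdict(self.synapse),
            "config": dc.asdict(self.config),
            "gL": self.gL.tolist(),
            "gNaP": self.gNaP.tolist(),
            "gCAN": self.gCAN.tolist(),
            "adjacency": self.adjacency.astype(int).tolist(),
            "WnonNMDA": self.WnonNMDA.tolist(),
            "WNMDA": self.WNMDA.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "NetworkModel":
        import json
        with open(path) as fh:
            d = json.load(fh)
        cfg = dict(d["config"])
        cfg["gL_het"] = HeterogeneitySpec(**cfg["gL_het"])
        cfg["gNaP_het"] = HeterogeneitySpec(**cfg["gNaP_het"])
        model = cls(
            base=NeuronParams(**d["base"]),
            gL=np.asarray(d["gL"], float),
            gNaP=np.asarray(d["gNaP"], float),
            gCAN=np.asarray(d["gCAN"], float),
            adjacency=np.asarray(d["adjacency"], bool),
            WnonNMDA=np.asarray(d["WnonNMDA"], float),
            WNMDA=np.asarray(d["WNMDA"], float),
            routing=variant_fractions(d["variant"]),
            synapse=SynapseParams(**d["synapse"]),
            config=NetworkConfig(**cfg),
            variant=d["variant"],
            redraws=d["redraws"])
        model.validate()
        return model


def build_network(
    config: NetworkConfig,
    variant: str = "can",
    base: NeuronParams | None = None,
    synapse: SynapseParams | None = None,
) -> NetworkModel:
    """Build a reproducible heterogeneous network for a model variant.

    The root seed is split into child streams (topology, parameters, each
    weight matrix); identical ``(config, variant)`` therefore yields a
    bit-identical model, and changing only a weight bound leaves the
    topology and parameter draws untouched.
    """
    base = base or NeuronParams()
    synapse = synapse or SynapseParams()
    n = config.N

    ss = np.random.SeedSequence(config.seed)
    r_topo, r_par, r_wa, r_wn = (np.random.default_rng(s) for s in ss.spawn(4))

    adj = r_topo.random((n, n)) < config.pConn
    np.fill_diagonal(adj, False)

    g_l, redraw_l = config.gL_het.draw(r_par, n)
    g_nap, redraw_p = config.gNaP_het.draw(r_par, n)
    g_can = r_par.uniform(0.0, config.gCANMax, size=n)

    w_non = np.where(adj, r_wa.uniform(0.0, config.WMaxNonNMDA, (n, n)), 0.0)
    w_nmda = np.where(adj, r_wn.uniform(0.0, config.WMaxNMDA, (n, n)), 0.0)

    model = NetworkModel(
        base=base, gL=g_l, gNaP=g_nap, gCAN=g_can, adjacency=adj,
        WnonNMDA=w_non, WNMDA=w_nmda, routing=variant_fractions(variant),
        synapse=synapse, config=config, variant=variant.lower(),
        redraws=redraw_l + redraw_p)
    model.validate()
    return model


def scale_nmda_weights(model: NetworkModel, *, factor: float | None = None,
                       new_wmax: float | None = None) -> NetworkModel:
    """Uniformly rescale the NMDA weight matrix, preserving its structure.

    Exactly one of ``factor`` or ``new_wmax`` must be given; ``new_wmax``
    rescales so that the configured bound becomes the requested value.  The
    non-NMDA matrix is untouched.
    """
    if (factor is None) == (new_wmax is None):
        raise ValueError("give exactly one of factor or new_wmax")
    if factor is None:
        if model.config.WMaxNMDA == 0:
            raise ValueError("cannot rescale from a zero NMDA bound")
        factor = new_wmax / model.config.WMaxNMDA
    if factor < 0:
        raise ValueError("scale factor must be >= 0")
    cfg = replace(model.config, WMaxNMDA=model.config.WMaxNMDA * factor)
    return replace(model, WNMDA=model.WNMDA * factor, config=cfg)
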