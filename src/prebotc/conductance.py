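"""Single-neuron membrane model for preBötzinger-complex bursting neurons.

The cell is a single-compartment Hodgkin–Huxley-style model in the
Butera/Jasinski framework family: a fast spike-generating sodium current
(INa), a delayed-rectifier potassium current (IK), a persistent sodium
current (INaP) with slow inactivation ``hNaP``, a voltage-gated calcium
current (ICa), a calcium-activated nonspecific cation current (ICAN), an
ohmic leak, a tonic excitatory conductance, and two dynamic excitatory
synaptic currents — fast non-NMDA (AMPA/kainate-like) and slow NMDA.

Intracellular calcium is a single first-order pool.  The fraction of each
inward current that is counted as calcium influx is set by a routing triple
(``PICa``, ``PnonNMDAca``, ``PNMDAca``); routing affects only the calcium
balance, never the membrane currents themselves.

Units: capacitance pF, conductances nS, potentials mV, currents pA,
calcium µM, time ms.  alphaCa converts charge (fC) to concentration (µM).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "load_neuron_params",
    "NeuronParams",
    "SynapseParams",
    "CaRouting",
    "NeuronState",
    "CurrentSet",
    "VARIANTS",
    "variant_fractions",
    "membrane_currents",
    "calcium_derivative",
    "synapse_derivatives",
    "state_derivatives",
    "steady_gates",
]


def load_neuron_params(path=None) -> NeuronParams:
    """Load neuron constants from a per-current YAML block file.

    With no path, reads the frozen framework-default file shipped with the
    package (``prebotc/data/framework_defaults.yaml``), which reproduces
    ``NeuronParams()`` exactly.
    """
    import yaml

    if path is None:
        from importlib.resources import files
        text = (files("prebotc") / "data"
                / "framework_defaults.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    blocks = yaml.safe_load(text)
    flat: dict = {}
    for block in blocks.values():
        flat.update(block)
    return NeuronParams(**flat)


def _sigmoid(v: float, theta: float, sigma: float) -> float:
    """Boltzmann gate x_inf(V) = 1 / (1 + exp((V - theta) / sigma)).

    Negative ``sigma`` gives an activation curve, positive an inactivation
    curve.
    """
    return 1.0 / (1.0 + math.exp((v - theta) / sigma))


def _tau_cosh(v: float, theta: float, sigma: float, tau_max: float) -> float:
    """Bell-shaped voltage-dependent time constant tau_max / cosh((V-theta)/(2 sigma))."""
    return tau_max / math.cosh((v - theta) / (2.0 * sigma))


@dataclass(frozen=True)
class NeuronParams:
    """Biophysical constants of one neuron.

    Defaults are framework-derived (Butera-style spiking/INaP kinetics with a
    Jasinski-style ICa/ICAN/calcium extension) and are meant to be
    reconciled against a published parameter set when one is available;
    every constant is exposed in configuration.
    """

    # passive / maximal conductances
    C: float = 21.0            # pF
    gNa: float = 28.0          # nS
    gNaP: float = 2.8          # nS (heterogeneous across a network)
    gK: float = 11.2           # nS
    gCa: float = 0.7           # nS
    gCAN: float = 1.0          # nS (heterogeneous across a network)
    gL: float = 2.8            # nS (heterogeneous across a network)
    gTonic: float = 0.25       # nS, constant excitatory drive

    # reversal potentials (mV)
    ENa: float = 50.0
    EK: float = -85.0
    ECa: float = 150.0
    EL: float = -66.0
    Esyn: float = 0.0
    ECAN: float = 0.0

    # ICAN calcium activation
    KCAN: float = 0.74         # µM half-activation
    nCAN: float = 2.0          # Hill coefficient (cooperative, TRPM4-like)

    # calcium pool
    tauCa: float = 150.0       # ms removal time constant
    alphaCa: float = 1.6e-3    # µM per fC of routed inward charge
    CaMin: float = 0.05        # µM resting concentration

    # INa activation (instantaneous m_inf^3; inactivation borrows 1 - n)
    theta_m: float = -34.0
    sigma_m: float = -5.0
    # IK activation n (fourth power)
    theta_n: float = -29.0
    sigma_n: float = -4.0
    tau_n_max: float = 10.0    # ms
    # INaP activation (instantaneous) and slow inactivation hNaP
    theta_mp: float = -40.0
    sigma_mp: float = -6.0
    theta_hp: float = -48.0
    sigma_hp: float = 6.0
    tau_hp_max: float = 10000.0  # ms
    # ICa activation/inactivation
    theta_mc: float = -27.5
    sigma_mc: float = -5.7
    tau_mc: float = 0.5        # ms
    theta_hc: float = -52.4
    sigma_hc: float = 5.2
    tau_hc: float = 18.0       # ms

    # NMDA Mg2+ block concentration (Jahr-Stevens form; 0 disables)
    mg_mM: float = 2.0

    def __post_init__(self) -> None:
        for name in ("gNa", "gNaP", "gK", "gCa", "gCAN", "gL", "gTonic"):
            if getattr(self, name) < 0:
                raise ValueError(f"conductance {name} must be >= 0")
        if self.tauCa <= 0 or self.alphaCa <= 0 or self.KCAN <= 0:
            raise ValueError("tauCa, alphaCa and KCAN must be positive")
        if self.C <= 0:
            raise ValueError("capacitance must be positive")

    def with_(self, **kw) -> "NeuronParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class SynapseParams:
    """Jump-and-decay synaptic gating.

    A presynaptic spike increments the postsynaptic summed gate by
    ``weight * increment`` (the gate is measured in nS so it acts directly
    as a conductance); between spikes each gate decays exponentially with
    its receptor time constant.  NMDA decay is slow (~20 ms) compared with
    the fast non-NMDA component (~5 ms); that kinetic difference, not the
    peak conductance, is what lets NMDA input accumulate across a burst.
    """

    tauNMDA: float = 20.0      # ms
    tauNonNMDA: float = 5.0    # ms
    increment: float = 1.0     # dimensionless per-spike scale

    def __post_init__(self) -> None:
        if self.tauNMDA <= 0 or self.tauNonNMDA <= 0:
            raise ValueError("synaptic time constants must be positive")
        if self.increment < 0:
            raise ValueError("per-spike increment must be >= 0")


@dataclass(frozen=True)
class CaRouting:
    """Fractions of ICa / non-NMDA / NMDA charge routed into the Ca pool."""

    PICa: float = 0.0
    PnonNMDAca: float = 0.0
    PNMDAca: float = 0.0

    def __post_init__(self) -> None:
        for name in ("PICa", "PnonNMDAca", "PNMDAca"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


#: The three named calcium-source model variants.  CaV routes only the
#: voltage-gated calcium current into the pool, CaK only the fast non-NMDA
#: synaptic current, CaN only the NMDA synaptic current.
VARIANTS = {
    "cav": CaRouting(PICa=1.0, PnonNMDAca=0.0, PNMDAca=0.0),
    "cak": CaRouting(PICa=0.0, PnonNMDAca=1.0, PNMDAca=0.0),
    "can": CaRouting(PICa=0.0, PnonNMDAca=0.0, PNMDAca=1.0),
}


def variant_fractions(variant: str) -> CaRouting:
    """Return the calcium-routing triple for a named model variant.

    Parameters
    ----------
    variant : {"CaV", "CaK", "CaN"}
        Case-insensitive variant name.
    """
    key = variant.lower()
    if key not in VARIANTS:
        raise ValueError(
            f"unknown model variant {variant!r}; expected one of CaV, CaK, CaN"
        )
    return VARIANTS[key]


@dataclass
class NeuronState:
    """Dynamic variables of one neuron.

    ``gating`` holds the remaining voltage-gated variables in the fixed
    order (n, mCa, hCa); ``sNMDA``/``sNonNMDA`` are the summed weighted
    postsynaptic gates in nS.
    """

    V: float = -61.0
    hNaP: float = 0.6
    gating: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 0.7]))
    Cai: float = 0.05
    sNMDA: float = 0.0
    sNonNMDA: float = 0.0

    def validate(self) -> None:
        vals = [self.hNaP, *np.asarray(self.gating, dtype=float)]
        if any(not 0.0 <= g <= 1.0 for g in vals):
            raise ValueError("gating variables must lie in [0, 1]")
        if self.Cai < 0 or self.sNMDA < 0 or self.sNonNMDA < 0:
            raise ValueError("Cai and synaptic gates must be >= 0")
        if not math.isfinite(self.V):
            raise FloatingPointError("non-finite membrane potential")


@dataclass(frozen=True)
class CurrentSet:
    """Instantaneous membrane currents in pA (inward currents negative)."""

    INa: float
    INaP: float
    IK: float
    ICa: float
    ICAN: float
    ILeak: float
    ITonic: float
    InonNMDA: float
    INMDA: float

    def total(self) -> float:
        return (self.INa + self.INaP + self.IK + self.ICa + self.ICAN
                + self.ILeak + self.ITonic + self.InonNMDA + self.INMDA)


def can_activation(cai: float, p: NeuronParams) -> float:
    """Saturating (Hill) calcium activation of ICAN in [0, 1)."""
    if cai <= 0.0:
        return 0.0
    if p.nCAN == 1.0:
        return cai / (cai + p.KCAN)
    r = (p.KCAN / cai) ** p.nCAN
    return 1.0 / (1.0 + r)


def mg_block(v: float, mg_mM: float) -> float:
    """Voltage-dependent Mg2+ unblock factor for NMDA conductance.

    With ``mg_mM == 0`` the factor is exactly 1 and the NMDA current is
    pure conductance x gate x driving force.
    """
    if mg_mM <= 0.0:
        return 1.0
    return 1.0 / (1.0 + (mg_mM / 3.57) * math.exp(-0.062 * v))


def membrane_currents(
    state: NeuronState,
    params: NeuronParams,
    syn_drive: tuple[float, float] | None = None,
) -> CurrentSet:
    """Compute all membrane currents for a neuron state.

    ``syn_drive`` optionally overrides the state's summed weighted gates as
    ``(sNonNMDA, sNMDA)`` in nS.  Calcium routing deliberately does not
    appear here: routing fractions touch only the calcium balance.
    """
    state.validate()
    v = state.V
    if syn_drive is None:
        s_non, s_nmda = state.sNonNMDA, state.sNMDA
    else:
        s_non, s_nmda = syn_drive
    n, m_ca, h_ca = (float(x) for x in state.gating)

    m_inf = _sigmoid(v, params.theta_m, params.sigma_m)
    mp_inf = _sigmoid(v, params.theta_mp, params.sigma_mp)

    i_na = params.gNa * m_inf ** 3 * (1.0 - n) * (v - params.ENa)
    i_nap = params.gNaP * mp_inf * state.hNaP * (v - params.ENa)
    i_k = params.gK * n ** 4 * (v - params.EK)
    i_ca = params.gCa * m_ca * h_ca * (v - params.ECa)
    i_can = params.gCAN * can_activation(state.Cai, params) * (v - params.ECAN)
    i_leak = params.gL * (v - params.EL)
    i_tonic = params.gTonic * (v - params.Esyn)
    i_non = s_non * (v - params.Esyn)
    i_nmda = s_nmda * mg_block(v, params.mg_mM) * (v - params.Esyn)

    cs = CurrentSet(i_na, i_nap, i_k, i_ca, i_can, i_leak, i_tonic, i_non, i_nmda)
    if not math.isfinite(cs.total()):
        raise FloatingPointError("non-finite membrane current")
    return cs


def calcium_derivative(
    state: NeuronState,
    currents: CurrentSet,
    routing: CaRouting,
    params: NeuronParams,
) -> float:
    """dCai/dt in µM/ms.

    Influx is ``-alphaCa`` times the routed sum of ICa, InonNMDA and INMDA
    (inward currents are negative, so influx raises Cai); removal is
    first-order relaxation to ``CaMin`` with time constant ``tauCa``.
    """
    routed = (routing.PICa * currents.ICa
              + routing.PnonNMDAca * currents.InonNMDA
              + routing.PNMDAca * currents.INMDA)
    return -params.alphaCa * routed - (state.Cai - params.CaMin) / params.tauCa


def synapse_derivatives(
    state: NeuronState,
    params: SynapseParams,
    incoming_spikes: list[tuple[int, float]] | None = None,
    weights_nmda=None,
    weights_non_nmda=None,
):
    """Gate decay derivatives and the event-driven gate increments.

    ``incoming_spikes`` is a list of ``(source_index, time)`` events within
    the current step; ``weights_*`` map source index to synaptic weight
    (nS).  Returns ``(dsNMDA_dt, dsNonNMDA_dt, jumpNMDA, jumpNonNMDA)``:
    the continuous decay derivatives and the instantaneous jumps (linear
    superposition over simultaneous events).
    """
    ds_nmda = -state.sNMDA / params.tauNMDA
    ds_non = -state.sNonNMDA / params.tauNonNMDA
    jump_nmda = 0.0
    jump_non = 0.0
    for src, _t in incoming_spikes or ():
        w_n = 0.0 if weights_nmda is None else float(weights_nmda[src])
        w_a = 0.0 if weights_non_nmda is None else float(weights_non_nmda[src])
        if w_n < 0 or w_a < 0:
            raise ValueError(f"negative synaptic weight from source {src}")
        jump_nmda += w_n * params.increment
        jump_non += w_a * params.increment
    return ds_nmda, ds_non, jump_nmda, jump_non


def steady_gates(v: float, p: NeuronParams) -> tuple[float, np.ndarray]:
    """Steady-state (hNaP, gating vector) at a holding potential."""
    h_nap = _sigmoid(v, p.theta_hp, p.sigma_hp)
    n = _sigmoid(v, p.theta_n, p.sigma_n)
    m_ca = _sigmoid(v, p.theta_mc, p.sigma_mc)
    h_ca = _sigmoid(v, p.theta_hc, p.sigma_hc)
    return h_nap, np.array([n, m_ca, h_ca])


def state_derivatives(
    state: NeuronState,
    params: NeuronParams,
    routing: CaRouting,
    syn: SynapseParams,
    syn_drive: tuple[float, float] | None = None,
) -> np.ndarray:
    """Full right-hand side for one neuron, as a flat vector.

    Order: (dV, dhNaP, dn, dmCa, dhCa, dCai, dsNMDA, dsNonNMDA).  Used by
    the high-accuracy reference integrator; the production network kernel
    advances the same equations with exponential Euler.
    """
    cs = membrane_currents(state, params, syn_drive)
    v = state.V
    dv = -cs.total() / params.C

    h_inf = _sigmoid(v, params.theta_hp, params.sigma_hp)
    tau_h = _tau_cosh(v, params.theta_hp, params.sigma_hp, params.tau_hp_max)
    dh = (h_inf - state.hNaP) / tau_h

    n, m_ca, h_ca = (float(x) for x in state.gating)
    n_inf = _sigmoid(v, params.theta_n, params.sigma_n)
    tau_n = _tau_cosh(v, params.theta_n, params.sigma_n, params.tau_n_max)
    dn = (n_inf - n) / tau_n
    dmc = (_sigmoid(v, params.theta_mc, params.sigma_mc) - m_ca) / params.tau_mc
    dhc = (_sigmoid(v, params.theta_hc, params.sigma_hc) - h_ca) / params.tau_hc

    dca = calcium_derivative(state, cs, routing, params)
    ds_nmda, ds_non, _, _ = synapse_derivatives(state, syn)
    return np.array([dv, dh, dn, dmc, dhc, dca, ds_nmda, ds_non])
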