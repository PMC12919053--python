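"""High-accuracy single-neuron reference integrator.

Classical fixed-step 4th-order Runge–Kutta on the exact right-hand side of
the single-neuron equations.  This path shares no code with the production
exponential-Euler network kernel — no lookup tables, no frozen relaxation
coefficients — and exists to validate it: run the same neuron through both
and compare trajectories.

The right-hand side is written directly over the packed state vector for
speed; :func:`prebotc.conductance.state_derivatives` computes the identical
quantities through the dataclass API and is cross-checked against this
implementation in the test suite.
"""

from __future__ import annotations

import numpy as np

from .conductance import (CaRouting, NeuronParams, NeuronState, SynapseParams,
                          steady_gates)

__all__ = ["reference_integrate", "initial_state"]

# packed state layout: V, hNaP, n, mCa, hCa, Cai, sNMDA, sNonNMDA


def initial_state(params: NeuronParams, v0: float | None = None) -> NeuronState:
    """State with gates at their steady values for the starting potential."""
    v0 = params.EL if v0 is None else v0
    h_nap, gate = steady_gates(v0, params)
    return NeuronState(V=v0, hNaP=h_nap, gating=gate.copy(),
                       Cai=params.CaMin, sNMDA=0.0, sNonNMDA=0.0)


def _pack(s: NeuronState) -> np.ndarray:
    return np.array([s.V, s.hNaP, *np.asarray(s.gating, float),
                     s.Cai, s.sNMDA, s.sNonNMDA])


def _make_rhs(p: NeuronParams, r: CaRouting, syn: SynapseParams):
    exp = np.exp

    def sig(v, theta, sigma):
        return 1.0 / (1.0 + exp((v - theta) / sigma))

    def rhs(y):
        v, h, n, mc, hc, ca, s_nmda, s_non = y
        n = min(max(n, 0.0), 1.0)
        h = min(max(h, 0.0), 1.0)
        ca = max(ca, 0.0)

        m_inf = sig(v, p.theta_m, p.sigma_m)
        mp_inf = sig(v, p.theta_mp, p.sigma_mp)
        caf = (0.0 if ca <= 0 else
               1.0 / (1.0 + (p.KCAN / ca) ** p.nCAN))
        mgb = (1.0 if p.mg_mM <= 0 else
               1.0 / (1.0 + (p.mg_mM / 3.57) * exp(-0.062 * v)))

        i_na = p.gNa * m_inf ** 3 * (1.0 - n) * (v - p.ENa)
        i_nap = p.gNaP * mp_inf * h * (v - p.ENa)
        i_k = p.gK * n ** 4 * (v - p.EK)
        i_ca = p.gCa * mc * hc * (v - p.ECa)
        i_can = p.gCAN * caf * (v - p.ECAN)
        i_leak = p.gL * (v - p.EL)
        i_tonic = p.gTonic * (v - p.Esyn)
        i_non = s_non * (v - p.Esyn)
        i_nmda = s_nmda * mgb * (v - p.Esyn)

        dv = -(i_na + i_nap + i_k + i_ca + i_can + i_leak + i_tonic
               + i_non + i_nmda) / p.C
        dh = (sig(v, p.theta_hp, p.sigma_hp) - h) * np.cosh(
            (v - p.theta_hp) / (2 * p.sigma_hp)) / p.tau_hp_max
        dn = (sig(v, p.theta_n, p.sigma_n) - n) * np.cosh(
            (v - p.theta_n) / (2 * p.sigma_n)) / p.tau_n_max
        dmc = (sig(v, p.theta_mc, p.sigma_mc) - mc) / p.tau_mc
        dhc = (sig(v, p.theta_hc, p.sigma_hc) - hc) / p.tau_hc
        dca = (-p.alphaCa * (r.PICa * i_ca + r.PnonNMDAca * i_non
                             + r.PNMDAca * i_nmda)
               - (ca - p.CaMin) / p.tauCa)
        ds_nmda = -s_nmda / syn.tauNMDA
        ds_non = -s_non / syn.tauNonNMDA
        return np.array([dv, dh, dn, dmc, dhc, dca, ds_nmda, ds_non])

    return rhs


def reference_integrate(
    params: NeuronParams,
    routing: CaRouting,
    syn: SynapseParams,
    state0: NeuronState,
    duration_ms: float,
    dt_ms: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate one isolated neuron; returns (times_ms, state_matrix).

    ``state_matrix`` rows follow the packing (V, hNaP, n, mCa, hCa, Cai,
    sNMDA, sNonNMDA), one row per step including t = 0.
    """
    f = _make_rhs(params, routing, syn)
    n_steps = int(round(duration_ms / dt_ms))
    y = _pack(state0)
    out = np.empty((n_steps + 1, y.size))
    out[0] = y
    for k in range(n_steps):
        k1 = f(y)
        k2 = f(y + 0.5 * dt_ms * k1)
        k3 = f(y + 0.5 * dt_ms * k2)
        k4 = f(y + dt_ms * k3)
        y = y + (dt_ms / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        out[k + 1] = y
    times = np.arange(n_steps + 1) * dt_ms
    return times, out
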