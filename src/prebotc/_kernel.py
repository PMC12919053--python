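"""Numba inner loop for the network integrator.

The kernel advances the whole network with fixed-step exponential Euler.
Voltage-dependent steady states and per-step decay factors are tabulated
on a fine membrane-potential grid once per run, so the inner loop is table
interpolation plus one exponential (the membrane relaxation factor) per
neuron per step.

Status codes returned by ``run_stage``: 0 ok, 1 divergence (non-finite or
|V| > 200 mV; offending step/neuron in ``err_out``), 2 spike-buffer
overflow.
"""

from __future__ import annotations

import math

import numba
import numpy as np

__all__ = ["build_tables", "run_stage", "V_GRID_MIN", "V_GRID_MAX", "V_GRID_STEP"]

V_GRID_MIN = -130.0
V_GRID_MAX = 70.0
V_GRID_STEP = 0.02


def build_tables(p, dt: float) -> dict:
    """Tabulate gating steady states and decay factors on the V grid.

    ``p`` is a NeuronParams; the tables depend only on shared kinetics
    constants and ``dt``.
    """
    v = np.arange(V_GRID_MIN, V_GRID_MAX + V_GRID_STEP / 2, V_GRID_STEP)

    def sig(theta, sigma):
        return 1.0 / (1.0 + np.exp((v - theta) / sigma))

    def tau(theta, sigma, tau_max):
        return tau_max / np.cosh((v - theta) / (2.0 * sigma))

    tables = {
        "minf3": sig(p.theta_m, p.sigma_m) ** 3,
        "ninf": sig(p.theta_n, p.sigma_n),
        "ndec": np.exp(-dt / tau(p.theta_n, p.sigma_n, p.tau_n_max)),
        "hpinf": sig(p.theta_hp, p.sigma_hp),
        "hpdec": np.exp(-dt / tau(p.theta_hp, p.sigma_hp, p.tau_hp_max)),
        "mpinf": sig(p.theta_mp, p.sigma_mp),
        "mcinf": sig(p.theta_mc, p.sigma_mc),
        "hcinf": sig(p.theta_hc, p.sigma_hc),
        "mgb": (np.ones_like(v) if p.mg_mM <= 0
                else 1.0 / (1.0 + (p.mg_mM / 3.57) * np.exp(-0.062 * v))),
        "v_grid": v,
    }
    return {k: np.ascontiguousarray(a) for k, a in tables.items()}


@numba.njit(cache=True, fastmath=True)
def run_stage(
    # state (modified in place)
    V, n, hp, mc, hc, ca, sN, sNN, armed,
    # per-neuron parameters
    gL, gNaP, gCAN,
    # transposed weight matrices: row j = outgoing weights of neuron j
    WN_T, WNN_T,
    # integration
    n_steps, dt,
    # scalar biophysics
    C, gNa, gK, gCa, gTonic,
    ENa, EK, ECa, EL, Esyn, ECAN,
    KCAN, nCAN, tauCa, alphaCa, CaMin,
    PICa, Pnn, Pnm,
    # constant per-step decay factors
    dec_sN, dec_sNN, dec_ca, dec_mc, dec_hc,
    # V-grid tables
    vmin, inv_dv,
    t_minf3, t_ninf, t_ndec, t_hpinf, t_hpdec, t_mpinf, t_mcinf, t_hcinf,
    t_mgb, use_mg,
    # spike detection
    thr, rearm,
    # outputs
    spike_steps, spike_units,
    rec_every, trV, trCa, trCAN, trH,
    err_out,
):
    N = V.shape[0]
    n_sp = 0
    cap = spike_steps.shape[0]
    n_grid = t_minf3.shape[0]
    cur = np.empty(N, dtype=np.int32)
    inv_c = 1.0 / C
    a_tau = alphaCa * tauCa

    for step in range(n_steps):
        rec = (step % rec_every) == 0
        if rec:
            r = step // rec_every
            sv = 0.0
            sca = 0.0
            sican = 0.0
            sh = 0.0
        n_cur = 0
        for i in range(N):
            v = V[i]
            u = (v - vmin) * inv_dv
            if u < 0.0:
                u = 0.0
            elif u > n_grid - 1.001:
                u = n_grid - 1.001
            k = int(u)
            f = u - k

            minf3 = t_minf3[k] + (t_minf3[k + 1] - t_minf3[k]) * f
            ninf = t_ninf[k] + (t_ninf[k + 1] - t_ninf[k]) * f
            ndec = t_ndec[k] + (t_ndec[k + 1] - t_ndec[k]) * f
            hpinf = t_hpinf[k] + (t_hpinf[k + 1] - t_hpinf[k]) * f
            hpdec = t_hpdec[k] + (t_hpdec[k + 1] - t_hpdec[k]) * f
            mpinf = t_mpinf[k] + (t_mpinf[k + 1] - t_mpinf[k]) * f
            mcinf = t_mcinf[k] + (t_mcinf[k + 1] - t_mcinf[k]) * f
            hcinf = t_hcinf[k] + (t_hcinf[k + 1] - t_hcinf[k]) * f

            ni = n[i]
            cai = ca[i]
            if nCAN == 1.0:
                caf = cai / (cai + KCAN)
            elif nCAN == 2.0:
                r2 = (KCAN / cai) * (KCAN / cai)
                caf = 1.0 / (1.0 + r2)
            else:
                caf = 1.0 / (1.0 + (KCAN / cai) ** nCAN)

            g_na = gNa * minf3 * (1.0 - ni)
            g_k = gK * ni * ni * ni * ni
            g_nap = gNaP[i] * mpinf * hp[i]
            g_ca = gCa * mc[i] * hc[i]
            g_can = gCAN[i] * caf
            g_l = gL[i]
            if use_mg:
                mgb = t_mgb[k] + (t_mgb[k + 1] - t_mgb[k]) * f
            else:
                mgb = 1.0
            g_nmda = sN[i] * mgb
            g_syn = g_nmda + sNN[i] + gTonic

            g_tot = g_na + g_k + g_nap + g_ca + g_can + g_l + g_syn
            v_inf = (g_na * ENa + g_k * EK + g_nap * ENa + g_ca * ECa
                     + g_can * ECAN + g_l * EL + g_syn * Esyn) / g_tot
            v_new = v_inf + (v - v_inf) * math.exp(-dt * g_tot * inv_c)

            # calcium: routed inward charge at the pre-step potential
            i_routed = (PICa * g_ca * (v - ECa)
                        + Pnn * sNN[i] * (v - Esyn)
                        + Pnm * g_nmda * (v - Esyn))
            ca_inf = CaMin - a_tau * i_routed
            ca[i] = ca_inf + (cai - ca_inf) * dec_ca

            n[i] = ninf + (ni - ninf) * ndec
            hp[i] = hpinf + (hp[i] - hpinf) * hpdec
            mc[i] = mcinf + (mc[i] - mcinf) * dec_mc
            hc[i] = hcinf + (hc[i] - hcinf) * dec_hc

            if armed[i]:
                if v_new >= thr:
                    armed[i] = False
                    cur[n_cur] = i
                    n_cur += 1
            elif v_new < rearm:
                armed[i] = True
            V[i] = v_new

            if rec:
                sv += v_new
                sca += ca[i]
                sican += g_can * (v - ECAN)
                sh += hp[i]

        if rec:
            trV[r] = sv / N
            trCa[r] = sca / N
            trCAN[r] = sican / N
            trH[r] = sh / N
            ok = True
            for i in range(N):
                vi = V[i]
                if not (-200.0 < vi < 200.0):
                    ok = False
                    err_out[0] = step
                    err_out[1] = i
                    break
            if not ok:
                return n_sp, 1

        if n_cur > 0:
            if n_sp + n_cur > cap:
                err_out[0] = step
                err_out[1] = -1
                return n_sp, 2
            # synaptic gates decay then receive this step's spikes
            for i in range(N):
                sN[i] *= dec_sN
                sNN[i] *= dec_sNN
            for c in range(n_cur):
                j = cur[c]
                spike_steps[n_sp] = step
                spike_units[n_sp] = j
                n_sp += 1
                for i in range(N):
                    sN[i] += WN_T[j, i]
                    sNN[i] += WNN_T[j, i]
        else:
            for i in range(N):
                sN[i] *= dec_sN
                sNN[i] *= dec_sNN

    return n_sp, 0
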