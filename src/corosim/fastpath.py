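"""Compiled evaluation kernel for the coupled system.

This module mirrors :meth:`corosim.simulator.ClosedLoopModel.rhs` (which
remains the reference implementation, tested for exact agreement) in a
numba-jitted kernel so a cardiac cycle integrates in tens of milliseconds.
The kernel also emits the observable waveforms (pressures, flows, IMP
components) needed for per-cycle metrics.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["pack_constants", "rhs_fast", "observables_fast", "OBS_NAMES"]

OBS_NAMES = (
    "P_lv", "P_la", "P_art", "P_ven", "q_ao", "q_mv", "q_per", "q_ven",
    "q_lad", "q_lcx", "q_lad_out", "q_lcx_out",
    "IMP_lad", "IMP_lcx", "CEP", "VE_lad", "VE_lcx", "SIP",
    "e_lad", "e_lcx", "V_lv", "V_la", "V_lumen_lad", "V_lumen_lcx",
)

# scalar-constant layout (indices into the sc array)
_SC_FIELDS = (
    "T", "dt_lcx", "dt_bar", "la_off",
    "Tmax_lv", "tau_lv", "Ees_lad", "Ees_lcx", "V0_lv", "A_lv", "B_lv",
    "Tmax_la", "tau_la", "Ees_la", "V0_la", "A_la", "B_la",
    "F", "alpha", "beta", "gamma",
    "R_ao", "R_per", "R_ven", "R_mv", "C_art", "C_ven", "V_art0", "V_ven0",
    "g_lad_prox", "g_lcx_prox", "mu", "EDV_ref", "floor",
)
_SC = {name: i for i, name in enumerate(_SC_FIELDS)}


def pack_constants(model) -> tuple:
    """Flatten a ClosedLoopModel's parameters into kernel arguments."""
    sched, circ, impp = model.sched, model.circ, model.imp_params
    la_off = sched.la_offset
    if la_off is None:
        la_off = sched.T - 1.5 * model.la.Tmax
    sc = np.array([
        sched.T, sched.dt_lcx, sched.dt_bar, la_off,
        model.lad.Tmax, model.lad.tau, model.lad.Ees, model.lcx.Ees,
        model.lad.V0, model.lad.A, model.lad.B,
        model.la.Tmax, model.la.tau, model.la.Ees, model.la.V0, model.la.A, model.la.B,
        model.F, impp.alpha, impp.beta, impp.gamma,
        circ.R_ao, circ.R_per, circ.R_ven, circ.R_mv, circ.C_art, circ.C_ven,
        circ.V_art0, circ.V_ven0,
        1.0 / model.net_lad.R_proximal, 1.0 / model.net_lcx.R_proximal,
        model.net_lad.mu, model.EDV_ref if model.EDV_ref else 0.0, 1e-9,
    ])
    nets = []
    for net in (model.net_lad, model.net_lcx):
        t = net.tree
        nets.append((
            net.parent.astype(np.int64), net.is_leaf.astype(np.bool_),
            t.length, t.Ap, t.Bp, t.phi_p, t.Cp, np.int64(net.root),
        ))
    return (sc, *nets[0], *nets[1])


@njit(cache=True, fastmath=False)
def _activation(t, T, Tmax, tau):
    tm = t % T
    if tm < 1.5 * Tmax:
        return 0.5 * (np.sin(np.pi * tm / Tmax - np.pi / 2.0) + 1.0)
    return 0.5 * np.exp(-(tm - 1.5 * Tmax) / tau)


@njit(cache=True, fastmath=False)
def _network(V, parent, isleaf, L, Ap, Bp, phi, Cp, root, g_prox, mu,
             P_in, P_out, P_T, dVdt, off):
    n = len(L)
    Pmid = np.empty(n)
    g = np.empty(n)
    for i in range(n):
        Vi = V[off + i]
        D = np.sqrt(4.0 * Vi / (np.pi * L[i]))
        u = (0.5 * D - Bp[i]) / (Ap[i] - Bp[i])
        dP = phi[i] - Cp[i] / np.tan(np.pi * u)
        Pmid[i] = P_T + dP
        g[i] = np.pi * D**4 / (64.0 * mu * L[i])
    num = np.zeros(n)
    den = np.zeros(n)
    for i in range(n):
        num[i] += g[i] * Pmid[i]
        den[i] += g[i]
        p = parent[i]
        if p >= 0:
            num[p] += g[i] * Pmid[i]
            den[p] += g[i]
    P0 = (P_in * g_prox + g[root] * Pmid[root]) / (g_prox + g[root])
    q_in = (P_in - P0) * g_prox
    q_out_total = 0.0
    for i in range(n):
        p = parent[i]
        pin = P0 if p < 0 else num[p] / den[p]
        pout = P_out if isleaf[i] else num[i] / den[i]
        qi = (pin - Pmid[i]) * g[i]
        qo = (Pmid[i] - pout) * g[i]
        dVdt[off + i] = qi - qo
        if isleaf[i]:
            q_out_total += qo
    return q_in, q_out_total


@njit(cache=True, fastmath=False)
def _eval(t, y, sc,
          parent1, leaf1, L1, Ap1, Bp1, phi1, Cp1, root1,
          parent2, leaf2, L2, Ap2, Bp2, phi2, Cp2, root2,
          dydt, obs):
    T = sc[0]
    V_la, V_lv, V_art, V_ven = y[0], y[1], y[2], y[3]
    P_art = (V_art - sc[27]) / sc[25]
    P_ven = (V_ven - sc[28]) / sc[26]

    e1 = _activation(t, T, sc[4], sc[5])
    e2 = _activation(t - sc[1], T, sc[4], sc[5])
    Ped = sc[9] * (np.exp(sc[10] * (V_lv - sc[8])) - 1.0)
    F = sc[17]
    w1 = sc[6] * e1
    w2 = sc[7] * e2
    den = F * w2 + (1.0 - F) * w1
    if den > sc[33]:
        P_lv = ((V_lv - sc[8]) * w1 * w2
                + Ped * (F * (1.0 - e1) * w2 + (1.0 - F) * (1.0 - e2) * w1)) / den
    else:
        P_lv = Ped

    e_la = _activation((t - sc[3]) % T, T, sc[11], sc[12])
    Pes_la = sc[13] * (V_la - sc[14])
    Ped_la = sc[15] * (np.exp(sc[16] * (V_la - sc[14])) - 1.0)
    P_la = e_la * Pes_la + (1.0 - e_la) * Ped_la

    e1i = _activation(t - sc[2], T, sc[4], sc[5])
    e2i = _activation(t - sc[1] - sc[2], T, sc[4], sc[5])
    if sc[2] != 0.0:
        # dt_bar > 0: CEP follows the chamber pressure law evaluated at the
        # lagged IMP clocks, delaying the whole IMP relative to P_lv
        w1i = sc[6] * e1i
        w2i = sc[7] * e2i
        deni = F * w2i + (1.0 - F) * w1i
        if deni > sc[33]:
            P_cep = ((V_lv - sc[8]) * w1i * w2i
                     + Ped * (F * (1.0 - e1i) * w2i
                              + (1.0 - F) * (1.0 - e2i) * w1i)) / deni
        else:
            P_cep = Ped
    else:
        P_cep = P_lv
    EDV = sc[32] if sc[32] > 0 else V_lv
    SSR = V_lv / EDV
    CEP = sc[18] * P_cep
    VE_lad = sc[19] * sc[6] * e1i
    VE_lcx = sc[19] * sc[7] * e2i
    SIP = sc[20] * (1.0 - SSR)
    imp_lad = CEP + VE_lad + SIP
    imp_lcx = CEP + VE_lcx + SIP

    q_ao = (P_lv - P_art) / sc[21] if P_lv >= P_art else 0.0
    q_mv = (P_la - P_lv) / sc[24] if P_la >= P_lv else 0.0
    q_per = (P_art - P_ven) / sc[22]
    q_ven = (P_ven - P_la) / sc[23]

    n1 = len(L1)
    q_lad_in, q_lad_out = _network(
        y, parent1, leaf1, L1, Ap1, Bp1, phi1, Cp1, root1, sc[29], sc[31],
        P_art, P_ven, imp_lad, dydt, 4)
    q_lcx_in, q_lcx_out = _network(
        y, parent2, leaf2, L2, Ap2, Bp2, phi2, Cp2, root2, sc[30], sc[31],
        P_art, P_ven, imp_lcx, dydt, 4 + n1)

    dydt[0] = q_ven - q_mv
    dydt[1] = q_mv - q_ao
    dydt[2] = q_ao - q_per - q_lad_in - q_lcx_in
    dydt[3] = q_per - q_ven + q_lad_out + q_lcx_out

    if obs.shape[0] > 0:
        obs[0] = P_lv; obs[1] = P_la; obs[2] = P_art; obs[3] = P_ven
        obs[4] = q_ao; obs[5] = q_mv; obs[6] = q_per; obs[7] = q_ven
        obs[8] = q_lad_in; obs[9] = q_lcx_in; obs[10] = q_lad_out; obs[11] = q_lcx_out
        obs[12] = imp_lad; obs[13] = imp_lcx; obs[14] = CEP
        obs[15] = VE_lad; obs[16] = VE_lcx; obs[17] = SIP
        obs[18] = e1; obs[19] = e2; obs[20] = V_lv; obs[21] = V_la
        s1 = 0.0
        for i in range(n1):
            s1 += y[4 + i]
        s2 = 0.0
        for i in range(len(L2)):
            s2 += y[4 + n1 + i]
        obs[22] = s1; obs[23] = s2


@njit(cache=True, fastmath=False)
def rhs_fast(t, y, sc,
             parent1, leaf1, L1, Ap1, Bp1, phi1, Cp1, root1,
             parent2, leaf2, L2, Ap2, Bp2, phi2, Cp2, root2):
    dydt = np.empty_like(y)
    obs = np.empty(0)
    _eval(t, y, sc, parent1, leaf1, L1, Ap1, Bp1, phi1, Cp1, root1,
          parent2, leaf2, L2, Ap2, Bp2, phi2, Cp2, root2, dydt, obs)
    return dydt


@njit(cache=True, fastmath=False)
def observables_fast(ts, Y, sc,
                     parent1, leaf1, L1, Ap1, Bp1, phi1, Cp1, root1,
                     parent2, leaf2, L2, Ap2, Bp2, phi2, Cp2, root2):
    nt = len(ts)
    out = np.empty((nt, 24))
    dydt = np.empty(Y.shape[1])
    for j in range(nt):
        _eval(ts[j], Y[j], sc, parent1, leaf1, L1, Ap1, Bp1, phi1, Cp1, root1,
              parent2, leaf2, L2, Ap2, Bp2, phi2, Cp2, root2, dydt, out[j])
    return out
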