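"""Coronary Windkessel network: vessel laws and the nodal flow solve."""

import numpy as np
import pytest

from corosim.chambers import ParameterError
from corosim.network import (
    MU_BLOOD,
    CoronaryNetwork,
    NetworkBoundary,
    StateError,
    cycle_flow_total,
    lumen_volume,
    transvascular_pressure,
    vessel_capacitance,
    vessel_diameter,
    vessel_resistance,
)
from corosim.tree import CoronaryTree, Vessel


def make_vessel(D=0.1, L=1.0, ap_frac=0.8, phi=30.0, Cp=10.0):
    return Vessel(0, None, 6, D, L, ap_frac * D, (1 - ap_frac) * D, phi, Cp)


def make_tree(parent, D, L, ap_frac=0.8, phi=30.0, Cp=10.0):
    n = len(parent)
    D = np.asarray(D, float)
    order = np.zeros(n, int)
    # orders along root->leaf paths must not increase
    depth = np.zeros(n, int)
    for i in range(n):
        j = i
        while parent[j] >= 0:
            depth[i] += 1
            j = parent[j]
    order = 6 - depth
    return CoronaryTree(
        np.arange(n), parent, order, D, L,
        Ap=ap_frac * D, Bp=(1 - ap_frac) * D,
        phi_p=np.full(n, phi), Cp=np.full(n, Cp),
    )


# ---- vessel laws ----------------------------------------------------------


def test_diameter_law_midpoint_and_asymptotes():
    v = make_vessel()
    # at dP = phi_p: D = 2*(Bp + (Ap-Bp)/2) = Ap + Bp
    assert vessel_diameter(v.phi_p, v) == pytest.approx(v.Ap + v.Bp, rel=1e-12)
    assert vessel_diameter(1e9, v) == pytest.approx(2 * v.Ap, rel=1e-6)
    assert vessel_diameter(-1e9, v) == pytest.approx(2 * v.Bp, rel=1e-6)


def test_diameter_law_is_strictly_increasing_and_bounded():
    v = make_vessel()
    dP = np.linspace(-200, 200, 401)
    D = vessel_diameter(dP, v)
    assert np.all(np.diff(D) > 0)
    assert np.all((D > 2 * v.Bp) & (D < 2 * v.Ap))


def test_transvascular_pressure_inverts_diameter():
    v = make_vessel()
    for dP in (-80.0, 0.0, 30.0, 120.0):
        assert transvascular_pressure(vessel_diameter(dP, v), v) == pytest.approx(
            dP, abs=1e-9
        )
    with pytest.raises(StateError):
        transvascular_pressure(2 * v.Ap, v)


def test_diameter_law_rejects_bad_constants():
    bad = make_vessel()
    bad.Ap, bad.Bp = bad.Bp, bad.Ap
    with pytest.raises(ParameterError):
        vessel_diameter(0.0, bad)
    bad2 = make_vessel()
    bad2.Cp = 0.0
    with pytest.raises(ParameterError):
        vessel_diameter(0.0, bad2)


def test_half_resistance_poiseuille_value():
    # R = 64 mu L / (pi D^4), half the full-vessel 128 mu L/(pi D^4)
    assert vessel_resistance(0.1, 2.0, mu=0.01) == pytest.approx(
        64 * 0.01 * 2.0 / (np.pi * 0.1**4), rel=1e-12
    )
    with pytest.raises(StateError):
        vessel_resistance(-0.1, 1.0)


def test_capacitance_matches_finite_difference():
    v = make_vessel()
    for dP in (-50.0, 0.0, 30.0, 90.0):
        h = 1e-5
        fd = (lumen_volume(dP + h, v) - lumen_volume(dP - h, v)) / (2 * h)
        assert vessel_capacitance(dP, v) == pytest.approx(fd, rel=1e-6)
        assert vessel_capacitance(dP, v) > 0


def test_cycle_flow_total_requires_full_cycle():
    t = np.linspace(0.0, 0.6, 301)
    q = 2.0 + np.sin(2 * np.pi * t / 0.6)
    # integral of the sine over one period vanishes
    assert cycle_flow_total(t, q, 0.6) == pytest.approx(1.2, rel=1e-4)
    with pytest.raises(ValueError, match="period"):
        cycle_flow_total(t[:100], q[:100], 0.6)


# ---- network solve --------------------------------------------------------


def test_three_vessel_hand_computed_flows():
    """Root bifurcating into two leaves, checked against the by-hand solve.

    Unknowns: root inlet node P0 and the single junction Pj.  With frozen
    volumes the mid-pressures and conductances are known, so
      P0 = (Pin/Rp + g0 Pm0) / (1/Rp + g0)
      Pj = (g0 Pm0 + g1 Pm1 + g2 Pm2) / (g0 + g1 + g2)
    """
    tree = make_tree([-1, 0, 0], D=[0.2, 0.12, 0.15], L=[1.5, 1.0, 1.2])
    Rp, mu = 0.8, MU_BLOOD
    net = CoronaryNetwork(tree, R_proximal=Rp, mu=mu)
    dP = np.array([40.0, 35.0, 30.0])
    V = net.volumes_from_dP(dP)
    bc = NetworkBoundary(P_in=95.0, P_out=5.0, P_T=20.0)

    D = vessel_diameter(dP, tree)
    g = np.pi * D**4 / (64 * mu * tree.length)
    Pm = bc.P_T + dP
    P0 = (bc.P_in / Rp + g[0] * Pm[0]) / (1 / Rp + g[0])
    Pj = (g * Pm).sum() / g.sum()
    q_in_exp = (bc.P_in - P0) / Rp
    dV_exp = np.array(
        [
            (P0 - Pm[0]) * g[0] - (Pm[0] - Pj) * g[0],
            (Pj - Pm[1]) * g[1] - (Pm[1] - bc.P_out) * g[1],
            (Pj - Pm[2]) * g[2] - (Pm[2] - bc.P_out) * g[2],
        ]
    )
    q_out_exp = (Pm[1] - bc.P_out) * g[1] + (Pm[2] - bc.P_out) * g[2]

    dVdt, q_in, P_mid, q_out, _ = net.rhs(V, bc)
    assert q_in == pytest.approx(q_in_exp, rel=1e-10)
    assert q_out == pytest.approx(q_out_exp, rel=1e-10)
    assert dVdt == pytest.approx(dV_exp, rel=1e-10)
    assert P_mid == pytest.approx(Pm, rel=1e-12)


def _nodal_oracle(net, V, bc):
    """Independent frozen-diameter solve: junction pressures by dense solve."""
    tree = net.tree
    n = tree.n_vessels
    dP = net.dP_from_volumes(V)
    Pm = bc.P_T + dP
    D = vessel_diameter(dP, tree)
    g = np.pi * D**4 / (64 * net.mu * tree.length)
    # unknown nodes: inlet node (index n) and one junction per internal vessel
    internal = np.flatnonzero(~tree.is_leaf)
    node_of = {int(i): k for k, i in enumerate(internal)}
    m = len(internal) + 1
    A = np.zeros((m, m))
    b = np.zeros(m)
    inlet = m - 1
    gp = 1.0 / net.R_proximal
    # inlet node: gp(Pin - P0) = g_root (P0 - Pm_root)
    A[inlet, inlet] = gp + g[tree.root]
    b[inlet] = gp * bc.P_in + g[tree.root] * Pm[tree.root]
    for i in internal:
        k = node_of[int(i)]
        A[k, k] += g[i]
        b[k] += g[i] * Pm[i]
        for c in np.flatnonzero(tree.parent == i):
            A[k, k] += g[c]
            b[k] += g[c] * Pm[c]
    P = np.linalg.solve(A, b)
    P_junction = {i: P[k] for i, k in node_of.items()}
    P0 = P[inlet]
    dVdt = np.empty(n)
    q_out = 0.0
    for i in range(n):
        pin = P0 if tree.parent[i] < 0 else P_junction[int(tree.parent[i])]
        pout = bc.P_out if tree.is_leaf[i] else P_junction[int(i)]
        dVdt[i] = (pin - Pm[i]) * g[i] - (Pm[i] - pout) * g[i]
        if tree.is_leaf[i]:
            q_out += (Pm[i] - pout) * g[i]
    return dVdt, (bc.P_in - P0) * gp, q_out


def test_rhs_matches_dense_nodal_oracle_on_random_tree():
    from corosim.tree import generate_tree
    from corosim import defaults

    tree = generate_tree(defaults.compact_tree_spec(seed=5))
    net = CoronaryNetwork(tree, R_proximal=1.0)
    rng = np.random.default_rng(3)
    dP = rng.uniform(10.0, 80.0, tree.n_vessels)
    V = net.volumes_from_dP(dP)
    for bc in (
        NetworkBoundary(100.0, 5.0, 10.0),
        NetworkBoundary(90.0, 3.0, 80.0),  # systolic compression
        NetworkBoundary(60.0, 8.0, 0.0),
    ):
        dVdt, q_in, _, q_out, _ = net.rhs(V, bc)
        dV_o, qin_o, qout_o = _nodal_oracle(net, V, bc)
        assert dVdt == pytest.approx(dV_o, rel=1e-8, abs=1e-12)
        assert q_in == pytest.approx(qin_o, rel=1e-8)
        assert q_out == pytest.approx(qout_o, rel=1e-8)


def test_volume_bookkeeping_is_exact():
    """inlet flow − summed terminal outflow == total lumen-volume rate."""
    from corosim.tree import generate_tree
    from corosim import defaults

    tree = generate_tree(defaults.compact_tree_spec(seed=8))
    net = CoronaryNetwork(tree, R_proximal=1.5)
    rng = np.random.default_rng(11)
    V = net.volumes_from_dP(rng.uniform(5.0, 90.0, tree.n_vessels))
    dVdt, q_in, _, q_out, _ = net.rhs(V, NetworkBoundary(100.0, 5.0, 30.0))
    assert dVdt.sum() == pytest.approx(q_in - q_out, abs=1e-10)


def test_imp_shifts_mid_pressure_additively_and_drives_backflow():
    tree = make_tree([-1, 0, 0], D=[0.2, 0.12, 0.15], L=[1.5, 1.0, 1.2])
    net = CoronaryNetwork(tree, R_proximal=0.8)
    V = net.volumes_from_dP(np.array([40.0, 35.0, 30.0]))
    low = NetworkBoundary(95.0, 5.0, 0.0)
    high = NetworkBoundary(95.0, 5.0, 120.0)
    _, q_lo, Pm_lo, _, _ = net.rhs(V, low)
    _, q_hi, Pm_hi, _, _ = net.rhs(V, high)
    assert Pm_hi - Pm_lo == pytest.approx(np.full(3, 120.0), rel=1e-12)
    assert q_lo > 0
    assert q_hi < 0  # squeezing expels volume back into the inlet


def test_equilibrium_volumes_are_stationary_and_decrease_with_imp():
    tree = make_tree([-1, 0, 0], D=[0.2, 0.12, 0.15], L=[1.5, 1.0, 1.2])
    net = CoronaryNetwork(tree, R_proximal=0.8)
    V0 = net.equilibrium_volumes(95.0, 5.0, P_T=0.0)
    dVdt, _, _, _, _ = net.rhs(V0, NetworkBoundary(95.0, 5.0, 0.0))
    assert np.max(np.abs(dVdt)) < 1e-7
    V1 = net.equilibrium_volumes(95.0, 5.0, P_T=40.0)
    assert np.all(V1 < V0)


def test_state_errors_on_inadmissible_volumes():
    tree = make_tree([-1, 0, 0], D=[0.2, 0.12, 0.15], L=[1.5, 1.0, 1.2])
    net = CoronaryNetwork(tree, R_proximal=0.8)
    V = net.volumes_from_dP(np.array([40.0, 35.0, 30.0]))
    for bad in (net.V_max * 1.01, net.V_min * 0.99, np.where([1, 0, 0], -1.0, V)):
        with pytest.raises(StateError):
            net.rhs(np.asarray(bad, float), NetworkBoundary(95.0, 5.0, 0.0))
    with pytest.raises(ParameterError):
        CoronaryNetwork(tree, R_proximal=0.0)


def test_open_loop_driver_conserves_volume_and_validates():
    from corosim.network import simulate_open_loop

    tree = make_tree([-1, 0, 0], D=[0.2, 0.12, 0.15], L=[1.5, 1.0, 1.2])
    net = CoronaryNetwork(tree, R_proximal=0.8)
    t = np.linspace(0.0, 1.2, 601)
    P_in = np.full_like(t, 95.0)
    P_out = np.full_like(t, 5.0)
    P_T = 40.0 * np.clip(np.sin(2 * np.pi * t / 0.6), 0.0, None)
    out = simulate_open_loop(net, t, P_in, P_out, P_T)
    assert out["V"].shape == (len(t), 3)
    # integral bookkeeping: stored volume change equals net inflow
    net_in = np.trapezoid(out["q_in"] - out["q_out"], t)
    assert net_in == pytest.approx(out["V_lumen"][-1] - out["V_lumen"][0], abs=5e-4)
    # compression squeezes the lumen
    assert out["V_lumen"].min() < out["V_lumen"][0]
    # second cycle repeats the first (started from equilibrium)
    assert out["q_in"][300:] == pytest.approx(out["q_in"][:301], abs=0.05)
    with pytest.raises(ValueError, match="increasing"):
        simulate_open_loop(net, t[::-1], P_in, P_out, P_T)
    with pytest.raises(ValueError, match="shape"):
        simulate_open_loop(net, t, P_in[:-1], P_out, P_T)
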