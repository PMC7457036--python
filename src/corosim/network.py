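"""Nonlinear three-element Windkessel flow on a coronary tree.

Every vessel is an R-C-R element: two equal half-resistances around a
mid-node whose nonlinear capacitance stores lumen volume.  Vessel diameter
is a sigmoidal (arctan) function of the transvascular pressure
dP = P_mid − P_T, where P_T is the intramyocardial pressure of the vessel's
territory; the half-resistances follow Poiseuille's law on the current
diameter.  The network state is the lumen volume of each vessel, which makes
volume bookkeeping exact: inlet flow − outlet flow = d/dt(total lumen
volume) identically.  Junction pressures are algebraic and eliminated
locally at each evaluation (each junction touches only its parent's and
children's mid-nodes, so Kirchhoff's balance is a scalar solve per node).

Units: mmHg, ml, s, cm.  The default effective blood viscosity is 3.5 cP
expressed in mmHg·s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chambers import ParameterError
from .tree import CoronaryTree

__all__ = [
    "MU_BLOOD",
    "NetworkBoundary",
    "CoronaryNetwork",
    "StateError",
    "vessel_diameter",
    "vessel_resistance",
    "vessel_capacitance",
    "cycle_flow_total",
    "simulate_open_loop",
]

#: 3.5 cP = 3.5e-3 Pa·s, converted to mmHg·s (1 mmHg = 133.322 Pa)
MU_BLOOD = 3.5e-3 / 133.322


class StateError(RuntimeError):
    """Raised when a network state leaves its admissible region."""


@dataclass
class NetworkBoundary:
    """Boundary conditions seen by one coronary network at one instant.

    P_in : driving pressure upstream of the proximal resistance (mmHg);
           the systemic arterial pressure in the coupled model.
    P_out: outlet pressure at every terminal vessel (mmHg); the systemic
           venous pressure in the coupled model.
    P_T  : intramyocardial pressure, homogeneous over the territory (mmHg).
    """

    P_in: float
    P_out: float
    P_T: float


def vessel_diameter(dP, v_or_tree, idx=None):
    """Sigmoidal passive diameter D(dP) = 2·[Bp + (Ap−Bp)/π·(π/2 + arctan((dP−phi_p)/Cp))].

    Strictly increasing in the transvascular pressure dP and bounded in
    (2·Bp, 2·Ap).  Accepts a Vessel-like object or a CoronaryTree (vector
    evaluation over all vessels).
    """
    Ap, Bp, phi, Cp = _pd_constants(v_or_tree)
    if np.any(Ap <= Bp):
        raise ParameterError("require Ap > Bp")
    if np.any(Cp <= 0):
        raise ParameterError("require Cp > 0")
    dP = np.asarray(dP, dtype=float)
    D = 2.0 * (Bp + (Ap - Bp) / np.pi * (np.pi / 2.0 + np.arctan((dP - phi) / Cp)))
    return D if np.ndim(D) else float(D)


def transvascular_pressure(D, v_or_tree):
    """Inverse of :func:`vessel_diameter` (dP from current diameter)."""
    Ap, Bp, phi, Cp = _pd_constants(v_or_tree)
    u = (np.asarray(D, dtype=float) / 2.0 - Bp) / (Ap - Bp)
    if np.any((u <= 0) | (u >= 1)):
        raise StateError("diameter outside the admissible range (2*Bp, 2*Ap)")
    dP = phi + Cp * np.tan(np.pi * u - np.pi / 2.0)
    return dP if np.ndim(dP) else float(dP)


def vessel_resistance(D, L, mu: float = MU_BLOOD):
    """Half-vessel Poiseuille resistance R1 = R2 = 64·mu·L/(π·D^4)."""
    D = np.asarray(D, dtype=float)
    if np.any(D <= 0):
        raise StateError("diameter must be positive")
    R = 64.0 * mu * np.asarray(L, dtype=float) / (np.pi * D**4)
    return R if np.ndim(R) else float(R)


def vessel_capacitance(dP, v_or_tree):
    """Analytic lumen capacitance C = ∂(π·D²·L/4)/∂dP (ml/mmHg); always > 0."""
    Ap, Bp, phi, Cp = _pd_constants(v_or_tree)
    L = _lengths(v_or_tree)
    D = vessel_diameter(dP, v_or_tree)
    dDddP = 2.0 * (Ap - Bp) / np.pi * Cp / (Cp**2 + (np.asarray(dP, dtype=float) - phi) ** 2)
    C = np.pi * D * L / 2.0 * dDddP
    return C if np.ndim(C) else float(C)


def lumen_volume(dP, v_or_tree):
    """Lumen volume π·D(dP)²·L/4 (ml)."""
    L = _lengths(v_or_tree)
    D = vessel_diameter(dP, v_or_tree)
    V = np.pi * D**2 * L / 4.0
    return V if np.ndim(V) else float(V)


def cycle_flow_total(t, q, T: float) -> float:
    """Time integral of a flow waveform over exactly one cycle (ml/cycle)."""
    t = np.asarray(t, dtype=float)
    q = np.asarray(q, dtype=float)
    if t[-1] - t[0] < T * (1.0 - 1e-9):
        raise ValueError(f"waveform spans {t[-1] - t[0]:.4g} s but the period is {T} s")
    return float(np.trapezoid(q, t))


def _pd_constants(v_or_tree):
    if isinstance(v_or_tree, CoronaryTree):
        return v_or_tree.Ap, v_or_tree.Bp, v_or_tree.phi_p, v_or_tree.Cp
    v = v_or_tree
    return v.Ap, v.Bp, v.phi_p, v.Cp


def _lengths(v_or_tree):
    if isinstance(v_or_tree, CoronaryTree):
        return v_or_tree.length
    return v_or_tree.length


class CoronaryNetwork:
    """Windkessel dynamics of one territory's tree behind its proximal resistance.

    The ODE state is the vector of vessel lumen volumes.  Mid-node pressures
    are recovered by inverting the pressure-diameter law; junction pressures
    are eliminated by local Kirchhoff balances, after which every vessel's
    volume rate is (inlet − outlet) flow.
    """

    def __init__(self, tree: CoronaryTree, R_proximal: float, mu: float = MU_BLOOD):
        if R_proximal <= 0:
            raise ParameterError(f"proximal resistance must be > 0, got {R_proximal}")
        tree.validate()
        self.tree = tree
        self.R_proximal = float(R_proximal)
        self.mu = float(mu)
        self.n = tree.n_vessels
        self.root = tree.root
        self.parent = tree.parent
        self.is_leaf = tree.is_leaf
        self._has_children = ~self.is_leaf
        self._nonroot = self.parent >= 0
        self._parent_of_nonroot = self.parent[self._nonroot]
        # volume bounds per vessel (open interval)
        self.V_min = np.pi * (2.0 * tree.Bp) ** 2 * tree.length / 4.0
        self.V_max = np.pi * (2.0 * tree.Ap) ** 2 * tree.length / 4.0

    # -- state mappings ------------------------------------------------------
    def volumes_from_dP(self, dP) -> np.ndarray:
        return lumen_volume(dP, self.tree)

    def dP_from_volumes(self, V: np.ndarray) -> np.ndarray:
        V = np.asarray(V, dtype=float)
        if np.any(V <= self.V_min) or np.any(V >= self.V_max):
            raise StateError("lumen volume outside admissible bounds")
        D = np.sqrt(4.0 * V / (np.pi * self.tree.length))
        return transvascular_pressure(D, self.tree)

    def equilibrium_volumes(self, P_art: float, P_ven: float, P_T: float = 0.0) -> np.ndarray:
        """Steady lumen volumes with frozen boundaries (fixed-point iteration).

        Used to initialize the coupled simulation.
        """
        dP = np.full(self.n, max((P_art + P_ven) / 2.0 - P_T, 1.0))
        bc = NetworkBoundary(P_art, P_ven, P_T)
        for _ in range(500):
            V = self.volumes_from_dP(dP)
            dVdt, _, _, _, _ = self.rhs(V, bc)
            # stationarity per vessel: q_in = q_out, i.e. P_mid is the mean of
            # its node pressures; with equal half-conductances g the imbalance
            # is dV/dt = (P_in + P_out - 2 P_mid) g, so the balancing shift is
            # dV/dt / (2 g)
            D = vessel_diameter(dP, self.tree)
            g = np.pi * D**4 / (64.0 * self.mu * self.tree.length)
            step = dVdt / (2.0 * g)
            if np.max(np.abs(step)) < 1e-10:
                break
            dP = dP + 0.5 * step
        return self.volumes_from_dP(dP)

    # -- dynamics --------------------------------------------------------------
    def rhs(self, V: np.ndarray, bc: NetworkBoundary):
        """Volume rates and boundary flows at one instant.

        Returns ``(dVdt, q_in, P_mid, q_out_total, q_out_leaves)`` where
        q_in is the flow drawn from the arterial compartment (can be
        negative during systolic compression) and q_out_total the summed
        terminal outflow into the venous compartment.
        """
        dP = self.dP_from_volumes(V)
        P_mid = bc.P_T + dP
        D = vessel_diameter(dP, self.tree)
        g = np.pi * D**4 / (64.0 * self.mu * self.tree.length)  # half-vessel conductance

        # junction pressure at each non-leaf vessel's outlet node
        num = np.zeros(self.n)
        den = np.zeros(self.n)
        gP = g * P_mid
        np.add.at(num, self._parent_of_nonroot, gP[self._nonroot])
        np.add.at(den, self._parent_of_nonroot, g[self._nonroot])
        num += gP
        den += g
        with np.errstate(invalid="ignore"):
            P_junction = num / den
        if not np.all(np.isfinite(P_junction[self._has_children])):
            raise StateError("singular junction system (all incident resistances infinite)")

        # outlet node pressure per vessel: junction if internal, P_out if leaf
        P_out_node = np.where(self.is_leaf, bc.P_out, P_junction)
        # inlet node pressure per vessel: parent's junction; root via R_proximal
        P_in_node = np.empty(self.n)
        P_in_node[self._nonroot] = P_out_node[self._parent_of_nonroot]
        g_prox = 1.0 / self.R_proximal
        r = self.root
        P_in_node[r] = (bc.P_in * g_prox + gP[r]) / (g_prox + g[r])

        q_in_vessel = (P_in_node - P_mid) * g
        q_out_vessel = (P_mid - P_out_node) * g
        dVdt = q_in_vessel - q_out_vessel
        q_in = (bc.P_in - P_in_node[r]) * g_prox
        q_out_leaves = q_out_vessel[self.is_leaf]
        return dVdt, float(q_in), P_mid, float(q_out_leaves.sum()), q_out_leaves


def simulate_open_loop(
    network: CoronaryNetwork,
    t: np.ndarray,
    P_in: np.ndarray,
    P_out: np.ndarray,
    P_T: np.ndarray,
    V0: np.ndarray | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-8,
) -> dict:
    """Drive one network with tabulated boundary-pressure traces.

    ``t`` must be strictly increasing; the three pressure traces are sampled
    on it and linearly interpolated during integration (periodic use is up to
    the caller: pass as many cycles as needed).  ``V0`` defaults to the
    frozen-boundary equilibrium at the initial samples.  Returns waveforms on
    ``t``: inlet flow ``q_in``, summed terminal outflow ``q_out``, total
    lumen volume ``V_lumen``, and the per-vessel volume matrix ``V``.
    """
    from scipy.integrate import solve_ivp

    t = np.asarray(t, dtype=float)
    if t.ndim != 1 or len(t) < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("t must be a strictly increasing 1-d array")
    traces = []
    for name, p in (("P_in", P_in), ("P_out", P_out), ("P_T", P_T)):
        p = np.asarray(p, dtype=float)
        if p.shape != t.shape:
            raise ValueError(f"{name} must have the same shape as t")
        traces.append(p)
    P_in, P_out, P_T = traces

    if V0 is None:
        V0 = network.equilibrium_volumes(P_in[0], P_out[0], P_T[0])

    def bc_at(tau):
        return NetworkBoundary(
            float(np.interp(tau, t, P_in)),
            float(np.interp(tau, t, P_out)),
            float(np.interp(tau, t, P_T)),
        )

    def rhs(tau, V):
        dVdt, _, _, _, _ = network.rhs(V, bc_at(tau))
        return dVdt

    sol = solve_ivp(rhs, (t[0], t[-1]), np.asarray(V0, float), method="LSODA",
                    t_eval=t, rtol=rtol, atol=atol)
    if not sol.success:
        raise StateError(f"open-loop integration failed: {sol.message}")
    q_in = np.empty(len(t))
    q_out = np.empty(len(t))
    for j in range(len(t)):
        _, q_in[j], _, q_out[j], _ = network.rhs(sol.y[:, j], bc_at(t[j]))
    return {
        "t": t, "q_in": q_in, "q_out": q_out,
        "V_lumen": sol.y.sum(axis=0), "V": sol.y.T,
    }
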