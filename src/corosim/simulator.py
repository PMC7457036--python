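"""Closed-loop coupling of chambers, systemic loop, coronary networks and IMP.

The monolithic ODE state is ``[V_LA, V_LV, V_art, V_ven, lumen volumes of the
LAD tree, lumen volumes of the LCX tree]``.  Pressures are algebraic
functions of the state and the activation clocks; both territory networks
see the arterial pressure (behind their proximal resistance) at the inlet,
the venous pressure at every terminal, and their territory's intramyocardial
pressure around every vessel.  One stiff implicit solve advances each
cardiac cycle; cycles repeat until the periodicity criterion holds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.sparse import lil_matrix

from .chambers import (
    ActivationSchedule,
    ChamberParams,
    activation,
    atrial_pressure,
    end_diastolic_pressure,
    two_compartment_pressure,
)
from .imp import IMPParams, imp
from .network import CoronaryNetwork, NetworkBoundary
from .systemic import CircParams, linear_flow, loop_derivatives, valve_flow

__all__ = [
    "ScenarioConfig",
    "CycleMetrics",
    "SolverOptions",
    "ConvergenceError",
    "ClosedLoopModel",
    "SimulationResult",
    "cycle_metrics",
    "compare_scenarios",
]

MODES = ("CON", "MD", "MD_IS")


class ConvergenceError(RuntimeError):
    """Periodic steady state not reached within the cycle cap."""


@dataclass
class ScenarioConfig:
    """Which experiment to run: control, dyssynchrony, or dyssynchrony+ischemia."""

    mode: str = "CON"
    sched: ActivationSchedule | None = None
    ischemia: object | None = None  # IschemiaParams for MD_IS
    heart_rate: float = 100.0

    def __post_init__(self) -> None:
        mode = self.mode.upper().replace("-", "_").replace("MD+IS", "MD_IS")
        if mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode}")
        self.mode = mode
        if self.sched is None:
            self.sched = ActivationSchedule(T=60.0 / self.heart_rate)
        if self.mode == "CON" and (self.sched.dt_lcx or self.sched.dt_bar):
            raise ValueError("control scenario requires dt_lcx = dt_bar = 0")
        if self.mode == "MD_IS" and self.ischemia is None:
            raise ValueError("MD_IS scenario requires ischemia parameters")


@dataclass
class SolverOptions:
    rtol: float = 1e-6
    atol: float = 1e-8
    method: str = "BDF"
    output_dt: float = 1e-3  # s, metric-extraction sampling step
    max_cycles: int = 50
    periodicity_tol: float = 1e-3  # relative change between consecutive cycles
    use_fast: bool = True  # compiled kernel + LSODA; False = reference numpy + BDF


@dataclass
class CycleMetrics:
    """Scalar summaries of one steady-state cycle."""

    EDV: float
    ESV: float
    peak_lvp: float
    mean_lvp: float
    peak_part: float
    mean_part: float
    dpdt_max: float
    dpdt_min: float
    sum_q_lad: float
    sum_q_lcx: float
    peak_imp_lad: float
    mean_imp_lad: float
    peak_imp_lcx: float
    mean_imp_lcx: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class SimulationResult:
    waveforms: dict
    metrics: CycleMetrics
    n_cycles: int
    converged: bool
    history: list = field(default_factory=list)  # per-cycle convergence trace
    y_end: np.ndarray | None = None
    Ees_lad: float | None = None
    Ees_lcx: float | None = None


class ClosedLoopModel:
    """The coupled cardiac-coronary system for one parameterization."""

    def __init__(
        self,
        lad_chamber: ChamberParams,
        lcx_chamber: ChamberParams,
        la_chamber: ChamberParams,
        F: float,
        circ: CircParams,
        imp_params: IMPParams,
        sched: ActivationSchedule,
        lad_network: CoronaryNetwork,
        lcx_network: CoronaryNetwork,
        solver: SolverOptions | None = None,
    ):
        if not 0 < F < 1:
            raise ValueError(f"F must be in (0, 1), got {F}")
        self.lad = lad_chamber
        self.lcx = lcx_chamber
        self.la = la_chamber
        self.F = float(F)
        self.circ = circ
        self.imp_params = imp_params
        self.sched = sched
        self.net_lad = lad_network
        self.net_lcx = lcx_network
        self.solver = solver or SolverOptions()
        self.n_lad = lad_network.n
        self.n_lcx = lcx_network.n
        self.nstate = 4 + self.n_lad + self.n_lcx
        self.EDV_ref = None  # previous completed cycle's EDV, drives SSR
        self._sparsity = self._build_sparsity()

    # -- construction helpers ------------------------------------------------
    def initial_state(self, volumes: dict) -> np.ndarray:
        """Loop volumes from a config dict; coronary lumens at the frozen-
        boundary equilibrium for the implied arterial/venous pressures."""
        from .systemic import compartment_pressure

        P_art = compartment_pressure(volumes["V_art"], self.circ.V_art0, self.circ.C_art)
        P_ven = compartment_pressure(volumes["V_ven"], self.circ.V_ven0, self.circ.C_ven)
        y = np.empty(self.nstate)
        y[:4] = [volumes["V_la"], volumes["V_lv"], volumes["V_art"], volumes["V_ven"]]
        y[4 : 4 + self.n_lad] = self.net_lad.equilibrium_volumes(P_art, P_ven, 0.0)
        y[4 + self.n_lad :] = self.net_lcx.equilibrium_volumes(P_art, P_ven, 0.0)
        self.EDV_ref = volumes["V_lv"]
        return y

    def set_contractility(self, Ees_lad: float, Ees_lcx: float) -> None:
        """Update territory contractility (used by the ischemia feedback);
        feeds both the two-compartment pressure law and the VE term of IMP."""
        self.lad = self.lad.replace(Ees=Ees_lad)
        self.lcx = self.lcx.replace(Ees=Ees_lcx)

    # -- instantaneous algebra -------------------------------------------------
    def algebraic(self, t: float, y: np.ndarray) -> dict:
        """All pressures/flows implied by the state at time t."""
        sched, circ = self.sched, self.circ
        V_la, V_lv, V_art, V_ven = y[0], y[1], y[2], y[3]
        P_art = (V_art - circ.V_art0) / circ.C_art
        P_ven = (V_ven - circ.V_ven0) / circ.C_ven

        e1 = activation(t, self.lad, sched.T)
        e2 = activation(t - sched.dt_lcx, self.lcx, sched.T)
        Ped = end_diastolic_pressure(V_lv, self.lad)
        P_lv = two_compartment_pressure(V_lv, e1, e2, self.lad, self.lcx, self.F, Ped)
        P_la = atrial_pressure(V_la, t, self.la, sched)

        # IMP clocks: both territories' elastance clocks inside the IMP may
        # additionally lag the pumping clocks by dt_bar.  The CEP component
        # uses the chamber pressure evaluated at the lagged clocks (identical
        # to P_lv when dt_bar = 0), so a positive dt_bar delays the whole IMP
        # waveform relative to P_lv and P_art.
        e_lad_imp = activation(t - sched.dt_bar, self.lad, sched.T)
        e_lcx_imp = activation(t - sched.dt_lcx - sched.dt_bar, self.lcx, sched.T)
        if sched.dt_bar:
            P_cep = two_compartment_pressure(
                V_lv, e_lad_imp, e_lcx_imp, self.lad, self.lcx, self.F, Ped
            )
        else:
            P_cep = P_lv
        EDV = self.EDV_ref if self.EDV_ref else V_lv
        SSR = V_lv / EDV
        imp_lad = imp(P_cep, e_lad_imp, self.lad.Ees, SSR, self.imp_params)
        imp_lcx = imp(P_cep, e_lcx_imp, self.lcx.Ees, SSR, self.imp_params)

        q_ao = valve_flow(P_lv, P_art, circ.R_ao)
        q_mv = valve_flow(P_la, P_lv, circ.R_mv)
        q_per = linear_flow(P_art, P_ven, circ.R_per)
        q_ven = linear_flow(P_ven, P_la, circ.R_ven)

        V_lumen_lad = y[4 : 4 + self.n_lad]
        V_lumen_lcx = y[4 + self.n_lad :]
        d_lad, q_lad_in, _, q_lad_out, _ = self.net_lad.rhs(
            V_lumen_lad, NetworkBoundary(P_art, P_ven, imp_lad.total)
        )
        d_lcx, q_lcx_in, _, q_lcx_out, _ = self.net_lcx.rhs(
            V_lumen_lcx, NetworkBoundary(P_art, P_ven, imp_lcx.total)
        )
        return {
            "P_lv": P_lv, "P_la": P_la, "P_art": P_art, "P_ven": P_ven,
            "q_ao": q_ao, "q_mv": q_mv, "q_per": q_per, "q_ven": q_ven,
            "q_lad": q_lad_in, "q_lcx": q_lcx_in,
            "q_lad_out": q_lad_out, "q_lcx_out": q_lcx_out,
            "imp_lad": imp_lad, "imp_lcx": imp_lcx,
            "e_lad": e1, "e_lcx": e2, "SSR": SSR,
            "d_lad": d_lad, "d_lcx": d_lcx,
        }

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        a = self.algebraic(t, y)
        dydt = np.empty(self.nstate)
        dydt[:4] = loop_derivatives(
            a["q_ven"], a["q_mv"], a["q_ao"], a["q_per"],
            a["q_lad"], a["q_lcx"], a["q_lad_out"], a["q_lcx_out"],
        )
        dydt[4 : 4 + self.n_lad] = a["d_lad"]
        dydt[4 + self.n_lad :] = a["d_lcx"]
        return dydt

    # -- integration -------------------------------------------------------------
    def run_cycle(self, y0: np.ndarray, t0: float):
        """Integrate one cardiac cycle; returns (y_end, waveforms)."""
        so = self.solver
        T = self.sched.T
        t_eval = t0 + np.arange(0.0, T + so.output_dt / 2, so.output_dt)
        if so.use_fast:
            return self._run_cycle_fast(y0, t_eval)
        sol = solve_ivp(
            self.rhs, (t0, t0 + T), y0, method=so.method,
            rtol=so.rtol, atol=so.atol, t_eval=t_eval,
            jac_sparsity=self._sparsity if so.method in ("BDF", "Radau") else None,
        )
        if not sol.success:  # pragma: no cover - solver failure is exceptional
            raise ConvergenceError(f"integrator failed at t={sol.t[-1]:.4f}: {sol.message}")
        wf = self._sample_waveforms(sol.t, sol.y)
        return sol.y[:, -1], wf

    def _run_cycle_fast(self, y0: np.ndarray, t_eval: np.ndarray):
        from scipy.integrate import odeint

        from .fastpath import OBS_NAMES, observables_fast, pack_constants, rhs_fast

        args = pack_constants(self)
        Y, info = odeint(
            rhs_fast, y0, t_eval, args=args, tfirst=True,
            rtol=self.solver.rtol, atol=self.solver.atol,
            mxstep=50000, full_output=True,
        )
        if info["message"] != "Integration successful.":  # pragma: no cover
            raise ConvergenceError(f"integrator failed: {info['message']}")
        obs = observables_fast(t_eval, Y, *args)
        wf = {name: obs[:, j].copy() for j, name in enumerate(OBS_NAMES)}
        wf["t"] = t_eval - t_eval[0]
        return Y[-1], wf

    def _sample_waveforms(self, t: np.ndarray, Y: np.ndarray) -> dict:
        cols = {k: np.empty_like(t) for k in (
            "P_lv", "P_la", "P_art", "P_ven", "V_lv", "V_la",
            "q_ao", "q_mv", "q_lad", "q_lcx", "q_lad_out", "q_lcx_out",
            "IMP_lad", "IMP_lcx", "CEP", "VE_lad", "VE_lcx", "SIP",
            "e_lad", "e_lcx", "V_lumen_lad", "V_lumen_lcx",
        )}
        for j in range(len(t)):
            a = self.algebraic(t[j], Y[:, j])
            for k in ("P_lv", "P_la", "P_art", "P_ven", "q_ao", "q_mv",
                      "q_lad", "q_lcx", "q_lad_out", "q_lcx_out", "e_lad", "e_lcx"):
                cols[k][j] = a[k]
            cols["V_lv"][j] = Y[1, j]
            cols["V_la"][j] = Y[0, j]
            cols["IMP_lad"][j] = a["imp_lad"].total
            cols["IMP_lcx"][j] = a["imp_lcx"].total
            cols["CEP"][j] = a["imp_lad"].CEP
            cols["VE_lad"][j] = a["imp_lad"].VE
            cols["VE_lcx"][j] = a["imp_lcx"].VE
            cols["SIP"][j] = a["imp_lad"].SIP
            cols["V_lumen_lad"][j] = Y[4 : 4 + self.n_lad, j].sum()
            cols["V_lumen_lcx"][j] = Y[4 + self.n_lad :, j].sum()
        cols["t"] = t - t[0]
        return cols

    def run_to_periodic(
        self,
        y0: np.ndarray | None = None,
        volumes: dict | None = None,
        per_cycle_update=None,
    ) -> SimulationResult:
        """Cycle until EDV, peak LVP and both cycle flows are stationary.

        ``per_cycle_update(model, metrics) -> residual`` is an optional hook
        (used by the ischemia feedback); its residual must also fall below
        the periodicity tolerance for convergence.

        The cycle-to-cycle map relaxes along one slow mode (redistribution of
        blood volume between the arterial and venous reservoirs, time constant
        of many cycles), so plain iteration approaches the fixed point
        geometrically with ratio close to 1 and a per-cycle stopping rule
        leaves a bias ~tol*r/(1-r).  When successive state increments are
        parallel and contracting, an Aitken extrapolation jumps along that
        mode; it is volume-conserving (the increment of a conservative map
        sums to ~0) and disabled while a feedback hook is mutating the model.
        """
        so = self.solver
        if y0 is None:
            from .defaults import INITIAL_VOLUMES

            y0 = self.initial_state(volumes or dict(INITIAL_VOLUMES))
        y = np.asarray(y0, dtype=float)
        prev = None
        history = []
        d_prev = None
        for k in range(so.max_cycles):
            y_in = y
            y, wf = self.run_cycle(y, 0.0)
            m = cycle_metrics(wf, self.sched.T)
            self.EDV_ref = m.EDV
            resid = 0.0
            if per_cycle_update is not None:
                resid = float(per_cycle_update(self, m))
            key = np.array([m.EDV, m.peak_lvp, m.sum_q_lad, m.sum_q_lcx])
            if not np.isfinite(key).all():
                raise ConvergenceError(
                    f"non-finite cycle metrics at cycle {k + 1}: {key}"
                )
            if prev is not None:
                rel = np.max(np.abs(key - prev) / np.maximum(np.abs(prev), 1e-12))
            else:
                rel = np.inf
            history.append({"cycle": k + 1, "rel_change": rel, "feedback_residual": resid,
                            **m.as_dict()})
            d = y - y_in
            # state-space periodicity: available every cycle (also right
            # after an extrapolation jump, when no metric pair exists yet)
            rel_state = float(
                np.max(np.abs(d) / np.maximum(np.abs(y), 1e-3 * np.max(np.abs(y))))
            )
            history[-1]["rel_state"] = rel_state
            if (min(rel, rel_state) < so.periodicity_tol
                    and resid < so.periodicity_tol):
                return SimulationResult(
                    wf, m, k + 1, True, history, y, self.lad.Ees, self.lcx.Ees
                )
            prev = key
            if per_cycle_update is None and d_prev is not None:
                denom = float(d_prev @ d_prev)
                r = float(d @ d_prev) / denom if denom > 0 else 0.0
                cos = 0.0
                nd = float(np.linalg.norm(d))
                if nd > 0 and denom > 0:
                    cos = float(d @ d_prev) / (nd * np.sqrt(denom))
                if 0.1 < r < 0.98 and cos > 0.9:
                    y_ext = y + d * (r / (1.0 - r))
                    # reject jumps that leave the physical region
                    if np.isfinite(y_ext).all() and (y_ext > 0.0).all():
                        y = y_ext
                        d_prev = None  # re-estimate the mode afresh
                        prev = None  # the jump invalidates the metric sample
                        continue
            d_prev = d
        raise ConvergenceError(
            f"no periodic steady state within {so.max_cycles} cycles "
            f"(last relative change {history[-1]['rel_change']:.3g}, "
            f"feedback residual {history[-1]['feedback_residual']:.3g})"
        )

    # -- Jacobian sparsity -------------------------------------------------------
    def _build_sparsity(self):
        n, nl = self.nstate, self.n_lad
        S = lil_matrix((n, n), dtype=np.int8)
        S[0, [0, 1, 3]] = 1  # LA: q_ven(V_ven,V_la), q_mv(V_la,V_lv)
        S[1, [0, 1, 2]] = 1  # LV: q_mv, q_ao(V_lv,V_art)
        S[2, [1, 2, 3]] = 1  # art: q_ao, q_per, coronary inlets (roots below)
        S[3, [0, 1, 2, 3]] = 1  # ven: q_per, q_ven, coronary outlets (leaves below)
        for net, off in ((self.net_lad, 4), (self.net_lcx, 4 + nl)):
            root = off + net.root
            S[2, root] = 1
            leaves = off + np.flatnonzero(net.is_leaf)
            S[3, leaves] = 1
            parent = net.parent
            for i in range(net.n):
                gi = off + i
                S[gi, gi] = 1
                S[gi, 1] = 1  # P_T depends on V_LV (CEP and SSR)
                p = parent[i]
                if p >= 0:
                    S[gi, off + p] = 1
                    sibs = np.flatnonzero(parent == p)
                    S[gi, off + sibs] = 1
                else:
                    S[gi, 2] = 1  # root inlet sees V_art
                kids = np.flatnonzero(parent == i)
                if len(kids):
                    S[gi, off + kids] = 1
                else:
                    S[gi, 3] = 1  # leaf outlet sees V_ven
        return S.tocsr()


def cycle_metrics(wf: dict, T: float) -> CycleMetrics:
    """Extrema, means and cycle integrals of one cycle's waveforms."""
    t = wf["t"]
    dpdt = np.gradient(wf["P_lv"], t)
    return CycleMetrics(
        EDV=float(np.max(wf["V_lv"])),
        ESV=float(np.min(wf["V_lv"])),
        peak_lvp=float(np.max(wf["P_lv"])),
        mean_lvp=float(np.mean(wf["P_lv"])),
        peak_part=float(np.max(wf["P_art"])),
        mean_part=float(np.mean(wf["P_art"])),
        dpdt_max=float(np.max(dpdt)),
        dpdt_min=float(np.min(dpdt)),
        sum_q_lad=float(np.trapezoid(wf["q_lad"], t)),
        sum_q_lcx=float(np.trapezoid(wf["q_lcx"], t)),
        peak_imp_lad=float(np.max(wf["IMP_lad"])),
        mean_imp_lad=float(np.mean(wf["IMP_lad"])),
        peak_imp_lcx=float(np.max(wf["IMP_lcx"])),
        mean_imp_lcx=float(np.mean(wf["IMP_lcx"])),
    )


def compare_scenarios(reference: CycleMetrics, variant: CycleMetrics) -> dict:
    """Per-metric percent change 100·(variant − reference)/reference.

    Metrics with a zero reference are reported as NaN (flagged undefined).
    """
    out = {}
    for k, ref in reference.as_dict().items():
        var = getattr(variant, k)
        out[k] = 100.0 * (var - ref) / ref if ref != 0 else float("nan")
    return out
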