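"""Perfusion-contraction matching: the contractility-flow feedback loop.

In the ischemic regime the maximal territory elastance varies linearly with
that territory's cycle-total coronary flow; above the transitional flow (the
flow of the healthy control animal) contractility plateaus at the
non-ischemic value.  The linear branch is anchored at the transitional point
(Qn, Ees_n) with slope k, so for the physiological slope k = Ees_n/Qn it
passes through the origin, while multiplying the slope steepens the penalty
below Qn without shifting the plateau onset.  In dyssynchrony-with-ischemia runs the
territory elastances are updated from each completed cycle's flows (with
under-relaxation, since raw updates can oscillate at steep slopes) until the
elastances and the hemodynamics are simultaneously stationary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chambers import ParameterError
from .simulator import ClosedLoopModel, SimulationResult

__all__ = ["IschemiaParams", "contractility_from_flow", "fixed_point_run"]


@dataclass
class IschemiaParams:
    """Slopes and transitional flows of the contractility-flow relationship.

    k_lad, k_lcx : ischemic-regime slopes (mmHg/ml² per cycle flow)
    Qn_lad, Qn_lcx : transitional cycle flows (ml/cycle)
    Ees_n : non-ischemic maximal elastance plateau (mmHg/ml)
    mult_lad, mult_lcx : slope multipliers (e.g. 10 for the steep-LCX case)
    relax : under-relaxation factor on the per-cycle elastance update
    tol : convergence tolerance on |ΔEes| (mmHg/ml)
    """

    k_lad: float
    k_lcx: float
    Qn_lad: float
    Qn_lcx: float
    Ees_n: float = 3.18
    mult_lad: float = 1.0
    mult_lcx: float = 1.0
    relax: float = 0.5
    tol: float = 1e-3

    def __post_init__(self) -> None:
        if self.k_lad < 0 or self.k_lcx < 0:
            raise ParameterError("slopes must be non-negative")
        if self.Qn_lad <= 0 or self.Qn_lcx <= 0:
            raise ParameterError("transitional flows must be positive")
        if not 0 < self.relax <= 1:
            raise ParameterError(f"relax must be in (0, 1], got {self.relax}")

    @classmethod
    def from_control(cls, sum_q_lad: float, sum_q_lcx: float, Ees_n: float = 3.18, **kw):
        """Derive slopes k = Ees_n/∑Q_n from the control (normal) cycle flows."""
        return cls(
            k_lad=Ees_n / sum_q_lad, k_lcx=Ees_n / sum_q_lcx,
            Qn_lad=sum_q_lad, Qn_lcx=sum_q_lcx, Ees_n=Ees_n, **kw,
        )

    def slope(self, territory: str) -> float:
        if territory == "lad":
            return self.k_lad * self.mult_lad
        if territory == "lcx":
            return self.k_lcx * self.mult_lcx
        raise ValueError(f"unknown territory {territory!r}")


def contractility_from_flow(Q: float, p: IschemiaParams, territory: str) -> float:
    """Piecewise-linear Ees(∑Q), anchored at the transitional point.

    Below the transitional flow Qn the elastance follows the line through
    (Qn, Ees_n) with the (possibly multiplied) ischemic slope, floored at
    zero; at or above Qn it plateaus at Ees_n.
    """
    if Q < 0:
        raise ValueError(f"cycle flow must be >= 0, got {Q}")
    Qn = p.Qn_lad if territory == "lad" else p.Qn_lcx
    if territory not in ("lad", "lcx"):
        raise ValueError(f"unknown territory {territory!r}")
    if Q >= Qn:
        return float(p.Ees_n)
    return float(max(p.Ees_n - p.slope(territory) * (Qn - Q), 0.0))


def fixed_point_run(model: ClosedLoopModel, p: IschemiaParams, y0=None) -> SimulationResult:
    """Run the coupled system with per-cycle contractility feedback.

    After every completed cycle the territory elastances are moved a
    fraction ``relax`` toward the values the contractility-flow relationship
    assigns to that cycle's flows.  Convergence requires both the hemodynamic
    periodicity criterion and |ΔEes| < tol on both territories.
    """
    trace = []

    def update(m: ClosedLoopModel, metrics) -> float:
        target_lad = contractility_from_flow(max(metrics.sum_q_lad, 0.0), p, "lad")
        target_lcx = contractility_from_flow(max(metrics.sum_q_lcx, 0.0), p, "lcx")
        new_lad = m.lad.Ees + p.relax * (target_lad - m.lad.Ees)
        new_lcx = m.lcx.Ees + p.relax * (target_lcx - m.lcx.Ees)
        resid = max(abs(new_lad - m.lad.Ees), abs(new_lcx - m.lcx.Ees))
        m.set_contractility(new_lad, new_lcx)
        trace.append((new_lad, new_lcx))
        return resid / p.tol * model.solver.periodicity_tol  # scale to solver tol

    result = model.run_to_periodic(y0=y0, per_cycle_update=update)
    result.history = [
        {**h, "Ees_lad": trace[i][0], "Ees_lcx": trace[i][1]}
        for i, h in enumerate(result.history)
    ]
    return result
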