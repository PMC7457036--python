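"""Closed systemic loop: four storage compartments and their flow laws.

The loop is LA -> (mitral valve) -> LV -> (aortic valve) -> arterial
compartment -> peripheral resistance -> venous compartment -> LA, with the
two coronary networks drawing from the arterial compartment and draining
into the venous compartment.  There is no pulmonary circulation: venous
return feeds the LA directly.  Units are mmHg, ml, s throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chambers import ParameterError

__all__ = [
    "LoopState",
    "CircParams",
    "valve_flow",
    "linear_flow",
    "compartment_pressure",
    "loop_derivatives",
]


@dataclass
class LoopState:
    """Stored volumes (ml) of the four systemic compartments."""

    V_la: float
    V_lv: float
    V_art: float
    V_ven: float

    def as_array(self) -> np.ndarray:
        return np.array([self.V_la, self.V_lv, self.V_art, self.V_ven], dtype=float)


@dataclass
class CircParams:
    """Resistances (mmHg·s/ml), compliances (ml/mmHg) and resting volumes (ml).

    R_lad and R_lcx are the proximal resistances connecting the arterial
    compartment to the two coronary networks.
    """

    R_ao: float
    R_per: float
    R_ven: float
    R_mv: float
    C_art: float
    C_ven: float
    V_art0: float
    V_ven0: float
    R_lad: float
    R_lcx: float

    def __post_init__(self) -> None:
        for name in ("R_ao", "R_per", "R_ven", "R_mv", "C_art", "C_ven", "R_lad", "R_lcx"):
            v = getattr(self, name)
            if v <= 0:
                raise ParameterError(f"{name} must be > 0, got {v}")

    def replace(self, **kw) -> "CircParams":
        d = self.__dict__.copy()
        d.update(kw)
        return CircParams(**d)


def valve_flow(P_up, P_down, R: float):
    """Unidirectional valve flow: (P_up − P_down)/R when P_up ≥ P_down, else 0."""
    if R <= 0:
        raise ParameterError(f"valve resistance must be > 0, got {R}")
    dp = np.asarray(P_up, dtype=float) - np.asarray(P_down, dtype=float)
    q = np.where(dp >= 0.0, dp / R, 0.0)
    return q if q.ndim else float(q)


def linear_flow(P_up, P_down, R: float):
    """Signed resistive flow (P_up − P_down)/R."""
    if R <= 0:
        raise ParameterError(f"resistance must be > 0, got {R}")
    q = (np.asarray(P_up, dtype=float) - np.asarray(P_down, dtype=float)) / R
    return q if np.ndim(q) else float(q)


def compartment_pressure(V, V0: float, C: float):
    """Linear storage-compartment pressure (V − V0)/C."""
    if C <= 0:
        raise ParameterError(f"compliance must be > 0, got {C}")
    p = (np.asarray(V, dtype=float) - V0) / C
    return p if np.ndim(p) else float(p)


def loop_derivatives(
    q_ven: float,
    q_mv: float,
    q_ao: float,
    q_per: float,
    q_lad_in: float,
    q_lcx_in: float,
    q_lad_out: float,
    q_lcx_out: float,
) -> np.ndarray:
    """Volume rates (dV_LA, dV_LV, dV_art, dV_ven)/dt in ml/s.

    The arterial compartment loses the coronary *inlet* flows while the
    venous compartment gains the *outlet* flows, so that total blood volume
    including the coronary lumen storage is conserved exactly.
    """
    dV_la = q_ven - q_mv
    dV_lv = q_mv - q_ao
    dV_art = q_ao - q_per - q_lad_in - q_lcx_in
    dV_ven = q_per - q_ven + q_lad_out + q_lcx_out
    return np.array([dV_la, dV_lv, dV_art, dV_ven])
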