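"""Packaged default parameter values.

The elastance constants are the published fixed set for the swine
experiments (RA pacing at 100 beats/min); the circulation defaults are
calibration seeds in the range used by lumped-parameter models of a ~50 ml
left ventricle; the morphometry tables define compact, territory-level
effective arterial networks whose total conductance is consistent with the
measured per-cycle coronary flows (see docs/methods.md).
"""

from __future__ import annotations

import pandas as pd

from .chambers import ActivationSchedule, ChamberParams
from .imp import IMPParams
from .systemic import CircParams
from .tree import MorphometrySpec, OrderStats

HEART_RATE = 100.0  # beats/min
PERIOD = 60.0 / HEART_RATE  # s

#: fixed elastance-model constants (per-territory LV values and LA values)
EES_LV = 3.18  # mmHg/ml, per territory (LAD and LCX alike in control)
EES_LA = 1.50
TMAX_LV = 0.200  # s
TMAX_LA = 0.125
A_LV = 12.8  # mmHg
B_LV = 0.015  # 1/ml
A_LA = 0.044
B_LA = 0.049
TAU_LV = 0.04  # s; relaxation constant, a calibration-seed default
TAU_LA = 0.025
V_LV0 = -10.0  # ml; negative ESPVR intercept (seed; per-animal after calibration)
V_LA0 = 3.0
F_LAD = 0.5  # LAD-territory fraction of V_LV

#: atrial activation onset within the cycle (s).  Late enough that the atrial
#: kick straddles the cycle wrap and is terminated by the ventricular pressure
#: rise (PA interval ~0.08 s at 100 bpm), which is what makes end-diastolic
#: filling sensitive to a delayed LV activation.
LA_OFFSET = 0.52


def lv_chamber(Ees: float = EES_LV, V0: float = V_LV0, tau: float = TAU_LV) -> ChamberParams:
    return ChamberParams(Ees=Ees, V0=V0, A=A_LV, B=B_LV, Tmax=TMAX_LV, tau=tau)


def la_chamber() -> ChamberParams:
    return ChamberParams(Ees=EES_LA, V0=V_LA0, A=A_LA, B=B_LA, Tmax=TMAX_LA, tau=TAU_LA)


def default_schedule(**kw) -> ActivationSchedule:
    kw.setdefault("la_offset", LA_OFFSET)
    return ActivationSchedule(T=PERIOD, **kw)


def default_circ() -> CircParams:
    return CircParams(
        R_ao=0.03,
        R_per=5.5,
        R_ven=0.15,
        R_mv=0.08,
        C_art=1.2,
        C_ven=25.0,
        V_art0=300.0,
        V_ven0=2000.0,
        R_lad=1.2,
        R_lcx=2.8,
    )


#: initial stored volumes (ml): a physiological starting point, refined by
#: running to periodic steady state (and by calibration of the preload)
INITIAL_VOLUMES = {"V_la": 80.0, "V_lv": 50.0, "V_art": 402.0, "V_ven": 2300.0}

IMP_DEFAULTS = IMPParams(alpha=0.8, beta=5.0, gamma=20.0)


def _order_table(scale: float) -> dict[int, OrderStats]:
    """Per-order diameter/length tables (cm), scaled by a conductance factor.

    Diameters follow a geometric progression across orders 0-6; ``scale``
    multiplies all diameters to set the territory conductance (used to keep
    reduced trees at the same total conductance as the full default tree).
    """
    base = {
        6: (0.374, 1.20),
        5: (0.274, 0.90),
        4: (0.202, 0.65),
        3: (0.144, 0.45),
        2: (0.104, 0.30),
        1: (0.075, 0.20),
        0: (0.055, 0.12),
    }
    # the passive-curve inflection phi_p tracks the transvascular operating
    # pressure, which falls from ~systolic aortic pressure at the epicardial
    # inlet (order 6) to ~0 at the pre-arteriolar terminals (order 0); a
    # narrow transition (Cp) gives near-full collapse at negative transmural
    # pressure, which is what couples IMP to flow
    table = {}
    for o, (d, ln) in base.items():
        d = d * scale
        table[o] = OrderStats(
            d_min=0.85 * d, d_mean=d, d_max=1.15 * d,
            l_min=0.8 * ln, l_mean=ln, l_max=1.2 * ln,
            phi_p=60.0 * o / 6.0, Cp=4.0,
        )
    return table


def full_tree_spec(seed: int = 1) -> MorphometrySpec:
    """The 400-vessel default territory network (195 bif + 3 trif)."""
    return MorphometrySpec(n_bif=195, n_trif=3, orders=_order_table(1.0),
                           seed=seed, ap_frac=AP_FRAC)


def compact_tree_spec(seed: int = 1) -> MorphometrySpec:
    """A reduced 51-vessel network (24 bif + 1 trif) with the per-order
    diameters scaled up so its total Poiseuille resistance matches the full
    default tree (the scale factor was fixed once from that comparison)."""
    return MorphometrySpec(n_bif=24, n_trif=1, orders=_order_table(COMPACT_SCALE),
                           seed=seed, ap_frac=AP_FRAC)


#: diameter scale of the compact tree; chosen so that the seed-averaged
#: compact.poiseuille_resistance(mu) matches the full default tree's
COMPACT_SCALE = 0.923

#: Ap = AP_FRAC·D_ref, Bp = (1 − AP_FRAC)·D_ref: intramural vessels collapse
#: to ~1/10 of their reference diameter at strongly negative transmural
#: pressure and distend to ~1.8× when fully unloaded
AP_FRAC = 0.90


#: published per-animal measurements (per-cycle coronary flows in ml/cycle,
#: EDV in ml, peak LV pressure in mmHg) and the corresponding published
#: model predictions, used as calibration targets and cross-checks
SWINE_MEASUREMENTS = pd.DataFrame(
    {
        "swine": [1, 2, 3],
        "sum_Q_lad": [18.09, 11.62, 18.61],
        "sum_Q_lcx": [9.38, 8.27, 14.54],
        "LV_EDV": [50.95, 44.18, 53.83],
        "peak_LVP": [107.31, 114.12, 107.21],
    }
).set_index("swine")

SWINE_MODEL_PREDICTIONS = pd.DataFrame(
    {
        "swine": [1, 2, 3],
        "sum_Q_lad": [18.09, 11.71, 18.68],
        "sum_Q_lcx": [9.48, 8.13, 14.33],
        "LV_EDV": [49.61, 42.61, 56.20],
        "peak_LVP": [107.70, 114.60, 107.01],
    }
).set_index("swine")
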