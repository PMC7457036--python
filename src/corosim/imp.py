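"""Intramyocardial pressure (IMP) per coronary territory.

IMP is the extravascular pressure compressing the intramural vessels.  It is
prescribed homogeneous within each territory as a sum of three mechanisms:

* CEP  — cavity-induced extracellular pressure, alpha·P_LV;
* VE   — time-varying elasticity, beta·Ees_territory·e_territory(t), with
  the activation evaluated on the territory's own (possibly delayed) clock;
* SIP  — shortening-induced intracellular pressure, gamma·(1 − SSR), where
  SSR is the stretch ratio V_LV/EDV (1 at end diastole, < 1 in ejection).

Defaults alpha = 0.8, beta = 5 (ml), gamma = 20 mmHg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chambers import ParameterError
from .network import StateError

__all__ = ["IMPParams", "IMPComponents", "stretch_ratio", "imp", "imp_constraint_check"]


@dataclass
class IMPParams:
    """Weights of the three IMP mechanisms."""

    alpha: float = 0.8  # CEP weight, dimensionless in [0, 1]
    beta: float = 5.0  # VE weight (ml): beta*Ees*e is in mmHg
    gamma: float = 20.0  # SIP scale (mmHg)

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ParameterError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.beta < 0:
            raise ParameterError(f"beta must be >= 0, got {self.beta}")
        if self.gamma < 0:
            raise ParameterError(f"gamma must be >= 0, got {self.gamma}")


@dataclass
class IMPComponents:
    """CEP/VE/SIP decomposition (mmHg) at one instant or over a waveform."""

    CEP: float | np.ndarray
    VE: float | np.ndarray
    SIP: float | np.ndarray
    SSR: float | np.ndarray

    @property
    def total(self):
        return self.CEP + self.VE + self.SIP


def stretch_ratio(V_lv, EDV):
    """Myocardial stretch ratio SSR = V_LV / EDV."""
    if np.any(np.asarray(EDV) <= 0):
        raise StateError(f"EDV must be > 0, got {EDV}")
    r = np.asarray(V_lv, dtype=float) / EDV
    return r if np.ndim(r) else float(r)


def imp(P_lv, e_territory, Ees_territory, SSR, p: IMPParams) -> IMPComponents:
    """Territory IMP decomposition: CEP + VE + SIP."""
    CEP = p.alpha * np.asarray(P_lv, dtype=float)
    VE = p.beta * Ees_territory * np.asarray(e_territory, dtype=float)
    SIP = p.gamma * (1.0 - np.asarray(SSR, dtype=float))
    if np.ndim(CEP) == 0:
        CEP, VE, SIP = float(CEP), float(VE), float(SIP)
        ssr = float(SSR)
    else:
        ssr = np.asarray(SSR, dtype=float)
    return IMPComponents(CEP=CEP, VE=VE, SIP=SIP, SSR=ssr)


def imp_constraint_check(components: IMPComponents, limit: float = 0.30) -> dict:
    """Report component fractions over one steady-state cycle.

    Returns peak SIP / peak IMP, (peak SIP + peak VE)/peak IMP, the
    cycle-mean fraction of each component, and whether the peak
    (SIP + VE) share exceeds the prescribed limit (default 30% of IMP),
    the experimental bound on how much IMP may exceed the cavity pressure.
    """
    total = np.asarray(components.total, dtype=float)
    peak = float(np.max(total))
    if peak <= 0:
        raise ValueError("IMP waveform has non-positive peak")
    peak_sip = float(np.max(components.SIP))
    peak_ve = float(np.max(components.VE))
    means = {k: float(np.mean(getattr(components, k))) for k in ("CEP", "VE", "SIP")}
    mean_total = sum(means.values())
    mean_frac = {k: (v / mean_total if mean_total else np.nan) for k, v in means.items()}
    ratio = (peak_sip + peak_ve) / peak
    return {
        "peak_sip_fraction": peak_sip / peak,
        "peak_sip_plus_ve_fraction": ratio,
        "mean_fractions": mean_frac,
        "violates_limit": bool(ratio >= limit),
        "limit": limit,
    }
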