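"""Time-varying elastance chambers.

Each cardiac chamber is described by a linear end-systolic pressure-volume
relationship (ESPVR, slope ``Ees``, volume intercept ``V0``), an exponential
end-diastolic pressure-volume relationship (EDPVR, scale ``A``, exponent
``B``), and a normalized activation function ``e(t)`` in [0, 1] that blends
the two.  The left ventricle is split into two compartments perfused by the
LAD (septum) and LCX (free wall) coronary territories; mechanical
dyssynchrony is modelled as a lag of the LCX territory's activation clock.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ChamberParams",
    "ActivationSchedule",
    "LVPartition",
    "ParameterError",
    "activation",
    "end_systolic_pressure",
    "end_diastolic_pressure",
    "atrial_pressure",
    "lv_pressure",
    "sdi_to_delay",
]

#: floor on the activation-weighted denominator of the two-compartment
#: pressure law; below it the chamber is in deep diastole and the EDPVR holds
ELASTANCE_FLOOR = 1e-9


class ParameterError(ValueError):
    """Raised when a physical parameter violates its admissible range."""


@dataclass
class ChamberParams:
    """Elastance-model constants of one chamber (or LV territory).

    Ees : maximal chamber elastance (mmHg/ml)
    V0  : volume at zero end-systolic pressure (ml; may be negative)
    A   : EDPVR scale (mmHg)
    B   : EDPVR exponent (1/ml)
    Tmax: time to end systole (s)
    tau : relaxation time constant (s)
    """

    Ees: float
    V0: float
    A: float
    B: float
    Tmax: float
    tau: float

    def __post_init__(self) -> None:
        if self.Ees <= 0:
            raise ParameterError(f"Ees must be > 0, got {self.Ees}")
        if self.B <= 0:
            raise ParameterError(f"B must be > 0, got {self.B}")
        if self.Tmax <= 0:
            raise ParameterError(f"Tmax must be > 0, got {self.Tmax}")
        if self.tau <= 0:
            raise ParameterError(f"tau must be > 0, got {self.tau}")

    def replace(self, **kw) -> "ChamberParams":
        d = self.__dict__.copy()
        d.update(kw)
        return ChamberParams(**d)


@dataclass
class ActivationSchedule:
    """Cycle timing: period, territory delays, and LA phase offset.

    T        : cardiac period (s)
    dt_lcx   : LCX activation delay Δt (s); Δt = T·SDI
    dt_bar   : additional delay Δt̄ of both territories' IMP elastance
               clocks relative to the LV pressure (s)
    SDI      : systolic dyssynchrony index (fraction of the cycle)
    la_offset: LA activation phase offset (s); the default places the end of
               atrial contraction at ventricular activation onset
    """

    T: float = 0.6
    dt_lcx: float = 0.0
    dt_bar: float = 0.0
    SDI: float = 0.0
    la_offset: float | None = None

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ParameterError(f"T must be > 0, got {self.T}")
        if self.SDI:
            if not 0 <= self.SDI < 1:
                raise ParameterError(f"SDI must be in [0, 1), got {self.SDI}")
            self.dt_lcx = sdi_to_delay(self.SDI, self.T)
        if not 0 <= self.dt_lcx < self.T:
            raise ParameterError(f"dt_lcx must be in [0, T), got {self.dt_lcx}")
        if not 0 <= self.dt_bar < self.T:
            raise ParameterError(f"dt_bar must be in [0, T), got {self.dt_bar}")

    def la_clock(self, t, la_params: ChamberParams):
        """Time on the LA activation clock.

        By default atrial systole (duration 1.5·Tmax,LA) finishes exactly at
        t = 0 mod T, i.e. at the onset of ventricular activation.
        """
        off = self.la_offset
        if off is None:
            off = self.T - 1.5 * la_params.Tmax
        return np.mod(np.asarray(t) - off, self.T)


@dataclass
class LVPartition:
    """Split of the LV cavity volume into LAD and LCX compartments."""

    F: float
    V_lv_lad: float = 0.0
    V_lv_lcx: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.F < 1:
            raise ParameterError(f"F must be in (0, 1), got {self.F}")


def sdi_to_delay(SDI: float, T: float) -> float:
    """Activation delay Δt = T·SDI of the late (LCX) territory."""
    if not 0 <= SDI < 1:
        raise ParameterError(f"SDI must be in [0, 1), got {SDI}")
    if T <= 0:
        raise ParameterError(f"T must be > 0, got {T}")
    return T * SDI


def activation(t, params: ChamberParams, T: float | None = None):
    """Normalized activation e(t) in [0, 1].

    Half-sine rise/fall to end systole at ``Tmax`` followed by exponential
    relaxation with time constant ``tau`` from 1.5·Tmax.  ``t`` is reduced
    modulo the cardiac period ``T`` (no reduction if T is None) so that
    delayed clocks wrap and periodic steady state is well defined.
    """
    t = np.asarray(t, dtype=float)
    if T is not None:
        t = np.mod(t, T)
    Tm, tau = params.Tmax, params.tau
    rise = 0.5 * (np.sin(np.pi * t / Tm - np.pi / 2.0) + 1.0)
    relax = 0.5 * np.exp(-(t - 1.5 * Tm) / tau)
    e = np.where(t < 1.5 * Tm, rise, relax)
    return e if e.ndim else float(e)


def end_systolic_pressure(V, params: ChamberParams):
    """Linear ESPVR: Ees·(V − V0). May be negative below V0."""
    return params.Ees * (np.asarray(V, dtype=float) - params.V0)


def end_diastolic_pressure(V, params: ChamberParams):
    """Exponential EDPVR: A·(exp(B·(V − V0)) − 1)."""
    return params.A * (np.exp(params.B * (np.asarray(V, dtype=float) - params.V0)) - 1.0)


def atrial_pressure(V_la, t, params: ChamberParams, sched: ActivationSchedule):
    """LA pressure: e·Pes + (1 − e)·Ped on the LA activation clock."""
    e = activation(sched.la_clock(t, params), params, sched.T)
    return e * end_systolic_pressure(V_la, params) + (1.0 - e) * end_diastolic_pressure(
        V_la, params
    )


def territory_activations(t, lad: ChamberParams, lcx: ChamberParams, sched: ActivationSchedule):
    """(e_LAD, e_LCX) driving the LV pressure; the LCX lags by Δt."""
    e1 = activation(t, lad, sched.T)
    e2 = activation(np.asarray(t) - sched.dt_lcx, lcx, sched.T)
    return e1, e2


def lv_pressure(
    V_lv,
    t,
    lad: ChamberParams,
    lcx: ChamberParams,
    F: float,
    sched: ActivationSchedule,
    Ped_value=None,
):
    """LV cavity pressure of the two-compartment ventricle.

    Both compartments share the cavity pressure P; compartment volumes
    V_j = F_j·V0 + F_j·(P − (1−e_j)·Ped)/(e_j·E_j) sum to V_LV, which gives

        P = [ (V_LV−V0)·E1 e1 E2 e2 + Ped·(F(1−e1)E2 e2 + (1−F)(1−e2)E1 e1) ]
            / (F·E2 e2 + (1−F)·E1 e1)

    with e1 = e(t) (LAD) and e2 = e(t−Δt) (LCX, lagging).  Ped is the EDPVR
    evaluated at the total V_LV with LV parameters.  When both activation
    weights fall below a numerical floor the chamber is fully relaxed and
    P = Ped.
    """
    e1, e2 = territory_activations(t, lad, lcx, sched)
    return two_compartment_pressure(V_lv, e1, e2, lad, lcx, F, Ped_value)


def two_compartment_pressure(
    V_lv,
    e1,
    e2,
    lad: ChamberParams,
    lcx: ChamberParams,
    F: float,
    Ped_value=None,
):
    """Two-compartment pressure law given the territory activations.

    ``lad`` carries the LV-wide V0/A/B (both territories share the cavity's
    ESPVR intercept and EDPVR); only Ees differs per territory.
    """
    if not 0 < F < 1:
        raise ParameterError(f"F must be in (0, 1), got {F}")
    V_lv = np.asarray(V_lv, dtype=float)
    e1 = np.asarray(e1, dtype=float)
    e2 = np.asarray(e2, dtype=float)
    w1 = lad.Ees * e1
    w2 = lcx.Ees * e2
    Ped = end_diastolic_pressure(V_lv, lad) if Ped_value is None else Ped_value
    den = F * w2 + (1.0 - F) * w1
    num = (V_lv - lad.V0) * w1 * w2 + Ped * (F * (1.0 - e1) * w2 + (1.0 - F) * (1.0 - e2) * w1)
    safe = den > ELASTANCE_FLOOR
    out = np.where(safe, num / np.where(safe, den, 1.0), Ped)
    return out if out.ndim else float(out)
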