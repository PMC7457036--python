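# Methods

This note records the governing equations and numerical choices. Symbols:
pressures in mmHg, volumes in ml, time in s, flows in ml/s, resistances in
mmHg·s/ml, diameters and lengths in cm.

## 1. Chambers and activation

Each chamber (LA, and the two LV compartments) carries an end-systolic
pressure–volume relation `Pes(V) = Ees (V − V0)` and an exponential
end-diastolic relation `Ped(V) = P0 (exp(λ(V − V0d)) − 1)`.

Activation is the half-sine/exponential elastance shape

```
e(t') = ½ [sin(π t'/Tmax − π/2) + 1]          0 ≤ t' < 1.5 Tmax
e(t') = ½ exp(−(t' − 1.5 Tmax)/τ)             t' ≥ 1.5 Tmax
```

with `t'` the time since that compartment's activation onset, wrapped on the
cycle period `T`. The LA clock leads the ventricular clock by a fixed offset
(`la_offset`) so the atrial kick lands at end-diastole.

**Two-compartment LV.** The LAD-perfused fraction `F` and LCX fraction
`1 − F` share one cavity volume `V`. With `w_i = Ees_i · e_i`, cavity
pressure is the compliance-weighted mix

```
P = [ (V − V0) w1 w2 + Ped(V) (F (1 − e1) w2 + (1 − F)(1 − e2) w1) ]
    / [ F w2 + (1 − F) w1 ]
```

which reduces exactly to the single-chamber law `P = e·Pes + (1−e)·Ped` when
the two compartments share parameters and clocks (unit-tested). When the
denominator underflows (both compartments fully relaxed) `P = Ped(V)`.

**Dyssynchrony.** The LCX compartment's activation onset is delayed by
`Δt = T · SDI`. A second, independent delay `dt_bar` lags the *IMP generator*
(both territories' elastance clocks and the cavity-induced component) behind
the cavity mechanics.

## 2. Systemic loop

States: `V_la`, `V_lv`, `V_art`, `V_ven`. Valves are ideal diodes with series
resistances (`R_mv`, `R_av`); the arterial Windkessel has compliance `C_art`
and peripheral resistance `R_per` into a venous reservoir (`C_ven`, `R_ven`)
that refills the atrium. Total blood volume is conserved: the sum of all
chamber, arterial, venous, and coronary lumen volumes is constant to the
integrator tolerance (tested to < 1e−3 ml over 10 cycles).

## 3. Coronary trees and networks

`corosim.tree` generates a seeded, order-structured branching tree (orders
6 → 0 from the inlet) with per-order mean diameters/lengths and lognormal
scatter. A "compact" variant prunes to a fixed vessel budget and rescales
lengths by a calibrated factor so the seed-averaged total resistance matches
the full tree.

Each segment's diameter follows the sigmoidal passive law in transmural
pressure `ΔP = P_lumen − P_ext`:

```
D(ΔP) = 2 [ Bp + (Ap − Bp)/π · (π/2 + arctan((ΔP − φp)/Cp)) ]
```

with `Ap = a·D_ref`, `Bp = (1 − a)·D_ref`, `a = ap_frac`, and a per-order
pressure offset `φp` graded linearly from 0 mmHg at order 0 to `φ6` at
order 6 (so large epicardial vessels sit below their inflection at diastolic
transmural pressure and distend systolically, while the microcirculation is
compressed by IMP). Segment resistance is Poiseuille, split in half around
the lumen-volume node: `R/2 = 64 µ L / (π D⁴)` with µ = 0.03 Poise converted
to mmHg·s.

The network lumps the tree into: proximal resistance `R_proximal` from the
aortic root to the inlet node, the inlet segment, and all terminal segments
draining to a common venous pressure through a shared junction. Lumen
volumes are ODE states; nodal pressures solve the algebraic conductance
balance exactly (closed-form for this topology; verified against a dense
nodal oracle to 1e−8). The external pressure on every segment of a territory
is that territory's IMP.

## 4. Intramyocardial pressure

For each territory,

```
IMP = α · CEP + β · VE + γ · SIP
CEP = P_cavity evaluated with the (possibly dt_bar-lagged) activation clocks
VE  = Ees_territory · e_territory(own clock)
SIP = 1 − SSR,   SSR = V_lv / EDV_prev
```

with α = 0.8, β = 5 mmHg per (mmHg/ml), γ = 20 mmHg. `imp_constraint_check`
reports the cycle-mean fractional contribution of each component; under
control conditions CEP dominates (~3/4), SIP is the next largest, VE small.

## 5. Contractility–flow feedback (ischemia)

From each animal's control run the per-territory operating point is
`(Qn, Ees_n)`; the measured depression slope is `k = Ees_n / Qn` (per-animal,
per-territory). Regional contractility under reduced flow is the line
anchored at the operating point:

```
Ees(Q) = Ees_n                                   Q ≥ Qn
Ees(Q) = max(Ees_n − m·k · (Qn − Q), 0)          Q < Qn
```

where `m` is a slope multiplier (1 for the measured line; a 10× multiplier
is used as a severe-sensitivity variant). For `m = 1` this is identical to
the through-origin line `k·Q`; anchoring is what makes the multiplier steepen
the response below `Qn` rather than merely shifting the plateau edge.
`fixed_point_run` iterates: simulate a cycle, read territory flows, update
`Ees` with under-relaxation (0.5), repeat to a relative tolerance of 1e−3.

## 6. Numerics

- Stiff integration with LSODA (`scipy`), one cardiac cycle per call;
  a numba-compiled right-hand side and observables pass is used when
  available and is equality-tested against the pure-NumPy reference at 1e−10.
- Periodic steady state: cycles repeat until either the key cycle metrics
  (EDV, peak LVP, both cycle flows) or the full state vector change by less
  than `periodicity_tol` between consecutive cycles.  The cycle map relaxes
  along one slow mode (arterial/venous volume redistribution, contraction
  ratio ≈0.96/cycle), so plain iteration would leave a bias ≈25·tol; when
  successive state increments are parallel and contracting, an Aitken
  extrapolation jumps along that mode (guarded against non-physical or
  non-finite states, and disabled while a per-cycle feedback hook is
  mutating the model).  Cold starts reach tol = 3e−5 in ~11 cycles.
- Coronary lumen volumes are initialized at the static equilibrium for the
  starting boundary pressures (damped fixed point on transmural pressure).
- All stochasticity (tree generation) flows from a single integer seed.

## 7. Calibration

Per animal, a bounded least-squares fit (relative errors) of six parameters
— `R_lad`, `R_lcx`, `R_per`, arterial compliance `C_art`, initial venous
volume (preload), and the ESPVR intercept `V_LV0` — to four targets:
cycle-total LAD and LCX flows, LV end-diastolic volume, and peak LV
pressure. Tree constants and IMP weights are never fitted. Resistances and
the compliance are fitted on a log scale, and every parameter is affinely
mapped to the unit box so the trust region and the finite-difference step
share one scale. Evaluations warm-start from the periodic state of the best
point seen so far (a deterministic, locally smooth objective), with
requested initial-volume changes injected as volume deltas so total blood
volume is honored; non-convergent points return a large residual. With six
parameters against four targets the fit is underdetermined, so a small
Tikhonov anchor (weight 1e−3 per unit-box deviation) resolves the null
space toward the nominal starting values without influencing the measured
targets.

`calibrate_refined` wraps this in the production recipe: a joint pass
(relative step 0.02), a finer restart from the best point (0.004) when any
target error exceeds 0.2 %, both run at a loosened integrator tolerance
(cycle metrics agree with the tight setting to ~1e−5 relative), and a final
verification simulation at the model's own solver settings, whose errors
are the ones reported.

## 8. Scenario battery (acceptance pipeline)

For each of three animals: calibrate the control model; run MD at SDI 10%
and 15% (warm-started from control); run MD at SDI 10% with `dt_bar = 0.07 s`;
run MD+ischemia at SDI 10% with slope multipliers 1 and 10 (fixed-point
feedback). Reported quantities are percent changes in cycle-total territory
flows versus the relevant baseline, cycle-mean IMP component fractions,
calibration errors, and the peak-`dP/dt` reduction under the 10× slope.
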