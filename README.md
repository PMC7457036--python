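# corosim

A closed-loop lumped-parameter simulator of the coupled heart–systemic–coronary
circulation, built to study how left-ventricular mechanical dyssynchrony and
flow-dependent contractility redistribute myocardial perfusion between the
LAD and LCX territories.

The model couples:

- a **two-compartment left ventricle** — LAD- and LCX-perfused walls, each
  with its own time-varying-elastance activation clock, combined into a single
  chamber pressure through a compliance-weighted mixing law;
- a **systemic loop** — left atrium, aortic/arterial Windkessel, peripheral
  resistance, and a venous reservoir closing the circuit through the mitral
  valve;
- two **nonlinear coronary networks** — seeded, order-structured vessel trees
  whose segment diameters follow a sigmoidal pressure–diameter law, lumped
  into per-vessel RCR elements and loaded externally by intramyocardial
  pressure (IMP);
- an **IMP model** composed of cavity-induced extracellular pressure (CEP),
  a varying-elastance fiber-stress component (VE), and a shortening-induced
  component (SIP);
- an optional **contractility–flow feedback** that depresses the regional
  end-systolic elastance when that territory's cycle flow falls below its
  normal operating point, iterated per cycle to a fixed point.

## Quick start

```python
from corosim import defaults
from corosim.network import CoronaryNetwork
from corosim.simulator import ClosedLoopModel
from corosim.tree import generate_tree

lad = generate_tree(defaults.compact_tree_spec(seed=1))
lcx = generate_tree(defaults.compact_tree_spec(seed=2))
circ = defaults.default_circ()
model = ClosedLoopModel(
    defaults.lv_chamber(), defaults.lv_chamber(), defaults.la_chamber(),
    defaults.F_LAD, circ, defaults.IMP_DEFAULTS, defaults.default_schedule(),
    CoronaryNetwork(lad, circ.R_lad), CoronaryNetwork(lcx, circ.R_lcx),
)
result = model.run_to_periodic(volumes=dict(defaults.INITIAL_VOLUMES))
print(result.metrics)
```

## Command line

```bash
corosim run config.json --out waveforms.csv      # simulate one scenario
corosim calibrate config.json --targets t.json   # fit per-animal parameters
corosim sweep config.json --sdi 0 0.05 0.10 0.15 # dyssynchrony sweep
corosim make-fixtures --seed 1 --out fixtures/   # small text fixtures
corosim check config.json                        # validate a config file
```

Configuration files are JSON; `corosim.config.RunConfig` documents every
block and default.

## Scenarios

- **CON** — synchronous activation of both LV compartments.
- **MD** — mechanical dyssynchrony: the LCX compartment's activation is
  delayed by `T · SDI` (systolic dyssynchrony index); optionally the whole
  IMP generator of both territories lags the cavity by `dt_bar`.
- **MD_IS** — dyssynchrony plus ischemia feedback: regional `Ees` follows the
  measured contractility–flow line below the normal flow, solved by
  under-relaxed per-cycle fixed-point iteration
  (`corosim.ischemia.fixed_point_run`).

## Validation

`scripts/acceptance.py` regenerates the headline validation numbers from
scratch (three calibrated animals; control, dyssynchrony, and
dyssynchrony-with-ischemia runs):

```bash
python scripts/acceptance.py --seed 1 --out acceptance.json
```

The test suite (`pytest`) covers unit oracles for every module plus
`tests/test_acceptance.py`, which asserts one criterion per validation
quantity. See `docs/methods.md` for the governing equations and numerical
choices.
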