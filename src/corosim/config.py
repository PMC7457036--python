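"""Run configuration: schema, validation, defaults, fixtures, waveform IO.

A run is described by one YAML file with named blocks (``chambers``,
``circulation``, ``imp``, ``trees``, ``scenario``, ``ischemia``,
``calibration``, ``solver``).  Every field has a packaged default, so an
empty file is a valid control-scenario configuration.  Validation reuses
each module's own invariants and reports errors as ``block.field: reason``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import defaults
from .chambers import ActivationSchedule, ChamberParams, ParameterError
from .imp import IMPParams
from .ischemia import IschemiaParams
from .simulator import ScenarioConfig, SolverOptions
from .systemic import CircParams
from .tree import generate_tree, read_tree, write_tree

__all__ = [
    "RunConfig",
    "ConfigError",
    "load_config",
    "make_fixtures",
    "write_waveforms",
    "read_waveforms",
]


class ConfigError(ValueError):
    """Schema violation; message names the offending block and field."""


#: block name -> {field: default} (scalar fields only; trees handled apart)
_SCHEMA = {
    "chambers": {
        "Ees_lv": defaults.EES_LV, "V_lv0": defaults.V_LV0,
        "A_lv": defaults.A_LV, "B_lv": defaults.B_LV,
        "Tmax_lv": defaults.TMAX_LV, "tau_lv": defaults.TAU_LV,
        "Ees_la": defaults.EES_LA, "V_la0": defaults.V_LA0,
        "A_la": defaults.A_LA, "B_la": defaults.B_LA,
        "Tmax_la": defaults.TMAX_LA, "tau_la": defaults.TAU_LA,
        "F_lad": defaults.F_LAD, "T": defaults.PERIOD,
        "la_offset": defaults.LA_OFFSET,
    },
    "circulation": {
        "R_ao": None, "R_per": None, "R_ven": None, "R_mv": None,
        "C_art": None, "C_ven": None, "V_art0": None, "V_ven0": None,
        "R_lad": None, "R_lcx": None,
        "V_la_init": defaults.INITIAL_VOLUMES["V_la"],
        "V_lv_init": defaults.INITIAL_VOLUMES["V_lv"],
        "V_art_init": defaults.INITIAL_VOLUMES["V_art"],
        "V_ven_init": defaults.INITIAL_VOLUMES["V_ven"],
    },
    "imp": {"alpha": 0.8, "beta": 5.0, "gamma": 20.0},
    "trees": {
        "lad_path": None, "lcx_path": None,
        "size": "compact",  # "compact" | "full"
        "seed_lad": 1, "seed_lcx": 2,
    },
    "scenario": {"mode": "CON", "sdi": 0.0, "dt_bar": 0.0},
    "ischemia": {
        "mult_lad": 1.0, "mult_lcx": 1.0, "relax": 0.5, "tol": 1e-3,
        "Ees_n": defaults.EES_LV,
    },
    "calibration": {
        "swine": 1, "max_nfev": 80, "xtol": 1e-8, "ftol": 1e-10,
        "diff_step": 0.02,
    },
    "solver": {
        "rtol": 1e-6, "atol": 1e-8, "output_dt": 1e-3, "max_cycles": 50,
        "periodicity_tol": 1e-3, "use_fast": True, "seed": 1,
    },
}


@dataclass
class RunConfig:
    """Validated run description; block dicts carry resolved values."""

    chambers: dict = field(default_factory=dict)
    circulation: dict = field(default_factory=dict)
    imp: dict = field(default_factory=dict)
    trees: dict = field(default_factory=dict)
    scenario: dict = field(default_factory=dict)
    ischemia: dict = field(default_factory=dict)
    calibration: dict = field(default_factory=dict)
    solver: dict = field(default_factory=dict)

    # -- factories building module objects ----------------------------------
    def lv_chamber(self) -> ChamberParams:
        c = self.chambers
        return ChamberParams(Ees=c["Ees_lv"], V0=c["V_lv0"], A=c["A_lv"],
                             B=c["B_lv"], Tmax=c["Tmax_lv"], tau=c["tau_lv"])

    def la_chamber(self) -> ChamberParams:
        c = self.chambers
        return ChamberParams(Ees=c["Ees_la"], V0=c["V_la0"], A=c["A_la"],
                             B=c["B_la"], Tmax=c["Tmax_la"], tau=c["tau_la"])

    def schedule(self) -> ActivationSchedule:
        c, s = self.chambers, self.scenario
        return ActivationSchedule(T=c["T"], SDI=s["sdi"], dt_bar=s["dt_bar"],
                                  la_offset=c["la_offset"])

    def circ_params(self) -> CircParams:
        base = defaults.default_circ()
        kw = {k: v for k, v in self.circulation.items()
              if v is not None and hasattr(base, k)}
        return base.replace(**kw)

    def imp_params(self) -> IMPParams:
        return IMPParams(**self.imp)

    def initial_volumes(self) -> dict:
        c = self.circulation
        return {"V_la": c["V_la_init"], "V_lv": c["V_lv_init"],
                "V_art": c["V_art_init"], "V_ven": c["V_ven_init"]}

    def trees_pair(self):
        """Return (lad_tree, lcx_tree), reading files or generating."""
        t = self.trees
        spec_of = (defaults.full_tree_spec if t["size"] == "full"
                   else defaults.compact_tree_spec)
        lad = (read_tree(t["lad_path"]) if t["lad_path"]
               else generate_tree(spec_of(seed=t["seed_lad"])))
        lcx = (read_tree(t["lcx_path"]) if t["lcx_path"]
               else generate_tree(spec_of(seed=t["seed_lcx"])))
        return lad, lcx

    def scenario_config(self) -> ScenarioConfig:
        s = self.scenario
        ischemia = None
        if s["mode"] == "MD_IS":
            row = defaults.SWINE_MEASUREMENTS.loc[self.calibration["swine"]]
            ischemia = self.ischemia_params(row.sum_Q_lad, row.sum_Q_lcx)
        return ScenarioConfig(mode=s["mode"], sched=self.schedule(),
                              ischemia=ischemia)

    def solver_options(self) -> SolverOptions:
        s = {k: v for k, v in self.solver.items() if k != "seed"}
        return SolverOptions(**s)

    def build_model(self):
        """Assemble the closed-loop model this configuration describes."""
        from .network import CoronaryNetwork
        from .simulator import ClosedLoopModel

        circ = self.circ_params()
        lad_tree, lcx_tree = self.trees_pair()
        return ClosedLoopModel(
            self.lv_chamber(), self.lv_chamber(), self.la_chamber(),
            self.chambers["F_lad"], circ, self.imp_params(), self.schedule(),
            CoronaryNetwork(lad_tree, circ.R_lad),
            CoronaryNetwork(lcx_tree, circ.R_lcx),
            solver=self.solver_options(),
        )

    def ischemia_params(self, sum_q_lad: float, sum_q_lcx: float) -> IschemiaParams:
        i = self.ischemia
        return IschemiaParams.from_control(
            sum_q_lad, sum_q_lcx, Ees_n=i["Ees_n"],
            mult_lad=i["mult_lad"], mult_lcx=i["mult_lcx"],
            relax=i["relax"], tol=i["tol"],
        )


_POSITIVE = {
    "chambers": {"Ees_lv", "A_lv", "B_lv", "Tmax_lv", "tau_lv", "Ees_la",
                 "A_la", "B_la", "Tmax_la", "tau_la", "T"},
    "circulation": {"R_ao", "R_per", "R_ven", "R_mv", "C_art", "C_ven",
                    "R_lad", "R_lcx", "V_la_init", "V_lv_init", "V_art_init",
                    "V_ven_init"},
    "imp": {"beta", "gamma"},
    "solver": {"rtol", "atol", "output_dt", "periodicity_tol"},
}


def _validate(cfg: RunConfig) -> None:
    for block, fields in _SCHEMA.items():
        values = getattr(cfg, block)
        for name in values:
            if name not in fields:
                raise ConfigError(f"{block}.{name}: unknown field")
        for name, v in values.items():
            if v is None:
                continue
            if name in _POSITIVE.get(block, ()) and not (
                isinstance(v, (int, float)) and v > 0
            ):
                raise ConfigError(f"{block}.{name}: must be a positive number")
    s = cfg.scenario
    if s["mode"] not in ("CON", "MD", "MD_IS"):
        raise ConfigError("scenario.mode: must be one of CON, MD, MD_IS")
    if not 0 <= s["sdi"] < 1:
        raise ConfigError("scenario.sdi: must be in [0, 1)")
    if s["dt_bar"] < 0:
        raise ConfigError("scenario.dt_bar: must be >= 0")
    if s["mode"] == "CON" and (s["sdi"] or s["dt_bar"]):
        raise ConfigError("scenario.sdi: control scenario requires sdi = dt_bar = 0")
    if not 0 < cfg.chambers["F_lad"] < 1:
        raise ConfigError("chambers.F_lad: must be in (0, 1)")
    if not 0 <= cfg.imp["alpha"] <= 1:
        raise ConfigError("imp.alpha: must be in [0, 1]")
    if cfg.trees["size"] not in ("compact", "full"):
        raise ConfigError("trees.size: must be 'compact' or 'full'")
    for key in ("seed_lad", "seed_lcx"):
        v = cfg.trees[key]
        if not (isinstance(v, int) and 0 <= v < 2**31):
            raise ConfigError(f"trees.{key}: must be an integer in [0, 2^31)")
    for key in ("lad_path", "lcx_path"):
        p = cfg.trees[key]
        if p is not None and not os.path.exists(p):
            raise ConfigError(f"trees.{key}: file not found: {p}")
    if cfg.calibration["swine"] not in (1, 2, 3):
        raise ConfigError("calibration.swine: must be 1, 2 or 3")
    if not (isinstance(cfg.solver["seed"], int) and 0 <= cfg.solver["seed"] < 2**31):
        raise ConfigError("solver.seed: must be an integer in [0, 2^31)")
    if not (isinstance(cfg.solver["max_cycles"], int) and cfg.solver["max_cycles"] > 0):
        raise ConfigError("solver.max_cycles: must be a positive integer")
    # build the typed objects so module invariants run too
    try:
        cfg.lv_chamber(); cfg.la_chamber(); cfg.schedule()
        cfg.circ_params(); cfg.imp_params(); cfg.solver_options()
    except (ParameterError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Load and validate a YAML run configuration.

    Missing blocks/fields are filled with packaged defaults; an empty (or
    absent) file yields the full default control configuration.  ``overrides``
    is a {block: {field: value}} mapping applied after the file (CLI flags).
    """
    raw = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError("top level: expected a mapping of blocks")
    for block in raw:
        if block not in _SCHEMA:
            raise ConfigError(f"{block}: unknown block")
        if not isinstance(raw[block], dict):
            raise ConfigError(f"{block}: expected a mapping of fields")
    merged = {}
    for block, fields in _SCHEMA.items():
        merged[block] = dict(fields)
        merged[block].update(raw.get(block, {}))
        for name, value in (overrides or {}).get(block, {}).items():
            if value is not None:
                merged[block][name] = value
    cfg = RunConfig(**merged)
    _validate(cfg)
    return cfg


def make_fixtures(out_dir, seed: int = 1) -> dict:
    """Write the packaged fixtures: default config, three-animal targets
    table, and a generated LAD/LCX tree pair.  Returns {name: path}."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {}

    cfg_path = os.path.join(out_dir, "default_config.yaml")
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(
            {b: {k: v for k, v in f.items()} for b, f in _SCHEMA.items()},
            fh, sort_keys=False,
        )
    paths["config"] = cfg_path

    targets_path = os.path.join(out_dir, "swine_targets.tsv")
    defaults.SWINE_MEASUREMENTS.to_csv(targets_path, sep="\t")
    paths["targets"] = targets_path

    for name, s in (("lad", seed), ("lcx", seed + 1)):
        tree = generate_tree(defaults.compact_tree_spec(seed=s))
        p = os.path.join(out_dir, f"tree_{name}.tsv")
        write_tree(tree, p)
        paths[f"tree_{name}"] = p
    return paths


def write_waveforms(waveforms: dict, path) -> None:
    """Write a waveform dict (name -> equal-length arrays) as TSV."""
    names = list(waveforms)
    if names:
        n = len(waveforms[names[0]])
        for k in names:
            if len(waveforms[k]) != n:
                raise ValueError(
                    f"waveform {k!r} has length {len(waveforms[k])}, expected {n}"
                )
    with open(path, "w") as fh:
        fh.write("\t".join(names) + "\n")
        if names:
            data = np.column_stack([np.asarray(waveforms[k]) for k in names])
            np.savetxt(fh, data, fmt="%.10g", delimiter="\t")


def read_waveforms(path) -> dict:
    """Read back a waveform TSV into {name: array}."""
    with open(path) as fh:
        header = fh.readline().strip("\n")
        names = header.split("\t") if header else []
        data = np.loadtxt(fh, ndmin=2) if names else np.empty((0, 0))
    if data.size == 0:
        return {k: np.empty(0) for k in names}
    return {k: data[:, i] for i, k in enumerate(names)}
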