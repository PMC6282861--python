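"""Scenario configuration schema and reproducible runs.

A scenario is one YAML file describing the population structure, the
assumed effects, the design (error rates, stages, boundary family,
selection rule, power definition) and the simulation settings.  Unknown
keys are rejected so published configs stay self-describing; every run
echoes its resolved configuration and a manifest (seed, package
version) next to its outputs.
"""

from __future__ import annotations

import json
import pathlib
from dataclasses import dataclass
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assess import assessment_table
from .multistage import (Boundaries, MultistageDesign,
                         required_stagewise_sample_size)
from .populations import EffectConfig, PopulationSet
from .simulate import SimulationConfig, simulate_trials
from .single_stage import DesignSpec, SingleStageDesign, required_sample_size

__all__ = ["ScenarioConfig", "load_config", "run_scenario", "write_report",
           "ConfigError"]


class ConfigError(ValueError):
    """Configuration schema violation, reported with its field path."""


_SCHEMA: dict[str, dict[str, Any]] = {
    "population": {"prevalences": list, "members": list},
    "effects": {"thetas": list, "sigma": (int, float)},
    "design": {"alpha": (int, float), "beta": (int, float), "stages": int,
               "selection_rule": str, "power_definition": str,
               "target": str, "lower_bound": (int, float, str),
               "binding": bool, "boundary_family": str},
    "simulation": {"n_reps": int, "seed": int, "mode": str},
    "sweep": {"start": (int, float), "stop": (int, float),
              "step": (int, float)},
}

_DEFAULTS = {
    "design": {"alpha": 0.025, "beta": 0.2, "stages": 1,
               "selection_rule": "max",
               "power_definition": "select-target-and-reject",
               "target": None, "lower_bound": 0.0, "binding": True,
               "boundary_family": "obf"},
    "simulation": {"n_reps": 0, "seed": 0, "mode": "sufficient"},
}


def _check_section(name: str, section: Any, allowed: dict) -> dict:
    if not isinstance(section, dict):
        raise ConfigError(f"{name}: expected a mapping")
    for key, value in section.items():
        if key not in allowed:
            raise ConfigError(f"{name}.{key}: unknown key")
        expected = allowed[key]
        if value is not None and not isinstance(value, expected):
            raise ConfigError(f"{name}.{key}: expected {expected}, "
                              f"got {type(value).__name__}")
    return section


@dataclass(frozen=True)
class ScenarioConfig:
    """Validated scenario: typed domain objects plus the raw mapping."""

    population_set: PopulationSet
    effect_config: EffectConfig
    design: DesignSpec
    lower_bound: float
    binding: bool
    selection_rule: str
    n_reps: int
    seed: int
    mode: str
    sweep: dict | None
    raw: dict


def load_config(source) -> ScenarioConfig:
    """Parse and validate a scenario from a path, stream, or mapping."""
    if isinstance(source, dict):
        raw = source
    else:
        text = (pathlib.Path(source).read_text()
                if isinstance(source, (str, pathlib.Path)) else source.read())
        raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ConfigError("top level: expected a mapping")
    for key in raw:
        if key not in _SCHEMA:
            raise ConfigError(f"{key}: unknown section")
    for required in ("population", "effects"):
        if required not in raw:
            raise ConfigError(f"{required}: section is required")

    pop_raw = _check_section("population", raw["population"],
                             _SCHEMA["population"])
    eff_raw = _check_section("effects", raw["effects"], _SCHEMA["effects"])
    des_raw = dict(_DEFAULTS["design"])
    des_raw.update(_check_section("design", raw.get("design", {}),
                                  _SCHEMA["design"]))
    sim_raw = dict(_DEFAULTS["simulation"])
    sim_raw.update(_check_section("simulation", raw.get("simulation", {}),
                                  _SCHEMA["simulation"]))
    sweep = raw.get("sweep")
    if sweep is not None:
        _check_section("sweep", sweep, _SCHEMA["sweep"])

    members = pop_raw.get("members")
    try:
        ps = PopulationSet(tuple(pop_raw["prevalences"]),
                           tuple(frozenset(m) for m in members) if members
                           else ())
        eff = EffectConfig(tuple(eff_raw["thetas"]),
                           float(eff_raw.get("sigma", 1.0)))
    except (KeyError, ValueError) as e:
        raise ConfigError(str(e)) from e
    if len(eff.thetas) != ps.n_subgroups:
        raise ConfigError("effects.thetas: one effect per subgroup required")

    target = des_raw["target"]
    target_idx = ps.member_index(target) if target is not None else None
    if des_raw["power_definition"] == "select-target-and-reject" \
            and target_idx is None:
        target_idx = 0  # default: the first-listed (highest-priority) candidate
    lower = des_raw["lower_bound"]
    lower = -np.inf if lower in ("-inf", None) else float(lower)
    try:
        spec = DesignSpec(ps, alpha=float(des_raw["alpha"]),
                          beta=float(des_raw["beta"]),
                          stages=int(des_raw["stages"]),
                          selection_rule=des_raw["selection_rule"],
                          power_definition=des_raw["power_definition"],
                          target=target_idx)
    except ValueError as e:
        raise ConfigError(f"design: {e}") from e
    return ScenarioConfig(ps, eff, spec, lower, bool(des_raw["binding"]),
                          des_raw["selection_rule"], int(sim_raw["n_reps"]),
                          int(sim_raw["seed"]), sim_raw["mode"], sweep, raw)


def _calibrate(cfg: ScenarioConfig) -> SingleStageDesign | MultistageDesign:
    if cfg.design.stages == 1:
        return required_sample_size(cfg.design, cfg.effect_config)
    return required_stagewise_sample_size(cfg.design, cfg.effect_config,
                                          lower_bound=cfg.lower_bound,
                                          binding=cfg.binding)


def run_scenario(cfg: ScenarioConfig, outdir) -> dict:
    """Calibrate, optionally simulate and assess; write all outputs.

    With ``simulation.n_reps == 0`` only the design (boundaries and
    sample sizes) is produced.  Returns the result bundle that was
    written: design summary, and, when simulated, the records path and
    assessment table.
    """
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    design = _calibrate(cfg)
    if isinstance(design, SingleStageDesign):
        boundaries = Boundaries((design.critical_value,),
                                (design.critical_value,))
        stage_n: tuple[int, ...] = (design.n_full,)
    else:
        boundaries = design.boundaries
        stage_n = design.stage_n
    summary = {
        "stage_n": list(stage_n),
        "total_n": int(sum(stage_n)),
        "upper_bounds": list(boundaries.upper),
        "lower_bounds": [float(c) for c in boundaries.lower],
        "achieved_power": design.achieved_power,
    }
    bundle: dict = {"design": summary}

    if cfg.n_reps > 0:
        sim = SimulationConfig(cfg.population_set, cfg.effect_config,
                               boundaries, stage_n,
                               selection_rule=cfg.selection_rule,
                               n_reps=cfg.n_reps, seed=cfg.seed,
                               mode="sufficient" if cfg.mode == "sufficient"
                               else "patient")
        records = simulate_trials(sim)
        table = assessment_table(records, cfg.population_set,
                                 cfg.effect_config)
        bundle["assessment"] = table
        write_report({"assessment": table}, outdir)
        # core columns first, per-population estimate columns after
        records.to_csv(outdir / "records.csv", index=False)
        bundle["records_path"] = str(outdir / "records.csv")

    with open(outdir / "design.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    manifest = {"seed": cfg.seed, "n_reps": cfg.n_reps,
                "enrichsel_version": __version__, "config": cfg.raw}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    with open(outdir / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(cfg.raw, fh, sort_keys=True)
    return bundle


def write_report(results: dict, outdir) -> list[pathlib.Path]:
    """Write result tables as CSV files; missing cells become ``NA``."""
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, table in results.items():
        if isinstance(table, pd.DataFrame):
            path = outdir / f"{name}.csv"
            table.to_csv(path, index=False, na_rep="NA", float_format="%.6g")
            written.append(path)
    return written
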