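"""YAML configuration loading/saving for the modelling pipeline.

The configuration file collects every base-case value in one place:

.. code-block:: yaml

    model:
      starting_age: 50
      cycle_length: 6          # months
      horizon: 600             # months
      discount_rate: 0.03
      lr_share: 0.33
      lr_to_dm_hr: 1.5
      lr_mortality_hr: 0.35
      t_obs: 60
      t_conv: 108
    economics:
      utility_rfs: 0.87
      ...
      treatment_cost_per_cycle: {treatment: 42000.0}
    arms: {treatment: treatment, comparator: observation}
    curves: {file: curves.csv, at_risk_file: at_risk.csv}
    life_table: {file: life_table.csv}
    projection: {OS: 0.8975, RFS: 0.9202, DMFS: 0.8827}   # optional
    hazard_ratios: [...]                                   # optional Bucher inputs
    scenarios:
      - {name: undiscounted, overrides: {discount_rate: 0.0}}

File paths are resolved relative to the config file's directory.
"""

from __future__ import annotations

import dataclasses
import os

import yaml

from .cohort import ModelConfig
from .curves import read_at_risk, read_curves
from .economics import EconomicsConfig
from .indirect import hazard_ratios_from_config
from .scenarios import AnalysisInputs, ScenarioSpec, fits_from_curves
from .survival import read_life_table


def load_raw(path: str) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _resolve(base_dir: str, p: str) -> str:
    return p if os.path.isabs(p) else os.path.join(base_dir, p)


def model_config_from(raw: dict) -> ModelConfig:
    return ModelConfig(**raw.get("model", {}))


def economics_config_from(raw: dict) -> EconomicsConfig:
    return EconomicsConfig(**raw["economics"])


def scenarios_from(raw: dict) -> list[ScenarioSpec]:
    return [
        ScenarioSpec(name=s["name"], overrides=s.get("overrides", {}))
        for s in raw.get("scenarios", [])
    ]


def load_inputs(path: str) -> AnalysisInputs:
    """Load a config file and build fitted AnalysisInputs from its data files."""
    raw = load_raw(path)
    base_dir = os.path.dirname(os.path.abspath(path))
    config = model_config_from(raw)
    econ = economics_config_from(raw)
    curves = read_curves(_resolve(base_dir, raw["curves"]["file"]))
    at_risk = read_at_risk(_resolve(base_dir, raw["curves"]["at_risk_file"]))
    life_table = read_life_table(_resolve(base_dir, raw["life_table"]["file"]))
    arms = raw.get("arms", {"treatment": "treatment", "comparator": "observation"})
    fits = fits_from_curves(curves, at_risk)
    projection = raw.get("projection")
    return AnalysisInputs(
        config=config,
        econ=econ,
        fits=fits,
        life_table=life_table,
        treatment_arm=arms["treatment"],
        comparator_arm=arms["comparator"],
        projection_hrs={k: float(v) for k, v in projection.items()} if projection else None,
    )


def load_hazard_ratios(path: str):
    raw = load_raw(path)
    return hazard_ratios_from_config(raw.get("hazard_ratios", []))


def dump_config(
    config: ModelConfig,
    econ: EconomicsConfig,
    path: str,
    curves_file: str = "curves.csv",
    at_risk_file: str = "at_risk.csv",
    life_table_file: str = "life_table.csv",
    arms: dict | None = None,
    projection: dict | None = None,
    scenarios: list[ScenarioSpec] | None = None,
) -> None:
    raw = {
        "model": dataclasses.asdict(config),
        "economics": dataclasses.asdict(econ),
        "arms": arms or {"treatment": "treatment", "comparator": "observation"},
        "curves": {"file": curves_file, "at_risk_file": at_risk_file},
        "life_table": {"file": life_table_file},
    }
    if projection:
        raw["projection"] = projection
    if scenarios:
        raw["scenarios"] = [{"name": s.name, "overrides": s.overrides} for s in scenarios]
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)
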