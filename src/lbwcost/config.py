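"""Run configuration: strict YAML/JSON parsing and round-tripping.

A :class:`RunConfig` bundles every model's parameters plus the draw
count, root seed and output directory.  Parsing is strict: unknown keys
anywhere in the file raise, so typos never silently fall back to
defaults.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml

from .daly import DALYParameters
from .health_system import CohortSpec, HealthSystemInputs
from .household import HouseholdCostConfig, WeightGainTable
from .psa import DistributionSpec
from .synthetic import SyntheticConfig

__all__ = ["DalyCohortConfig", "RunConfig", "load_config"]


@dataclass(frozen=True)
class DalyCohortConfig:
    """Death/disability event counts entering the DALY calculation.

    The expected death counts per 1000 live births are taken directly as
    inputs (8 of 10 VLBW; 17 of 110 other LBW), not derived from the
    case-fatality rates.  Disability episodes accrue to all LBW newborns
    by default ("survivors" restricts them to those not dying).
    """

    vlbw_deaths: float = 8.0
    lbw_deaths: float = 17.0
    vlbw_death_age: float = 0.0
    lbw_death_age: float = 0.0
    yld_recipients: str = "all_lbw"  # or "survivors"

    def __post_init__(self) -> None:
        if self.vlbw_deaths < 0 or self.lbw_deaths < 0:
            raise ValueError("death counts must be >= 0")
        if self.vlbw_death_age < 0 or self.lbw_death_age < 0:
            raise ValueError("death ages must be >= 0")
        if self.yld_recipients not in ("all_lbw", "survivors"):
            raise ValueError("yld_recipients must be 'all_lbw' or 'survivors'")


@dataclass(frozen=True)
class RunConfig:
    """Full pipeline configuration."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    health_inputs: HealthSystemInputs = field(default_factory=HealthSystemInputs)
    household: HouseholdCostConfig = field(default_factory=HouseholdCostConfig)
    daly: DALYParameters = field(default_factory=DALYParameters)
    daly_cohort: DalyCohortConfig = field(default_factory=DalyCohortConfig)
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    gains: WeightGainTable = field(default_factory=WeightGainTable)
    n_births_population: float = 3322.0
    draws: int = 10_000
    seed: int = 0
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if self.draws < 1:
            raise ValueError("draws must be >= 1")
        if self.n_births_population <= 0:
            raise ValueError("n_births_population must be > 0")


_SECTIONS = {
    "cohort": CohortSpec,
    "health_inputs": HealthSystemInputs,
    "household": HouseholdCostConfig,
    "daly": DALYParameters,
    "daly_cohort": DalyCohortConfig,
    "synthetic": SyntheticConfig,
}


def _to_plain(obj: Any) -> Any:
    if isinstance(obj, DistributionSpec):
        return obj.to_dict()
    if isinstance(obj, WeightGainTable):
        return {"bands": [list(b) for b in obj.bands], "variability": obj.variability}
    if dataclasses.is_dataclass(obj):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in fields(obj)}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def _section_from_dict(cls: type, d: dict, path: str) -> Any:
    if not isinstance(d, dict):
        raise ValueError(f"{path}: expected a mapping")
    known = {f.name: f for f in fields(cls)}
    extra = set(d) - set(known)
    if extra:
        raise ValueError(f"{path}: unknown keys {sorted(extra)}")
    kwargs = {}
    for key, value in d.items():
        f = known[key]
        if isinstance(value, dict) and "kind" in value and "DistributionSpec" in str(f.type):
            kwargs[key] = DistributionSpec.from_dict(value)
        else:
            kwargs[key] = value
    return cls(**kwargs)


def run_config_to_dict(cfg: RunConfig) -> dict:
    return _to_plain(cfg)


def run_config_from_dict(d: dict) -> RunConfig:
    if not isinstance(d, dict):
        raise ValueError("run config must be a mapping")
    known = {f.name for f in fields(RunConfig)}
    extra = set(d) - known
    if extra:
        raise ValueError(f"unknown config keys {sorted(extra)}")
    kwargs: dict[str, Any] = {}
    for key, value in d.items():
        if key in _SECTIONS:
            kwargs[key] = _section_from_dict(_SECTIONS[key], value, key)
        elif key == "gains":
            extra_g = set(value) - {"bands", "variability"}
            if extra_g:
                raise ValueError(f"gains: unknown keys {sorted(extra_g)}")
            kwargs[key] = WeightGainTable(
                bands=tuple(tuple(b) for b in value.get("bands", WeightGainTable().bands)),
                variability=value.get("variability", 0.25),
            )
        else:
            kwargs[key] = value
    return RunConfig(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML or JSON run configuration (format auto-detected)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if data is None:
        data = {}
    return run_config_from_dict(data)


def save_config(cfg: RunConfig, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = run_config_to_dict(cfg)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    return path
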