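"""Run configuration: YAML-backed, schema-checked, with genotype presets.

Scenario presets encode the genotype panel the analyses compare:
wild type (one designated crossover per pair, stage-graded kinetics),
break-initiation mutants (rare spontaneous lesions, persistently dynamic
SC), crossover-maturation mutants (no foci), a break-reduced mutant, the
kinase mutant without focus-triggered enrichment, and a translocation
heterozygote in which a third of the genome is non-homologously synapsed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any, Dict, Optional

import yaml

from .frap import AnalysisConfig
from .render import ImagingParams
from .synthetic import (
    ConfigurationError,
    FLAT_STAGE_KINETICS,
    GenotypeParams,
    GonadSpec,
    WT_STAGE_KINETICS,
)

__all__ = [
    "RunConfig",
    "BleachConfig",
    "CohortConfig",
    "SCENARIOS",
    "scenario_genotype",
    "load_config",
    "dump_config",
    "config_hash",
]


def _scenarios() -> Dict[str, GenotypeParams]:
    return {
        "wt": GenotypeParams(
            label="wt", designated_co_per_pair=True, break_rate_lambda=0.0,
            enrichment_active=True, stage_kinetics=dict(WT_STAGE_KINETICS),
        ),
        "spo11": GenotypeParams(
            label="spo11", break_rate_lambda=0.2, enrichment_active=True,
            stage_kinetics=dict(FLAT_STAGE_KINETICS),
        ),
        "cosa1": GenotypeParams(
            label="cosa1", break_rate_lambda=0.0, enrichment_active=False,
            stage_kinetics=dict(FLAT_STAGE_KINETICS),
        ),
        "dsb2": GenotypeParams(
            label="dsb2", break_rate_lambda=2.0, enrichment_active=True,
            stage_kinetics=dict(WT_STAGE_KINETICS),
        ),
        "plk2": GenotypeParams(
            label="plk2", designated_co_per_pair=True, enrichment_active=False,
            stage_kinetics=dict(FLAT_STAGE_KINETICS),
        ),
        "plk2-dsb2": GenotypeParams(
            label="plk2-dsb2", break_rate_lambda=2.0, enrichment_active=False,
            stage_kinetics=dict(FLAT_STAGE_KINETICS),
        ),
        "szt1-spo11": GenotypeParams(
            label="szt1-spo11", break_rate_lambda=0.3,
            heterosynapsis_fraction_h=0.33, enrichment_active=True,
            stage_kinetics=dict(FLAT_STAGE_KINETICS),
        ),
        # irradiated break-initiation mutant: comparison cohort for the
        # translocation heterozygote (same lesion rate, full homology)
        "spo11-ir": GenotypeParams(
            label="spo11-ir", break_rate_lambda=0.3, enrichment_active=True,
            stage_kinetics=dict(FLAT_STAGE_KINETICS),
        ),
    }


SCENARIOS = _scenarios()


def scenario_genotype(name: str) -> GenotypeParams:
    try:
        return SCENARIOS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown scenario '{name}'; choose from {sorted(SCENARIOS)}"
        ) from None


@dataclasses.dataclass(frozen=True)
class BleachConfig:
    mode: str = "zstack"
    survival_s: float = 0.25
    fraction_min: float = 0.3  # bleached share of nuclear content
    fraction_max: float = 0.5
    depth_sigma_um: float = 0.5

    def validate(self) -> None:
        if not 0 <= self.survival_s <= 1:
            raise ConfigurationError("survival_s must be in [0, 1]")
        if not 0 < self.fraction_min <= self.fraction_max < 1:
            raise ConfigurationError("bleach fraction range must be inside (0, 1)")


@dataclasses.dataclass(frozen=True)
class CohortConfig:
    """Problem sizes for the simulated cohorts."""

    frap_n_per_stage: int = 20
    distribution_n_rendered: int = 20
    break_cohort_n: int = 2000

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) < 1:
                raise ConfigurationError(f"{f.name} must be >= 1")


@dataclasses.dataclass(frozen=True)
class RunConfig:
    seed: int = 1
    scenario: str = "wt"
    out_dir: str = "results/run"
    log_level: str = "INFO"
    gonad: GonadSpec = dataclasses.field(default_factory=GonadSpec)
    genotype: Optional[GenotypeParams] = None  # None: use the scenario preset
    imaging: ImagingParams = dataclasses.field(default_factory=ImagingParams)
    bleach: BleachConfig = dataclasses.field(default_factory=BleachConfig)
    analysis: AnalysisConfig = dataclasses.field(default_factory=AnalysisConfig)
    cohorts: CohortConfig = dataclasses.field(default_factory=CohortConfig)

    def resolved_genotype(self) -> GenotypeParams:
        return self.genotype if self.genotype is not None else scenario_genotype(
            self.scenario
        )

    def validate(self) -> "RunConfig":
        self.gonad.validate()
        self.resolved_genotype().validate()
        self.imaging.validate()
        self.bleach.validate()
        self.analysis.validate()
        self.cohorts.validate()
        return self


_NESTED = {
    "gonad": GonadSpec,
    "genotype": GenotypeParams,
    "imaging": ImagingParams,
    "bleach": BleachConfig,
    "analysis": AnalysisConfig,
    "cohorts": CohortConfig,
}


def _build_dataclass(cls, data: Dict[str, Any], path: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = sorted(set(data) - names)
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) {unknown} in config section '{path or 'top level'}'"
        )
    kwargs = {}
    for key, value in data.items():
        if isinstance(value, dict) and key in _NESTED:
            kwargs[key] = _build_dataclass(_NESTED[key], value, f"{path}{key}.")
        elif key == "stage_boundaries" and isinstance(value, (list, tuple)):
            kwargs[key] = tuple(value)
        elif key == "total_length_range_um" and isinstance(value, (list, tuple)):
            kwargs[key] = tuple(value)
        elif key == "stage_kinetics" and isinstance(value, dict):
            kwargs[key] = {s: tuple(fk) for s, fk in value.items()}
        else:
            kwargs[key] = value
    return cls(**kwargs)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration; defaults fill gaps."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"config file not found: {p}")
    data = yaml.safe_load(p.read_text()) or {}
    if not isinstance(data, dict):
        raise ConfigurationError("config root must be a mapping")
    cfg = _build_dataclass(RunConfig, data, "")
    return cfg.validate()


def _to_plain(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, list):
        return [_to_plain(v) for v in obj]
    return obj


def dump_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_plain(cfg), sort_keys=True))


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash identifying a configuration."""
    canon = json.dumps(_to_plain(cfg), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]
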