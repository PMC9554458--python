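"""Schema-validated run configuration (YAML/JSON) for the CLI pipeline."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .model import DosingRegimen, MODES
from .pkpd import PKPDCriteria
from .population import PopulationSpec
from .synthetic import SyntheticStudySpec

__all__ = [
    "ConfigError",
    "RunConfig",
    "load_config",
    "config_hash",
]


class ConfigError(ValueError):
    """Configuration schema violation with path-level messages."""


class _Base(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SolverConfig(_Base):
    mode: Literal["mass_conserving", "as_printed"] = "mass_conserving"
    method: str = "expm"
    dt: float = Field(0.05, gt=0)
    rtol: float = Field(1e-8, gt=0)
    atol: float = Field(1e-10, gt=0)


class PopulationConfig(_Base):
    label: Literal["preterm", "term"] = "preterm"
    n: int = Field(1000, ge=1)
    vd_policy: Literal["fixed", "sampled"] = "fixed"
    volume_units: Literal["mL", "L/kg"] = "mL"
    cv_map: dict[str, float] | None = None

    def spec(self, seed: int) -> PopulationSpec:
        kwargs = {}
        if self.cv_map is not None:
            kwargs["cv_map"] = self.cv_map
        return PopulationSpec(
            label=self.label, n=self.n, seed=seed, vd_policy=self.vd_policy,
            volume_units=self.volume_units, **kwargs,
        )


class RegimenConfig(_Base):
    name: str
    dose_per_kg: float = Field(gt=0)
    interval: float = Field(gt=0)
    infusion_duration: float = Field(0.5, gt=0)
    n_doses: int = Field(1, ge=1)

    @model_validator(mode="after")
    def _duration_inside_interval(self):
        if self.infusion_duration >= self.interval:
            raise ValueError("infusion_duration must be smaller than interval")
        return self

    def regimen(self) -> DosingRegimen:
        return DosingRegimen(
            dose_per_kg=self.dose_per_kg,
            interval=self.interval,
            infusion_duration=self.infusion_duration,
            n_doses=self.n_doses,
        )


class CriteriaConfig(_Base):
    cmax_mic_ratio: float = Field(8.0, gt=0)
    t_above_mic_percent: float = Field(60.0, gt=0)
    cmin_toxic: float = Field(2.0, gt=0)
    cmax_toxic: float = Field(25.0, gt=0)
    pta_effective: float = Field(90.0, gt=0)
    pta_safe: float = Field(10.0, gt=0)

    def criteria(self) -> PKPDCriteria:
        return PKPDCriteria(**self.model_dump())


class MicGridConfig(_Base):
    start: float = Field(0.05, gt=0)
    stop: float = Field(2.0, gt=0)
    step: float = Field(0.05, gt=0)

    def grid(self):
        import numpy as np

        if self.stop < self.start:
            raise ConfigError("mic_grid.stop must be >= mic_grid.start")
        return np.round(np.arange(self.start, self.stop + 1e-9, self.step), 10)


class SyntheticConfig(_Base):
    group: Literal["both", "preterm", "term"] = "both"
    n_preterm: int = Field(31, ge=1)
    n_term: int = Field(16, ge=1)
    dose_policy: Literal["fixed", "realistic"] = "fixed"
    dose_fixed: float = Field(6.0, gt=0)
    residual_cv: float = Field(0.10, ge=0)
    lloq: float = Field(0.3, gt=0)
    n_missing: int = Field(3, ge=0)
    vd_policy: Literal["fixed", "sampled"] = "fixed"

    def spec(self, seed: int) -> SyntheticStudySpec:
        base = SyntheticStudySpec(
            dose_policy=self.dose_policy, dose_fixed=self.dose_fixed,
            residual_cv=self.residual_cv, lloq=self.lloq,
            n_missing=self.n_missing, vd_policy=self.vd_policy, seed=seed,
        )
        if self.group == "preterm":
            return base.preterm_only(n=self.n_preterm)
        if self.group == "term":
            return base.term_only(n=self.n_term)
        from dataclasses import replace

        from .synthetic import PRETERM_GROUP, TERM_GROUP, _with_n

        return replace(
            base, groups=(_with_n(PRETERM_GROUP, self.n_preterm), _with_n(TERM_GROUP, self.n_term))
        )


class EstimationConfig(_Base):
    group: str | None = None
    initial_gfr: float = Field(1.31, gt=0)
    initial_omega: float = Field(0.385, ge=0)
    initial_sigma: float = Field(0.10, gt=0)
    max_iter: int = Field(30, ge=0)
    tol: float = Field(1e-3, gt=0)
    estimate_sigma: bool = True


class ValidationConfig(_Base):
    times: list[float] = Field(default_factory=lambda: [2.0, 24.0])
    standard_dose_per_kg: float = Field(6.0, gt=0)
    n_simulated: int = Field(1000, ge=100)
    dose_normalized_metrics: bool = False  # raw pairs by default


class RunConfig(_Base):
    """Top-level run configuration; blocks are subcommand-specific."""

    seed: int = Field(12345, ge=0)
    log_level: str = "INFO"
    solver: SolverConfig = Field(default_factory=SolverConfig)
    populations: list[PopulationConfig] = Field(default_factory=lambda: [PopulationConfig()])
    regimens: list[RegimenConfig] = Field(
        default_factory=lambda: [
            RegimenConfig(name="conventional-q24h", dose_per_kg=4.0, interval=24.0),
            RegimenConfig(name="extended-q48h", dose_per_kg=6.0, interval=48.0),
        ]
    )
    criteria: CriteriaConfig = Field(default_factory=CriteriaConfig)
    mic_grid: MicGridConfig = Field(default_factory=MicGridConfig)
    reference_mic: float = Field(1.0, gt=0)
    synthetic: SyntheticConfig = Field(default_factory=SyntheticConfig)
    estimation: EstimationConfig = Field(default_factory=EstimationConfig)
    validation: ValidationConfig = Field(default_factory=ValidationConfig)

    @model_validator(mode="after")
    def _non_empty(self):
        if not self.regimens:
            raise ValueError("at least one regimen must be configured")
        if not self.populations:
            raise ValueError("at least one population must be configured")
        return self


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML/JSON config; None yields the defaults."""
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    try:
        payload = yaml.safe_load(text) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"could not parse {path}: {exc}") from exc
    try:
        return RunConfig.model_validate(payload)
    except ValidationError as exc:
        lines = [
            f"  {'.'.join(str(p) for p in err['loc'])}: {err['msg']}" for err in exc.errors()
        ]
        raise ConfigError(f"invalid configuration {path}:\n" + "\n".join(lines)) from exc


def config_hash(config: RunConfig) -> str:
    """Stable sha256 of the resolved configuration."""
    canonical = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()
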