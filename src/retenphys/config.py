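"""Experiment configuration: schema-validated JSON via pydantic.

One :class:`ExperimentConfig` describes a full run: reactor geometry, the
maintenance model, noise levels, which strain preset to emulate, and where
artifacts live.  Validation errors are re-raised as :class:`ConfigError`
with the offending field path in the message.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional, Union

from pydantic import BaseModel, Field, ValidationError, model_validator

from .errors import ConfigError
from .retentostat import (
    DEFAULT_SAMPLING_HOURS,
    ConstantMaintenance,
    MaintenanceModel,
    RetentostatConfig,
    SaturatingMaintenance,
)
from .stoichiometry import MolarConstants
from .synthetic import NoiseSpec

__all__ = ["ExperimentConfig", "load_config", "config_hash"]


class RetentostatSection(BaseModel):
    reactor_volume_L: float = Field(1.4, gt=0)
    mixing_volume_L: float = Field(1.2, gt=0)
    dilution_rate: float = Field(0.025, gt=0)
    chemostat_feed_g_L: float = Field(10.0, gt=0)
    retentostat_feed_g_L: float = Field(5.0, gt=0)
    death_rate: float = Field(0.0, ge=0)
    sampling_hours: list[float] = Field(default_factory=lambda: list(DEFAULT_SAMPLING_HOURS))
    instant_feed_switch: bool = False
    sample_volume_L: float = Field(0.0, ge=0)

    def build(self) -> RetentostatConfig:
        return RetentostatConfig(
            reactor_volume_L=self.reactor_volume_L,
            mixing_volume_L=self.mixing_volume_L,
            dilution_rate=self.dilution_rate,
            chemostat_feed_g_L=self.chemostat_feed_g_L,
            retentostat_feed_g_L=self.retentostat_feed_g_L,
            death_rate=self.death_rate,
            sampling_hours=tuple(self.sampling_hours),
            instant_feed_switch=self.instant_feed_switch,
            sample_volume_L=self.sample_volume_L,
        )


class MaintenanceSection(BaseModel):
    kind: Literal["constant", "saturating"] = "constant"
    m_s: float = Field(0.0142, ge=0)
    m_min: Optional[float] = Field(None, ge=0)
    m_max: Optional[float] = Field(None, ge=0)
    k_mu: Optional[float] = Field(None, gt=0)

    @model_validator(mode="after")
    def _check_kind(self) -> "MaintenanceSection":
        if self.kind == "saturating":
            missing = [
                f for f in ("m_min", "m_max", "k_mu") if getattr(self, f) is None
            ]
            if missing:
                raise ValueError(
                    f"saturating maintenance requires fields {missing}"
                )
            if self.m_min > self.m_max:
                raise ValueError("m_min must not exceed m_max")
        return self

    def build(self) -> MaintenanceModel:
        if self.kind == "constant":
            return ConstantMaintenance(self.m_s)
        return SaturatingMaintenance(self.m_min, self.m_max, self.k_mu)


class MolarSection(BaseModel):
    glucose_molar_mass: float = Field(180.156, gt=0)
    o2_molar_mass: float = Field(31.998, gt=0)
    co2_molar_mass: float = Field(44.009, gt=0)
    carbon_molar_mass: float = Field(12.011, gt=0)

    def build(self) -> MolarConstants:
        return MolarConstants(
            glucose_molar_mass=self.glucose_molar_mass,
            o2_molar_mass=self.o2_molar_mass,
            co2_molar_mass=self.co2_molar_mass,
            carbon_molar_mass=self.carbon_molar_mass,
        )


class NoiseSection(BaseModel):
    biomass_cv: float = Field(0.02, ge=0)
    feed_cv: float = Field(0.005, ge=0)

    def build(self, seed: Optional[int]) -> NoiseSpec:
        if self.biomass_cv == 0 and self.feed_cv == 0:
            return NoiseSpec(0.0, 0.0, None)
        return NoiseSpec(self.biomass_cv, self.feed_cv, seed)


class ExperimentConfig(BaseModel):
    """Top-level experiment description (see module docstring)."""

    preset: str = "wildtype-adaptive"
    y_xs_max: float = Field(0.545, gt=0)
    retentostat: RetentostatSection = Field(default_factory=RetentostatSection)
    maintenance: MaintenanceSection = Field(default_factory=MaintenanceSection)
    molar_constants: MolarSection = Field(default_factory=MolarSection)
    noise: NoiseSection = Field(default_factory=NoiseSection)
    chemostat_dilution_rates: list[float] = Field(default_factory=lambda: [0.025, 0.1])
    chemostat_feed_g_L: float = Field(7.5, gt=0)
    replicates: int = Field(2, ge=1)
    window: int = Field(5, ge=2)
    prepend_chemostat_pairs: bool = True
    seed: int = 0
    outdir: str = "results"
    chemostat_csv: Optional[str] = None
    samples_csv: Optional[str] = None

    def canonical_json(self) -> str:
        """Stable JSON of the experiment description.

        Artifact locations (outdir) are excluded: the hash identifies the
        experiment, not where its files land.
        """
        data = self.model_dump(exclude={"outdir"})
        return json.dumps(data, sort_keys=True, separators=(",", ":"))


def config_hash(config: ExperimentConfig) -> str:
    """Short stable hash identifying a configuration (provenance headers)."""
    return hashlib.sha256(config.canonical_json().encode()).hexdigest()[:12]


def load_config(source: Union[str, Path, dict, None]) -> ExperimentConfig:
    """Build an ExperimentConfig from a JSON file, a dict, or defaults (None)."""
    try:
        if source is None:
            return ExperimentConfig()
        if isinstance(source, dict):
            return ExperimentConfig.model_validate(source)
        data = json.loads(Path(source).read_text())
        return ExperimentConfig.model_validate(data)
    except ValidationError as exc:
        locs = "; ".join(
            ".".join(str(p) for p in err["loc"]) + ": " + err["msg"]
            for err in exc.errors()
        )
        raise ConfigError(f"invalid experiment configuration ({locs})") from exc
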