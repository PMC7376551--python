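"""Synthetic chemostat and retentostat datasets with known ground truth.

Every estimator in the package is exercised against data generated here, so
the generator encodes the study conditions it emulates: duplicate
glucose-limited chemostats at dilution rates 0.025 and 0.1 1/h, and 23-day
retentostat runs (two replicates) started from a D = 0.025 1/h chemostat
through a 1.2 L mixing vessel with a 10 -> 5 g/L feed shift.  Measurement
error is multiplicative log-normal on biomass dry weight (2% CV by default,
the scale of the replicate scatter such cultures show) and on the feed
assay (0.5% CV); the log-normal is mean-one so noisy data are unbiased
around the noise-free value.

Two strain presets carry the package's reference physiology: a wild-type
-like strain (m_S 0.0142 g/(g·h), Y_X/S_max 0.545 g/g) and a respiration-
impaired strain with weaker energy coupling (0.0241, 0.485).  Each exists
in a constant-maintenance form and an "adaptive" form whose maintenance
relaxes 2.75-fold at near-zero growth (m_min = m_max/2.75, half-saturation
k_mu = 0.005 1/h).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .chemostat import ChemostatRecord, gas_from_rates
from .errors import WashoutError
from .inference import BiomassSample
from .retentostat import (
    ConstantMaintenance,
    MaintenanceModel,
    RetentostatConfig,
    SaturatingMaintenance,
    Trajectory,
    simulate,
)
from .stoichiometry import DEFAULT_COMPOSITION, DEFAULT_MOLAR

__all__ = [
    "NoiseSpec",
    "ScenarioPreset",
    "PRESETS",
    "preset",
    "generate_chemostat_dataset",
    "generate_retentostat_dataset",
]

MAINTENANCE_RELAXATION_FOLD = 2.75
MAINTENANCE_K_MU = 0.005  # 1/h


@dataclass(frozen=True)
class NoiseSpec:
    """Multiplicative measurement noise. A seed is mandatory for nonzero CVs."""

    biomass_cv: float = 0.02
    feed_cv: float = 0.005
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.biomass_cv < 0 or self.feed_cv < 0:
            raise ValueError("CVs must be >= 0")
        if (self.biomass_cv > 0 or self.feed_cv > 0) and self.seed is None:
            raise ValueError("a seed is required when any CV is nonzero")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Mean-one multiplicative log-normal factors with the given CV."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


@dataclass(frozen=True)
class ScenarioPreset:
    """Ground-truth physiology plus reactor configuration for one strain."""

    name: str
    maintenance: MaintenanceModel
    y_xs_max: float
    config: RetentostatConfig = field(default_factory=RetentostatConfig)
    mu_max: float = 0.37  # batch-observed ceiling, used for washout checks

    def chemostat_m_s(self) -> float:
        """Maintenance the chemostat regime expresses (m_max for adaptive)."""
        m = self.maintenance
        return m.m_s if isinstance(m, ConstantMaintenance) else m.m_max


def _saturating(m_max: float) -> SaturatingMaintenance:
    return SaturatingMaintenance(
        m_min=m_max / MAINTENANCE_RELAXATION_FOLD,
        m_max=m_max,
        k_mu=MAINTENANCE_K_MU,
    )


PRESETS: dict[str, ScenarioPreset] = {
    "wildtype-constant": ScenarioPreset(
        "wildtype-constant", ConstantMaintenance(0.0142), 0.545
    ),
    "wildtype-adaptive": ScenarioPreset(
        "wildtype-adaptive", _saturating(0.0142), 0.545
    ),
    "cxi-deficient-constant": ScenarioPreset(
        "cxi-deficient-constant", ConstantMaintenance(0.0241), 0.485
    ),
    "cxi-deficient-adaptive": ScenarioPreset(
        "cxi-deficient-adaptive", _saturating(0.0241), 0.485
    ),
}


def preset(name: str) -> ScenarioPreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None


def generate_chemostat_dataset(
    scenario: ScenarioPreset,
    dilution_rates: Sequence[float] = (0.025, 0.1),
    feed_glucose_g_L: float = 7.5,
    replicates: int = 2,
    noise: Optional[NoiseSpec] = None,
    broth_volume_L: float = 1.4,
    vvm: float = 0.5,
) -> list[ChemostatRecord]:
    """Steady-state chemostat records with known ground truth.

    Biomass follows the substrate-partition closure C_X = D*C_in/q_S(D) with
    residual glucose below detection; off-gas fractions are constructed from
    stoichiometric respiration (carbon balance closed at RQ = 1) so the gas
    route reproduces the same physiology.  Deterministic given the noise seed.
    """
    if noise is None:
        noise = NoiseSpec(biomass_cv=0.0, feed_cv=0.0)
    rng = noise.rng()
    flow_in_L_h = vvm * broth_volume_L * 60.0
    records: list[ChemostatRecord] = []
    for d in dilution_rates:
        if d <= 0:
            raise WashoutError("dilution rate must be positive")
        if d >= scenario.mu_max:
            raise WashoutError(
                f"D={d} exceeds the strain's maximum growth rate "
                f"{scenario.mu_max}; culture would wash out"
            )
        q_s = d / scenario.y_xs_max + scenario.maintenance.rate(d)
        c_x_true = d * feed_glucose_g_L / q_s
        # respiration stoichiometry: carbon not fixed in biomass leaves as CO2
        q_s_mmol = q_s * 1000.0 / DEFAULT_MOLAR.glucose_molar_mass
        q_co2 = (
            6.0 * q_s_mmol
            - d * DEFAULT_COMPOSITION.carbon_fraction * 1000.0
            / DEFAULT_MOLAR.carbon_molar_mass
        )
        q_o2 = q_co2  # RQ = 1 baseline for fully respiratory glucose catabolism
        for rep in range(replicates):
            c_x = c_x_true * _lognormal_factor(rng, noise.biomass_cv)
            feed = feed_glucose_g_L * _lognormal_factor(rng, noise.feed_cv)
            gas = gas_from_rates(
                q_o2_mmol_g_h=q_o2,
                q_co2_mmol_g_h=q_co2,
                biomass_g_L=c_x_true,
                broth_volume_L=broth_volume_L,
                flow_in_L_h=flow_in_L_h,
            )
            records.append(
                ChemostatRecord(
                    dilution_rate=d,
                    feed_glucose_g_L=float(feed),
                    biomass_g_L=float(c_x),
                    residual_glucose_g_L=None,  # below detection
                    gas=gas,
                    strain=scenario.name,
                    replicate=rep,
                )
            )
    return records


def generate_retentostat_dataset(
    scenario: ScenarioPreset,
    schedule_h: Optional[Sequence[float]] = None,
    noise: Optional[NoiseSpec] = None,
    replicates: int = 2,
) -> tuple[list[BiomassSample], dict]:
    """Noisy retentostat biomass samples plus the generating ground truth.

    Simulates the scenario's trajectory once and overlays independent
    multiplicative biomass noise per replicate and sampling time; viability
    is drawn near 1.0 (its measured range).  Returns (samples, truth) where
    ``truth`` records the generating parameters so consumers never re-derive
    them.
    """
    if noise is None:
        noise = NoiseSpec(biomass_cv=0.0, feed_cv=0.0)
    rng = noise.rng()
    config = scenario.config
    if schedule_h is None:
        schedule_h = config.sampling_hours
    schedule = np.asarray(schedule_h, dtype=float)
    traj: Trajectory = simulate(config, scenario.maintenance, scenario.y_xs_max, schedule)

    samples: list[BiomassSample] = []
    for rep in range(replicates):
        factors = _lognormal_factor(rng, noise.biomass_cv, size=schedule.size)
        viab = np.clip(rng.normal(0.997, 0.002, size=schedule.size), 0.95, 1.0)
        for t, c, f, v in zip(schedule, traj.c_x_g_L, factors, viab):
            samples.append(
                BiomassSample(
                    time_h=float(t),
                    c_x_g_L=float(c * f),
                    viability=float(v),
                    strain=scenario.name,
                    replicate=rep,
                )
            )

    m = scenario.maintenance
    truth = {
        "preset": scenario.name,
        "maintenance": {"kind": type(m).__name__, **dataclasses.asdict(m)},
        "y_xs_max": scenario.y_xs_max,
        "config": dataclasses.asdict(config),
        "schedule_h": schedule.tolist(),
        "noise": dataclasses.asdict(noise),
        "replicates": replicates,
        "noise_free_cx_g_L": traj.c_x_g_L.tolist(),
        "noise_free_mu_h": traj.mu_h.tolist(),
        "noise_free_qs_g_g_h": traj.q_s_g_g_h.tolist(),
    }
    return samples, truth
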