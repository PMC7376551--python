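"""Steady-state chemostat mass balances.

At steady state the biomass balance gives mu = D and the substrate balance
gives q_S * C_X = D * (C_S,in - C_S,res), so biomass-specific rates and
yields follow directly from measured concentrations.  Off-gas exchange rates
are recovered from inlet/outlet mole fractions with the standard inert-gas
balance (N2 + trace gases pass through unchanged, fixing the outlet flow).

Residual glucose below the assay detection limit (10 uM) is treated as zero
but flagged, and an upper-bound uptake rate computed at the detection limit
is carried alongside so the approximation stays traceable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

from .errors import (
    InvalidGasError,
    InvalidRecordError,
    NoConsumptionError,
)
from .stoichiometry import (
    DEFAULT_COMPOSITION,
    DEFAULT_MOLAR,
    BiomassComposition,
    MolarConstants,
    carbon_recovery,
    respiratory_quotient,
    yield_on_oxygen,
)

__all__ = [
    "DETECTION_LIMIT_G_L",
    "MOLAR_VOLUME_STP_L_MOL",
    "GasMeasurement",
    "ChemostatRecord",
    "RatesRecord",
    "specific_substrate_uptake",
    "gas_exchange_rates",
    "gas_from_rates",
    "summarize_steady_state",
]

#: 10 uM glucose expressed in g/L (the HPLC detection limit).
DETECTION_LIMIT_G_L = 10e-6 * 180.156

#: Molar volume of an ideal gas at 0 degC, 1 atm (dried, cooled off-gas).
MOLAR_VOLUME_STP_L_MOL = 22.414


@dataclass(frozen=True)
class GasMeasurement:
    """One off-gas analysis: inlet flow and inlet/outlet O2 and CO2 mole fractions."""

    flow_in_L_h: float
    y_o2_in: float
    y_o2_out: float
    y_co2_in: float
    y_co2_out: float
    broth_volume_L: float

    def __post_init__(self) -> None:
        if self.flow_in_L_h <= 0:
            raise InvalidGasError("inlet gas flow must be positive")
        if self.broth_volume_L <= 0:
            raise InvalidGasError("broth volume must be positive")
        for name in ("y_o2_in", "y_o2_out", "y_co2_in", "y_co2_out"):
            y = getattr(self, name)
            if not 0.0 <= y < 1.0:
                raise InvalidGasError(f"{name} must lie in [0, 1)")
        if self.y_o2_in + self.y_co2_in >= 1.0:
            raise InvalidGasError("inlet O2+CO2 fractions leave no inert carrier")
        if self.y_o2_out + self.y_co2_out >= 1.0:
            raise InvalidGasError("outlet O2+CO2 fractions leave no inert carrier")


@dataclass(frozen=True)
class ChemostatRecord:
    """One steady-state glucose-limited chemostat culture.

    ``residual_glucose_g_L`` of ``None`` means below the detection limit
    (``residual_below_detection`` is then implied true).
    """

    dilution_rate: float  # 1/h
    feed_glucose_g_L: float
    biomass_g_L: float
    residual_glucose_g_L: Optional[float] = None
    gas: Optional[GasMeasurement] = None
    strain: str = ""
    replicate: int = 0

    def __post_init__(self) -> None:
        if self.dilution_rate <= 0:
            raise InvalidRecordError("dilution rate must be positive")
        if self.feed_glucose_g_L <= 0:
            raise InvalidRecordError("feed glucose must be positive")
        if self.biomass_g_L <= 0:
            raise InvalidRecordError("biomass concentration must be positive")
        res = self.residual_glucose_g_L
        if res is not None:
            if res < 0:
                raise InvalidRecordError("residual glucose must be >= 0")
            if res >= self.feed_glucose_g_L:
                raise NoConsumptionError(
                    "residual glucose is not below the feed concentration"
                )

    @property
    def residual_below_detection(self) -> bool:
        return self.residual_glucose_g_L is None


@dataclass(frozen=True)
class RatesRecord:
    """Biomass-specific rates and yields of one steady-state culture.

    Uptake rates are positive magnitudes.  ``q_s_upper_g_g_h`` is the
    detection-limit upper bound on q_S when residual glucose was below
    detection, else equal to ``q_s_g_g_h``.
    """

    strain: str
    replicate: int
    mu_h: float
    q_s_g_g_h: float
    q_s_mmol_g_h: float
    q_s_upper_g_g_h: float
    y_xs_g_g: float
    residual_below_detection: bool
    q_o2_mmol_g_h: Optional[float] = None
    q_co2_mmol_g_h: Optional[float] = None
    y_xo2_g_g: Optional[float] = None
    rq: Optional[float] = None
    carbon_recovery_pct: Optional[float] = None
    extras: dict = field(default_factory=dict)


def specific_substrate_uptake(
    record: ChemostatRecord, constants: MolarConstants = DEFAULT_MOLAR
) -> float:
    """Biomass-specific glucose uptake q_S = D (C_in - C_res) / C_X, g/(g·h).

    Residual glucose below detection is taken as 0 (the flag lives on the
    record); use :func:`summarize_steady_state` for the detection-limit
    upper bound.
    """
    res = record.residual_glucose_g_L or 0.0
    return record.dilution_rate * (record.feed_glucose_g_L - res) / record.biomass_g_L


def gas_exchange_rates(
    gas: GasMeasurement,
    biomass_g_L: float,
    molar_volume_L_mol: float = MOLAR_VOLUME_STP_L_MOL,
) -> tuple[float, float]:
    """(q_O2, q_CO2) in mmol/(g·h), positive magnitudes, from the inert-gas balance.

    The inert (non-O2, non-CO2) molar flow is conserved, fixing the outlet
    flow: F_out = F_in (1 - yO2,in - yCO2,in) / (1 - yO2,out - yCO2,out).
    """
    if biomass_g_L <= 0:
        raise InvalidRecordError("biomass concentration must be positive")
    inert_out = 1.0 - gas.y_o2_out - gas.y_co2_out
    if inert_out <= 0:
        raise InvalidGasError("outlet inert fraction must be positive")
    f_out = gas.flow_in_L_h * (1.0 - gas.y_o2_in - gas.y_co2_in) / inert_out
    denom = molar_volume_L_mol * gas.broth_volume_L * biomass_g_L
    q_o2 = (gas.flow_in_L_h * gas.y_o2_in - f_out * gas.y_o2_out) * 1000.0 / denom
    q_co2 = (f_out * gas.y_co2_out - gas.flow_in_L_h * gas.y_co2_in) * 1000.0 / denom
    return q_o2, q_co2


def gas_from_rates(
    q_o2_mmol_g_h: float,
    q_co2_mmol_g_h: float,
    biomass_g_L: float,
    broth_volume_L: float,
    flow_in_L_h: float,
    y_o2_in: float = 0.2095,
    y_co2_in: float = 0.0004,
    molar_volume_L_mol: float = MOLAR_VOLUME_STP_L_MOL,
) -> GasMeasurement:
    """Construct the off-gas measurement a culture with the given exchange
    rates would produce (forward model; exact inverse of
    :func:`gas_exchange_rates`)."""
    fm_in = flow_in_L_h / molar_volume_L_mol  # mol gas / h
    r_o2 = q_o2_mmol_g_h * biomass_g_L * broth_volume_L / 1000.0  # mol/h consumed
    r_co2 = q_co2_mmol_g_h * biomass_g_L * broth_volume_L / 1000.0  # mol/h produced
    n_o2_out = fm_in * y_o2_in - r_o2
    n_co2_out = fm_in * y_co2_in + r_co2
    n_inert = fm_in * (1.0 - y_o2_in - y_co2_in)
    if n_o2_out < 0:
        raise InvalidGasError("oxygen uptake exceeds oxygen supplied")
    total_out = n_o2_out + n_co2_out + n_inert
    return GasMeasurement(
        flow_in_L_h=flow_in_L_h,
        y_o2_in=y_o2_in,
        y_o2_out=n_o2_out / total_out,
        y_co2_in=y_co2_in,
        y_co2_out=n_co2_out / total_out,
        broth_volume_L=broth_volume_L,
    )


def summarize_steady_state(
    record: ChemostatRecord,
    composition: BiomassComposition = DEFAULT_COMPOSITION,
    constants: MolarConstants = DEFAULT_MOLAR,
    molar_volume_L_mol: float = MOLAR_VOLUME_STP_L_MOL,
) -> RatesRecord:
    """Assemble rates, yields, RQ and carbon recovery for one steady state.

    Gas-derived fields are None when the record carries no off-gas data.
    Note Y_X/S = C_X / (C_in - C_res) is algebraically identical to mu/q_S
    under the steady-state balance; the concentration form is used.
    """
    res = record.residual_glucose_g_L or 0.0
    consumed = record.feed_glucose_g_L - res
    q_s = specific_substrate_uptake(record, constants)
    # With residual below detection the true residual lies in [0, DL]:
    # residual 0 gives the point estimate (and upper bound), the detection
    # limit the lower bound.  The spread is ~0.02% of q_S here.
    q_s_upper = q_s
    q_s_lower = q_s
    if record.residual_below_detection:
        q_s_lower = (
            record.dilution_rate
            * (record.feed_glucose_g_L - DETECTION_LIMIT_G_L)
            / record.biomass_g_L
        )
    q_s_mmol = q_s * 1000.0 / constants.glucose_molar_mass
    y_xs = record.biomass_g_L / consumed

    q_o2 = q_co2 = y_xo2 = rq = crec = None
    if record.gas is not None:
        q_o2, q_co2 = gas_exchange_rates(
            record.gas, record.biomass_g_L, molar_volume_L_mol
        )
        if q_o2 > 0:
            y_xo2 = yield_on_oxygen(record.dilution_rate, q_o2, constants)
            rq = respiratory_quotient(q_co2, q_o2)
        crec = carbon_recovery(
            q_s_mmol, q_co2, record.dilution_rate, composition, constants
        )

    extras: dict = {}
    if record.residual_below_detection:
        extras["q_s_lower_g_g_h"] = q_s_lower
        extras["residual_assumed_g_L"] = 0.0

    return RatesRecord(
        strain=record.strain,
        replicate=record.replicate,
        mu_h=record.dilution_rate,
        q_s_g_g_h=q_s,
        q_s_mmol_g_h=q_s_mmol,
        q_s_upper_g_g_h=q_s_upper,
        y_xs_g_g=y_xs,
        residual_below_detection=record.residual_below_detection,
        q_o2_mmol_g_h=q_o2,
        q_co2_mmol_g_h=q_co2,
        y_xo2_g_g=y_xo2,
        rq=rq,
        carbon_recovery_pct=crec,
        extras=extras,
    )
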