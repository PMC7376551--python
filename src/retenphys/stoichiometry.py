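"""Unit conversions, yields, carbon recovery and respiratory-chain coupling arithmetic.

The package works internally in h, g/L and g/(g·h); molar (mmol-based) rates
appear only at the I/O boundary and are bridged through :class:`MolarConstants`.
Uptake rates are handled as positive magnitudes throughout (instruments and
publications often print uptake as negative; the sign is a direction
convention, not information the formulas need).

The respiratory-chain arithmetic quantifies how much ATP conservation is lost
when the proton-translocating complex I is replaced by a non-pumping
alternative NADH dehydrogenase.  Per 2 electrons, complex I translocates
4 charges and the downstream chain (complexes III + IV) 6, so removing
complex I removes 4 of 10 charge translocations per NADH oxidized — a 40 %
loss of ATP at a fixed ATP-synthase charge stoichiometry.  The charge counts
are explicit, overridable model inputs, not hidden constants.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .errors import InvalidRateError, InvalidYieldError, UndefinedModelError

__all__ = [
    "MolarConstants",
    "BiomassComposition",
    "RespiratoryModel",
    "DEFAULT_MOLAR",
    "DEFAULT_COMPOSITION",
    "DEFAULT_RESPIRATORY",
    "yield_on_substrate",
    "yield_on_oxygen",
    "respiratory_quotient",
    "carbon_recovery",
    "relative_po_ratio",
    "atp_reduction_without_complex_i",
]


@dataclass(frozen=True)
class MolarConstants:
    """Molar masses (g/mol) bridging g-based and mmol-based rates."""

    glucose_molar_mass: float = 180.156
    o2_molar_mass: float = 31.998
    co2_molar_mass: float = 44.009
    carbon_molar_mass: float = 12.011

    def __post_init__(self) -> None:
        for name in (
            "glucose_molar_mass",
            "o2_molar_mass",
            "co2_molar_mass",
            "carbon_molar_mass",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class BiomassComposition:
    """Elemental/macromolecular composition of dry biomass.

    carbon_fraction: g carbon per g dry biomass (0.48 for glucose-grown yeast).
    protein_fraction: g protein per g dry biomass, if measured.
    """

    carbon_fraction: float = 0.48
    protein_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.carbon_fraction < 1.0:
            raise ValueError("carbon_fraction must lie in (0, 1)")
        if self.protein_fraction is not None and not 0.0 <= self.protein_fraction < 1.0:
            raise ValueError("protein_fraction must lie in [0, 1)")


@dataclass(frozen=True)
class RespiratoryModel:
    """Charge-translocation stoichiometry of the respiratory chain, per 2 e-.

    ``charges_complex_i``: charges pumped by complex I (NADH:ubiquinone
    oxidoreductase); ``charges_downstream``: complexes III + IV combined;
    ``charges_alternative_dh``: the alternative (Ndh2-type) NADH
    dehydrogenase, 0 because it does not translocate protons.
    ``yx_atp_assumed_equal`` flags the assumption that biomass formed per mol
    ATP is strain-independent, which is what licenses reading relative
    biomass-per-oxygen yields as relative P/O ratios.
    """

    charges_complex_i: float = 4.0
    charges_downstream: float = 6.0
    charges_alternative_dh: float = 0.0
    yx_atp_assumed_equal: bool = True

    def __post_init__(self) -> None:
        for name in ("charges_complex_i", "charges_downstream", "charges_alternative_dh"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


DEFAULT_MOLAR = MolarConstants()
DEFAULT_COMPOSITION = BiomassComposition()
DEFAULT_RESPIRATORY = RespiratoryModel()


def yield_on_substrate(
    mu: float, q_s: float, constants: MolarConstants = DEFAULT_MOLAR
) -> float:
    """Biomass yield on glucose, g biomass / g glucose.

    Parameters
    ----------
    mu : specific growth rate, 1/h (>= 0).
    q_s : biomass-specific glucose uptake magnitude, mmol glucose/(g·h) (> 0).
    """
    if q_s <= 0:
        raise InvalidRateError("q_s must be a positive uptake magnitude")
    if mu < 0:
        raise InvalidRateError("mu must be >= 0")
    return mu / (q_s * constants.glucose_molar_mass / 1000.0)


def yield_on_oxygen(
    mu: float, q_o2: float, constants: MolarConstants = DEFAULT_MOLAR
) -> float:
    """Biomass yield on oxygen, g biomass / g O2 (q_o2 in mmol O2/(g·h), > 0)."""
    if q_o2 <= 0:
        raise InvalidRateError("q_o2 must be a positive uptake magnitude")
    if mu < 0:
        raise InvalidRateError("mu must be >= 0")
    return mu / (q_o2 * constants.o2_molar_mass / 1000.0)


def respiratory_quotient(q_co2: float, q_o2: float) -> float:
    """RQ = q_CO2 / q_O2 (both positive magnitudes, mmol/(g·h))."""
    if q_o2 == 0:
        raise InvalidRateError("q_o2 must be nonzero for RQ")
    if q_co2 < 0 or q_o2 < 0:
        raise InvalidRateError("rates must be positive magnitudes")
    return q_co2 / q_o2


def carbon_recovery(
    q_s: float,
    q_co2: float,
    mu: float,
    composition: BiomassComposition = DEFAULT_COMPOSITION,
    constants: MolarConstants = DEFAULT_MOLAR,
) -> float:
    """Carbon recovery in percent.

    Carbon leaves the glucose pool (6 C per molecule) as CO2 and as biomass
    carbon (``mu * carbon_fraction`` g C/(g·h), converted to mmol C with the
    carbon molar mass); recovery is their sum over the carbon fed.
    """
    if q_s <= 0:
        raise InvalidRateError("q_s must be a positive uptake magnitude")
    if mu < 0 or q_co2 < 0:
        raise InvalidRateError("mu and q_co2 must be >= 0")
    biomass_c = mu * composition.carbon_fraction * 1000.0 / constants.carbon_molar_mass
    return 100.0 * (q_co2 + biomass_c) / (6.0 * q_s)


def relative_po_ratio(y_xo2_ref: float, y_xo2_test: float) -> float:
    """Fractional reduction of the in vivo P/O ratio inferred from Y_X/O2.

    Valid as a P/O proxy only under the equal-Y_X/ATP assumption
    (see :class:`RespiratoryModel`).  Returns (ref - test)/ref; negative if
    the test strain couples better than the reference.
    """
    if y_xo2_ref <= 0 or y_xo2_test <= 0:
        raise InvalidYieldError("yields must be strictly positive")
    return (y_xo2_ref - y_xo2_test) / y_xo2_ref


def atp_reduction_without_complex_i(
    model: RespiratoryModel = DEFAULT_RESPIRATORY,
) -> float:
    """Fractional ATP loss per NADH when complex I is replaced by Ndh2.

    At fixed charges-per-ATP of the ATP synthase, ATP conserved per NADH is
    proportional to charges translocated per 2 e-.  With complex I the chain
    translocates ``charges_complex_i + charges_downstream``; with a
    non-pumping dehydrogenase only ``charges_alternative_dh +
    charges_downstream``.  Defaults (4, 6, 0) give 0.40.
    """
    total = model.charges_complex_i + model.charges_downstream
    if total == 0:
        raise UndefinedModelError("all charge counts are zero; model undefined")
    return (model.charges_complex_i - model.charges_alternative_dh) / total
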