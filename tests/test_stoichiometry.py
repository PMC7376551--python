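"""Yields, carbon recovery and respiratory-chain coupling arithmetic."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from retenphys.errors import (
    InvalidRateError,
    InvalidYieldError,
    UndefinedModelError,
)
from retenphys.stoichiometry import (
    BiomassComposition,
    MolarConstants,
    RespiratoryModel,
    atp_reduction_without_complex_i,
    carbon_recovery,
    relative_po_ratio,
    respiratory_quotient,
    yield_on_oxygen,
    yield_on_substrate,
)

positive = st.floats(0.01, 100.0, allow_nan=False)


class TestYields:
    @pytest.mark.parametrize(
        "mu, q_s, expected",
        [
            (0.37, 3.88, 0.529),  # batch growth on excess glucose
            (0.099, 1.08, 0.509),  # glucose-limited chemostat, D ~ 0.1/h
            (0.0, 2.0, 0.0),
        ],
    )
    def test_yield_on_substrate(self, mu, q_s, expected):
        assert yield_on_substrate(mu, q_s) == pytest.approx(expected, abs=5e-4)

    @pytest.mark.parametrize(
        "mu, q_o2, expected",
        [
            (0.100, 3.54, 0.883),  # complex-I-deficient chemostat
            (0.099, 2.44, 1.268),  # wild-type chemostat
            (0.0, 2.0, 0.0),
        ],
    )
    def test_yield_on_oxygen(self, mu, q_o2, expected):
        assert yield_on_oxygen(mu, q_o2) == pytest.approx(expected, abs=5e-4)

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_nonpositive_uptake_rejected(self, bad):
        with pytest.raises(InvalidRateError):
            yield_on_substrate(0.1, bad)
        with pytest.raises(InvalidRateError):
            yield_on_oxygen(0.1, bad)

    @given(mu=positive, q=positive, c=st.floats(0.1, 10.0))
    @settings(max_examples=50, deadline=None)
    def test_yield_invariant_under_joint_scaling(self, mu, q, c):
        # yields are ratios of rates: scaling mu and q together cancels
        assert yield_on_substrate(c * mu, c * q) == pytest.approx(
            yield_on_substrate(mu, q), rel=1e-12
        )


class TestRespiratoryQuotient:
    @pytest.mark.parametrize(
        "q_co2, q_o2, expected",
        [(2.52, 2.44, 1.033), (3.64, 3.54, 1.028)],
    )
    def test_chemostat_values(self, q_co2, q_o2, expected):
        assert respiratory_quotient(q_co2, q_o2) == pytest.approx(expected, abs=5e-4)

    @given(x=positive)
    @settings(max_examples=25, deadline=None)
    def test_balanced_respiration_gives_unity(self, x):
        assert respiratory_quotient(x, x) == pytest.approx(1.0)

    def test_zero_oxygen_undefined(self):
        with pytest.raises(InvalidRateError):
            respiratory_quotient(1.0, 0.0)


class TestCarbonRecovery:
    def test_chemostat_wildtype_column(self):
        # arithmetic on the steady-state means of the wild-type culture
        assert carbon_recovery(1.08, 2.52, 0.099) == pytest.approx(99.94, abs=0.05)

    def test_chemostat_deficient_column(self):
        assert carbon_recovery(1.27, 3.64, 0.100) == pytest.approx(100.21, abs=0.05)

    def test_complete_combustion_no_biomass(self):
        assert carbon_recovery(1.0, 6.0, 0.0) == pytest.approx(100.0)

    @given(q_s=positive, mu=st.floats(0.0, 0.5))
    @settings(max_examples=50, deadline=None)
    def test_constructed_balance_closes_exactly(self, q_s, mu):
        comp = BiomassComposition()
        const = MolarConstants()
        biomass_c = mu * comp.carbon_fraction * 1000.0 / const.carbon_molar_mass
        q_co2 = 6.0 * q_s - biomass_c
        if q_co2 < 0:
            return
        assert carbon_recovery(q_s, q_co2, mu) == pytest.approx(100.0, rel=1e-12)

    def test_invalid_uptake_rejected(self):
        with pytest.raises(InvalidRateError):
            carbon_recovery(0.0, 1.0, 0.1)


class TestRelativePO:
    def test_thirty_percent_lower_coupling(self):
        # wild-type vs complex-I-deficient oxygen yields
        assert relative_po_ratio(1.26, 0.88) == pytest.approx(0.302, abs=1e-3)

    @pytest.mark.parametrize("y", [0.5, 1.26])
    def test_identity_and_halving(self, y):
        assert relative_po_ratio(y, y) == 0.0
        assert relative_po_ratio(y, y / 2) == pytest.approx(0.5)

    @given(a=positive, b=positive)
    @settings(max_examples=50, deadline=None)
    def test_round_trip_consistency(self, a, b):
        # applying the reduction then inverting it restores the reference
        r = relative_po_ratio(a, b)
        assert a * (1 - r) == pytest.approx(b, rel=1e-12)

    def test_nonpositive_yield_rejected(self):
        with pytest.raises(InvalidYieldError):
            relative_po_ratio(0.0, 1.0)


class TestAtpReduction:
    def test_default_chain_loses_forty_percent(self):
        assert atp_reduction_without_complex_i() == pytest.approx(0.40)

    def test_no_pumping_nothing_to_lose(self):
        model = RespiratoryModel(charges_complex_i=0)
        assert atp_reduction_without_complex_i(model) == 0.0

    def test_two_charge_pump(self):
        model = RespiratoryModel(charges_complex_i=2)
        assert atp_reduction_without_complex_i(model) == pytest.approx(0.25)

    @given(
        ci=st.floats(0.0, 10.0),
        down=st.floats(0.5, 10.0),
        delta=st.floats(0.1, 5.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_chain_composition(self, ci, down, delta):
        base = atp_reduction_without_complex_i(
            RespiratoryModel(charges_complex_i=ci, charges_downstream=down)
        )
        more_pump = atp_reduction_without_complex_i(
            RespiratoryModel(charges_complex_i=ci + delta, charges_downstream=down)
        )
        more_down = atp_reduction_without_complex_i(
            RespiratoryModel(charges_complex_i=ci, charges_downstream=down + delta)
        )
        assert more_pump >= base
        assert more_down <= base

    def test_degenerate_chain_rejected(self):
        with pytest.raises(UndefinedModelError):
            atp_reduction_without_complex_i(
                RespiratoryModel(
                    charges_complex_i=0, charges_downstream=0, charges_alternative_dh=0
                )
            )


def test_molar_constants_immutable_and_positive():
    const = MolarConstants()
    with pytest.raises(Exception):
        const.glucose_molar_mass = 100.0  # type: ignore[misc]
    with pytest.raises(ValueError):
        MolarConstants(glucose_molar_mass=-1.0)
    with pytest.raises(ValueError):
        BiomassComposition(carbon_fraction=1.5)
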