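"""Retentostat forward model: feed transition, initial state, integration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from retenphys.retentostat import (
    ConstantMaintenance,
    RetentostatConfig,
    SaturatingMaintenance,
    constant_maintenance_asymptote,
    constant_maintenance_solution,
    initial_state,
    mixing_vessel_conc,
    mixing_vessel_mean,
    simulate,
    solve_mu,
)

from conftest import CXI_MS, CXI_YMAX, WT_MS, WT_YMAX


class TestMixingVessel:
    def test_initial_condition(self, config):
        assert mixing_vessel_conc(0.0, config) == pytest.approx(10.0)

    def test_asymptote(self, config):
        assert mixing_vessel_conc(1e6, config) == pytest.approx(5.0)

    def test_one_time_constant(self, config):
        tau = 1.0 / config.mixing_rate_h
        assert tau == pytest.approx(34.29, abs=0.01)
        assert mixing_vessel_conc(tau, config) == pytest.approx(5 + 5 / math.e, abs=1e-3)

    def test_instant_switch_mode(self):
        config = RetentostatConfig(instant_feed_switch=True)
        assert mixing_vessel_conc(0.0, config) == 5.0
        assert mixing_vessel_mean(0.0, 10.0, config) == 5.0

    @given(t0=st.floats(0.0, 400.0), dt=st.floats(0.1, 200.0))
    @settings(max_examples=50, deadline=None)
    def test_interval_mean_bracketed_by_endpoints(self, t0, dt):
        config = RetentostatConfig()
        mean = mixing_vessel_mean(t0, t0 + dt, config)
        hi = mixing_vessel_conc(t0, config)
        lo = mixing_vessel_conc(t0 + dt, config)
        assert lo - 1e-12 <= mean <= hi + 1e-12


class TestInitialState:
    def test_wildtype_chemostat_biomass(self, config, wt_fit):
        assert initial_state(config, wt_fit) == pytest.approx(4.162, abs=1e-3)

    def test_deficient_chemostat_biomass(self, config, cxi_fit):
        assert initial_state(config, cxi_fit) == pytest.approx(3.305, abs=1e-3)

    def test_maintenance_free_limit(self, config):
        from retenphys.pirt import RatePair, fit_pirt

        fit = fit_pirt([RatePair(mu, mu / 0.5 + 1e-15) for mu in (0.01, 0.1)])
        assert initial_state(config, fit) == pytest.approx(5.0, rel=1e-6)


class TestSolveMu:
    @given(q=st.floats(0.006, 0.3))
    @settings(max_examples=50, deadline=None)
    def test_fixed_point_matches_quadratic_root(self, q):
        # For the saturating law, mu = y(q - m(mu)) reduces to a quadratic;
        # the damped fixed point must land on its positive root.
        maint = SaturatingMaintenance(WT_MS / 2.75, WT_MS, 0.005)
        y = WT_YMAX
        mu = solve_mu(q, maint, y)
        k, dm = maint.k_mu, maint.m_max - maint.m_min
        b = k - y * (q - maint.m_min) + y * dm
        c = -y * (q - maint.m_min) * k
        root = (-b + math.sqrt(b * b - 4 * c)) / 2
        assert mu == pytest.approx(root, abs=1e-10)

    def test_constant_is_closed_form(self):
        assert solve_mu(0.06, ConstantMaintenance(0.0142), 0.545) == pytest.approx(
            0.545 * (0.06 - 0.0142), rel=1e-12
        )


class TestSimulate:
    def test_constant_maintenance_reaches_asymptote(self, config):
        for m_s, y, asym in [(WT_MS, WT_YMAX, 8.803), (CXI_MS, CXI_YMAX, 5.187)]:
            grid = np.linspace(0.0, 4000.0, 201)
            traj = simulate(config, ConstantMaintenance(m_s), y, grid)
            assert constant_maintenance_asymptote(config, m_s) == pytest.approx(
                asym, abs=1e-3
            )
            assert traj.c_x_g_L[-1] == pytest.approx(asym, rel=1e-3)

    def test_matches_closed_form_solution(self, config):
        grid = np.linspace(0.0, 2000.0, 101)
        traj = simulate(config, ConstantMaintenance(WT_MS), WT_YMAX, grid)
        closed = constant_maintenance_solution(
            grid, config, WT_MS, WT_YMAX, traj.c_x_g_L[0]
        )
        assert np.max(np.abs(traj.c_x_g_L - closed) / closed) < 1e-7

    def test_monotone_after_transient(self, config):
        grid = np.linspace(0.0, 2000.0, 401)
        traj = simulate(config, ConstantMaintenance(WT_MS), WT_YMAX, grid)
        # biomass never decreases for the wild-type scenario and mu declines
        # once the mixing-vessel transient (~5 time constants) has passed
        assert np.all(np.diff(traj.c_x_g_L) >= -1e-9)
        transient = grid > 5 / config.mixing_rate_h
        assert np.all(np.diff(traj.mu_h[transient]) <= 1e-10)

    def test_substrate_conservation_each_step(self, config):
        grid = np.linspace(0.0, 552.0, 24)
        traj = simulate(
            config, SaturatingMaintenance(WT_MS / 2.75, WT_MS, 0.005), WT_YMAX, grid
        )
        supply = config.dilution_rate * traj.c_mix_g_L
        assert np.allclose(traj.q_s_g_g_h * traj.c_x_g_L, supply, rtol=1e-12)
        # and the partition closure holds at the solved mu
        assert np.allclose(
            traj.q_s_g_g_h, traj.mu_h / WT_YMAX + traj.m_s_g_g_h, atol=1e-10
        )

    def test_fixed_point_start_stays_flat(self):
        config = RetentostatConfig(
            chemostat_feed_g_L=5.0, instant_feed_switch=True
        )
        asym = constant_maintenance_asymptote(config, WT_MS)
        grid = np.linspace(0.0, 500.0, 26)
        traj = simulate(
            config, ConstantMaintenance(WT_MS), WT_YMAX, grid, c_x0=asym
        )
        assert np.allclose(traj.c_x_g_L, asym, rtol=1e-9)
        assert np.allclose(traj.mu_h, 0.0, atol=1e-9)

    def test_saturating_exceeds_constant_asymptote(self, config):
        grid = np.linspace(0.0, 552.0, 50)
        sat = SaturatingMaintenance(WT_MS / 2.75, WT_MS, 0.005)
        traj = simulate(config, sat, WT_YMAX, grid)
        assert traj.c_x_g_L[-1] > constant_maintenance_asymptote(config, WT_MS)

    def test_grid_refinement_converges(self, config):
        end = 552.0
        coarse = simulate(
            config, ConstantMaintenance(WT_MS), WT_YMAX, np.linspace(0, end, 24)
        )
        fine = simulate(
            config, ConstantMaintenance(WT_MS), WT_YMAX, np.linspace(0, end, 553)
        )
        assert coarse.c_x_g_L[-1] == pytest.approx(fine.c_x_g_L[-1], rel=1e-4)

    def test_sampling_withdrawal_lowers_biomass(self):
        base = RetentostatConfig()
        withdrawn = RetentostatConfig(sample_volume_L=0.05)
        grid = np.asarray(base.sampling_hours)
        t0 = simulate(base, ConstantMaintenance(WT_MS), WT_YMAX, grid)
        t1 = simulate(withdrawn, ConstantMaintenance(WT_MS), WT_YMAX, grid)
        assert t1.c_x_g_L[-1] < t0.c_x_g_L[-1]

    def test_death_rate_lowers_net_accumulation(self, config):
        grid = np.linspace(0.0, 552.0, 24)
        alive = simulate(config, ConstantMaintenance(WT_MS), WT_YMAX, grid)
        dying = simulate(
            RetentostatConfig(death_rate=0.001),
            ConstantMaintenance(WT_MS),
            WT_YMAX,
            grid,
        )
        assert dying.c_x_g_L[-1] < alive.c_x_g_L[-1]


def test_config_validation():
    with pytest.raises(ValueError):
        RetentostatConfig(mixing_volume_L=0.0)
    with pytest.raises(ValueError):
        RetentostatConfig(dilution_rate=-0.01)
    with pytest.raises(ValueError):
        SaturatingMaintenance(m_min=0.02, m_max=0.01, k_mu=0.005)
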