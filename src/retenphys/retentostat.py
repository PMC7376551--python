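"""Forward simulation of retentostat biomass accumulation.

A retentostat is a chemostat whose effluent passes through a filter so all
biomass is retained.  Substrate keeps flowing in at dilution rate D, but as
biomass accumulates the biomass-specific supply D*C_mix/C_X falls until it
only covers maintenance and growth asymptotically stops.  Here the feed
transition is buffered by a mixing vessel: at retentostat start the feed to
the mixing vessel switches from the chemostat-phase to the retentostat-phase
glucose concentration, and the reactor inflow concentration relaxes
exponentially between the two with time constant V_M / (D * V_R).

Model equations (full biomass retention, quasi-steady residual substrate):

    dC_X/dt = (mu - k_d) * C_X
    q_S * C_X = D * C_mix(t)            (substrate balance, residual ~ 0)
    q_S = mu / Y_X/S_max + m_S(mu)      (substrate partition closure)

With a constant maintenance coefficient the system is linear and has a
closed-form solution (provided as an independent benchmark); with a
growth-rate-dependent m_S(mu) the growth rate is solved per step by damped
fixed-point iteration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import InfeasibleStateError, SolverError
from .pirt import PirtFit, predict_qs

__all__ = [
    "RetentostatConfig",
    "ConstantMaintenance",
    "SaturatingMaintenance",
    "MaintenanceModel",
    "Trajectory",
    "DEFAULT_SAMPLING_HOURS",
    "mixing_vessel_conc",
    "mixing_vessel_mean",
    "initial_state",
    "solve_mu",
    "simulate",
    "constant_maintenance_solution",
    "constant_maintenance_asymptote",
]

#: Default sampling schedule, hours: ~12 points over 23 days, denser early.
DEFAULT_SAMPLING_HOURS: tuple[float, ...] = (
    0.0, 24.0, 48.0, 96.0, 168.0, 216.0, 264.0, 336.0, 384.0, 432.0, 504.0, 552.0,
)


@dataclass(frozen=True)
class RetentostatConfig:
    """Vessel geometry, feed regime and sampling schedule.

    Defaults are the working setup this model targets: a 1.4 L reactor fed at
    D = 0.025 1/h through a 1.2 L mixing vessel, 10 g/L glucose during the
    preceding chemostat phase and 5 g/L during the retentostat phase.
    """

    reactor_volume_L: float = 1.4
    mixing_volume_L: float = 1.2
    dilution_rate: float = 0.025  # 1/h
    chemostat_feed_g_L: float = 10.0
    retentostat_feed_g_L: float = 5.0
    death_rate: float = 0.0  # 1/h, first-order loss of viable biomass
    sampling_hours: tuple[float, ...] = DEFAULT_SAMPLING_HOURS
    instant_feed_switch: bool = False  # bypass the mixing vessel
    sample_volume_L: float = 0.0  # broth withdrawn per sampling event

    def __post_init__(self) -> None:
        if self.reactor_volume_L <= 0 or self.mixing_volume_L <= 0:
            raise ValueError("vessel volumes must be positive")
        if self.dilution_rate <= 0:
            raise ValueError("dilution rate must be positive")
        if self.chemostat_feed_g_L <= 0 or self.retentostat_feed_g_L <= 0:
            raise ValueError("feed concentrations must be positive")
        if self.death_rate < 0:
            raise ValueError("death rate must be >= 0")
        if self.sample_volume_L < 0 or self.sample_volume_L >= self.reactor_volume_L:
            raise ValueError("sample volume must lie in [0, reactor volume)")

    @property
    def feed_flow_L_h(self) -> float:
        return self.dilution_rate * self.reactor_volume_L

    @property
    def mixing_rate_h(self) -> float:
        """Turnover rate of the mixing vessel, F/V_M (1/h)."""
        return self.feed_flow_L_h / self.mixing_volume_L


@dataclass(frozen=True)
class ConstantMaintenance:
    """Growth-rate-independent maintenance coefficient, g glucose/(g·h)."""

    m_s: float

    def __post_init__(self) -> None:
        if self.m_s < 0:
            raise ValueError("m_s must be >= 0")

    def rate(self, mu: float) -> float:
        return self.m_s


@dataclass(frozen=True)
class SaturatingMaintenance:
    """Maintenance declining toward m_min as growth slows.

    m_S(mu) = m_min + (m_max - m_min) * mu / (mu + k_mu): at growth rates
    well above k_mu maintenance sits at m_max (the chemostat regime); as mu
    approaches zero it relaxes to m_min.  This is a phenomenological form for
    the observed down-regulation of maintenance at near-zero growth; the
    half-saturation rate k_mu is a modelling choice, not a measured constant.
    """

    m_min: float
    m_max: float
    k_mu: float

    def __post_init__(self) -> None:
        if self.m_min < 0 or self.m_max < 0:
            raise ValueError("maintenance coefficients must be >= 0")
        if self.m_min > self.m_max:
            raise ValueError("m_min must not exceed m_max")
        if self.k_mu <= 0:
            raise ValueError("k_mu must be positive")

    def rate(self, mu: float) -> float:
        mu = max(mu, 0.0)  # maintenance saturates at m_min for mu <= 0
        return self.m_min + (self.m_max - self.m_min) * mu / (mu + self.k_mu)


MaintenanceModel = Union[ConstantMaintenance, SaturatingMaintenance]


@dataclass(frozen=True)
class Trajectory:
    """Simulated retentostat time course on a fixed grid."""

    time_h: np.ndarray
    c_mix_g_L: np.ndarray
    c_x_g_L: np.ndarray
    mu_h: np.ndarray
    q_s_g_g_h: np.ndarray
    m_s_g_g_h: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.time_h,
                "cmix_g_L": self.c_mix_g_L,
                "cx_g_L": self.c_x_g_L,
                "mu_h-1": self.mu_h,
                "qs_g_g_h": self.q_s_g_g_h,
                "ms_g_g_h": self.m_s_g_g_h,
            }
        )


def mixing_vessel_conc(t: float, config: RetentostatConfig) -> float:
    """Glucose concentration entering the reactor at time t (h) after the switch.

    Closed form of the mixing-vessel balance:
    C_mix(t) = C_new + (C_old - C_new) exp(-F t / V_M).
    """
    if t < 0:
        raise ValueError("t must be >= 0 (t=0 is retentostat start)")
    if config.instant_feed_switch:
        return config.retentostat_feed_g_L
    c_new = config.retentostat_feed_g_L
    c_old = config.chemostat_feed_g_L
    return c_new + (c_old - c_new) * math.exp(-config.mixing_rate_h * t)


def mixing_vessel_mean(t0: float, t1: float, config: RetentostatConfig) -> float:
    """Time-average of C_mix over [t0, t1] (exact integral of the closed form)."""
    if t1 <= t0:
        raise ValueError("t1 must exceed t0")
    if config.instant_feed_switch:
        return config.retentostat_feed_g_L
    beta = config.mixing_rate_h
    c_new = config.retentostat_feed_g_L
    c_old = config.chemostat_feed_g_L
    decay = (math.exp(-beta * t0) - math.exp(-beta * t1)) / (beta * (t1 - t0))
    return c_new + (c_old - c_new) * decay


def initial_state(config: RetentostatConfig, fit: PirtFit) -> float:
    """Steady-state biomass of the preceding chemostat phase, g/L.

    C_X = D * C_feed,chemostat / q_S(D) with q_S from the fitted partition line.
    """
    qs = predict_qs(fit, config.dilution_rate)
    if qs <= 0:
        raise InfeasibleStateError("predicted uptake at D is non-positive")
    return config.dilution_rate * config.chemostat_feed_g_L / qs


def solve_mu(
    q_s: float,
    maintenance: MaintenanceModel,
    y_xs_max: float,
    mu_guess: float = 0.0,
    tol: float = 1e-12,
    max_iter: int = 10_000,
    damping: float = 0.5,
) -> float:
    """Growth rate consistent with uptake q_S under the partition closure.

    Solves mu = Y_X/S_max * (q_S - m_S(mu)).  Constant maintenance is closed
    form; mu-dependent maintenance is solved by damped fixed-point iteration
    to |delta mu| < tol.
    """
    if isinstance(maintenance, ConstantMaintenance):
        return y_xs_max * (q_s - maintenance.m_s)
    mu = mu_guess
    for _ in range(max_iter):
        target = y_xs_max * (q_s - maintenance.rate(mu))
        new = mu + damping * (target - mu)
        if abs(new - mu) < tol:
            return new
        mu = new
    raise SolverError("fixed-point iteration for mu did not converge")


def simulate(
    config: RetentostatConfig,
    maintenance: MaintenanceModel,
    y_xs_max: float,
    t_grid: Optional[Sequence[float]] = None,
    c_x0: Optional[float] = None,
    rtol: float = 1e-9,
    atol: float = 1e-12,
) -> Trajectory:
    """Integrate the retentostat biomass balance on t_grid (hours from switch).

    If ``c_x0`` is omitted the chemostat-phase steady state implied by the
    maintenance model at mu = D is used.  If ``config.sample_volume_L`` is
    positive, that broth volume is withdrawn (and replaced by feed) at every
    sampling time, diluting biomass by (1 - v/V_R) per event.
    """
    if t_grid is None:
        t_grid = config.sampling_hours
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 2:
        raise ValueError("t_grid must contain at least two times")
    if t_grid[0] != 0.0 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must increase strictly from 0")

    d = config.dilution_rate
    k_d = config.death_rate
    if c_x0 is None:
        qs0 = d / y_xs_max + maintenance.rate(d)
        c_x0 = d * config.chemostat_feed_g_L / qs0
    if c_x0 <= 0:
        raise InfeasibleStateError("initial biomass must be positive")

    mu_cache = {"mu": d}

    def rhs(t: float, y: np.ndarray) -> list[float]:
        c_x = y[0]
        if c_x <= 0:
            raise InfeasibleStateError("biomass concentration reached zero")
        q_s = d * mixing_vessel_conc(t, config) / c_x
        # mu from the closure may be slightly negative once supply only
        # covers maintenance (endogenous consumption); it is bounded below
        # by -Y*m_S automatically, so no explicit floor is applied.
        mu = solve_mu(q_s, maintenance, y_xs_max, mu_guess=mu_cache["mu"])
        mu_cache["mu"] = mu
        return [(mu - k_d) * c_x]

    events = []
    if config.sample_volume_L > 0:
        events = [t for t in config.sampling_hours if 0.0 < t < t_grid[-1]]
    breakpoints = np.unique(np.concatenate([t_grid, np.asarray(events, float)]))

    c_x_out = np.empty_like(t_grid)
    c_x_out[0] = c_x0
    dilution = 1.0 - config.sample_volume_L / config.reactor_volume_L
    state = c_x0
    t_prev = 0.0
    out_idx = {t: i for i, t in enumerate(t_grid)}
    for t_next in breakpoints[1:]:
        sol = solve_ivp(
            rhs,
            (t_prev, t_next),
            [state],
            method="RK45",
            rtol=rtol,
            atol=atol,
            dense_output=False,
        )
        if not sol.success:
            raise SolverError(f"ODE integration failed: {sol.message}")
        state = float(sol.y[0, -1])
        if t_next in out_idx:
            c_x_out[out_idx[t_next]] = state
        if config.sample_volume_L > 0 and t_next in events:
            state *= dilution
        t_prev = t_next

    c_mix = np.array([mixing_vessel_conc(t, config) for t in t_grid])
    q_s = d * c_mix / c_x_out
    mu = np.empty_like(q_s)
    guess = d
    for i, q in enumerate(q_s):
        guess = solve_mu(q, maintenance, y_xs_max, mu_guess=guess)
        mu[i] = guess
    m_s = np.array([maintenance.rate(m) for m in mu])
    return Trajectory(
        time_h=t_grid,
        c_mix_g_L=c_mix,
        c_x_g_L=c_x_out,
        mu_h=mu,
        q_s_g_g_h=q_s,
        m_s_g_g_h=m_s,
    )


def constant_maintenance_asymptote(config: RetentostatConfig, m_s: float) -> float:
    """Long-run biomass ceiling D * C_feed,retentostat / m_S (death rate 0)."""
    if m_s <= 0:
        raise InfeasibleStateError("asymptote undefined for m_s <= 0")
    return config.dilution_rate * config.retentostat_feed_g_L / m_s


def constant_maintenance_solution(
    t: Union[float, np.ndarray],
    config: RetentostatConfig,
    m_s: float,
    y_xs_max: float,
    c_x0: float,
) -> Union[float, np.ndarray]:
    """Closed-form biomass trajectory for constant maintenance, zero death rate.

    With C_mix(t) = C_new + B e^{-beta t} the balance
    dC_X/dt = Y D C_mix(t) - Y m_S C_X is linear:
    C_X(t) = C_inf + P e^{-beta t} + A e^{-a t}, a = Y m_S,
    C_inf = D C_new / m_S, P = Y D B / (a - beta), A = C_X0 - C_inf - P.

    Used as an independent benchmark for the numerical integrator.
    """
    if config.death_rate != 0:
        raise ValueError("closed form assumes zero death rate")
    t = np.asarray(t, dtype=float)
    a = y_xs_max * m_s
    beta = config.mixing_rate_h
    c_new = config.retentostat_feed_g_L
    b = 0.0 if config.instant_feed_switch else config.chemostat_feed_g_L - c_new
    c_inf = config.dilution_rate * c_new / m_s
    if math.isclose(a, beta, rel_tol=1e-12):
        raise ValueError("degenerate case a == beta not supported")
    p = y_xs_max * config.dilution_rate * b / (a - beta)
    amp = c_x0 - c_inf - p
    out = c_inf + p * np.exp(-beta * t) + amp * np.exp(-a * t)
    return float(out) if out.ndim == 0 else out
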