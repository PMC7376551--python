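"""Recovering growth and uptake rates from measured retentostat biomass.

Between two adjacent sampling points the biomass trajectory is treated as
exponential, giving the interval growth rate mu = ln(C2/C1)/dt.  The
matching uptake rate comes from the substrate balance with the feed averaged
analytically over the interval and the biomass averaged with the logarithmic
mean (the time-average of an exponential segment):

    q_S = D * mean(C_mix) / logmean(C_X1, C_X2).

Sliding a 5-point window over the resulting (mu, q_S) pairs and refitting
the substrate-partition line in each window yields a time-resolved
maintenance-coefficient estimate m_S(t): the window intercept tracks the
maintenance requirement at the growth rates spanned by that window.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import (
    InsufficientDataError,
    InvalidSampleError,
    OrderingError,
)
from .pirt import RatePair
from .retentostat import RetentostatConfig, mixing_vessel_mean

__all__ = [
    "BiomassSample",
    "MsEstimate",
    "interval_rates",
    "moving_window_ms",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BiomassSample:
    """One timestamped biomass dry-weight measurement."""

    time_h: float
    c_x_g_L: float
    viability: Optional[float] = None  # propidium-iodide based fraction
    strain: str = ""
    replicate: int = 0

    def __post_init__(self) -> None:
        if self.time_h < 0:
            raise InvalidSampleError("time must be >= 0")
        if self.c_x_g_L <= 0:
            raise InvalidSampleError("biomass concentration must be positive")
        if self.viability is not None and not 0.0 <= self.viability <= 1.0:
            raise InvalidSampleError("viability must lie in [0, 1]")


@dataclass(frozen=True)
class MsEstimate:
    """Windowed maintenance-coefficient estimate."""

    time_h: float  # mean of member pair midpoints
    m_s: float
    se_m_s: float
    window: int
    pair_indices: tuple[int, ...]
    strain: str = ""
    replicate: int = 0


def _log_mean(a: float, b: float) -> float:
    if a == b:
        return a
    return (b - a) / math.log(b / a)


def interval_rates(
    samples: Sequence[BiomassSample],
    config: RetentostatConfig,
    viability_corrected: bool = False,
) -> list[RatePair]:
    """(mu, q_S) pairs from biomass accumulation between adjacent samples.

    Rates are computed per reactor; pass one replicate's samples at a time.
    With ``viability_corrected`` rates refer to viable biomass (samples must
    then carry viability fractions); off by default since measured viability
    stays near 100%.
    """
    if len(samples) < 2:
        raise InsufficientDataError("at least two samples are required")
    times = [s.time_h for s in samples]
    if any(t1 - t0 <= 0 for t0, t1 in zip(times, times[1:])):
        raise OrderingError("sample times must be strictly increasing")

    def biomass(s: BiomassSample) -> float:
        if not viability_corrected:
            return s.c_x_g_L
        if s.viability is None:
            raise InvalidSampleError("viability correction requires viability data")
        return s.c_x_g_L * s.viability

    pairs: list[RatePair] = []
    for i, (s0, s1) in enumerate(zip(samples, samples[1:])):
        c0, c1 = biomass(s0), biomass(s1)
        dt = s1.time_h - s0.time_h
        mu = math.log(c1 / c0) / dt
        c_mix = mixing_vessel_mean(s0.time_h, s1.time_h, config)
        q_s = config.dilution_rate * c_mix / _log_mean(c0, c1)
        pairs.append(
            RatePair(
                mu_h=mu,
                q_s_g_g_h=q_s,
                source="retentostat-interval",
                time_h=0.5 * (s0.time_h + s1.time_h),
                strain=s0.strain,
                replicate=s0.replicate,
            )
        )
    return pairs


def moving_window_ms(
    pairs: Sequence[RatePair], window: int = 5
) -> list[MsEstimate]:
    """Maintenance coefficient over time from sliding-window regressions.

    Each contiguous window of ``window`` pairs is refit with ordinary least
    squares of q_S on mu; the intercept and its standard error become one
    :class:`MsEstimate`, timestamped at the mean of the member pairs'
    midpoints.  Windows advance one pair at a time.  Windows with no mu
    spread are skipped (logged), not returned as estimates.

    Chemostat-derived pairs may be prepended by the caller so the earliest
    windows are anchored by steady-state data.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    if len(pairs) < window:
        raise InsufficientDataError(
            f"need at least {window} pairs, got {len(pairs)}"
        )
    estimates: list[MsEstimate] = []
    for start in range(len(pairs) - window + 1):
        members = pairs[start : start + window]
        mu = np.array([p.mu_h for p in members])
        qs = np.array([p.q_s_g_g_h for p in members])
        if np.ptp(mu) == 0:
            logger.warning(
                "window %d-%d has no mu spread; skipped", start, start + window - 1
            )
            continue
        res = stats.linregress(mu, qs)
        times = [p.time_h for p in members if p.time_h is not None]
        center = float(np.mean(times)) if times else float("nan")
        estimates.append(
            MsEstimate(
                time_h=center,
                m_s=float(res.intercept),
                se_m_s=float(res.intercept_stderr),
                window=window,
                pair_indices=tuple(range(start, start + window)),
                strain=members[-1].strain,
                replicate=members[-1].replicate,
            )
        )
    return estimates
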