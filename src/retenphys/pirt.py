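"""Maintenance-energy estimation from (mu, q_S) pairs.

The linear substrate-partition model splits glucose consumption into a
growth-proportional term and a growth-independent maintenance term,

    q_S = mu / Y_X/S_max + m_S,

so ordinary least squares of q_S on mu yields the maintenance coefficient
m_S as the intercept and the maximum biomass yield Y_X/S_max as the
reciprocal slope.  The standard error of Y_X/S_max follows from first-order
propagation, SE(1/s) = SE(s)/s^2.

Two-group comparison of replicate physiology values uses the pooled-variance
(Student's) two-sample t test, matching how duplicate cultures are compared
in steady-state physiology tables.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, SingularDesignError

__all__ = ["RatePair", "PirtFit", "fit_pirt", "predict_qs", "compare_groups"]


@dataclass(frozen=True)
class RatePair:
    """One (mu, q_S) observation, from a chemostat steady state or a
    retentostat sampling interval."""

    mu_h: float
    q_s_g_g_h: float
    weight: Optional[float] = None
    source: str = "chemostat"
    time_h: Optional[float] = None
    strain: str = ""
    replicate: int = 0

    def __post_init__(self) -> None:
        if self.q_s_g_g_h <= 0:
            raise ValueError("q_s must be positive")


@dataclass(frozen=True)
class PirtFit:
    """Fitted maintenance coefficient and maximum yield, with uncertainties."""

    m_s: float  # g glucose/(g biomass·h), intercept
    y_xs_max: float  # g biomass/g glucose, 1/slope
    se_m_s: float
    se_y_xs_max: float
    slope: float
    se_slope: float
    n: int
    r_squared: float
    residual_sd: float

    def __post_init__(self) -> None:
        if self.y_xs_max <= 0:
            raise ValueError("fitted maximum yield must be positive")


def fit_pirt(pairs: Sequence[RatePair], on_means: bool = False) -> PirtFit:
    """Least-squares fit of q_S on mu over the given pairs.

    Parameters
    ----------
    pairs : rate pairs; at least two distinct mu values are required.
    on_means : if True, replicate pairs sharing the same mu are averaged
        before fitting (fit on condition means instead of on points).

    A negative fitted intercept is reported as-is with a warning rather than
    clamped: it usually signals either too little mu spread or a maintenance
    requirement below the resolution of the data.
    """
    if len(pairs) < 2:
        raise InsufficientDataError("at least two rate pairs are required")
    mu = np.asarray([p.mu_h for p in pairs], dtype=float)
    qs = np.asarray([p.q_s_g_g_h for p in pairs], dtype=float)
    if on_means:
        keys = np.round(mu, 12)
        uniq = np.unique(keys)
        mu = np.array([mu[keys == k].mean() for k in uniq])
        qs = np.array([qs[keys == k].mean() for k in uniq])
    if np.ptp(mu) == 0:
        raise SingularDesignError("all mu values identical; slope is undefined")
    res = stats.linregress(mu, qs)
    slope = float(res.slope)
    if slope <= 0:
        raise SingularDesignError(
            "fitted slope is non-positive; pairs are inconsistent with a "
            "substrate-partition line"
        )
    n = mu.size
    fitted = res.intercept + slope * mu
    dof = max(n - 2, 1)
    residual_sd = float(np.sqrt(np.sum((qs - fitted) ** 2) / dof))
    m_s = float(res.intercept)
    if m_s < 0:
        warnings.warn(
            f"fitted maintenance coefficient is negative ({m_s:.3g}); "
            "reported unclamped",
            stacklevel=2,
        )
    rvalue = float(res.rvalue) if n > 2 else 1.0
    return PirtFit(
        m_s=m_s,
        y_xs_max=1.0 / slope,
        se_m_s=float(res.intercept_stderr),
        se_y_xs_max=float(res.stderr) / slope**2,
        slope=slope,
        se_slope=float(res.stderr),
        n=int(n),
        r_squared=rvalue**2,
        residual_sd=residual_sd,
    )


def predict_qs(fit: PirtFit, mu: float) -> float:
    """Substrate uptake the fitted partition line predicts at growth rate mu."""
    if mu < 0:
        raise ValueError("mu must be >= 0")
    return mu / fit.y_xs_max + fit.m_s


def compare_groups(
    a: Sequence[float], b: Sequence[float]
) -> tuple[float, float]:
    """Two-sample Student's t test (pooled variance, two-sided).

    Returns (t statistic, p value).  Two zero-variance groups with equal
    means return (0, 1) by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each group needs at least two values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return math.copysign(math.inf, a.mean() - b.mean()), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)
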