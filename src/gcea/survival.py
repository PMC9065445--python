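"""Weibull survival law and per-cycle transition probabilities.

The model's hazard source is the two-parameter Weibull survival function

    S(t) = exp(-lambda * t**gamma)

with *scale* ``lambda`` (units month**-gamma) and *shape* ``gamma``
(dimensionless), the parameterization conventional in Markov
cost-effectiveness models.  Per-cycle transition probabilities follow from
the conditional survival over one cycle,

    P(t) = 1 - exp(lambda * (t-1)**gamma - lambda * t**gamma),

the probability of leaving the state during cycle ``t`` (covering the
interval ``(t-1, t]`` in months) given occupancy at its start.

Maximum-likelihood fitting to right-censored individual patient data,
hazard-ratio adjustment and annual-to-cycle probability conversion live
here as well.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "WeibullParams",
    "BackgroundMortality",
    "DegenerateFitWarning",
    "survival_at",
    "cycle_transition_probability",
    "fit_weibull",
    "apply_hazard_ratio",
    "annual_to_cycle_probability",
]


class DegenerateFitWarning(UserWarning):
    """The likelihood surface is too flat or degenerate for reliable SEs."""


@dataclass(frozen=True)
class WeibullParams:
    """Scale/shape of one survival endpoint of one arm, with uncertainty.

    ``scale_lambda`` and ``shape_gamma`` parameterize
    ``S(t) = exp(-scale_lambda * t**shape_gamma)`` with t in months.
    Standard errors and 95% confidence limits are optional (NaN when the
    parameters are taken from a published table without refitting, or when
    a fit is degenerate).
    """

    scale_lambda: float
    shape_gamma: float
    se_scale: float = float("nan")
    se_shape: float = float("nan")
    ci_scale: tuple[float, float] = (float("nan"), float("nan"))
    ci_shape: tuple[float, float] = (float("nan"), float("nan"))
    label: str = ""

    def __post_init__(self) -> None:
        if not (self.scale_lambda > 0):
            raise ValueError(f"scale_lambda must be > 0, got {self.scale_lambda}")
        if not (self.shape_gamma > 0):
            raise ValueError(f"shape_gamma must be > 0, got {self.shape_gamma}")
        for mean, (lo, hi), name in (
            (self.scale_lambda, self.ci_scale, "scale"),
            (self.shape_gamma, self.ci_shape, "shape"),
        ):
            if np.isfinite(lo) and np.isfinite(hi) and not (lo <= mean <= hi):
                raise ValueError(f"{name} CI ({lo}, {hi}) does not bracket mean {mean}")

    @property
    def median(self) -> float:
        """Analytic median survival time (months): (ln 2 / lambda)**(1/gamma)."""
        return float((np.log(2.0) / self.scale_lambda) ** (1.0 / self.shape_gamma))


@dataclass(frozen=True)
class BackgroundMortality:
    """All-cause death probability per year applied from the PFS state."""

    annual_probability: float = 0.00707

    def __post_init__(self) -> None:
        if not (0.0 <= self.annual_probability <= 1.0):
            raise ValueError("annual_probability must lie in [0, 1]")

    def monthly(self, cycle_length_months: float = 1.0) -> float:
        return annual_to_cycle_probability(self.annual_probability, cycle_length_months)


def survival_at(params: WeibullParams, t):
    """Weibull survival probability S(t) = exp(-lambda t^gamma) at time t (months).

    Accepts a scalar or array of nonnegative times.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be nonnegative")
    out = np.exp(-params.scale_lambda * np.power(t, params.shape_gamma))
    return float(out) if out.ndim == 0 else out


def cycle_transition_probability(params: WeibullParams, cycle_index) -> float:
    """Probability of leaving the state during cycle t, conditional on occupancy.

    ``P(t) = 1 - exp(lambda (t-1)^gamma - lambda t^gamma)``, identically
    ``1 - S(t)/S(t-1)``; cycle ``t >= 1`` covers months ``(t-1, t]``.
    """
    c = np.asarray(cycle_index, dtype=float)
    if np.any(c < 1):
        raise ValueError("cycle_index must be >= 1")
    lam, gam = params.scale_lambda, params.shape_gamma
    out = 1.0 - np.exp(lam * np.power(c - 1.0, gam) - lam * np.power(c, gam))
    return float(out) if out.ndim == 0 else out


def apply_hazard_ratio(params: WeibullParams, hr: float) -> WeibullParams:
    """Proportional-hazards adjustment: scale -> hr*scale, shape unchanged.

    Under a Weibull law a constant hazard ratio preserves the shape and
    multiplies the scale, so that S_hr(t) = S(t)**hr for all t.  Standard
    errors and CIs are dropped (they no longer refer to a fitted quantity).
    """
    if not hr > 0:
        raise ValueError("hazard ratio must be positive")
    return WeibullParams(
        scale_lambda=params.scale_lambda * hr,
        shape_gamma=params.shape_gamma,
        label=f"{params.label}|hr={hr:g}" if params.label else f"hr={hr:g}",
    )


def annual_to_cycle_probability(p_annual: float, cycle_length_months: float) -> float:
    """Convert an annual probability to one for a cycle of the given length.

    Assumes a constant hazard within the year:
    ``1 - (1 - p_annual)**(cycle_length_months / 12)``.
    """
    if not (0.0 <= p_annual < 1.0):
        raise ValueError("p_annual must lie in [0, 1)")
    if not cycle_length_months > 0:
        raise ValueError("cycle_length_months must be positive")
    return 1.0 - (1.0 - p_annual) ** (cycle_length_months / 12.0)


# ---------------------------------------------------------------------------
# Maximum-likelihood fitting


def _neg_loglik_and_grad(theta: np.ndarray, t: np.ndarray, event: np.ndarray):
    """Negative log-likelihood in (log lambda, log gamma) with analytic gradient.

    ll = sum_events [log lam + log gam + (gam-1) log t] - lam * sum_all t^gam
    """
    a, b = theta
    lam, gam = np.exp(a), np.exp(b)
    logt = np.log(t)
    tg = np.power(t, gam)
    d = float(event.sum())
    ll = d * (a + b) + (gam - 1.0) * logt[event].sum() - lam * tg.sum()
    # d ll / d a = d - lam * sum t^gam
    ga = d - lam * tg.sum()
    # d ll / d b = gam * [d/gam + sum_ev log t - lam * sum t^gam log t]
    gb = d + gam * (logt[event].sum() - lam * (tg * logt).sum())
    return -ll, -np.array([ga, gb])


def _numeric_hessian(theta: np.ndarray, t: np.ndarray, event: np.ndarray, h: float = 1e-5):
    """Central-difference Hessian of the negative log-likelihood."""
    n = len(theta)
    H = np.empty((n, n))
    for j in range(n):
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        _, gp = _neg_loglik_and_grad(tp, t, event)
        _, gm = _neg_loglik_and_grad(tm, t, event)
        H[:, j] = (gp - gm) / (2.0 * h)
    return 0.5 * (H + H.T)


def fit_weibull(ipd: pd.DataFrame, label: str = "") -> WeibullParams:
    """Fit S(t) = exp(-lambda t^gamma) to right-censored IPD by maximum likelihood.

    Parameters
    ----------
    ipd : DataFrame with columns ``time_months`` (positive float) and
        ``event`` (1 = event observed, 0 = right-censored).
    label : tag stored on the result.

    Returns
    -------
    WeibullParams with observed-information standard errors (delta method
    from the log-scale fit) and 95% Wald intervals on the log of each
    parameter, hence always-positive confidence limits.

    Raises
    ------
    ValueError for nonpositive times or a dataset with no events.

    Warns with :class:`DegenerateFitWarning` when the observed information
    is not positive definite or the optimum sits on the internal shape
    bounds (e.g. all events at a single time); point estimates are still
    returned, with NaN standard errors.
    """
    t = np.asarray(ipd["time_months"], dtype=float)
    event = np.asarray(ipd["event"]).astype(bool)
    if len(t) == 0:
        raise ValueError("empty dataset")
    if np.any(t <= 0):
        raise ValueError("all times must be positive")
    if event.sum() < 1:
        raise ValueError("at least one event is required to fit a Weibull")

    # moment-style start: exponential rate for lambda, shape 1
    theta0 = np.array([np.log(event.sum() / t.sum()), 0.0])
    bounds = [(-30.0, 10.0), (-4.0, 4.0)]
    res = optimize.minimize(
        _neg_loglik_and_grad,
        theta0,
        args=(t, event),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
    )
    a, b = res.x
    lam, gam = float(np.exp(a)), float(np.exp(b))

    on_bound = any(
        abs(x - lo) < 1e-8 or abs(x - hi) < 1e-8 for x, (lo, hi) in zip(res.x, bounds)
    )
    se_a = se_b = float("nan")
    if on_bound:
        warnings.warn(
            "Weibull fit hit an internal parameter bound; variance is degenerate",
            DegenerateFitWarning,
            stacklevel=2,
        )
    else:
        H = _numeric_hessian(res.x, t, event)
        try:
            cov = np.linalg.inv(H)
            if np.any(np.diag(cov) <= 0):
                raise np.linalg.LinAlgError
            se_a, se_b = np.sqrt(np.diag(cov))
        except np.linalg.LinAlgError:
            warnings.warn(
                "observed information not positive definite; SEs unavailable",
                DegenerateFitWarning,
                stacklevel=2,
            )

    z = 1.959963984540054
    ci_scale = (lam * np.exp(-z * se_a), lam * np.exp(z * se_a)) if np.isfinite(se_a) else (np.nan, np.nan)
    ci_shape = (gam * np.exp(-z * se_b), gam * np.exp(z * se_b)) if np.isfinite(se_b) else (np.nan, np.nan)
    return WeibullParams(
        scale_lambda=lam,
        shape_gamma=gam,
        se_scale=lam * se_a if np.isfinite(se_a) else float("nan"),
        se_shape=gam * se_b if np.isfinite(se_b) else float("nan"),
        ci_scale=tuple(float(x) for x in ci_scale),
        ci_shape=tuple(float(x) for x in ci_shape),
        label=label,
    )
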