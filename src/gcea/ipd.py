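"""Pseudo individual-patient data: simulation, Kaplan-Meier, reconstruction.

Published trial reports rarely deposit per-patient survival times; health
economic models instead digitize the Kaplan-Meier figures and rebuild
"pseudo-IPD" consistent with the curve and its numbers-at-risk table.
This module provides the full loop so every downstream stage is testable
without any external data:

* :func:`simulate_ipd` draws event/censoring times from a Weibull law
  (inverse transform) with exponential dropout and administrative
  censoring, standing in for the trial cohort;
* :func:`km_estimate` produces a digitized-curve surrogate (survival on a
  regular grid plus a numbers-at-risk table) from IPD;
* :func:`reconstruct_ipd` inverts a digitized curve back to pseudo-IPD by
  deterministic interval allocation, a simplified variant of the Guyot
  algorithm.

IPD is carried as a pandas DataFrame with columns ``time_months`` (float),
``event`` (0/1), ``arm`` (str) and ``endpoint`` ("PFS" | "OS").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .survival import WeibullParams

__all__ = [
    "DigitizedCurve",
    "simulate_ipd",
    "km_estimate",
    "reconstruct_ipd",
    "read_ipd_csv",
    "write_ipd_csv",
]

IPD_COLUMNS = ["time_months", "event", "arm", "endpoint"]


@dataclass(frozen=True)
class DigitizedCurve:
    """Survival read off a Kaplan-Meier figure plus its risk table.

    ``times`` start at 0 with ``survival[0] == 1``; ``risk_times`` start at
    0 with ``numbers_at_risk[0] == n0``.  Both survival and numbers at risk
    are non-increasing.
    """

    times: np.ndarray
    survival: np.ndarray
    risk_times: np.ndarray
    numbers_at_risk: np.ndarray
    n0: int
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "survival", np.asarray(self.survival, dtype=float))
        object.__setattr__(self, "risk_times", np.asarray(self.risk_times, dtype=float))
        object.__setattr__(
            self, "numbers_at_risk", np.asarray(self.numbers_at_risk, dtype=int)
        )
        if self.times[0] != 0 or abs(self.survival[0] - 1.0) > 1e-12:
            raise ValueError("curve must start at (t=0, S=1)")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival must be non-increasing")
        if self.numbers_at_risk[0] != self.n0:
            raise ValueError("numbers_at_risk[0] must equal n0")
        if np.any(np.diff(self.numbers_at_risk) > 0):
            raise ValueError("numbers at risk must be non-increasing")

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """(curve, risk table) as DataFrames for CSV export."""
        curve = pd.DataFrame({"time_months": self.times, "survival": self.survival})
        risk = pd.DataFrame(
            {"time_months": self.risk_times, "n_at_risk": self.numbers_at_risk}
        )
        return curve, risk


def simulate_ipd(
    params: WeibullParams,
    n: int,
    admin_censor_time: float = 36.0,
    dropout_annual_prob: float = 0.0,
    seed: int | np.random.Generator = 0,
    arm: str = "",
    endpoint: str = "OS",
) -> pd.DataFrame:
    """Draw n subjects from a Weibull event-time law with censoring.

    Event times use the inverse transform ``t = (-ln U / lambda)**(1/gamma)``;
    dropout is exponential at the given annual probability; whichever of
    event, dropout and administrative censoring at ``admin_censor_time``
    comes first determines the record.  A fixed seed gives an identical
    dataset.
    """
    if n < 0:
        raise ValueError("n must be nonnegative")
    if not admin_censor_time > 0:
        raise ValueError("admin_censor_time must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = rng.uniform(size=n)
    t_event = np.power(
        -np.log(u) / params.scale_lambda, 1.0 / params.shape_gamma
    )
    if dropout_annual_prob > 0:
        monthly_rate = -np.log1p(-dropout_annual_prob) / 12.0
        t_drop = rng.exponential(1.0 / monthly_rate, size=n)
    else:
        t_drop = np.full(n, np.inf)
    t_cens = np.minimum(t_drop, admin_censor_time)
    time = np.minimum(t_event, t_cens)
    event = t_event <= t_cens
    return pd.DataFrame(
        {
            "time_months": time,
            "event": event.astype(int),
            "arm": arm,
            "endpoint": endpoint,
        }
    )


def km_estimate(
    ipd: pd.DataFrame,
    grid_step: float = 1.0,
    risk_step: float = 3.0,
    max_time: float | None = None,
    label: str = "",
) -> DigitizedCurve:
    """Product-limit estimate of IPD, sampled the way a figure is digitized.

    Survival is evaluated on a regular grid (default monthly) and the
    numbers-at-risk table on a coarser grid (default every 3 months),
    mirroring a typical trial figure.
    """
    if len(ipd) == 0:
        raise ValueError("empty dataset")
    t = np.asarray(ipd["time_months"], dtype=float)
    event = np.asarray(ipd["event"]).astype(bool)
    if max_time is None:
        max_time = float(t.max())
    # risk grid covers the full follow-up so the curve is fully constrained
    n_risk_steps = int(np.ceil(max_time / risk_step - 1e-9))
    risk_times = np.arange(n_risk_steps + 1) * risk_step
    grid = np.arange(0.0, risk_times[-1] + grid_step / 2, grid_step)
    if grid[-1] < risk_times[-1] - 1e-9:  # non-commensurate steps
        grid = np.append(grid, risk_times[-1])

    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=event)
    surv = kmf.survival_function_at_times(grid).to_numpy()
    n_at_risk = np.array([(t >= tau - 1e-12).sum() for tau in risk_times])
    return DigitizedCurve(
        times=grid,
        survival=surv,
        risk_times=risk_times,
        numbers_at_risk=n_at_risk,
        n0=len(ipd),
        label=label,
    )


def reconstruct_ipd(
    curve: DigitizedCurve, arm: str = "", endpoint: str = "OS"
) -> pd.DataFrame:
    """Rebuild pseudo-IPD from a digitized curve by interval allocation.

    Within each risk-table interval, integer event counts at the digitized
    times are chosen to match the survival drops under the product-limit
    relation, and the censoring count is iterated until the number at risk
    at the interval end matches the risk table exactly; censoring times are
    spread uniformly over the interval.  The procedure is deterministic.
    Subjects still at risk after the last digitized time are censored
    there, so the output always contains exactly ``n0`` records.
    """
    if len(curve.risk_times) < 2:
        raise ValueError("risk table must define at least one interval")
    times, surv = curve.times, curve.survival
    records: list[tuple[float, int]] = []
    n_cur = int(curve.n0)
    s_km = 1.0  # running product-limit value of the reconstruction

    for k in range(len(curve.risk_times) - 1):
        lo, hi = curve.risk_times[k], curve.risk_times[k + 1]
        n_target = int(curve.numbers_at_risk[k + 1])
        sel = (times > lo + 1e-9) & (times <= hi + 1e-9)
        tj = times[sel]
        sj = surv[sel]

        c_k = 0
        best = None
        for _ in range(40):  # iterate censoring count until the risk table matches
            n_it, s_it = n_cur, s_km
            events: list[tuple[float, int]] = []
            cens_alloc = _spread(c_k, lo, hi)
            ci = 0
            for t_j, s_target in zip(tj, sj):
                # censorings occurring before this grid time leave the risk set
                while ci < c_k and cens_alloc[ci] <= t_j:
                    n_it -= 1
                    ci += 1
                if n_it <= 0 or s_it <= 0:
                    break
                d_j = int(round(n_it * (1.0 - s_target / s_it)))
                d_j = min(max(d_j, 0), n_it)
                if d_j > 0:
                    s_it *= 1.0 - d_j / n_it
                    n_it -= d_j
                    # a drop read off at t_j reflects events during the
                    # preceding digitization step; midpoint placement avoids
                    # biasing downstream fits late
                    prev = times[times < t_j - 1e-9]
                    step = t_j - (prev[-1] if len(prev) else 0.0)
                    events.append((t_j - 0.5 * step, d_j))
            n_it -= c_k - ci  # censorings after the last grid time in interval
            best = (events, cens_alloc, n_it, s_it)
            if n_it == n_target:
                break
            c_next = c_k + (n_it - n_target)
            if c_next < 0 or c_next > n_cur:
                break
            if c_next == c_k:
                break
            c_k = c_next

        events, cens_alloc, n_it, s_it = best
        records.extend((t_j, 1) for t_j, d in events for _ in range(d))
        records.extend((tc, 0) for tc in cens_alloc)
        n_cur, s_km = max(n_it, 0), max(s_it, 0.0)

    if n_cur > 0:  # administratively censored at end of follow-up
        records.extend((float(curve.risk_times[-1]), 0) for _ in range(n_cur))

    out = pd.DataFrame(records, columns=["time_months", "event"])
    out["time_months"] = out["time_months"].clip(lower=1e-6)
    out["arm"] = arm
    out["endpoint"] = endpoint
    return out.sort_values("time_months", ignore_index=True)


def _spread(count: int, lo: float, hi: float) -> np.ndarray:
    """Place `count` censoring times uniformly over (lo, hi]."""
    if count <= 0:
        return np.empty(0)
    return lo + (np.arange(count) + 0.5) / count * (hi - lo)


def read_ipd_csv(path) -> pd.DataFrame:
    ipd = pd.read_csv(path)
    missing = set(IPD_COLUMNS) - set(ipd.columns)
    if missing:
        raise ValueError(f"IPD CSV missing columns: {sorted(missing)}")
    return ipd


def write_ipd_csv(ipd: pd.DataFrame, path) -> None:
    ipd.to_csv(path, index=False, columns=IPD_COLUMNS)
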