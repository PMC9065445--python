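"""Deterministic and probabilistic sensitivity analysis, CEAC, price search.

* One-way deterministic analysis re-runs the full base case with each
  parameter at its lower and upper plausible bound (tornado diagram).
* Probabilistic analysis jointly redraws all non-fixed parameters --
  triangular distributions for costs and body surface area, beta
  (method-of-moments from mean and range-implied SD) for incidences and
  utilities -- and records each draw's incremental cost and QALYs.
* The cost-effectiveness acceptability curve (CEAC) is the fraction of
  draws with positive incremental net monetary benefit, w*dQALY - dCost,
  over a willingness-to-pay grid.
* The threshold-price search bisects a multiplier on the nivolumab unit
  price until the deterministic ICER equals a target willingness-to-pay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import ParamSpecConfig, RunConfig, get_path, set_path
from .model import run_base_case

__all__ = [
    "TornadoEntry",
    "PSASample",
    "CEACPoint",
    "ThresholdResult",
    "one_way_dsa",
    "sample_parameter",
    "run_psa",
    "ceac",
    "threshold_price",
    "DEFAULT_WTP_GRID",
]

#: default willingness-to-pay grid, USD/QALY
DEFAULT_WTP_GRID = np.arange(0, 400_001, 5_000, dtype=float)


@dataclass(frozen=True)
class TornadoEntry:
    name: str
    icer_at_low: float
    icer_at_high: float
    base_icer: float

    @property
    def span(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)


@dataclass(frozen=True)
class PSASample:
    draw: int
    values: dict[str, float]
    delta_cost: float
    delta_qaly: float


@dataclass(frozen=True)
class CEACPoint:
    wtp: float
    probability: float


@dataclass(frozen=True)
class ThresholdResult:
    multiplier: float          # fraction of the current price
    reduction: float           # 1 - multiplier
    icer_at_multiplier: float
    converged: bool


def _rerun_at(cfg: RunConfig, overrides: dict[str, float]):
    trial = cfg.model_copy(deep=True)
    for path, value in overrides.items():
        set_path(trial, path, value)
    return run_base_case(trial)


def one_way_dsa(
    cfg: RunConfig, specs: list[ParamSpecConfig] | None = None
) -> list[TornadoEntry]:
    """Re-run the model at each parameter's bounds; sort by descending span."""
    if specs is None:
        specs = cfg.sensitivity.parameters
    base = run_base_case(cfg).incremental.icer
    entries = []
    for spec in specs:
        lo = _rerun_at(cfg, {spec.path: spec.low}).incremental.icer
        hi = _rerun_at(cfg, {spec.path: spec.high}).incremental.icer
        entries.append(TornadoEntry(spec.name, lo, hi, base))
    entries.sort(key=lambda e: (-e.span, e.name))  # name breaks exact ties
    return entries


def sample_parameter(
    spec: ParamSpecConfig, base: float, rng: np.random.Generator
) -> float:
    """One random draw of a parameter according to its assigned distribution.

    Triangle(low, mode=base, high) for costs and body surface area; Beta
    with mean=base and sd=(high-low)/(2*1.96) (the range read as a 95%
    interval), shapes by method of moments, for probabilities and
    utilities; Fixed returns the base value.
    """
    if spec.distribution == "fixed":
        return base
    if spec.distribution == "triangle":
        width = spec.high - spec.low
        if width <= 0:
            return base
        c = (base - spec.low) / width
        return float(stats.triang.ppf(rng.uniform(), c, loc=spec.low, scale=width))
    # beta
    mean = base
    sd = (spec.high - spec.low) / (2.0 * 1.959963984540054)
    var = sd * sd
    if var >= mean * (1.0 - mean) or var <= 0:
        raise ValueError(
            f"beta moments infeasible for {spec.name!r}: mean={mean}, sd={sd}"
        )
    nu = mean * (1.0 - mean) / var - 1.0
    a, b = mean * nu, (1.0 - mean) * nu
    return float(stats.beta.ppf(rng.uniform(), a, b))


def run_psa(
    cfg: RunConfig,
    n_draws: int = 1000,
    seed: int = 0,
    specs: list[ParamSpecConfig] | None = None,
) -> list[PSASample]:
    """Monte-Carlo parameter uncertainty: jointly redraw all sampled inputs."""
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if specs is None:
        specs = cfg.sensitivity.parameters
    sampled = [s for s in specs if s.distribution != "fixed"]
    bases = {s.path: float(get_path(cfg, s.path)) for s in sampled}
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_draws):
        values = {
            s.path: sample_parameter(s, bases[s.path], rng) for s in sampled
        }
        res = _rerun_at(cfg, values)
        out.append(
            PSASample(
                draw=i,
                values=values,
                delta_cost=res.incremental.delta_cost,
                delta_qaly=res.incremental.delta_qaly,
            )
        )
    return out


def psa_frame(samples: list[PSASample]) -> pd.DataFrame:
    rows = [
        {"draw": s.draw, "delta_cost": s.delta_cost, "delta_qaly": s.delta_qaly}
        for s in samples
    ]
    return pd.DataFrame(rows)


def ceac(samples: list[PSASample], wtp_grid=None) -> list[CEACPoint]:
    """P(cost-effective) = fraction of draws with w*dQALY - dCost > 0."""
    if not samples:
        raise ValueError("no PSA samples")
    if wtp_grid is None:
        wtp_grid = DEFAULT_WTP_GRID
    dc = np.array([s.delta_cost for s in samples])
    dq = np.array([s.delta_qaly for s in samples])
    return [
        CEACPoint(float(w), float(np.mean(w * dq - dc > 0))) for w in wtp_grid
    ]


def threshold_price(
    cfg: RunConfig,
    target_wtp: float,
    drug: str = "nivolumab",
    tol: float = 1.0,
    max_iter: int = 200,
) -> ThresholdResult:
    """Bisection on a price multiplier m in [0, 1] so that ICER(m) = target.

    The drug's cost enters the incremental cost linearly, so the ICER is
    monotone increasing in m and the root (when bracketed) is unique.
    Returns ``converged=False`` with m=0 when the strategy is still above
    the target even at zero drug price.
    """
    if target_wtp <= 0:
        raise ValueError("target_wtp must be positive")
    path = f"economics.drug_prices.{drug}.price_usd"
    base_price = float(get_path(cfg, path))

    def icer_at(m: float) -> float:
        return _rerun_at(cfg, {path: m * base_price}).incremental.icer

    lo, hi = 0.0, 1.0
    f_lo, f_hi = icer_at(lo), icer_at(hi)
    if f_hi <= target_wtp:  # already cost-effective at full price
        return ThresholdResult(1.0, 0.0, f_hi, True)
    if f_lo >= target_wtp:  # unattainable even free of charge
        return ThresholdResult(0.0, 1.0, f_lo, False)
    m, f_m = 0.5, icer_at(0.5)
    for _ in range(max_iter):
        if abs(f_m - target_wtp) <= tol:
            break
        if f_m < target_wtp:
            lo = m
        else:
            hi = m
        m = 0.5 * (lo + hi)
        f_m = icer_at(m)
    return ThresholdResult(m, 1.0 - m, f_m, abs(f_m - target_wtp) <= tol)
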