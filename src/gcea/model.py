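"""Base-case pipeline: configuration -> traces -> costs/QALYs -> ICER."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .config import RunConfig
from .economics import CEResult, ICERResult, accumulate, icer
from .markov import CohortTrace, run_cohort

__all__ = ["BaseCaseResult", "run_strategy", "run_base_case"]


@dataclass(frozen=True)
class BaseCaseResult:
    """Both strategies' discounted totals and their incremental comparison."""

    intervention: CEResult
    comparator: CEResult
    incremental: ICERResult
    traces: dict[str, CohortTrace]

    def summary_frame(self) -> pd.DataFrame:
        """Cost/effectiveness table mirroring the published result layout."""
        rows = []
        for r in (self.intervention, self.comparator):
            rows.append(
                {
                    "strategy": r.strategy,
                    "cost_pfs": r.cost_pfs,
                    "cost_pd": r.cost_pd,
                    "cost_total": r.cost_total,
                    "qaly_pfs": r.qaly_pfs,
                    "qaly_pd": r.qaly_pd,
                    "qaly_total": r.qaly_total,
                }
            )
        df = pd.DataFrame(rows)
        df["delta_cost"] = [self.incremental.delta_cost, None]
        df["delta_qaly"] = [self.incremental.delta_qaly, None]
        df["icer"] = [self.incremental.icer, None]
        return df


def run_strategy(cfg: RunConfig, key: str) -> tuple[CohortTrace, CEResult]:
    """Cohort trace and discounted totals for one strategy."""
    model_cfg = cfg.model.build()
    trace = run_cohort(cfg.strategies[key].build(), model_cfg)
    result = accumulate(trace, cfg.build_arm(key), cfg.economics.build())
    return trace, result


def run_base_case(cfg: RunConfig) -> BaseCaseResult:
    """Run intervention and comparator and compare them incrementally."""
    traces: dict[str, CohortTrace] = {}
    results: dict[str, CEResult] = {}
    for key in (cfg.intervention, cfg.comparator):
        traces[key], results[key] = run_strategy(cfg, key)
    return BaseCaseResult(
        intervention=results[cfg.intervention],
        comparator=results[cfg.comparator],
        incremental=icer(results[cfg.intervention], results[cfg.comparator]),
        traces=traces,
    )
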