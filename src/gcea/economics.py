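"""Costs and QALYs over a cohort trace, and incremental results.

All monetary values are 2020 US dollars.  Accounting conventions:

* Progression-free (PFS) state time accrues first-line drug acquisition
  costs (while on treatment), routine follow-up and tests/examinations,
  and utility ``u_pfs``; the one-off expected cost of serious adverse
  events (SAEs) is charged at model entry and booked to the PFS bucket.
* Progressed (PD) state time accrues salvage therapy, supportive care and
  follow-up, and utility ``u_pd``; terminal care is charged to each
  cycle's increment of death occupancy (expected-value accounting),
  discounted at that cycle, and booked to the PD bucket.
* Drug dosing uses the reference patient (65 kg, 1.64 m, BSA 1.72 m^2);
  acquisition cost is fractional (per-mg) by default with optional
  whole-vial rounding.  A per-administration schedule (e.g. every 21
  days) is converted to the monthly cycle via the mean month length
  365.25/12 days.
* First-line treatment duration may be capped at a maximum number of
  administrations per regimen, reflecting the finite median number of
  treatment cycles delivered in the trial; the cap is prorated within
  the month where it falls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import ceil

import numpy as np

from .markov import CohortTrace
from .survival import WeibullParams, survival_at

__all__ = [
    "DAYS_PER_MONTH",
    "PatientProfile",
    "DrugPrice",
    "RegimenComponent",
    "Regimen",
    "SAEProfile",
    "EconomicInputs",
    "ArmEconomics",
    "CEResult",
    "ICERResult",
    "dose_amount",
    "regimen_cost_per_model_cycle",
    "expected_sae_cost",
    "accumulate",
    "icer",
]

DAYS_PER_MONTH = 365.25 / 12.0


@dataclass(frozen=True)
class PatientProfile:
    """Reference patient used for all dosing arithmetic."""

    weight_kg: float = 65.0
    height_m: float = 1.64
    bsa_m2: float = 1.72

    def __post_init__(self) -> None:
        if min(self.weight_kg, self.height_m, self.bsa_m2) <= 0:
            raise ValueError("patient measurements must be positive")


@dataclass(frozen=True)
class DrugPrice:
    """Acquisition price of one pack/vial of a drug."""

    pack_size_mg: float
    price_usd: float

    def __post_init__(self) -> None:
        if self.pack_size_mg <= 0 or self.price_usd < 0:
            raise ValueError("invalid drug price")


@dataclass(frozen=True)
class RegimenComponent:
    """One drug within a regimen.

    ``dose`` is per administration-day in mg (``basis='flat'``) or
    mg/m^2 (``basis='per_m2'``); ``doses_per_admin`` counts how many such
    doses one administration cycle delivers (capecitabine: twice daily for
    14 days = 28).
    """

    drug: str
    dose: float
    basis: str = "flat"  # 'flat' | 'per_m2'
    doses_per_admin: int = 1

    def __post_init__(self) -> None:
        if self.dose <= 0 or self.doses_per_admin <= 0:
            raise ValueError("doses must be positive")
        if self.basis not in ("flat", "per_m2"):
            raise ValueError(f"unknown dose basis {self.basis!r}")


@dataclass(frozen=True)
class Regimen:
    """A schedule of components administered every ``admin_interval_days``.

    ``max_admin_count`` caps the number of administrations delivered
    (None = until progression).
    """

    name: str
    components: tuple[RegimenComponent, ...]
    admin_interval_days: float
    max_admin_count: int | None = None

    def __post_init__(self) -> None:
        if self.admin_interval_days <= 0:
            raise ValueError("admin_interval_days must be positive")

    @property
    def max_months(self) -> float:
        if self.max_admin_count is None:
            return float("inf")
        return self.max_admin_count * self.admin_interval_days / DAYS_PER_MONTH


@dataclass(frozen=True)
class SAEProfile:
    """Grade >=3 serious adverse events: unit management costs and incidences."""

    unit_costs: dict[str, float]
    incidence: dict[str, float]

    def __post_init__(self) -> None:
        for name, p in self.incidence.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"SAE incidence for {name} outside [0, 1]")
            if name not in self.unit_costs:
                raise ValueError(f"no unit cost for SAE {name!r}")


@dataclass(frozen=True)
class EconomicInputs:
    """Unit prices, per-cycle costs, one-off costs and utilities."""

    drug_prices: dict[str, DrugPrice]
    salvage_per_cycle: float = 478.82
    followup_per_cycle: float = 80.71
    tests_per_cycle: float = 141.29
    supportive_per_cycle: float = 164.57
    terminal_care: float = 1460.30
    u_pfs: float = 0.797
    u_pd: float = 0.577
    profile: PatientProfile = field(default_factory=PatientProfile)
    vial_rounding: bool = False

    def __post_init__(self) -> None:
        costs = (
            self.salvage_per_cycle,
            self.followup_per_cycle,
            self.tests_per_cycle,
            self.supportive_per_cycle,
            self.terminal_care,
        )
        if any(c < 0 for c in costs):
            raise ValueError("costs must be nonnegative")
        if not (0.0 <= self.u_pd <= 1.0 and 0.0 <= self.u_pfs <= 1.0):
            raise ValueError("utilities must lie in [0, 1]")
        if self.u_pfs <= self.u_pd:
            # expected in the base case; tolerated for joint sensitivity draws
            logging.getLogger(__name__).debug(
                "u_pfs (%.3f) <= u_pd (%.3f) in this input set", self.u_pfs, self.u_pd
            )


@dataclass(frozen=True)
class ArmEconomics:
    """First-line regimens, SAE profile and treatment exposure of one strategy.

    ``exposure`` is the time-on-first-line-treatment law.  Treatment
    delivery is an observed trial quantity (patients treated until
    progression, capped at the median number of treatment cycles), so it
    is carried separately from the survival extrapolation: scanning the
    PFS curve in sensitivity analysis changes health-state occupancy but
    not how much drug was delivered.  When None, drug costs accrue on the
    trace's PFS occupancy directly.
    """

    label: str
    regimens: tuple[Regimen, ...]
    sae: SAEProfile
    exposure: "WeibullParams | None" = None


@dataclass(frozen=True)
class CEResult:
    """Discounted cost and QALY totals for one strategy (Table-3 layout)."""

    strategy: str
    cost_pfs: float
    cost_pd: float
    qaly_pfs: float
    qaly_pd: float

    @property
    def cost_total(self) -> float:
        return self.cost_pfs + self.cost_pd

    @property
    def qaly_total(self) -> float:
        return self.qaly_pfs + self.qaly_pd


@dataclass(frozen=True)
class ICERResult:
    delta_cost: float
    delta_qaly: float
    icer: float | None
    classification: str  # 'ratio' | 'dominant' | 'dominated' | 'undefined'


def dose_amount(component: RegimenComponent, profile: PatientProfile) -> float:
    """Total mg of a component delivered per administration cycle."""
    if component.basis == "per_m2":
        if profile.bsa_m2 <= 0:
            raise ValueError("body surface area must be positive")
        per_dose = component.dose * profile.bsa_m2
    else:
        per_dose = component.dose
    return per_dose * component.doses_per_admin


def _acquisition_cost(mg: float, price: DrugPrice, vial_rounding: bool) -> float:
    packs = mg / price.pack_size_mg
    if vial_rounding:
        packs = ceil(packs - 1e-9)
    return packs * price.price_usd


def regimen_cost_per_model_cycle(
    regimen: Regimen,
    prices: dict[str, DrugPrice],
    profile: PatientProfile,
    cycle_length_months: float = 1.0,
    vial_rounding: bool = False,
) -> float:
    """Drug cost of one regimen per model cycle (USD/month for 1-month cycles).

    The per-administration cost is scaled by cycle days / interval days,
    spreading a q2w/q3w schedule evenly over calendar time.
    """
    per_admin = 0.0
    for comp in regimen.components:
        try:
            price = prices[comp.drug]
        except KeyError:
            raise KeyError(f"no price configured for drug {comp.drug!r}") from None
        per_admin += _acquisition_cost(
            dose_amount(comp, profile), price, vial_rounding
        )
    return per_admin * cycle_length_months * DAYS_PER_MONTH / regimen.admin_interval_days


def expected_sae_cost(sae: SAEProfile) -> float:
    """One-off expected SAE management cost: sum of incidence x unit cost."""
    return sum(sae.incidence[k] * sae.unit_costs[k] for k in sae.incidence)


def accumulate(trace: CohortTrace, arm: ArmEconomics, inputs: EconomicInputs) -> CEResult:
    """Fold a cohort trace into discounted costs and QALYs for one strategy."""
    cfg = trace.config
    cl = cfg.cycle_length_months
    pfs_time = trace.corrected[:, 0] * trace.discount  # discounted months in PFS
    pd_time = trace.corrected[:, 1] * trace.discount
    deaths = trace.death_increments * trace.discount

    months_pfs = float(pfs_time.sum()) * cl
    months_pd = float(pd_time.sum()) * cl

    qaly_pfs = months_pfs * inputs.u_pfs / 12.0
    qaly_pd = months_pd * inputs.u_pd / 12.0

    # first-line drugs: accrue on time-on-treatment up to each regimen's
    # duration cap, prorated within the cycle where the cap falls
    if arm.exposure is not None:
        grid = np.arange(cfg.horizon_cycles + 1) * cl
        s_exp = survival_at(arm.exposure, grid)
        exp_time = 0.5 * (s_exp[:-1] + s_exp[1:]) * trace.discount \
            if cfg.half_cycle_correction else s_exp[1:] * trace.discount
    else:
        exp_time = pfs_time
    drug_cost = 0.0
    cycle_start = np.arange(cfg.horizon_cycles) * cl
    for reg in arm.regimens:
        monthly = regimen_cost_per_model_cycle(
            reg, inputs.drug_prices, inputs.profile, cl, inputs.vial_rounding
        )
        treated_frac = np.clip((reg.max_months - cycle_start) / cl, 0.0, 1.0)
        drug_cost += monthly * float((exp_time * treated_frac).sum())

    cost_pfs = (
        drug_cost
        + months_pfs * (inputs.tests_per_cycle + inputs.followup_per_cycle) / cl
        + expected_sae_cost(arm.sae)
    )
    cost_pd = (
        months_pd
        * (inputs.salvage_per_cycle + inputs.supportive_per_cycle + inputs.followup_per_cycle)
        / cl
        + float(deaths.sum()) * inputs.terminal_care
    )
    return CEResult(
        strategy=arm.label,
        cost_pfs=cost_pfs,
        cost_pd=cost_pd,
        qaly_pfs=qaly_pfs,
        qaly_pd=qaly_pd,
    )


def icer(a: CEResult, b: CEResult) -> ICERResult:
    """Incremental cost-effectiveness of strategy a over comparator b."""
    d_cost = a.cost_total - b.cost_total
    d_qaly = a.qaly_total - b.qaly_total
    if abs(d_qaly) < 1e-12:
        return ICERResult(d_cost, d_qaly, None, "undefined")
    if d_cost < 0 and d_qaly > 0:
        return ICERResult(d_cost, d_qaly, None, "dominant")
    if d_cost > 0 and d_qaly < 0:
        return ICERResult(d_cost, d_qaly, None, "dominated")
    return ICERResult(d_cost, d_qaly, d_cost / d_qaly, "ratio")
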