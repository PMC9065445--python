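"""Declarative run configuration: schema, bundled base case, path overrides.

Every number the model uses -- Weibull parameters per arm and endpoint,
unit prices, per-cycle costs, SAE incidences, utilities, regimen schedules,
the discount rate and the willingness-to-pay threshold -- lives in a single
YAML document validated against the pydantic schema below.  The bundled
``data/base_case.yaml`` reproduces the published base case, so running the
model "as published" needs no user input.

Sensitivity analyses address individual inputs by dotted path
(``economics.drug_prices.nivolumab.price_usd``); :func:`set_path` /
:func:`get_path` implement that traversal over the validated model.
"""

from __future__ import annotations

import hashlib
from importlib import resources
from typing import Literal

import yaml
from pydantic import BaseModel, Field, model_validator

from . import economics as econ
from . import markov, survival

__all__ = [
    "RunConfig",
    "load_config",
    "default_config",
    "get_path",
    "set_path",
    "config_hash",
]


class WeibullSpec(BaseModel):
    scale_lambda: float = Field(gt=0)
    shape_gamma: float = Field(gt=0)
    se_scale: float | None = None
    se_shape: float | None = None
    ci_scale: tuple[float, float] | None = None
    ci_shape: tuple[float, float] | None = None

    def build(self, label: str = "") -> survival.WeibullParams:
        nan = float("nan")
        return survival.WeibullParams(
            scale_lambda=self.scale_lambda,
            shape_gamma=self.shape_gamma,
            se_scale=self.se_scale if self.se_scale is not None else nan,
            se_shape=self.se_shape if self.se_shape is not None else nan,
            ci_scale=tuple(self.ci_scale) if self.ci_scale else (nan, nan),
            ci_shape=tuple(self.ci_shape) if self.ci_shape else (nan, nan),
            label=label,
        )


class StrategySpec(BaseModel):
    label: str
    n: int = Field(ge=0)
    pfs: WeibullSpec
    os: WeibullSpec

    def build(self) -> markov.StrategyCurves:
        return markov.StrategyCurves(
            pfs=self.pfs.build(f"{self.label} PFS"),
            os=self.os.build(f"{self.label} OS"),
            label=self.label,
        )


class ModelSpec(BaseModel):
    cycle_length_months: float = 1.0
    horizon_cycles: int = 60
    annual_discount_rate: float = Field(default=0.03, ge=0.0, le=0.08)
    half_cycle_correction: bool = True
    background_mortality_annual: float = Field(default=0.00707, ge=0.0, le=1.0)

    def build(self) -> markov.ModelConfig:
        return markov.ModelConfig(
            cycle_length_months=self.cycle_length_months,
            horizon_cycles=self.horizon_cycles,
            annual_discount_rate=self.annual_discount_rate,
            half_cycle_correction=self.half_cycle_correction,
            background_mortality=survival.BackgroundMortality(
                self.background_mortality_annual
            ),
        )


class ProfileSpec(BaseModel):
    weight_kg: float = Field(default=65.0, gt=0)
    height_m: float = Field(default=1.64, gt=0)
    bsa_m2: float = Field(default=1.72, gt=0)


class DrugPriceSpec(BaseModel):
    pack_size_mg: float = Field(gt=0)
    price_usd: float = Field(ge=0)


class EconomicsSpec(BaseModel):
    profile: ProfileSpec = ProfileSpec()
    drug_prices: dict[str, DrugPriceSpec]
    salvage_per_cycle: float = Field(ge=0)
    followup_per_cycle: float = Field(ge=0)
    tests_per_cycle: float = Field(ge=0)
    supportive_per_cycle: float = Field(ge=0)
    terminal_care: float = Field(ge=0)
    u_pfs: float = Field(ge=0, le=1)
    u_pd: float = Field(ge=0, le=1)
    vial_rounding: bool = False
    sae_unit_costs: dict[str, float]

    @model_validator(mode="after")
    def _utility_ordering(self) -> "EconomicsSpec":
        if self.u_pfs <= self.u_pd:
            raise ValueError("u_pfs must exceed u_pd in the configured base case")
        return self

    def build(self) -> econ.EconomicInputs:
        return econ.EconomicInputs(
            drug_prices={
                k: econ.DrugPrice(v.pack_size_mg, v.price_usd)
                for k, v in self.drug_prices.items()
            },
            salvage_per_cycle=self.salvage_per_cycle,
            followup_per_cycle=self.followup_per_cycle,
            tests_per_cycle=self.tests_per_cycle,
            supportive_per_cycle=self.supportive_per_cycle,
            terminal_care=self.terminal_care,
            u_pfs=self.u_pfs,
            u_pd=self.u_pd,
            profile=econ.PatientProfile(
                self.profile.weight_kg, self.profile.height_m, self.profile.bsa_m2
            ),
            vial_rounding=self.vial_rounding,
        )


class ComponentSpec(BaseModel):
    drug: str
    dose: float = Field(gt=0)
    basis: Literal["flat", "per_m2"] = "flat"
    doses_per_admin: int = Field(default=1, ge=1)


class RegimenSpec(BaseModel):
    admin_interval_days: float = Field(gt=0)
    max_admin_count: int | None = Field(default=None, ge=1)
    components: list[ComponentSpec]

    def build(self, name: str) -> econ.Regimen:
        return econ.Regimen(
            name=name,
            components=tuple(
                econ.RegimenComponent(c.drug, c.dose, c.basis, c.doses_per_admin)
                for c in self.components
            ),
            admin_interval_days=self.admin_interval_days,
            max_admin_count=self.max_admin_count,
        )


class ArmSpec(BaseModel):
    regimens: list[str]
    sae_incidence: dict[str, float]
    # time-on-treatment law (observed delivery); None couples drug costs
    # to the trace's PFS occupancy instead
    exposure: WeibullSpec | None = None


class ParamSpecConfig(BaseModel):
    name: str
    path: str
    low: float
    high: float
    distribution: Literal["triangle", "beta", "fixed"]


class SensitivitySpec(BaseModel):
    parameters: list[ParamSpecConfig] = []


class SyntheticSpec(BaseModel):
    admin_censor_months: float = Field(default=36.0, gt=0)
    dropout_annual_prob: float = Field(default=0.0, ge=0.0, lt=1.0)


class RunConfig(BaseModel):
    """Complete, validated model input set."""

    label: str = ""
    currency: str = "USD 2020"
    wtp: float = Field(default=31498.70, gt=0)
    model: ModelSpec = ModelSpec()
    intervention: str
    comparator: str
    strategies: dict[str, StrategySpec]
    economics: EconomicsSpec
    regimens: dict[str, RegimenSpec]
    arms: dict[str, ArmSpec]
    sensitivity: SensitivitySpec = SensitivitySpec()
    synthetic: SyntheticSpec = SyntheticSpec()

    @model_validator(mode="after")
    def _cross_check(self) -> "RunConfig":
        for key in (self.intervention, self.comparator):
            if key not in self.strategies:
                raise ValueError(f"strategy {key!r} not defined")
            if key not in self.arms:
                raise ValueError(f"arm economics for {key!r} not defined")
        for arm, spec in self.arms.items():
            for r in spec.regimens:
                if r not in self.regimens:
                    raise ValueError(f"arm {arm!r} references unknown regimen {r!r}")
            for comp in (c for r in spec.regimens for c in self.regimens[r].components):
                if comp.drug not in self.economics.drug_prices:
                    raise ValueError(f"no price for drug {comp.drug!r}")
            for sae in spec.sae_incidence:
                if sae not in self.economics.sae_unit_costs:
                    raise ValueError(f"no unit cost for SAE {sae!r}")
        return self

    def build_arm(self, key: str) -> econ.ArmEconomics:
        spec = self.arms[key]
        return econ.ArmEconomics(
            label=self.strategies[key].label,
            regimens=tuple(self.regimens[r].build(r) for r in spec.regimens),
            sae=econ.SAEProfile(
                unit_costs=dict(self.economics.sae_unit_costs),
                incidence=dict(spec.sae_incidence),
            ),
            exposure=spec.exposure.build(f"{key} exposure") if spec.exposure else None,
        )


def default_config() -> RunConfig:
    """The bundled published base case."""
    text = resources.files("gcea.data").joinpath("base_case.yaml").read_text()
    return RunConfig.model_validate(yaml.safe_load(text))


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.model_validate(yaml.safe_load(fh))


def _walk(cfg, parts):
    node = cfg
    for p in parts:
        if isinstance(node, dict):
            if p not in node:
                raise KeyError(f"unknown config key {p!r} in path")
            node = node[p]
        elif isinstance(node, BaseModel) and p in node.__class__.model_fields:
            node = getattr(node, p)
        else:
            raise KeyError(f"cannot resolve {p!r} on {type(node).__name__}")
    return node


def get_path(cfg: RunConfig, path: str):
    """Read a scalar input by dotted path."""
    return _walk(cfg, path.split("."))


def set_path(cfg: RunConfig, path: str, value) -> None:
    """Overwrite a scalar input by dotted path (in place on a copy you own)."""
    *head, last = path.split(".")
    node = _walk(cfg, head)
    if isinstance(node, dict):
        if last not in node:
            raise KeyError(f"unknown config key {last!r} in path {path!r}")
        node[last] = value
    elif isinstance(node, BaseModel) and last in node.__class__.model_fields:
        setattr(node, last, value)
    else:
        raise KeyError(f"cannot resolve {last!r} in path {path!r}")


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash of the full input set, for run manifests."""
    payload = cfg.model_dump_json().encode()
    return hashlib.sha256(payload).hexdigest()[:12]
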