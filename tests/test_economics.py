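"""Dosing arithmetic, SAE costs, accumulation and the ICER."""

import numpy as np
import pytest

from gcea.config import default_config
from gcea.economics import (
    CEResult,
    DrugPrice,
    PatientProfile,
    Regimen,
    RegimenComponent,
    SAEProfile,
    dose_amount,
    expected_sae_cost,
    icer,
    regimen_cost_per_model_cycle,
)
from gcea.markov import run_cohort
from gcea.model import run_base_case, run_strategy

PROFILE = PatientProfile()  # 65 kg, 1.64 m, BSA 1.72 m^2


class TestDoseAmount:
    def test_per_m2_scaling(self):
        oxa = RegimenComponent("oxaliplatin", 130.0, "per_m2")
        assert dose_amount(oxa, PROFILE) == pytest.approx(223.6)

    def test_flat_ignores_bsa(self):
        nivo = RegimenComponent("nivolumab", 360.0, "flat")
        big = PatientProfile(bsa_m2=2.06)
        assert dose_amount(nivo, PROFILE) == dose_amount(nivo, big) == 360.0

    def test_multi_dose_course(self):
        # capecitabine 1,000 mg/m2 twice daily for 14 days of a 3-week cycle
        cape = RegimenComponent("capecitabine", 1000.0, "per_m2", doses_per_admin=28)
        assert dose_amount(cape, PROFILE) == pytest.approx(48_160.0)


class TestRegimenCost:
    PRICES = {
        "nivolumab": DrugPrice(100.0, 1342.03),
        "oxaliplatin": DrugPrice(100.0, 90.00),
        "free": DrugPrice(100.0, 0.0),
    }

    def test_fractional_pricing_per_administration(self):
        reg = Regimen(
            "nivo", (RegimenComponent("nivolumab", 360.0, "flat"),), 21.0
        )
        monthly = regimen_cost_per_model_cycle(reg, self.PRICES, PROFILE)
        per_admin = 3.6 * 1342.03
        assert monthly == pytest.approx(per_admin * (365.25 / 12) / 21.0)

    def test_oxaliplatin_example(self):
        reg = Regimen("oxa", (RegimenComponent("oxaliplatin", 130.0, "per_m2"),), 21.0)
        monthly = regimen_cost_per_model_cycle(reg, self.PRICES, PROFILE)
        assert monthly * 21.0 / (365.25 / 12) == pytest.approx(201.24)

    def test_vial_rounding_rounds_up(self):
        reg = Regimen("oxa", (RegimenComponent("oxaliplatin", 130.0, "per_m2"),), 21.0)
        fractional = regimen_cost_per_model_cycle(reg, self.PRICES, PROFILE)
        rounded = regimen_cost_per_model_cycle(
            reg, self.PRICES, PROFILE, vial_rounding=True
        )
        assert rounded > fractional
        assert rounded * 21.0 / (365.25 / 12) == pytest.approx(3 * 90.0)

    def test_zero_price_drug_costs_nothing(self):
        reg = Regimen("x", (RegimenComponent("free", 500.0, "flat"),), 14.0)
        assert regimen_cost_per_model_cycle(reg, self.PRICES, PROFILE) == 0.0

    def test_unknown_drug_raises(self):
        reg = Regimen("y", (RegimenComponent("mystery", 10.0, "flat"),), 14.0)
        with pytest.raises(KeyError):
            regimen_cost_per_model_cycle(reg, self.PRICES, PROFILE)


class TestExpectedSAECost:
    COSTS = {
        "anemia": 508.20,
        "neutrophil_count_decreased": 534.40,
        "neutropenia": 466.00,
        "lipase_increased": 44.30,
    }

    def test_combination_arm_value(self):
        sae = SAEProfile(
            self.COSTS,
            {
                "anemia": 0.0646,
                "neutrophil_count_decreased": 0.1140,
                "neutropenia": 0.1621,
                "lipase_increased": 0.0618,
            },
        )
        assert expected_sae_cost(sae) == pytest.approx(172.02766)

    def test_chemotherapy_arm_value(self):
        sae = SAEProfile(
            self.COSTS,
            {
                "anemia": 0.0274,
                "neutrophil_count_decreased": 0.0874,
                "neutropenia": 0.1213,
                "lipase_increased": 0.0209,
            },
        )
        assert expected_sae_cost(sae) == pytest.approx(118.08291)

    def test_zero_incidence_is_free(self):
        sae = SAEProfile(self.COSTS, {k: 0.0 for k in self.COSTS})
        assert expected_sae_cost(sae) == 0.0

    def test_incidence_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            SAEProfile(self.COSTS, {"anemia": 1.2})


class TestAccumulate:
    def test_zero_utilities_zero_qalys(self, cfg):
        cfg.economics.u_pd = 0.0
        # bypass the base-case ordering check: probe the accounting only
        cfg.economics.u_pfs = 1e-9
        _, res = run_strategy(cfg, "chemo")
        assert res.qaly_total == pytest.approx(0.0, abs=1e-9)

    def test_unit_utilities_recover_life_years(self, cfg):
        cfg.economics.u_pfs = 1.0
        cfg.economics.u_pd = 0.999999999
        cfg.model.annual_discount_rate = 0.0
        cfg.model.half_cycle_correction = False
        trace, res = run_strategy(cfg, "chemo")
        life_months = trace.corrected[:, :2].sum()
        assert res.qaly_total == pytest.approx(life_months / 12.0, rel=1e-6)

    def test_totals_are_sums_of_state_buckets(self, base_result):
        for r in (base_result.intervention, base_result.comparator):
            assert r.cost_total == r.cost_pfs + r.cost_pd
            assert r.qaly_total == r.qaly_pfs + r.qaly_pd

    def test_cost_linearity_in_unit_costs(self, cfg):
        base = run_base_case(cfg).comparator.cost_total
        for name in (
            "salvage_per_cycle",
            "followup_per_cycle",
            "tests_per_cycle",
            "supportive_per_cycle",
            "terminal_care",
        ):
            setattr(cfg.economics, name, 2 * getattr(cfg.economics, name))
        for price in cfg.economics.drug_prices.values():
            price.price_usd *= 2
        for k in cfg.economics.sae_unit_costs:
            cfg.economics.sae_unit_costs[k] *= 2
        assert run_base_case(cfg).comparator.cost_total == pytest.approx(
            2 * base, rel=1e-12
        )

    def test_discounting_shrinks_totals(self, cfg):
        cfg.model.annual_discount_rate = 0.0
        undiscounted = run_base_case(cfg)
        cfg.model.annual_discount_rate = 0.08
        discounted = run_base_case(cfg)
        assert undiscounted.intervention.cost_total > discounted.intervention.cost_total
        assert undiscounted.intervention.qaly_total > discounted.intervention.qaly_total

    def test_qalys_increase_with_utility(self, cfg):
        lo = run_base_case(cfg).intervention.qaly_total
        cfg.economics.u_pfs = 0.956
        hi = run_base_case(cfg).intervention.qaly_total
        assert hi > lo


class TestICER:
    A = CEResult("a", cost_pfs=1000.0, cost_pd=500.0, qaly_pfs=0.6, qaly_pd=0.2)

    def test_identical_results_undefined(self):
        out = icer(self.A, self.A)
        assert out.classification == "undefined"
        assert out.icer is None

    def test_dominant_classification(self):
        worse = CEResult("b", cost_pfs=2000.0, cost_pd=500.0, qaly_pfs=0.5, qaly_pd=0.2)
        out = icer(self.A, worse)
        assert out.classification == "dominant"

    def test_ratio_on_unrounded_values(self):
        b = CEResult("b", cost_pfs=900.0, cost_pd=400.0, qaly_pfs=0.5, qaly_pd=0.2)
        out = icer(self.A, b)
        assert out.icer == pytest.approx(200.0 / 0.1)

    def test_published_increments_are_self_consistent(self):
        # printed dCost / printed ICER implies the unrounded dQALY
        assert 78626.53 / 278658.71 == pytest.approx(0.28216, abs=5e-6)
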