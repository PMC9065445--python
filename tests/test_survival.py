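"""Weibull survival law, transition probabilities, and MLE fitting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from gcea.ipd import simulate_ipd
from gcea.survival import (
    DegenerateFitWarning,
    WeibullParams,
    annual_to_cycle_probability,
    apply_hazard_ratio,
    cycle_transition_probability,
    fit_weibull,
    survival_at,
)

from conftest import TABLE1

NIVO_PFS = TABLE1[("nivo_chemo", "PFS")]
CHEMO_PFS = TABLE1[("chemo", "PFS")]
CHEMO_OS = TABLE1[("chemo", "OS")]


class TestSurvivalAt:
    @pytest.mark.parametrize(
        "params, t, expected",
        [
            (NIVO_PFS, 0.0, 1.0),
            # frozen from arbitrary-precision evaluation of exp(-lam t^gam)
            (NIVO_PFS, 12.0, 0.405549539599939685),
            (CHEMO_PFS, 6.0, 0.548772344381167930),
        ],
    )
    def test_matches_closed_form(self, params, t, expected):
        assert survival_at(params, t) == pytest.approx(expected, abs=1e-12)

    def test_rejects_negative_time(self):
        with pytest.raises(ValueError):
            survival_at(NIVO_PFS, -0.1)

    def test_monotone_decreasing_to_zero(self):
        t = np.linspace(0.0, 600.0, 2001)
        s = survival_at(NIVO_PFS, t)
        assert s[0] == 1.0
        assert np.all(np.diff(s) < 0)
        assert s[-1] < 1e-6


class TestCycleTransitionProbability:
    def test_first_cycle_is_one_minus_exp_lambda(self):
        assert cycle_transition_probability(NIVO_PFS, 1) == pytest.approx(
            0.0461873400160205790, abs=1e-12
        )

    def test_rejects_cycle_below_one(self):
        with pytest.raises(ValueError):
            cycle_transition_probability(NIVO_PFS, 0)

    @given(
        lam=st.floats(1e-4, 0.5),
        gam=st.floats(0.3, 3.0),
        t=st.integers(1, 120),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_identity_with_conditional_survival(self, lam, gam, t):
        """P(t) == 1 - S(t)/S(t-1) to machine precision."""
        assume(lam * t**gam < 500.0)  # keep S(t-1) well away from underflow
        p = WeibullParams(lam, gam)
        lhs = cycle_transition_probability(p, t)
        rhs = 1.0 - survival_at(p, float(t)) / survival_at(p, float(t - 1))
        assert lhs == pytest.approx(rhs, abs=1e-12)
        assert 0.0 <= lhs <= 1.0


class TestApplyHazardRatio:
    def test_identity_at_unit_hr(self):
        out = apply_hazard_ratio(NIVO_PFS, 1.0)
        assert out.scale_lambda == NIVO_PFS.scale_lambda
        assert out.shape_gamma == NIVO_PFS.shape_gamma

    def test_power_law_at_trial_os_hr(self):
        # HR 0.71 is the trial's OS effect size
        adj = apply_hazard_ratio(CHEMO_OS, 0.71)
        for t in (3.0, 6.0, 12.0):
            assert survival_at(adj, t) == pytest.approx(
                survival_at(CHEMO_OS, t) ** 0.71, rel=1e-12
            )

    def test_inverse_composition_recovers_params(self):
        back = apply_hazard_ratio(apply_hazard_ratio(CHEMO_OS, 2.0), 0.5)
        assert back.scale_lambda == pytest.approx(CHEMO_OS.scale_lambda, rel=1e-15)

    def test_rejects_nonpositive_hr(self):
        with pytest.raises(ValueError):
            apply_hazard_ratio(CHEMO_OS, 0.0)


class TestAnnualToCycleProbability:
    @pytest.mark.parametrize(
        "p, months, expected",
        [
            (0.0, 1.0, 0.0),
            (0.00707, 1.0, 0.000591084480360474560),  # frozen, 1-(0.99293)^(1/12)
            (0.35, 12.0, 0.35),
        ],
    )
    def test_values(self, p, months, expected):
        assert annual_to_cycle_probability(p, months) == pytest.approx(
            expected, abs=1e-15
        )

    def test_domain(self):
        with pytest.raises(ValueError):
            annual_to_cycle_probability(1.0, 1.0)
        with pytest.raises(ValueError):
            annual_to_cycle_probability(-0.1, 1.0)


class TestFitWeibull:
    def test_parameter_recovery_within_own_ci(self):
        """A large uncensored sample recovers the generating parameters."""
        ipd = simulate_ipd(NIVO_PFS, n=473, admin_censor_time=1e9, seed=7)
        fit = fit_weibull(ipd)
        assert fit.ci_scale[0] <= NIVO_PFS.scale_lambda <= fit.ci_scale[1]
        assert fit.ci_shape[0] <= NIVO_PFS.shape_gamma <= fit.ci_shape[1]

    @pytest.mark.parametrize("key", sorted(TABLE1))
    def test_relative_error_below_ten_percent_at_n2000(self, key):
        """Median estimate over independent n=2000 draws is within 10%.

        The median over replicates asserts the recovery property itself
        rather than the luck of a single finite sample (at n=2000 the
        scale estimate's sampling SD is ~6%).
        """
        params = TABLE1[key]
        lams, gams = [], []
        for rep in range(5):
            ipd = simulate_ipd(params, n=2000, admin_censor_time=1e9, seed=11 + rep)
            fit = fit_weibull(ipd)
            lams.append(fit.scale_lambda)
            gams.append(fit.shape_gamma)
        assert np.median(lams) == pytest.approx(params.scale_lambda, rel=0.10)
        assert np.median(gams) == pytest.approx(params.shape_gamma, rel=0.10)

    def test_censored_likelihood_handles_admin_censoring(self):
        ipd = simulate_ipd(CHEMO_PFS, n=2000, admin_censor_time=12.0, seed=3)
        assert (ipd["event"] == 0).any()
        fit = fit_weibull(ipd)
        assert fit.scale_lambda == pytest.approx(CHEMO_PFS.scale_lambda, rel=0.15)

    def test_agrees_with_independent_fitter(self):
        """Cross-check against lifelines' Weibull AFT parameterization."""
        from lifelines import WeibullFitter

        ipd = simulate_ipd(CHEMO_OS, n=800, admin_censor_time=36.0, seed=5)
        ours = fit_weibull(ipd)
        wf = WeibullFitter().fit(ipd["time_months"], ipd["event"])
        # lifelines: S(t) = exp(-(t/lambda_)^rho_)  =>  scale = lambda_^-rho_
        assert ours.shape_gamma == pytest.approx(wf.rho_, rel=1e-4)
        assert ours.scale_lambda == pytest.approx(wf.lambda_ ** -wf.rho_, rel=1e-4)

    def test_no_events_raises(self):
        ipd = pd.DataFrame({"time_months": [1.0, 2.0], "event": [0, 0]})
        with pytest.raises(ValueError):
            fit_weibull(ipd)

    def test_nonpositive_times_raise(self):
        ipd = pd.DataFrame({"time_months": [0.0, 2.0], "event": [1, 1]})
        with pytest.raises(ValueError):
            fit_weibull(ipd)

    def test_two_identical_events_warn_not_crash(self):
        ipd = pd.DataFrame({"time_months": [5.0, 5.0], "event": [1, 1]})
        with pytest.warns(DegenerateFitWarning):
            fit = fit_weibull(ipd)
        assert fit.scale_lambda > 0
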