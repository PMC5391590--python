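"""Conditional-logit estimation: closed form, Newton, CIs, reporting."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ppx.errors import DegenerateEstimateError, EstimationError
from ppx.estimation import (closed_form_or, event_rate, fit_conditional_logit,
                            sets_from_counts, truncate1, wald_ci)

from oracles import brute_force_beta, random_matched_sets


class TestClosedForm:
    @pytest.mark.parametrize("a,b,M,expected_or", [
        (259, 115, 5, 11.2),   # weeks 3-4
        (48, 122, 5, 1.9),     # weeks 11-12
        (387, 112, 5, 17.2),   # weeks 1-2
        (1, 5, 5, 1.0),        # balanced
    ])
    def test_reported_odds_ratios(self, a, b, M, expected_or):
        or_hat, _ = closed_form_or(a, b, M)
        assert truncate1(or_hat) == expected_or

    def test_standard_error_formula(self):
        _, se = closed_form_or(259, 115, 5)
        assert se == pytest.approx(math.sqrt(1 / 259 + 1 / 115))

    @pytest.mark.parametrize("a,b", [(0, 5), (5, 0)])
    def test_degenerate_counts(self, a, b):
        with pytest.raises(DegenerateEstimateError):
            closed_form_or(a, b, 5)

    @given(a=st.integers(1, 500), b=st.integers(1, 500),
           delta=st.integers(1, 50))
    def test_monotonicity(self, a, b, delta):
        base, _ = closed_form_or(a, b, 5)
        more_cases, _ = closed_form_or(a + delta, b, 5)
        more_controls, _ = closed_form_or(a, b + delta, 5)
        assert more_cases > base > more_controls


class TestNewtonEstimator:
    def test_agrees_with_closed_form_on_single_exposure_sets(self):
        for a, b in [(387, 112), (259, 115), (85, 110), (24, 136), (3, 7)]:
            fit = fit_conditional_logit(sets_from_counts(a, b, 5))
            cf_or, cf_se = closed_form_or(a, b, 5)
            assert fit.odds_ratio == pytest.approx(cf_or, abs=1e-8)
            assert fit.se == pytest.approx(cf_se, abs=1e-8)

    def test_handles_doubly_exposed_sets(self):
        sets = np.array([
            [1, 1, 0, 0, 0, 0],   # exposed in case AND one control period
            [1, 0, 0, 0, 0, 0],
            [0, 1, 0, 0, 0, 0],
            [0, 0, 1, 1, 0, 0],
            [1, 1, 1, 1, 1, 1],   # concordant: dropped
            [0, 0, 0, 0, 0, 0],   # concordant: dropped
        ])
        fit = fit_conditional_logit(sets)
        assert fit.n_dropped == 2
        assert fit.beta == pytest.approx(brute_force_beta(sets), abs=1e-6)

    def test_no_discordant_sets(self):
        concordant = np.array([[1, 1, 1], [0, 0, 0]])
        with pytest.raises(EstimationError):
            fit_conditional_logit(concordant)

    def test_case_only_exposure_flags_infinite_or(self):
        sets = np.zeros((5, 6), dtype=int)
        sets[:, 0] = 1
        with pytest.raises(DegenerateEstimateError) as err:
            fit_conditional_logit(sets)
        assert err.value.kind == "infinite"

    def test_control_only_exposure_flags_zero_or(self):
        sets = np.zeros((5, 6), dtype=int)
        sets[:, 2] = 1
        with pytest.raises(DegenerateEstimateError) as err:
            fit_conditional_logit(sets)
        assert err.value.kind == "zero"

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(25):
            sets = random_matched_sets(rng)
            fit = fit_conditional_logit(sets)
            assert fit.beta == pytest.approx(brute_force_beta(sets),
                                             abs=1e-6)


class TestWaldCI:
    def test_weeks_3_4_interval(self):
        or_hat, se = closed_form_or(259, 115, 5)
        lo, hi = wald_ci(math.log(or_hat), se)
        assert (truncate1(lo), truncate1(hi)) == (9.0, 14.0)

    def test_weeks_11_12_interval(self):
        or_hat, se = closed_form_or(48, 122, 5)
        lo, hi = wald_ci(math.log(or_hat), se)
        assert (truncate1(lo), truncate1(hi)) == (1.4, 2.7)

    def test_zero_se_degenerates_to_point(self):
        assert wald_ci(0.5, 0.0) == (math.exp(0.5), math.exp(0.5))

    @pytest.mark.parametrize("level", [0.0, 1.0, -0.1, 1.5])
    def test_level_domain(self, level):
        with pytest.raises(ValueError):
            wald_ci(0.0, 1.0, level=level)

    def test_interval_brackets_the_estimate(self):
        lo, hi = wald_ci(1.2, 0.3)
        assert lo < math.exp(1.2) < hi


class TestReporting:
    @pytest.mark.parametrize("n,d,expected", [
        (387, 3_566_375, 10.8),
        (62, 3_566_375, 1.7),
        (0, 1000, 0.0),
    ])
    def test_event_rate_per_100k(self, n, d, expected):
        assert event_rate(n, d) == expected

    def test_event_rate_zero_denominator(self):
        with pytest.raises(ValueError):
            event_rate(1, 0)

    @pytest.mark.parametrize("x,expected", [
        (17.2767, 17.2), (1.0, 1.0), (0.99, 0.9), (22.4, 22.4),
    ])
    def test_truncate_one_decimal(self, x, expected):
        assert truncate1(x) == expected

    def test_truncate_rejects_negative(self):
        with pytest.raises(ValueError):
            truncate1(-0.1)

    @given(x=st.floats(0, 1e6))
    def test_truncation_never_rounds_up(self, x):
        t = truncate1(x)
        assert t <= x + 1e-6
        assert round(t * 10) == int(t * 10)
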