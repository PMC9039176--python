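"""SCORE risk equations, annualization, excess-risk adjustment, matrices."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import rtburden as rb
from rtburden.parameters import ValidationError
from rtburden.risk import (
    AgeTable,
    FATAL_CV,
    NONFATAL,
    RiskProfile,
    build_cycle_matrices,
    build_transition_matrix,
    load_score_coefficients,
)


def oracle_score_risk(age, sbp, chol, smoker, coefficients):
    """Independent scalar transcription of the two-cause Weibull model."""
    risks = []
    for cause in (coefficients.chd, coefficients.non_chd):
        s_now = math.exp(-math.exp(cause.alpha) * (age - 20.0) ** cause.p)
        s_10 = math.exp(-math.exp(cause.alpha) * (age + 10.0 - 20.0) ** cause.p)
        w = (
            cause.beta_chol * (chol - 6.0)
            + cause.beta_sbp * (sbp - 120.0)
            + cause.beta_smoker * smoker
        )
        risks.append(1.0 - (s_10**math.exp(w)) / (s_now**math.exp(w)))
    return 1.0 - (1.0 - risks[0]) * (1.0 - risks[1])


class TestScore:
    def test_matches_independent_transcription(self):
        coef = load_score_coefficients()
        for age, sbp, chol, smoking in [(40, 120, 5, 0.0), (60, 140, 6.5, 1.0), (65, 136.2094, 5.4144, 0.0)]:
            ours = rb.score_10yr_fatal_cv_risk(RiskProfile(age, sbp, chol, smoking), coef)
            assert ours == pytest.approx(oracle_score_risk(age, sbp, chol, smoking, coef), rel=1e-12)

    def test_published_chart_cell_regression(self):
        """Low-risk chart, woman aged 60, non-smoker, SBP 120, chol 5: the
        published chart rounds this cell to 1%."""
        risk = rb.score_10yr_fatal_cv_risk(RiskProfile(60, 120.0, 5.0, 0.0))
        assert round(risk, 2) == 0.01
        assert risk == pytest.approx(0.008915542803790588, rel=1e-12)  # frozen

    def test_cohort_covariates_regression(self):
        risk = rb.score_10yr_fatal_cv_risk(RiskProfile(60, 116.0847, 5.1832, 0.0951))
        assert risk == pytest.approx(0.009202570041032577, rel=1e-12)  # frozen

    @given(st.floats(min_value=0.0, max_value=1.0))
    def test_smoking_prevalence_is_exact_mixture(self, prevalence):
        coef = load_score_coefficients()
        lo = rb.score_10yr_fatal_cv_risk(RiskProfile(55, 125.0, 5.5, 0.0), coef)
        hi = rb.score_10yr_fatal_cv_risk(RiskProfile(55, 125.0, 5.5, 1.0), coef)
        mid = rb.score_10yr_fatal_cv_risk(RiskProfile(55, 125.0, 5.5, prevalence), coef)
        assert mid == pytest.approx((1 - prevalence) * lo + prevalence * hi, rel=1e-12)
        assert lo - 1e-15 <= mid <= hi + 1e-15

    def test_risk_increases_in_sbp_chol_and_age(self):
        base = rb.score_10yr_fatal_cv_risk(RiskProfile(60, 120.0, 5.0, 0.0))
        assert rb.score_10yr_fatal_cv_risk(RiskProfile(60, 140.0, 5.0, 0.0)) > base
        assert rb.score_10yr_fatal_cv_risk(RiskProfile(60, 120.0, 6.0, 0.0)) > base
        ages = [rb.score_10yr_fatal_cv_risk(RiskProfile(a, 120.0, 5.0, 0.0)) for a in range(40, 66)]
        assert all(b > a for a, b in zip(ages, ages[1:]))

    def test_age_floor_applies_below_forty(self):
        assert rb.score_10yr_fatal_cv_risk(
            RiskProfile(39, 120.0, 5.0, 0.0)
        ) == rb.score_10yr_fatal_cv_risk(RiskProfile(40, 120.0, 5.0, 0.0))

    def test_additive_combination_dominates_survival_scale(self):
        profile = RiskProfile(64, 136.0, 5.4, 0.1)
        surv = rb.score_10yr_fatal_cv_risk(profile, combine="survival")
        add = rb.score_10yr_fatal_cv_risk(profile, combine="additive")
        assert add >= surv


class TestAnnualize:
    @pytest.mark.parametrize(
        "p,years,expected",
        [(0.0, 10, 0.0), (0.1, 10, 0.0104808), (0.37, 1, 0.37)],
    )
    def test_worked_values(self, p, years, expected):
        assert rb.annualize(p, years) == pytest.approx(expected, abs=1e-7)

    def test_certain_event_rejected(self):
        with pytest.raises(ValidationError):
            rb.annualize(1.0, 10)

    @given(
        st.floats(min_value=0.0, max_value=0.999, allow_nan=False),
        st.integers(min_value=1, max_value=50),
    )
    def test_recomposition_recovers_multiyear_risk(self, p, years):
        annual = rb.annualize(p, years)
        assert 1.0 - (1.0 - annual) ** years == pytest.approx(p, abs=1e-12)


class TestExcessRisk:
    def test_zero_dose_is_comparator(self):
        assert rb.apply_excess_risk(0.0123, 0.041, 0.0) == 0.0123

    def test_worked_value(self):
        assert rb.apply_excess_risk(0.0100, 0.041, 3.6) == pytest.approx(0.0114760, abs=1e-12)

    def test_dose_ratio_between_strata(self):
        # the high/moderate excess increments scale by the published dose ratio
        inc_high = rb.apply_excess_risk(0.01, 0.041, 3.6) - 0.01
        inc_mod = rb.apply_excess_risk(0.01, 0.041, 1.9) - 0.01
        assert inc_high / inc_mod == pytest.approx(1.8947, abs=1e-4)

    def test_negative_dose_rejected(self):
        with pytest.raises(ValidationError):
            rb.apply_excess_risk(0.01, 0.041, -1.0)

    def test_caps_at_one(self):
        assert rb.apply_excess_risk(0.9, 0.5, 10.0) == 1.0


class TestNonfatalScaling:
    def test_published_consistency(self):
        assert round(rb.nonfatal_from_fatal(0.0427, 2.7515), 4) == 0.1175

    def test_zero(self):
        assert rb.nonfatal_from_fatal(0.0, 2.7515) == 0.0

    def test_bound_violation(self):
        with pytest.raises(ValidationError):
            rb.nonfatal_from_fatal(0.5, 2.7515)


class TestTransitionMatrix:
    def test_rows_sum_to_one_at_every_age(self, ps, tables):
        for age in range(39, 105):
            for with_excess in (False, True):
                m = build_transition_matrix(
                    age, ps, tables.fatal_cv, tables.background, with_excess
                )
                assert np.allclose(m.sum(axis=1), 1.0, atol=1e-12)
                assert (m >= 0).all()

    def test_absorbing_death_rows(self, ps, tables):
        m = build_transition_matrix(60, ps, tables.fatal_cv, tables.background, True)
        assert m[4, 4] == 1.0 and m[5, 5] == 1.0
        assert m[4].sum() == 1.0 and m[5].sum() == 1.0

    def test_excess_factor_on_high_stratum(self, ps, tables):
        for age in (39, 50, 70, 90, 104):
            on = build_transition_matrix(age, ps, tables.fatal_cv, tables.background, True)
            off = build_transition_matrix(age, ps, tables.fatal_cv, tables.background, False)
            assert on[0, FATAL_CV] / off[0, FATAL_CV] == pytest.approx(1.1476, abs=1e-12)
            assert on[1, FATAL_CV] / off[1, FATAL_CV] == pytest.approx(1 + 0.041 * 1.9, abs=1e-12)

    def test_unexposed_row_identical_across_comparators(self, ps, tables):
        on = build_transition_matrix(60, ps, tables.fatal_cv, tables.background, True)
        off = build_transition_matrix(60, ps, tables.fatal_cv, tables.background, False)
        assert (on[2] == off[2]).all()
        assert (on[3] == off[3]).all()  # post-event row carries no dose effect

    def test_cycle_stack_covers_horizon(self, ps, tables):
        stack = build_cycle_matrices(84, ps, tables.fatal_cv, tables.background, True)
        assert stack.shape == (20, 6, 6)


class TestAgeTable:
    def test_csv_roundtrip(self, tmp_path, tables):
        path = tmp_path / "fatal.csv"
        tables.fatal_cv.to_csv(path)
        loaded = AgeTable.from_csv(path)
        assert (loaded.ages == tables.fatal_cv.ages).all()
        assert np.allclose(loaded.values, tables.fatal_cv.values, rtol=1e-12)

    def test_out_of_range_lookup_rejected(self, tables):
        with pytest.raises(ValidationError):
            tables.fatal_cv.value(200)

    def test_non_consecutive_ages_rejected(self):
        with pytest.raises(ValidationError):
            AgeTable(np.array([40, 42]), np.array([0.1, 0.2]))
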