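import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nss import (
    BetaBinomParams,
    ConfigurationError,
    adequate_lne,
    adjusted_rate,
    build_nss_table,
    estimate_false_negatives,
    fit_mle,
    nodal_staging_score,
    pmf,
    prob_false_negative,
    simulate_cohort,
    stratum_adjusted_rate,
)
from tests.conftest import single_stage_config

shapes_st = st.floats(min_value=0.05, max_value=50.0)


class TestProbFalseNegative:
    def test_no_examination_no_information(self):
        assert prob_false_negative(0, BetaBinomParams(2, 3)) == pytest.approx(1.0)

    def test_uniform_shapes_closed_form(self):
        # alpha = beta = 1: P(FN | e) = 1 / (e + 1)
        assert prob_false_negative(4, BetaBinomParams(1, 1)) == pytest.approx(0.2)

    def test_exact_beta_ratio(self):
        # B(2,5)/B(2,3) = (1/30)/(1/12) = 0.4
        assert prob_false_negative(2, BetaBinomParams(2, 3)) == pytest.approx(0.4)

    def test_equals_pmf_at_zero(self):
        p = BetaBinomParams(0.7, 3.3)
        e = np.arange(1, 50)
        np.testing.assert_allclose(prob_false_negative(e, p), pmf(0, e, p))

    def test_negative_e_rejected(self):
        with pytest.raises(ValueError):
            prob_false_negative(-1, BetaBinomParams(1, 1))

    @given(a=shapes_st, b=shapes_st)
    @settings(max_examples=50, deadline=None)
    def test_strictly_decreasing_in_e(self, a, b):
        vals = prob_false_negative(np.arange(0, 201), BetaBinomParams(a, b))
        assert np.all(np.diff(vals) < 0)


class TestEstimateFalseNegatives:
    @pytest.mark.parametrize(
        "p_fn,tp,n,expected",
        [
            (0.5, 10, 100, 10.0),  # odds 1:1 scale the positives
            (0.9, 10, 50, 50.0),  # cap binds: min(90, 50)
            (0.0, 7, 9, 0.0),
            (1.0, 3, 12, 12.0),  # limit of the cap at certain misses
        ],
    )
    def test_cases(self, p_fn, tp, n, expected):
        assert estimate_false_negatives(p_fn, tp, n) == pytest.approx(expected)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            estimate_false_negatives(1.2, 1, 1)


class TestAdjustedRate:
    def test_zero_fn_leaves_rate_unchanged(self):
        r = adjusted_rate({5: 0.0}, {5: 12}, {5: 88}, 1)
        assert r.adjusted_rate == pytest.approx(r.raw_rate)
        assert r.increase == pytest.approx(0.0)

    def test_single_e_arithmetic(self):
        r = adjusted_rate({3: 10.0}, {3: 10}, {3: 100}, 2)
        assert r.raw_rate == pytest.approx(10 / 110)
        assert r.adjusted_rate == pytest.approx(20 / 110)

    def test_full_reclassification_gives_one(self):
        r = adjusted_rate({1: 4.0, 2: 6.0}, {1: 3, 2: 2}, {1: 4, 2: 6}, 3)
        assert r.adjusted_rate == pytest.approx(1.0)

    def test_empty_stratum_rejected(self):
        from nss import UndefinedRateError

        with pytest.raises(UndefinedRateError):
            adjusted_rate({}, {}, {}, 1)


class TestNodalStagingScore:
    def test_zero_examined_equals_prior(self):
        p = BetaBinomParams(2, 3)
        assert nodal_staging_score(0, 0.3, p) == pytest.approx(0.7)

    def test_vanishing_fn_probability_tends_to_one(self):
        p = BetaBinomParams(5, 1)  # heavy involvement: P(FN) dies fast
        assert nodal_staging_score(500, 0.5, p) == pytest.approx(1.0, abs=1e-6)

    def test_bayes_substitution(self):
        # P(FN | 1) = beta/(alpha+beta) = 0.5 at alpha = beta = 1
        score = nodal_staging_score(1, 0.243, BetaBinomParams(1, 1))
        assert score == pytest.approx(0.757 / (0.757 + 0.243 * 0.5), rel=1e-9)
        assert score == pytest.approx(0.862, abs=5e-4)

    def test_rate_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            nodal_staging_score(5, 0.0, BetaBinomParams(1, 1))
        with pytest.raises(ValueError):
            nodal_staging_score(5, 1.0, BetaBinomParams(1, 1))

    @given(a=shapes_st, b=shapes_st, rate=st.floats(min_value=0.01, max_value=0.99))
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing_in_e(self, a, b, rate):
        vals = nodal_staging_score(np.arange(0, 201), rate, BetaBinomParams(a, b))
        diffs = np.diff(vals)
        assert np.all(diffs >= 0)
        # strictness holds wherever the score has not saturated to 1.0
        assert np.all(diffs[vals[1:] < 1 - 1e-12] > 0)


class TestAdequateLNE:
    def test_low_prevalence_prior_suffices(self):
        with pytest.warns(UserWarning, match="already exceeds"):
            res = adequate_lne(0.05, BetaBinomParams(1, 1), threshold=0.90)
        assert res.e_required == 0

    def test_uniform_shapes_closed_form(self):
        # NSS(e) = 0.5 / (0.5 + 0.5/(e+1)) > 0.9  <=>  e + 1 > 9
        res = adequate_lne(0.5, BetaBinomParams(1, 1), threshold=0.9)
        assert res.e_required == 9 and res.attainable

    def test_threshold_monotonicity(self):
        p = BetaBinomParams(1.3, 4.1)
        lo = adequate_lne(0.4, p, threshold=0.90).e_required
        hi = adequate_lne(0.4, p, threshold=0.95).e_required
        assert hi >= lo

    def test_unattainable_reports_score_at_cap(self):
        # nearly flat P(FN): tiny alpha keeps misses likely at any e
        res = adequate_lne(0.6, BetaBinomParams(1e-3, 5), threshold=0.9, e_max=50)
        assert not res.attainable
        assert res.nss_attained < 0.9

    def test_non_strict_never_demands_more_nodes(self):
        p = BetaBinomParams(1.3, 4.1)
        for thr in (0.85, 0.90, 0.95):
            strict = adequate_lne(0.4, p, thr, strict=True).e_required
            loose = adequate_lne(0.4, p, thr, strict=False).e_required
            assert loose <= strict


@pytest.fixture(scope="module")
def table_and_inputs(fitted_single_stage):
    _, cohort, _, fit = fitted_single_stage
    table = build_nss_table(cohort, {3: fit})
    return cohort, fit, table


class TestBuildNSSTable:
    def test_pfn_column_matches_direct_evaluation(self, table_and_inputs):
        _, fit, table = table_and_inputs
        np.testing.assert_allclose(
            table["p_fn"].to_numpy(),
            prob_false_negative(table["e"].to_numpy(), fit.params),
        )

    def test_monotone_columns(self, table_and_inputs):
        _, _, table = table_and_inputs
        assert (table.groupby("t_stage")["p_fn"].apply(lambda s: s.is_monotonic_decreasing)).all()
        assert (table.groupby("t_stage")["nss"].apply(lambda s: s.is_monotonic_increasing)).all()

    def test_fn_cap_never_exceeded(self, table_and_inputs):
        _, _, table = table_and_inputs
        assert (table["fn_est"] <= table["n"] + 1e-12).all()

    def test_tallies_account_for_every_patient(self, table_and_inputs):
        cohort, _, table = table_and_inputs
        assert table["tp"].sum() + table["n"].sum() == len(cohort)

    def test_missing_fit_is_configuration_error(self, fitted_single_stage):
        _, cohort, _, _ = fitted_single_stage
        with pytest.raises(ConfigurationError):
            build_nss_table(cohort, {})

    def test_higher_rate_means_lower_score_at_fixed_e(self):
        # two strata sharing shapes: ordering follows the adjusted rate
        p = BetaBinomParams(2, 6)
        low = nodal_staging_score(10, 0.2, p)
        high = nodal_staging_score(10, 0.6, p)
        assert high < low

    def test_nss_at_zero_equals_one_minus_adjusted(self, fitted_single_stage):
        _, cohort, _, fit = fitted_single_stage
        adj = stratum_adjusted_rate(cohort, 3, fit.params)
        s0 = nodal_staging_score(0, adj.adjusted_rate, fit.params)
        assert s0 == pytest.approx(1 - adj.adjusted_rate, rel=1e-12)
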