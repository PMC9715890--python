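import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from nss import (
    BetaBinomParams,
    FitError,
    exclude_all_positive,
    fit_mle,
    grid_search_mle,
    log_likelihood,
    pmf,
)
shapes_st = st.floats(min_value=0.05, max_value=50.0)


class TestPmf:
    def test_uniform_shapes_give_discrete_uniform(self):
        # alpha = beta = 1 mixes over Uniform(0,1): every m equally likely
        p = BetaBinomParams(1, 1)
        assert pmf(0, 1, p) == pytest.approx(0.5)
        assert pmf(2, 5, p) == pytest.approx(1 / 6)

    def test_exact_beta_function_arithmetic(self):
        # C(3,1) * B(3, 5) / B(2, 3) = 3 * (1/105) / (1/12) = 12/35
        assert pmf(1, 3, BetaBinomParams(2, 3)) == pytest.approx(12 / 35)

    def test_zero_examined_is_certain_zero_positive(self):
        assert pmf(0, 0, BetaBinomParams(2, 3)) == pytest.approx(1.0)

    def test_m_above_e_rejected(self):
        with pytest.raises(ValueError):
            pmf(3, 2, BetaBinomParams(1, 1))

    def test_nonpositive_shapes_rejected(self):
        with pytest.raises(ValueError):
            BetaBinomParams(0, 1)
        with pytest.raises(ValueError):
            BetaBinomParams(1, -2)

    @given(a=shapes_st, b=shapes_st, e=st.integers(min_value=1, max_value=100))
    @settings(max_examples=100, deadline=None)
    def test_normalization_and_symmetry(self, a, b, e):
        p = BetaBinomParams(a, b)
        q = BetaBinomParams(b, a)
        m = np.arange(e + 1)
        probs = pmf(m, e, p)
        assert np.sum(probs) == pytest.approx(1.0, abs=1e-10)
        # mirror symmetry: counting negatives under swapped shapes
        np.testing.assert_allclose(probs, pmf(e - m, e, q), rtol=1e-9)

    @given(
        a=shapes_st,
        b=shapes_st,
        e=st.integers(min_value=1, max_value=60),
        m=st.integers(min_value=0, max_value=60),
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_scipy_reference(self, a, b, e, m):
        m = min(m, e)
        ours = pmf(m, e, BetaBinomParams(a, b))
        ref = scipy.stats.betabinom.pmf(m, e, a, b)
        assert ours == pytest.approx(ref, rel=1e-9, abs=1e-12)


class TestLogLikelihood:
    def test_uniform_pairs_closed_form(self):
        ll = log_likelihood([(1, 2), (1, 2)], BetaBinomParams(1, 1))
        assert ll == pytest.approx(2 * np.log(1 / 3))

    def test_sum_of_per_pair_logs(self):
        p = BetaBinomParams(2, 3)
        expected = np.log(pmf(1, 3, p)) + np.log(pmf(2, 5, p))
        assert log_likelihood([(1, 3), (2, 5)], p) == pytest.approx(expected)

    def test_finite_for_any_positive_shapes(self):
        pairs = [(1, 4), (3, 9), (2, 2)]
        for a, b in [(1e-3, 1e3), (50, 0.05), (1, 1)]:
            assert np.isfinite(log_likelihood(pairs, BetaBinomParams(a, b)))

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            log_likelihood([], BetaBinomParams(1, 1))

    def test_zero_count_pairs_rejected(self):
        with pytest.raises(ValueError, match="m >= 1"):
            log_likelihood([(0, 5)], BetaBinomParams(1, 1))


class TestExcludeAllPositive:
    def test_mixed_pairs(self):
        kept, n = exclude_all_positive([(2, 2), (1, 3)])
        assert kept == [(1, 3)] and n == 1

    def test_empty(self):
        assert exclude_all_positive([]) == ([], 0)

    def test_count_matches_direct_enumeration(self):
        rng = np.random.default_rng(17)
        e = rng.integers(1, 6, size=100)
        m = rng.integers(1, e + 1)
        pairs = list(zip(m.tolist(), e.tolist()))
        kept, n = exclude_all_positive(pairs)
        assert n == int(np.sum(m == e))
        assert len(kept) + n == 100


class TestFitMLE:
    def test_parameter_recovery_within_25_percent(self):
        # 500 observed-positive pairs from alpha=2, beta=8, e ~ U{5..30}
        rng = np.random.default_rng(0)
        e = rng.integers(5, 31, size=700)
        p = rng.beta(2.0, 8.0, size=700)
        m = rng.binomial(e, p)
        keep = m >= 1  # fitting set is conditioned on observed positivity
        fit = fit_mle(np.column_stack([m[keep], e[keep]])[:500])
        assert fit.converged
        assert fit.params.alpha == pytest.approx(2.0, rel=0.25)
        assert fit.params.beta == pytest.approx(8.0, rel=0.25)

    def test_beats_coarse_grid(self, fitted_single_stage):
        _, cohort, _, fit = fitted_single_stage
        pairs = cohort.positive_pairs(3)
        grid_params, grid_ll = grid_search_mle(pairs, n_grid=60)
        assert fit.log_likelihood >= grid_ll - 1e-6
        # argmax within one coarse-grid step of the optimizer's solution
        step = (100 / 0.01) ** (1 / 59)
        assert grid_params.alpha / fit.params.alpha < step * 1.01
        assert fit.params.alpha / grid_params.alpha < step * 1.01

    def test_mean_fraction_bias_shrinks_with_n(self):
        biases = {}
        for n, seed in ((200, 3), (2000, 3)):
            rng = np.random.default_rng(seed)
            e = rng.integers(5, 31, size=n * 3)
            p = rng.beta(2.0, 8.0, size=n * 3)
            m = rng.binomial(e, p)
            keep = m >= 1
            pairs = np.column_stack([m[keep], e[keep]])[:n]
            fit = fit_mle(pairs)
            biases[n] = abs(fit.params.mean_fraction - 0.2)
        assert biases[2000] < 0.02

    def test_all_positive_pairs_unfittable(self):
        with pytest.raises(FitError):
            fit_mle([(2, 2), (3, 3), (1, 1)])

    def test_single_informative_pair_unfittable(self):
        with pytest.raises(FitError):
            fit_mle([(1, 3)])

    def test_counts_excluded_all_positive(self):
        fit = fit_mle([(1, 3), (2, 5), (4, 4), (2, 2), (1, 6)])
        assert fit.n_used == 3
        assert fit.n_excluded_all_positive == 2

    def test_plain_objective_available(self, fitted_single_stage):
        # unconditional likelihood overstates involvement on pN+-only data
        _, cohort, _, fit = fitted_single_stage
        plain = fit_mle(cohort.positive_pairs(3), truncated=False)
        assert plain.params.mean_fraction > fit.params.mean_fraction
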