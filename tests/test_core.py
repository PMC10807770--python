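import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy import stats

from tpac.core import (
    TpacConfig,
    bh_fdr,
    fit_gamma_mle,
    fit_gamma_null,
    permute_columns,
    prepare_expression,
    score_with_null,
    set_distances,
    split_deviations,
    tissue_specificity,
    total_distances,
    tpac,
    weighted_variances,
)
from tpac.gene_sets import GeneSetCollection, SetIndex, build_set_index


def make_index(sets):
    return SetIndex(indices={k: np.asarray(v, dtype=np.intp) for k, v in sets.items()})


class TestPrepareExpression:
    def test_constant_column_removed(self):
        values = np.array([[1.0, 5.0, 2.0], [2.0, 5.0, 3.0], [3.0, 5.0, 1.0]])
        matrix, dropped = prepare_expression(values, ["a", "b", "c"], ["g1", "g2", "g3"])
        assert matrix.values.shape == (3, 2)
        assert dropped == ["g2"]
        assert matrix.gene_ids == ["g1", "g3"]

    def test_no_constant_columns_identity(self, small_expression):
        values, sample_ids, gene_ids = small_expression
        matrix, dropped = prepare_expression(values, sample_ids, gene_ids)
        assert dropped == []
        np.testing.assert_array_equal(matrix.values, values)

    def test_planted_constant_columns_oracle(self, rng):
        values = rng.gamma(2.0, 3.0, size=(50, 200))
        planted = rng.choice(200, size=17, replace=False)
        values[:, planted] = rng.uniform(1, 10, size=17)
        gene_ids = [f"g{j}" for j in range(200)]
        # independent oracle: a column has zero variance iff one distinct value
        expected_dropped = {
            gene_ids[j] for j in range(200) if len(np.unique(values[:, j])) == 1
        }
        assert len(expected_dropped) == 17
        _, dropped = prepare_expression(values, [f"s{i}" for i in range(50)], gene_ids)
        assert set(dropped) == expected_dropped

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError, match="2 samples"):
            prepare_expression(np.array([[1.0, 2.0]]), ["a"], ["g1", "g2"])

    def test_all_constant_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            prepare_expression(np.ones((3, 2)), list("abc"), ["g1", "g2"])

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            prepare_expression(np.array([[1.0, -1.0], [2.0, 3.0]]), ["a", "b"], ["g1", "g2"])

    def test_nan_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            prepare_expression(np.array([[1.0, np.nan], [2.0, 3.0]]), ["a", "b"], ["g1", "g2"])


class TestTissueSpecificity:
    def test_direct_ratio(self):
        ref = tissue_specificity([2.0, 4.0], [2.0, 2.0])
        np.testing.assert_allclose(ref.t_star, [1.0, 2.0])

    def test_identity_when_equal(self, rng):
        t = rng.uniform(1, 10, size=20)
        ref = tissue_specificity(t, t.copy())
        np.testing.assert_allclose(ref.t_star, 1.0)

    def test_clamp_boundaries(self):
        ref = tissue_specificity([5.0, 0.001], [0.0005, 1.0], clamp_hi=1e4)
        np.testing.assert_allclose(ref.t_star, [1e4, 0.001])

    def test_zero_tbar_flagged_with_unit_weight(self):
        ref = tissue_specificity([3.0, 2.0], [0.0, 1.0])
        assert ref.t_star[0] == 1.0
        assert ref.no_tissue_info.tolist() == [True, False]

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="equal length"):
            tissue_specificity([1.0, 2.0], [1.0])


class TestSplitDeviations:
    def test_row_equal_to_reference_is_zero(self):
        t = np.array([1.0, 2.0, 3.0])
        dev = split_deviations(t[np.newaxis, :].repeat(2, axis=0), t)
        np.testing.assert_array_equal(dev.delta_plus, 0.0)
        np.testing.assert_array_equal(dev.delta_minus, 0.0)

    def test_sign_split(self):
        dev = split_deviations(np.array([[4.0, 0.0]]), np.array([1.0, 2.0]))
        np.testing.assert_array_equal(dev.delta_plus, [[3.0, 0.0]])
        np.testing.assert_array_equal(dev.delta_minus, [[0.0, -2.0]])

    def test_reconstruction_oracle(self, rng):
        X = rng.gamma(2.0, 3.0, size=(20, 30))
        t = rng.uniform(0, 10, size=30)
        dev = split_deviations(X, t)
        np.testing.assert_array_equal(dev.delta_plus + dev.delta_minus, X - t)
        np.testing.assert_array_equal(dev.delta_plus * dev.delta_minus, 0.0)

    @given(
        X=hnp.arrays(np.float64, (5, 7), elements=st.floats(0, 1e6)),
        t=hnp.arrays(np.float64, (7,), elements=st.floats(0, 1e6)),
    )
    @settings(max_examples=50, deadline=None)
    def test_decomposition_property(self, X, t):
        dev = split_deviations(X, t)
        assert np.all(dev.delta_plus >= 0)
        assert np.all(dev.delta_minus <= 0)
        np.testing.assert_array_equal(dev.delta_plus + dev.delta_minus, X - t)
        assert np.all(dev.delta_plus * dev.delta_minus == 0)

    def test_alignment_error(self):
        with pytest.raises(ValueError, match="gene axis"):
            split_deviations(np.ones((2, 3)), np.ones(4))


class TestWeightedVariances:
    def test_definition(self):
        X = np.array([[0.0, 0.0], [4.0, 4.0]])  # var = 8 per column
        wv = weighted_variances(X, np.array([2.0, 1.0]))
        np.testing.assert_allclose(wv.var_plus, [16.0, 8.0])
        np.testing.assert_allclose(wv.var_minus, [4.0, 8.0])

    def test_unit_weight_identity(self, rng):
        X = rng.gamma(2.0, 3.0, size=(15, 8))
        wv = weighted_variances(X, np.ones(8))
        expected = X.var(axis=0, ddof=1)
        np.testing.assert_allclose(wv.var_plus, expected)
        np.testing.assert_allclose(wv.var_minus, expected)

    def test_product_identity(self, rng):
        X = rng.gamma(2.0, 3.0, size=(15, 8))
        t_star = rng.uniform(0.1, 10, size=8)
        wv = weighted_variances(X, t_star)
        np.testing.assert_allclose(wv.var_plus * wv.var_minus, wv.base**2, rtol=1e-12)

    def test_directionality(self, rng):
        X = rng.gamma(2.0, 3.0, size=(15, 4))
        up = weighted_variances(X, np.full(4, 3.0))
        base = X.var(axis=0, ddof=1)
        assert np.all(up.var_plus > base) and np.all(up.var_minus < base)


class TestSetDistances:
    def test_one_gene_set(self):
        M = set_distances(np.array([[2.0]]), np.array([4.0]), make_index({"A": [0]}))
        np.testing.assert_allclose(M, [[1.0]])

    def test_zero_deviation_zero_distance(self):
        M = set_distances(np.zeros((3, 5)), np.ones(5), make_index({"A": [0, 1, 2]}))
        np.testing.assert_array_equal(M, 0.0)

    def test_brute_force_mahalanobis_oracle(self, rng):
        for _ in range(20):
            n, p = 10, 8
            g = int(rng.integers(1, 6))
            dev = rng.normal(size=(n, p))
            variances = rng.uniform(0.5, 5.0, size=p)
            cols = np.sort(rng.choice(p, size=g, replace=False))
            index = make_index({"K": cols})
            M = set_distances(dev, variances, index)
            # oracle: explicit quadratic form with matrix inversion
            sigma_inv = np.linalg.inv(np.diag(variances[cols]))
            expected = np.diag(dev[:, cols] @ sigma_inv @ dev[:, cols].T)
            np.testing.assert_allclose(M[:, 0], expected, rtol=1e-10)

    def test_column_order_follows_index(self, rng):
        dev = rng.normal(size=(4, 6))
        variances = np.ones(6)
        index = make_index({"B": [0, 1], "A": [2, 3]})
        M = set_distances(dev, variances, index)
        np.testing.assert_allclose(M[:, 0], (dev[:, :2] ** 2).sum(axis=1))
        np.testing.assert_allclose(M[:, 1], (dev[:, 2:4] ** 2).sum(axis=1))


class TestTotalDistances:
    def test_zero_plus(self, rng):
        M_minus = rng.uniform(size=(3, 4))
        np.testing.assert_array_equal(total_distances(np.zeros((3, 4)), M_minus), M_minus)

    def test_single_cell(self):
        np.testing.assert_allclose(total_distances(np.array([[1.5]]), np.array([[2.5]])), [[4.0]])

    def test_commutative(self, rng):
        a, b = rng.uniform(size=(3, 4)), rng.uniform(size=(3, 4))
        np.testing.assert_array_equal(total_distances(a, b), total_distances(b, a))

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            total_distances(np.zeros((2, 2)), np.zeros((2, 3)))


class TestPermuteColumns:
    def test_multiset_preserved(self):
        X = np.array([[1.0], [2.0], [3.0]])
        (out,) = permute_columns(X, rng=0)
        assert sorted(out[:, 0]) == [1.0, 2.0, 3.0]

    def test_seed_determinism(self, rng):
        X = np.random.default_rng(5).uniform(size=(10, 6))
        a = permute_columns(X, rng=7, n_permutations=3)
        b = permute_columns(X, rng=7, n_permutations=3)
        for m1, m2 in zip(a, b):
            np.testing.assert_array_equal(m1, m2)

    def test_columns_permuted_independently(self):
        # chi-square independence test over pairs of 3-element permutations
        from itertools import permutations

        X = np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]])
        perms = {p: i for i, p in enumerate(permutations((0, 1, 2)))}
        table = np.zeros((6, 6))
        rng = np.random.default_rng(11)
        for out in permute_columns(X, rng=rng, n_permutations=3000):
            i = perms[tuple(int(v) - 1 for v in out[:, 0])]
            j = perms[tuple(int(v) - 4 for v in out[:, 1])]
            table[i, j] += 1
        _, pvalue, _, _ = stats.chi2_contingency(table)
        assert pvalue > 0.01

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError, match="2 samples"):
            permute_columns(np.ones((1, 3)), rng=0)


class TestFitGammaMle:
    def test_parameter_recovery(self):
        x = stats.gamma.rvs(a=2.0, scale=1 / 3.0, size=100_000,
                            random_state=np.random.default_rng(0))
        fit = fit_gamma_mle(x)
        assert fit.fit_ok
        assert 1.95 <= fit.shape <= 2.05
        assert 2.9 <= fit.rate <= 3.1

    def test_agrees_with_scipy_mle(self, rng):
        # dual route: independent MLE via scipy with loc fixed at 0
        x = rng.gamma(shape=3.5, scale=0.7, size=5000)
        fit = fit_gamma_mle(x)
        a, loc, scale = stats.gamma.fit(x, floc=0)
        assert loc == 0
        np.testing.assert_allclose(fit.shape, a, rtol=1e-4)
        np.testing.assert_allclose(fit.rate, 1 / scale, rtol=1e-4)

    def test_mle_stationarity(self, rng):
        # gradient of the log-likelihood vanishes at the reported optimum
        from scipy.special import digamma

        x = rng.gamma(shape=1.7, scale=2.0, size=2000)
        fit = fit_gamma_mle(x)
        grad_shape = np.mean(np.log(x)) - digamma(fit.shape) + np.log(fit.rate)
        grad_rate = fit.shape / fit.rate - np.mean(x)
        assert abs(grad_shape) < 1e-8
        assert abs(grad_rate) < 1e-8

    def test_bias_shrinks_with_n(self):
        rng = np.random.default_rng(123)
        errors = []
        for n in (1_000, 10_000, 100_000):
            reps = [fit_gamma_mle(rng.gamma(2.0, 1 / 3.0, size=n)).shape for _ in range(5)]
            errors.append(abs(np.mean(reps) - 2.0))
        assert errors[2] < errors[0]

    def test_constant_input_degenerate(self):
        fit = fit_gamma_mle(np.full(100, 2.5))
        assert not fit.fit_ok

    def test_zero_values_violate_contract(self):
        with pytest.raises(ValueError, match="positive"):
            fit_gamma_mle(np.array([0.0, 1.0, 2.0] * 10))

    def test_too_few_values(self):
        fit = fit_gamma_mle(np.array([1.0, 2.0]), min_fit_n=10)
        assert not fit.fit_ok
        assert "min_fit_n" in fit.message


class TestScoreWithNull:
    @staticmethod
    def null_from_draws(draws):
        return fit_gamma_null(
            {"total": [draws.reshape(-1, 1)],
             "plus": [draws.reshape(-1, 1)],
             "minus": [draws.reshape(-1, 1)]},
            ["K"],
        )

    def test_zero_distance_scores_zero(self, rng):
        null = self.null_from_draws(rng.gamma(2.0, 1.0, size=1000))
        S, P = score_with_null(np.array([[0.0]]), null, "total")
        assert S[0, 0] == 0.0 and P[0, 0] == 1.0

    def test_median_scores_half(self, rng):
        null = self.null_from_draws(rng.gamma(2.0, 1.0, size=5000))
        fit = null.for_direction("total")[0]
        median = stats.gamma.ppf(0.5, a=fit.shape, scale=1 / fit.rate)
        S, _ = score_with_null(np.array([[median]]), null, "total")
        np.testing.assert_allclose(S[0, 0], 0.5, atol=1e-12)

    def test_probability_integral_transform(self, rng):
        null = self.null_from_draws(rng.gamma(2.0, 1.0, size=20000))
        fit = null.for_direction("total")[0]
        draws = stats.gamma.rvs(a=fit.shape, scale=1 / fit.rate, size=5000,
                                random_state=rng)
        _, P = score_with_null(draws.reshape(-1, 1), null, "total")
        assert stats.kstest(P[:, 0], "uniform").pvalue > 0.01

    def test_failed_fit_yields_nan(self):
        null = fit_gamma_null(
            {d: [np.zeros((50, 1))] for d in ("total", "plus", "minus")}, ["K"]
        )
        S, P = score_with_null(np.ones((3, 1)), null, "total")
        assert np.isnan(S).all() and np.isnan(P).all()

    def test_unknown_direction(self, rng):
        null = self.null_from_draws(rng.gamma(2.0, 1.0, size=1000))
        with pytest.raises(KeyError, match="direction"):
            score_with_null(np.ones((1, 1)), null, "sideways")


class TestBhFdr:
    def test_all_equal(self):
        np.testing.assert_allclose(bh_fdr([0.2, 0.2, 0.2]), 0.2)

    def test_textbook_step_up(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p(self):
        np.testing.assert_allclose(bh_fdr([0.07]), [0.07])

    def test_statsmodels_oracle(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=200)
        expected = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(bh_fdr(p), expected, rtol=1e-12)

    def test_nan_family_exclusion(self):
        q = bh_fdr([0.01, np.nan, 0.02, 0.03])
        assert np.isnan(q[1])
        np.testing.assert_allclose(q[[0, 2, 3]], bh_fdr([0.01, 0.02, 0.03]))

    def test_out_of_range(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            bh_fdr([0.5, 1.5])

    def test_shape_preserved(self, rng):
        p = rng.uniform(size=(4, 5))
        assert bh_fdr(p).shape == (4, 5)

    @given(hnp.arrays(np.float64, 30, elements=st.floats(0, 1)))
    @settings(max_examples=50, deadline=None)
    def test_bounds_property(self, p):
        q = bh_fdr(p)
        assert np.all(q >= p - 1e-15)
        assert np.all(q <= 1.0)


def run_small_tpac(rng, n=30, p=40, seed=0, **config_kwargs):
    values = rng.gamma(2.0, 3.0, size=(n, p))
    gene_ids = [f"g{j}" for j in range(p)]
    sample_ids = [f"s{i}" for i in range(n)]
    t = values.mean(axis=0)
    sets = {f"K{k}": gene_ids[k * 8:(k + 1) * 8] for k in range(4)}
    collection = GeneSetCollection(sets=sets)
    config = TpacConfig(seed=seed, **config_kwargs)
    return tpac(values, sample_ids, gene_ids, t, t.copy(), collection, config), values, t


class TestTpacPipeline:
    def test_sample_matching_reference_scores_zero(self, rng):
        values = rng.gamma(2.0, 3.0, size=(10, 20))
        t = values[1:].mean(axis=0)
        values[0] = t  # one sample exactly at the reference
        gene_ids = [f"g{j}" for j in range(20)]
        collection = GeneSetCollection(sets={"K": gene_ids[:10]})
        result = tpac(values, [f"s{i}" for i in range(10)], gene_ids, t, t.copy(),
                      collection, TpacConfig(seed=1))
        assert result.S[0, 0] == 0.0
        assert result.P[0, 0] == 1.0

    def test_scores_bounded_and_p_complementary(self, rng):
        result, _, _ = run_small_tpac(rng)
        for direction in ("total", "plus", "minus"):
            S = result.scores(direction)
            assert np.all((S >= 0) & (S <= 1))
            np.testing.assert_allclose(result.pvalues(direction), 1 - S)

    def test_deterministic_given_seed(self, rng):
        values = rng.gamma(2.0, 3.0, size=(30, 40))
        gene_ids = [f"g{j}" for j in range(40)]
        sample_ids = [f"s{i}" for i in range(30)]
        t = values.mean(axis=0)
        collection = GeneSetCollection(sets={"K": gene_ids[:10]})
        r1 = tpac(values, sample_ids, gene_ids, t, t.copy(), collection, TpacConfig(seed=3))
        r2 = tpac(values, sample_ids, gene_ids, t, t.copy(), collection, TpacConfig(seed=3))
        np.testing.assert_array_equal(r1.S, r2.S)

    def test_inflating_deviation_increases_score(self, rng):
        values = rng.gamma(2.0, 3.0, size=(30, 40))
        gene_ids = [f"g{j}" for j in range(40)]
        sample_ids = [f"s{i}" for i in range(30)]
        t = values.mean(axis=0)
        collection = GeneSetCollection(sets={"K": gene_ids[:10]})
        result = tpac(values, sample_ids, gene_ids, t, t.copy(), collection, TpacConfig(seed=3))
        bumped = values.copy()
        bumped[0, :10] = t[:10] + 2 * (values[0, :10] - t[:10]) + 1.0
        result2 = tpac(bumped, sample_ids, gene_ids, t, t.copy(), collection, TpacConfig(seed=3))
        assert result2.S[0, 0] >= result.S[0, 0]

    def test_m_equals_m_plus_plus_m_minus(self, rng):
        # Eq-3-style conservation re-derived through public stages
        values = rng.gamma(2.0, 3.0, size=(20, 16))
        t = values.mean(axis=0)
        dev = split_deviations(values, t)
        wv = weighted_variances(values, np.ones(16))
        index = make_index({"K": list(range(8))})
        M_plus = set_distances(dev.delta_plus, wv.var_plus, index)
        M_minus = set_distances(dev.delta_minus, wv.var_minus, index)
        M = total_distances(M_plus, M_minus)
        np.testing.assert_array_equal(M, M_plus + M_minus)
        assert np.all(M >= 0)

    def test_row_permutation_equivariance(self, rng):
        # same null parameters => reordering samples reorders scores
        values = rng.gamma(2.0, 3.0, size=(20, 16))
        t = values.mean(axis=0)
        index = make_index({"K": list(range(8))})
        wv = weighted_variances(values, np.ones(16))
        draws = rng.gamma(3.0, 2.0, size=500)
        null = TestScoreWithNull.null_from_draws(draws)

        def score(v):
            dev = split_deviations(v, t)
            M = total_distances(
                set_distances(dev.delta_plus, wv.var_plus, index),
                set_distances(dev.delta_minus, wv.var_minus, index),
            )
            return score_with_null(M, null, "total")[0]

        perm = rng.permutation(20)
        np.testing.assert_allclose(score(values)[perm], score(values[perm]))

    def test_null_calibration_small(self):
        # spec's 200x100 Poisson null fixture with a 20-gene set
        rng = np.random.default_rng(7)
        values = rng.poisson(5.0, size=(200, 100)).astype(float)
        gene_ids = [f"g{j}" for j in range(100)]
        collection = GeneSetCollection(sets={"K": gene_ids[:20]})
        t = values.mean(axis=0)
        result = tpac(values, [f"s{i}" for i in range(200)], gene_ids, t, t.copy(),
                      collection, TpacConfig(seed=5))
        rate = np.mean(result.P[:, 0] < 0.05)
        assert 0.01 <= rate <= 0.09  # binomial 99% envelope around 0.05 at n=200

    def test_provenance_fields(self, rng):
        result, _, _ = run_small_tpac(rng)
        assert result.set_names == ["K0", "K1", "K2", "K3"]
        assert result.dropped_genes == []
        assert result.dropped_sets == []
        assert result.config.seed == 0

    def test_pandas_series_references(self, rng):
        import pandas as pd

        values = rng.gamma(2.0, 3.0, size=(10, 12))
        gene_ids = [f"g{j}" for j in range(12)]
        t = pd.Series(values.mean(axis=0), index=gene_ids)
        collection = GeneSetCollection(sets={"K": gene_ids[:6]})
        result = tpac(values, [f"s{i}" for i in range(10)], gene_ids, t, t * 1.0,
                      collection, TpacConfig(seed=2))
        assert result.S.shape == (10, 1)


class TestDirectionality:
    def test_doubling_t_star_halves_plus_doubles_minus(self, rng):
        # contribution of gene i: (delta+)^2/(var*t*) and (delta-)^2*t*/var
        values = rng.gamma(2.0, 3.0, size=(12, 6))
        t = values.mean(axis=0)
        dev = split_deviations(values, t)
        index = make_index({"K": [0]})
        for scale in (1.0, 2.0):
            t_star = np.ones(6)
            t_star[0] = scale
            wv = weighted_variances(values, t_star)
            M_plus = set_distances(dev.delta_plus, wv.var_plus, index)
            M_minus = set_distances(dev.delta_minus, wv.var_minus, index)
            if scale == 1.0:
                base_plus, base_minus = M_plus, M_minus
        np.testing.assert_allclose(M_plus, base_plus / 2.0, rtol=1e-12)
        np.testing.assert_allclose(M_minus, base_minus * 2.0, rtol=1e-12)
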