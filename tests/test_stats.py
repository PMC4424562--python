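"""Statistical core against independent oracles.

Every test here checks the package's own implementation against a second,
independent route: a direct formula, full enumeration, numerical
quadrature, an all-pairs count, or an established library implementation.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate
from scipy.stats import binomtest, chi2, hypergeom, nbinom

from epiremodel.intervals import GenomicInterval, IntervalSet
from epiremodel.stats import (
    ModeratedTPrior,
    auc_mann_whitney,
    bh_adjust,
    estimate_dispersion,
    fisher_combine,
    hypergeom_test,
    moderated_t,
    nb_exact_test,
    permutation_enrichment,
)


class TestBH:
    def test_single_p_identity(self):
        assert bh_adjust([0.05]) == pytest.approx([0.05])

    def test_matches_direct_formula(self):
        # adj for the i-th smallest p is min_{j >= i} m * p_(j) / j, capped
        p = np.array([0.01, 0.02, 0.03, 1.0])
        m = len(p)
        order = np.argsort(p)
        expected = np.empty(m)
        for pos, i in enumerate(order):
            expected[i] = min(1.0, min(
                m * p[order[j]] / (j + 1) for j in range(pos, m)
            ))
        assert bh_adjust(p) == pytest.approx(expected)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        p = rng.uniform(size=200)
        assert bh_adjust(p) == pytest.approx(
            multipletests(p, method="fdr_bh")[1])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50),
           st.randoms(use_true_random=False))
    @settings(max_examples=50, deadline=None)
    def test_permutation_equivariant_and_dominates_raw(self, ps, rnd):
        p = np.array(ps)
        adj = bh_adjust(p)
        assert np.all(adj >= p - 1e-12) and np.all(adj <= 1.0)
        perm = list(range(len(p)))
        rnd.shuffle(perm)
        assert bh_adjust(p[perm]) == pytest.approx(adj[perm])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestFisherCombine:
    def test_single_p_passthrough(self):
        assert fisher_combine([0.2]).p == pytest.approx(0.2)

    def test_matches_chi2_quadrature(self):
        x = -2 * (math.log(0.05) + math.log(0.05))
        tail, _ = integrate.quad(lambda t: chi2.pdf(t, 4), x, np.inf)
        assert fisher_combine([0.05, 0.05]).p == pytest.approx(tail, rel=1e-6)

    def test_all_ones(self):
        assert fisher_combine([1.0, 1.0, 1.0]).p == pytest.approx(1.0)

    def test_zero_clamped(self):
        res = fisher_combine([0.0, 0.5])
        assert 0.0 <= res.p < 1e-200


class TestAUC:
    def test_perfect_separation(self):
        assert auc_mann_whitney([0.8, 0.9], [0.1, 0.2]) == 1.0

    def test_tie_convention(self):
        assert auc_mann_whitney([0.5], [0.5]) == 0.5

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pos = rng.normal(0.6, 0.3, 20)
        neg = rng.normal(0.4, 0.3, 30)
        oracle = np.mean([
            1.0 if p > n else 0.5 if p == n else 0.0
            for p in pos for n in neg
        ])
        got = auc_mann_whitney(pos, neg)
        assert got == pytest.approx(oracle)
        assert auc_mann_whitney(neg, pos) == pytest.approx(1 - got)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(3)
        pos, neg = rng.normal(1, 1, 15), rng.normal(0, 1, 25)
        y = [1] * 15 + [0] * 25
        assert auc_mann_whitney(pos, neg) == pytest.approx(
            roc_auc_score(y, np.concatenate([pos, neg])))

    @given(st.lists(st.floats(-5, 5), min_size=1, max_size=15),
           st.lists(st.floats(-5, 5), min_size=1, max_size=15))
    @settings(max_examples=50, deadline=None)
    def test_invariant_under_monotone_transform(self, pos, neg):
        pos, neg = np.array(pos), np.array(neg)
        base = auc_mann_whitney(pos, neg)
        # power-of-two scaling is exact in floats, so ties stay ties
        trans = auc_mann_whitney(4.0 * pos, 4.0 * neg)
        assert trans == pytest.approx(base, abs=1e-9)

    def test_empty_group_error(self):
        with pytest.raises(ValueError):
            auc_mann_whitney([], [0.1])


class TestNBExact:
    def test_mode_split_p_is_one(self):
        res = nb_exact_test([5, 5], [5, 5], [100.0] * 4, 0.1)
        assert res.p == pytest.approx(1.0)

    @pytest.mark.parametrize("a,b", [([8, 9], [3, 2]), ([1, 0], [4, 6]),
                                     ([10, 12], [10, 9])])
    def test_dispersion_zero_matches_binomial(self, a, b):
        res = nb_exact_test(a, b, [50.0] * 4, 0.0)
        sa, total = sum(a), sum(a) + sum(b)
        oracle = binomtest(sa, total, 0.5).pvalue
        assert res.p == pytest.approx(oracle, rel=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_small_totals_match_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 8, size=2)
        b = rng.integers(0, 8, size=3)
        phi = 0.15
        res = nb_exact_test(a, b, [30.0] * 5, phi)
        # independent enumeration of the conditional two-sided p
        total = int(a.sum() + b.sum())
        na, nb_ = len(a), len(b)
        frac = na / (na + nb_)
        k = np.arange(total + 1)
        pa = nbinom.pmf(k, na / phi, (na / phi) / (na / phi + total * frac))
        pb = nbinom.pmf(total - k, nb_ / phi,
                        (nb_ / phi) / (nb_ / phi + total * (1 - frac)))
        joint = pa * pb
        joint /= joint.sum()
        obs = joint[int(a.sum())]
        oracle = joint[joint <= obs * (1 + 1e-9)].sum()
        assert res.p == pytest.approx(oracle, rel=1e-6)

    def test_symmetric_under_group_swap(self):
        r1 = nb_exact_test([9, 7], [2, 3], [40.0] * 4, 0.1)
        r2 = nb_exact_test([2, 3], [9, 7], [40.0] * 4, 0.1)
        assert r1.p == pytest.approx(r2.p)
        assert r1.effect == pytest.approx(-r2.effect)

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ValueError):
            nb_exact_test([1], [1], [1.0, 1.0], -0.1)


class TestDispersion:
    def test_poisson_counts_near_zero(self):
        rng = np.random.default_rng(0)
        y = rng.poisson(20.0, size=(2000, 8))
        assert estimate_dispersion(y, np.full(8, y.sum() / 8)) <= 0.05

    def test_nb_parameter_recovery(self):
        rng = np.random.default_rng(1)
        phi = 0.2
        mu = rng.uniform(10, 60, size=2000)[:, None]
        r = 1 / phi
        y = rng.negative_binomial(r, r / (r + mu), size=(2000, 8))
        est = estimate_dispersion(y, np.full(8, 1000.0))
        assert 0.1 <= est <= 0.3

    def test_single_row_finite(self):
        est = estimate_dispersion(np.array([[3, 5, 4, 6]]),
                                  np.full(4, 100.0))
        assert est >= 0 and np.isfinite(est)

    def test_constant_matrix_floors_at_zero(self):
        with pytest.warns(UserWarning):
            assert estimate_dispersion(np.zeros((5, 4)),
                                       np.full(4, 10.0)) == 0.0

    def test_grouped_estimate_ignores_between_group_shift(self):
        rng = np.random.default_rng(2)
        a = rng.poisson(10.0, size=(1500, 4))
        b = rng.poisson(40.0, size=(1500, 4))
        y = np.hstack([a, b])
        libs = np.full(8, y.sum() / 8)
        pooled = estimate_dispersion(y, libs)
        grouped = estimate_dispersion(y, libs, ["a"] * 4 + ["b"] * 4)
        assert grouped <= 0.05 < pooled


class TestModeratedT:
    def test_identical_groups_give_null(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(50, 4))
        res = moderated_t(x, x.copy())
        assert np.allclose(res["statistic"], 0.0)
        assert np.allclose(res["p"], 1.0)

    def test_infinite_prior_reduces_to_z_with_pooled_s0(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, size=(30, 4))
        b = rng.normal(0, 1, size=(30, 4))
        prior = ModeratedTPrior(math.inf, 1.0)
        res = moderated_t(a, b, prior=prior)
        z = (a.mean(1) - b.mean(1)) / math.sqrt(1.0 * (1 / 4 + 1 / 4))
        assert np.allclose(res["statistic"], z)
        from scipy.stats import norm

        assert np.allclose(res["p"], 2 * norm.sf(np.abs(z)))

    def test_zero_prior_df_equals_pooled_t(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, size=(20, 5))
        b = rng.normal(0, 1, size=(20, 5))
        res = moderated_t(a, b, prior=ModeratedTPrior(0.0, 1.0))
        from scipy.stats import ttest_ind

        t, p = ttest_ind(a, b, axis=1, equal_var=True)
        assert np.allclose(res["statistic"], t)
        assert np.allclose(res["p"], p)

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(2000, 4))
        b = rng.normal(size=(2000, 4))
        res = moderated_t(a, b)
        rate = float((res["p"] < 0.05).mean())
        assert 0.02 <= rate <= 0.09

    def test_all_zero_variance_floored_with_warning(self):
        a = np.ones((5, 3))
        b = np.zeros((5, 3))
        with pytest.warns(UserWarning):
            res = moderated_t(a, b)
        assert res.attrs["variance_floored"]
        assert np.all(np.isfinite(res["statistic"]))


class TestHypergeom:
    def test_saturated_and_empty(self):
        assert hypergeom_test(10, 100, 10, 100).p == pytest.approx(1.0)
        assert hypergeom_test(0, 5, 10, 100).p == pytest.approx(1.0)

    def test_matches_pmf_summation(self):
        k, K, n, N = 3, 5, 10, 100
        oracle = sum(hypergeom.pmf(x, N, K, n) for x in range(k, min(K, n) + 1))
        assert hypergeom_test(k, K, n, N).p == pytest.approx(oracle, rel=1e-9)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_test(6, 5, 10, 100)


class TestPermutationEnrichment:
    @staticmethod
    def _universe(n=300, w=50):
        return IntervalSet([
            GenomicInterval("c", i * 2 * w, i * 2 * w + w) for i in range(n)
        ])

    def test_feature_equals_universe_saturates(self):
        uni = self._universe()
        rng = np.random.default_rng(0)
        query = IntervalSet([uni[i] for i in rng.choice(len(uni), 40,
                                                        replace=False)])
        res = permutation_enrichment(query, uni, uni, n_perm=300, seed=1)
        assert res.fold == pytest.approx(1.0, abs=0.05)
        assert res.p > 0.05

    def test_null_query_fold_near_one(self):
        uni = self._universe()
        rng = np.random.default_rng(2)
        feature = IntervalSet([uni[i] for i in rng.choice(len(uni), 60,
                                                          replace=False)])
        query = IntervalSet([uni[i] for i in rng.choice(len(uni), 50)])
        res = permutation_enrichment(query, feature, uni, n_perm=1000, seed=3)
        assert 0.5 <= res.fold <= 2.0

    def test_constructed_enrichment_detected(self):
        uni = self._universe()
        feature = IntervalSet([uni[i] for i in range(40)])
        query = IntervalSet([uni[i] for i in range(30)])  # all inside feature
        res = permutation_enrichment(query, feature, uni, n_perm=1000, seed=4)
        assert res.fold > 1
        assert res.p <= 0.01

    def test_query_outside_universe_rejected(self):
        uni = self._universe(10)
        query = IntervalSet([GenomicInterval("other", 0, 10)])
        with pytest.raises(ValueError):
            permutation_enrichment(query, uni, uni, n_perm=100, seed=0)
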