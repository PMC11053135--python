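"""Exact nonparametric tests: printed-table values, enumeration oracles,
tie handling, adjustments and invariances."""

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

import eesmap as em
from eesmap.errors import DegenerateTestError, ParameterError

from oracles import kruskal_h_formula, mannwhitney_brute, wilcoxon_brute

# the per-cat %BG pairs (rostral, caudal) behind the paired site-specificity tests
CYST_PAIRS = [(3077, 80), (4600, 3400), (9500, 1100), (14500, 5700), (2070, 81)]
DETR_PAIRS = [(1630, 170), (360, 180), (2050, 450), (2500, 120), (360, 85)]
EUS_PAIRS = [(555, 300), (850, 820), (270, 115), (900, 230), (1010, 110)]  # (caudal, rostral)


class TestWilcoxonExact:
    def test_five_positive_pairs_one_sided_p(self):
        # five concordant pairs -> one tail of 2^5 = 1/32
        for pairs in (CYST_PAIRS, DETR_PAIRS, EUS_PAIRS):
            a, b = zip(*pairs)
            res = em.wilcoxon_exact(a, b, alternative="greater")
            assert res.p_value == pytest.approx(1 / 32)
            assert res.exact and res.statistic == 15.0
            assert em.round_half_up(res.p_value, 4) == 0.0313

    def test_all_equal_pairs_degenerate(self):
        with pytest.raises(DegenerateTestError):
            em.wilcoxon_exact([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_any_all_positive_magnitudes_give_one_over_32(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            d = rng.uniform(0.1, 100.0, size=5)
            res = em.wilcoxon_exact(d, np.zeros(5), alternative="greater")
            assert res.p_value == pytest.approx(1 / 32)

    def test_zero_differences_dropped(self):
        res = em.wilcoxon_exact([5, 2, 3, 7], [5, 1, 1, 2], alternative="greater")
        ref = em.wilcoxon_exact([2, 3, 7], [1, 1, 2], alternative="greater")
        assert res.p_value == ref.p_value
        assert res.n == (4,)

    def test_matches_scipy_exact_no_ties(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = rng.integers(3, 10)
            a = rng.normal(size=n)
            b = rng.normal(size=n)
            for alt in ("two-sided", "greater", "less"):
                ours = em.wilcoxon_exact(a, b, alternative=alt).p_value
                ref = scipy.stats.wilcoxon(a, b, alternative=alt,
                                           method="exact").pvalue
                assert ours == pytest.approx(ref, rel=1e-12)

    def test_normal_approximation_path(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0.4, 1.0, size=40)
        res = em.wilcoxon_exact(a, np.zeros(40), method="approx")
        assert not res.exact
        exact = em.wilcoxon_exact(a, np.zeros(40), method="exact")
        assert exact.exact
        assert res.p_value == pytest.approx(exact.p_value, rel=0.15)


class TestMannWhitneyExact:
    @pytest.mark.parametrize("n1,n2,expected", [(4, 5, 2 / 126), (3, 5, 2 / 56)])
    def test_complete_separation_two_sided(self, n1, n2, expected):
        x = list(range(1, n1 + 1))
        y = list(range(n1 + 1, n1 + n2 + 1))
        res = em.mannwhitney_exact(x, y)
        assert res.p_value == pytest.approx(expected)
        assert res.exact

    def test_identical_samples_p_one(self):
        res = em.mannwhitney_exact([1, 2, 2, 3], [1, 2, 2, 3])
        assert res.p_value == 1.0

    def test_matches_scipy_exact_no_ties(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.normal(size=rng.integers(2, 8))
            y = rng.normal(size=rng.integers(2, 8))
            for alt in ("two-sided", "greater", "less"):
                ours = em.mannwhitney_exact(x, y, alternative=alt)
                ref = scipy.stats.mannwhitneyu(x, y, alternative=alt,
                                               method="exact")
                assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-12)
                assert ours.statistic == pytest.approx(ref.statistic)

    def test_empty_sample_rejected(self):
        with pytest.raises(ParameterError):
            em.mannwhitney_exact([], [1, 2])


class TestEnumerationOracles:
    """Implementation vs literal enumeration, including ties."""

    def test_wilcoxon_agrees_with_brute_force(self):
        rng = np.random.default_rng(10)
        for _ in range(40):
            n = int(rng.integers(2, 9))
            a = rng.integers(0, 5, size=n).astype(float)
            b = rng.integers(0, 5, size=n).astype(float)
            if np.all(a == b):
                continue
            for alt in ("two-sided", "greater", "less"):
                assert em.wilcoxon_exact(a, b, alternative=alt).p_value == (
                    pytest.approx(wilcoxon_brute(a, b, alt), rel=1e-12)
                )

    def test_mannwhitney_agrees_with_brute_force(self):
        rng = np.random.default_rng(11)
        for _ in range(40):
            x = rng.integers(0, 6, size=int(rng.integers(1, 9))).astype(float)
            y = rng.integers(0, 6, size=int(rng.integers(1, 9))).astype(float)
            for alt in ("two-sided", "greater", "less"):
                assert em.mannwhitney_exact(x, y, alternative=alt).p_value == (
                    pytest.approx(mannwhitney_brute(x, y, alt), rel=1e-12)
                )


class TestKruskalWallis:
    def test_hand_computed_h(self):
        res = em.kruskal_wallis([[1, 2], [3, 4], [5, 6]])
        assert res.statistic == pytest.approx(32 / 7, abs=1e-9)
        assert res.p_value == pytest.approx(
            scipy.stats.kruskal([1, 2], [3, 4], [5, 6]).pvalue, rel=1e-12
        )

    def test_identical_groups_h_zero(self):
        res = em.kruskal_wallis([[2, 2], [2, 2], [2, 2]])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_tie_correction_matches_scipy(self):
        groups = [[1, 2, 2], [2, 3, 3], [1, 1, 4]]
        res = em.kruskal_wallis(groups)
        ref = scipy.stats.kruskal(*groups)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert res.tie_corrected

    def test_h_invariant_under_group_label_permutation(self):
        # pooled data fixed; permuting which values belong to which group
        # changes H, but the *null* permutation distribution is invariant:
        # check by comparing exact permutation p-values from two orderings
        g1 = [[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]]
        g2 = [[3.0, 6.0], [1.0, 4.0], [2.0, 5.0]]
        p1 = em.kruskal_wallis(g1, method="permutation").p_value
        p2 = em.kruskal_wallis(g2, method="permutation").p_value
        assert p1 == p2

    def test_permutation_p_is_valid_for_tiny_samples(self):
        res = em.kruskal_wallis([[1, 2], [3, 4], [5, 6]], method="permutation")
        assert res.exact and 0 < res.p_value <= 1


class TestDunn:
    def test_identical_groups_have_p_one(self):
        out = em.dunn_posthoc([[1, 2, 3], [1, 2, 3], [10, 11, 12]])
        first_pair = next(r for r in out if r.pair == (0, 1))
        assert first_pair.p_value == pytest.approx(1.0)

    def test_extreme_pair_has_largest_z(self):
        out = em.dunn_posthoc([[1, 2], [3, 4], [5, 6]])
        zs = {r.pair: abs(r.statistic) for r in out}
        assert zs[(0, 2)] == max(zs.values())

    def test_bonferroni_multiplies_and_caps(self):
        raw = em.dunn_posthoc([[1, 2], [3, 4], [5, 6]])
        adj = em.dunn_posthoc([[1, 2], [3, 4], [5, 6]], adjustment="bonferroni")
        for r, a in zip(raw, adj):
            assert a.p_value == pytest.approx(min(1.0, 3 * r.p_value))

    def test_holm_is_monotone_and_bounded_by_bonferroni(self):
        groups = [[1, 5, 2], [8, 9, 7], [3, 4, 6]]
        raw = em.dunn_posthoc(groups)
        holm = em.dunn_posthoc(groups, adjustment="holm")
        bonf = em.dunn_posthoc(groups, adjustment="bonferroni")
        for r, h, b in zip(raw, holm, bonf):
            assert r.p_value <= h.p_value <= b.p_value + 1e-15


class TestMeanSE:
    @pytest.mark.parametrize("values,mean,se", [([2, 4], 3.0, 1.0),
                                                ([5], 5.0, 0.0),
                                                ([7, 7, 7], 7.0, 0.0)])
    def test_examples(self, values, mean, se):
        s = em.mean_se(values)
        assert (s.mean, s.se) == (mean, se)
        assert s.degenerate == (len(values) == 1)


class TestRankInvariance:
    @settings(derandomize=True, max_examples=40)
    @given(st.lists(st.integers(-20, 20), min_size=2, max_size=7),
           st.lists(st.integers(-20, 20), min_size=2, max_size=7))
    def test_mannwhitney_invariant_under_monotone_transform(self, x, y):
        # cubing preserves order and ties on integers
        f = lambda v: [float(t) ** 3 for t in v]
        p0 = em.mannwhitney_exact(x, y).p_value
        p1 = em.mannwhitney_exact(f(x), f(y)).p_value
        assert p0 == pytest.approx(p1, rel=1e-12)

    @settings(derandomize=True, max_examples=40)
    @given(st.lists(st.tuples(st.integers(-9, 9), st.integers(-9, 9)),
                    min_size=2, max_size=7))
    def test_wilcoxon_invariant_under_shared_positive_scaling(self, pairs):
        a = np.array([p[0] for p in pairs], dtype=float)
        b = np.array([p[1] for p in pairs], dtype=float)
        if np.all(a == b):
            return
        p0 = em.wilcoxon_exact(a, b).p_value
        p1 = em.wilcoxon_exact(3.5 * a, 3.5 * b).p_value
        assert p0 == pytest.approx(p1, rel=1e-12)


def test_wilcoxon_type_i_error_is_conservative():
    """Exact discrete test at alpha=0.05 rejects at most ~5% under the null."""
    rng = np.random.default_rng(42)
    n_rep, n = 10_000, 6
    d = rng.normal(size=(n_rep, n))
    rejections = 0
    for i in range(n_rep):
        p = em.wilcoxon_exact(d[i], np.zeros(n)).p_value
        rejections += p <= 0.05
    rate = rejections / n_rep
    mc_se = np.sqrt(0.05 * 0.95 / n_rep)
    assert rate <= 0.05 + 2 * mc_se


def test_round_half_up_prints_conventional_p():
    assert em.round_half_up(1 / 32, 4) == 0.0313
    assert em.round_half_up(2 / 126, 4) == 0.0159
    assert em.round_half_up(2 / 56, 4) == 0.0357
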