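"""Per-family correlations, permutation null, shift tests and BH-FDR."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import neogfs as ng
from neogfs.association import UndefinedCorrelationError, matrix_pearson
from neogfs.data_io import GeneFamilyMatrix


def _matrix(sizes, species=None):
    sizes = np.asarray(sizes)
    species = species or [f"s{i}" for i in range(sizes.shape[1])]
    return GeneFamilyMatrix([f"F{i}" for i in range(sizes.shape[0])], species, sizes)


class TestPearson:
    def test_perfect_positive(self):
        r, p = ng.pearson_r([1, 2, 3], [2, 4, 6])
        assert r == pytest.approx(1.0)

    def test_perfect_negative(self):
        r, _ = ng.pearson_r([1, 2, 3], [6, 4, 2])
        assert r == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        r, p = ng.pearson_r([1, 2, 3, 4, 5], [1, 3, 2, 5, 4])
        assert r == pytest.approx(0.8)
        assert p == pytest.approx(0.104, abs=5e-4)

    def test_zero_variance_raises(self):
        with pytest.raises(UndefinedCorrelationError):
            ng.pearson_r([1, 1, 1], [1, 2, 3])

    def test_too_few_points(self):
        with pytest.raises(UndefinedCorrelationError):
            ng.pearson_r([1, 2], [1, 2])


class TestFamilyAssociations:
    def test_family_equal_to_phenotype(self):
        y = np.arange(28.0) + 1
        res = ng.family_associations(_matrix([list(range(1, 29))]), y)
        assert res[0].r == pytest.approx(1.0)
        assert res[0].p < 0.001

    def test_constant_family_under_drop_policy_is_na(self):
        y = np.arange(10.0)
        sizes = np.vstack([[2] * 5 + [0] * 5, np.arange(10)])
        with pytest.warns(UserWarning, match="undefined"):
            res = ng.family_associations(_matrix(sizes), y, absent_policy="drop")
        assert not res[0].is_defined
        assert res[1].is_defined and res[1].n == 9  # one zero dropped

    def test_null_families_p_calibration(self, rng):
        # iid noise families: about 5% of two-sided p-values fall below 0.05
        y = rng.normal(size=28)
        sizes = rng.poisson(5.0, size=(400, 28))
        m = _matrix(sizes)
        kept, _ = ng.filter_families(m)
        res = ng.family_associations(kept, y)
        frac = np.mean([r.p < 0.05 for r in res])
        assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / len(res))

    def test_matches_scalar_pearson(self, rng):
        y = rng.normal(size=12)
        sizes = rng.poisson(4.0, size=(5, 12))
        res = ng.family_associations(_matrix(sizes), y)
        for i, r in enumerate(res):
            if np.ptp(sizes[i]) == 0:
                continue
            expect_r, expect_p = ng.pearson_r(sizes[i], y)
            assert r.r == pytest.approx(expect_r, abs=1e-12)
            assert r.p == pytest.approx(expect_p, rel=1e-9)

    def test_species_mismatch_rejected(self):
        with pytest.raises(ValueError, match="phenotype length"):
            ng.family_associations(_matrix([[1, 2, 3]]), np.array([1.0, 2.0]))


class TestPermutationNull:
    def test_exhaustive_matches_brute_force(self, rng):
        sizes = rng.poisson(4.0, size=(3, 4)) + np.arange(4)  # ensure variance
        y = np.array([0.5, 1.5, -1.0, 2.0])
        m = _matrix(sizes.astype(int))
        null = ng.permutation_null(m, y, exhaustive=True)
        expected = []
        for perm in itertools.permutations(range(4)):
            rs = [stats.pearsonr(sizes[i], y[list(perm)]).statistic for i in range(3)]
            expected.append(np.mean(rs))
        np.testing.assert_allclose(null.replicate_means, expected, atol=1e-12)
        assert null.n_replicates == 24

    def test_same_seed_identical(self, bundle):
        m, _ = ng.filter_families(bundle["matrix"])
        y = bundle["table"].reordered(m.species_ids).trait("nr")
        a = ng.permutation_null(m, y, n_replicates=200, seed=9)
        b = ng.permutation_null(m, y, n_replicates=200, seed=9)
        np.testing.assert_array_equal(a.replicate_means, b.replicate_means)

    def test_schemes_agree_on_single_family(self, rng):
        sizes = rng.poisson(6.0, size=(1, 8))
        y = rng.normal(size=8)
        m = _matrix(sizes)
        a = ng.permutation_null(m, y, n_replicates=300, scheme="joint", seed=1)
        b = ng.permutation_null(m, y, n_replicates=300, scheme="per_family", seed=1)
        # with one family the two schemes sample the same distribution
        assert abs(a.replicate_means.mean() - b.replicate_means.mean()) < 0.05

    def test_constant_phenotype_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            ng.permutation_null(_matrix([[1, 2, 3, 4]]), np.ones(4))

    def test_small_replicate_count_warns(self):
        with pytest.warns(UserWarning, match="unstable"):
            ng.permutation_null(_matrix([[1, 2, 3, 4]]), np.arange(4.0),
                                n_replicates=50, seed=0)


class TestZScoreShift:
    def test_observed_at_null_mean_gives_half(self):
        null = ng.NullDistribution(np.array([-0.1, 0.0, 0.1, 0.0]), 4, None, "joint")
        z, p, _ = ng.zscore_shift_test(0.0, null)
        assert z == 0.0
        assert p == pytest.approx(0.5)

    def test_printed_z_to_p_convention(self):
        assert round(ng.normal_upper_tail_p(2.225819868), 3) == 0.013
        assert round(ng.normal_upper_tail_p(1.70943), 3) == 0.044

    def test_degenerate_null_rejected(self):
        null = ng.NullDistribution(np.zeros(10), 10, None, "joint")
        with pytest.raises(ValueError, match="degenerate"):
            ng.zscore_shift_test(0.5, null)

    def test_empirical_p_never_zero(self):
        null = ng.NullDistribution(np.linspace(-1, 1, 99), 99, None, "joint")
        _, _, p_emp = ng.zscore_shift_test(10.0, null)
        assert p_emp == pytest.approx(1 / 100)


class TestSignChisq:
    def test_balanced_counts(self):
        chi2, p, *_ = ng.sign_chisq_counts(50, 50)
        assert chi2 == 0.0
        assert p == pytest.approx(1.0)

    def test_one_sided_counts(self):
        chi2, p, *_ = ng.sign_chisq_counts(0, 10)
        assert chi2 == pytest.approx(10.0)
        assert p == pytest.approx(0.00157, abs=5e-5)

    def test_headline_counts(self):
        chi2, p, *_ = ng.sign_chisq_counts(8951, 2992)
        assert chi2 == pytest.approx(2973.263, abs=5e-4)
        assert p < 1e-20

    def test_zero_r_excluded_and_order_invariant(self, rng):
        res = [ng.AssociationResult(f"F{i}", r, 0.5, 0.5, 10)
               for i, r in enumerate([0.5, -0.2, 0.0, 0.3, float("nan")])]
        chi2, p, n_pos, n_neg = ng.sign_chisq(res)
        assert (n_pos, n_neg) == (2, 1)
        shuffled = [res[i] for i in rng.permutation(len(res))]
        assert ng.sign_chisq(shuffled) == (chi2, p, n_pos, n_neg)


def _brute_force_bh(p):
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        q[i] = prev
    return q


class TestBhFdr:
    def test_single_p(self):
        assert ng.bh_fdr([0.05]).tolist() == [0.05]

    def test_step_up_example(self):
        np.testing.assert_allclose(ng.bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert ng.bh_fdr([1.0, 1.0]).tolist() == [1.0, 1.0]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ng.bh_fdr([0.5, 1.5])

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
    def test_matches_brute_force(self, pvals):
        np.testing.assert_allclose(ng.bh_fdr(pvals), _brute_force_bh(np.array(pvals)),
                                   atol=1e-12)

    def test_q_at_least_p(self, rng):
        p = rng.uniform(size=500)
        assert (ng.bh_fdr(p) >= p - 1e-15).all()
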