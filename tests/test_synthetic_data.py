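"""Generators: determinism, shape contracts and planted-signal sanity."""

import numpy as np
import pytest

import neogfs as ng
from neogfs.synthetic_data import BRAINSPAN_AGES_YEARS, BRAINSPAN_REGIONS


class TestSimulateTree:
    def test_reproducible_ultrametric_28_tips(self):
        a = ng.simulate_tree(28, seed=3)
        b = ng.simulate_tree(28, seed=3)
        assert a.is_ultrametric()
        assert len(a.tip_labels) == 28
        assert a.to_newick() == b.to_newick()
        assert a.height == pytest.approx(1.0)

    def test_three_tips_two_internal_nodes(self):
        t = ng.simulate_tree(3, seed=0)
        internal = [n for n in t.tree.preorder_node_iter() if not n.is_leaf()]
        assert len(internal) == 2

    def test_different_seeds_differ(self):
        assert ng.simulate_tree(28, seed=1).to_newick() != \
               ng.simulate_tree(28, seed=2).to_newick()

    def test_too_few_tips_rejected(self):
        with pytest.raises(ValueError):
            ng.simulate_tree(2, seed=0)

    def test_strictly_positive_branch_lengths(self):
        t = ng.simulate_tree(28, seed=11)
        lengths = [e.length for e in t.tree.preorder_edge_iter()
                   if e.head_node is not t.tree.seed_node]
        assert min(lengths) > 0


class TestSimulateTraits:
    def test_fixed_seed_identical(self):
        tree = ng.simulate_tree(10, seed=1)
        a = ng.simulate_traits(tree, seed=2)
        b = ng.simulate_traits(tree, seed=2)
        np.testing.assert_array_equal(a.trait("nr"), b.trait("nr"))

    def test_volumes_invert_to_simulated_nr(self):
        tree = ng.simulate_tree(10, seed=1)
        table = ng.simulate_traits(tree, seed=2)
        for rec in table:
            assert ng.compute_nr(rec.brain_volume, rec.neocortex_volume) == \
                pytest.approx(rec.nr, rel=1e-9)

    def test_covariance_scaling_scales_contrast_variance(self):
        tree = ng.simulate_tree(12, seed=4)
        L, _ = ng.contrasts_matrix(tree, tree.tip_labels)
        var = {}
        for c in (1.0, 4.0):
            contrasts = []
            for rep in range(60):
                t = ng.simulate_traits(tree, covariance=c * np.eye(3), seed=rep)
                contrasts.append(L @ np.log(t.trait("nr")))
            var[c] = np.var(np.concatenate(contrasts))
        assert var[4.0] / var[1.0] == pytest.approx(4.0, rel=0.25)

    def test_uncorrelated_traits_give_centred_pic_correlation(self):
        tree = ng.simulate_tree(12, seed=4)
        L, _ = ng.contrasts_matrix(tree, tree.tip_labels)
        rs = []
        for rep in range(200):
            t = ng.simulate_traits(tree, covariance=np.eye(3) * 0.3, seed=rep)
            u, v = L @ np.log(t.trait("nr")), L @ t.trait("ei")
            rs.append(ng.corr_through_origin(u, v)[0])
        assert abs(np.mean(rs)) < 3 * np.std(rs) / np.sqrt(len(rs)) + 0.02

    def test_non_pd_covariance_rejected(self):
        tree = ng.simulate_tree(5, seed=1)
        with pytest.raises(ValueError, match="positive-definite"):
            ng.simulate_traits(tree, covariance=-np.eye(3), seed=0)


@pytest.fixture(scope="module")
def tree_table():
    tree = ng.simulate_tree(28, seed=7)
    return tree, ng.simulate_traits(tree, seed=8)


class TestSimulateGfs:
    def test_null_positive_fraction_near_half(self, tree_table):
        tree, table = tree_table
        m, truth = ng.simulate_gfs(table, tree, n_families=400, frac_planted=0.0,
                                   beta=0.0, phylo_noise_sd=0.0, seed=9)
        assert truth.planted_family_ids == set()
        kept, _ = ng.filter_families(m)
        res = ng.family_associations(kept, table.reordered(kept.species_ids).trait("nr"))
        frac_pos = np.mean([r.r > 0 for r in res if r.is_defined])
        assert abs(frac_pos - 0.5) < 3 * np.sqrt(0.25 / len(res))

    def test_planted_families_shift_upward(self, tree_table):
        tree, table = tree_table
        m, truth = ng.simulate_gfs(table, tree, n_families=1000, frac_planted=0.1,
                                   beta=1.5, seed=10)
        kept, _ = ng.filter_families(m)
        res = ng.family_associations(kept, table.reordered(kept.species_ids).trait("nr"))
        rp = np.mean([r.r for r in res
                      if r.is_defined and r.family_id in truth.planted_family_ids])
        ru = np.mean([r.r for r in res
                      if r.is_defined and r.family_id not in truth.planted_family_ids])
        assert rp > ru + 0.3

    def test_fixed_seed_identical(self, tree_table):
        tree, table = tree_table
        a, _ = ng.simulate_gfs(table, tree, n_families=50, seed=3)
        b, _ = ng.simulate_gfs(table, tree, n_families=50, seed=3)
        np.testing.assert_array_equal(a.sizes, b.sizes)

    def test_invalid_fraction_rejected(self, tree_table):
        tree, table = tree_table
        with pytest.raises(ValueError):
            ng.simulate_gfs(table, tree, frac_planted=1.5, seed=0)


class TestSimulateAnnotations:
    def test_planted_bias_concentrates_planted_families(self, bundle):
        truth = bundle["truth"]
        ann = bundle["annotations"]
        planted = truth.planted_family_ids
        bg_freq = len(planted) / len(truth.family_ids)
        for term in truth.planted_terms:
            members = ann.families_for_term(term)
            assert len(members & planted) / len(members) > bg_freq * 2

    def test_unbiased_terms_not_enriched(self, bundle):
        truth = bundle["truth"]
        matrix = bundle["matrix"]
        ann, _ = ng.simulate_annotations(matrix, truth, n_planted_terms=0,
                                         planted_bias=1.0, seed=77)
        planted = truth.planted_family_ids
        fracs = [len(ann.families_for_term(t) & planted) / len(ann.families_for_term(t))
                 for t in sorted(ann.terms)]
        assert abs(np.mean(fracs) - len(planted) / len(truth.family_ids)) < 0.05

    def test_fixed_seed_identical(self, bundle):
        truth = bundle["truth"]
        a, _ = ng.simulate_annotations(bundle["matrix"], truth, seed=5)
        b, _ = ng.simulate_annotations(bundle["matrix"], truth, seed=5)
        assert a.pairs == b.pairs


class TestSimulateExpression:
    def test_brainspan_shape_143_samples(self, bundle):
        expr = bundle["expression"]
        assert len(expr.sample_ids) == len(BRAINSPAN_AGES_YEARS) * len(BRAINSPAN_REGIONS)
        assert len(expr.sample_ids) == 143

    def test_no_effect_gives_unshifted_windows(self):
        tree = ng.simulate_tree(8, seed=1)
        table = ng.simulate_traits(tree, seed=1)
        _, truth = ng.simulate_gfs(table, tree, n_families=50, frac_planted=0.2, seed=1)
        ps = []
        for rep in range(10):
            expr = ng.simulate_expression(truth, early_multiplier=1.0, seed=rep)
            ws = ng.window_means(ng.normalize_samples(expr),
                                 gene_subset=truth.genes_of_planted_families())
            ps.append(ng.paired_wilcoxon(ws, alternative="two_sided")[1])
        assert np.mean(ps) > 0.15  # no systematic shift without the effect

    def test_fixed_seed_identical(self, bundle):
        truth = bundle["truth"]
        a = ng.simulate_expression(truth, seed=6)
        b = ng.simulate_expression(truth, seed=6)
        np.testing.assert_array_equal(a.values.to_numpy(), b.values.to_numpy())

    def test_degenerate_ages_rejected(self, bundle):
        with pytest.raises(ValueError, match="ages"):
            ng.simulate_expression(bundle["truth"], ages=[1.0, 2.0], seed=0)


def test_bundle_is_pure_function_of_seed():
    a = ng.simulate_bundle(seed=5)
    b = ng.simulate_bundle(seed=5)
    np.testing.assert_array_equal(a["matrix"].sizes, b["matrix"].sizes)
    assert a["annotations"].pairs == b["annotations"].pairs
    assert a["tree"].to_newick() == b["tree"].to_newick()
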