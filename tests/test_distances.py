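import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microbeta import (
    DistanceSpec,
    OtuTable,
    PhyloTree,
    ValidationError,
    bray_curtis,
    distance_matrix,
    generalized_unifrac,
    jaccard,
    presence_weighted_unifrac,
    to_presence,
    to_proportions,
    unweighted_unifrac,
    weighted_unifrac,
)
from microbeta.distances import branch_profiles, condensed_distances, leaf_descendant_matrix


def brute_force_branch_leafsets(tree):
    """Independent oracle: descendant leaf sets per branch via explicit
    recursion, bypassing the indicator-matrix construction."""
    sets = {}

    def rec(node):
        if node.is_tip():
            sets[id(node)] = {node.name}
            return {node.name}
        acc = set()
        for ch in node.children:
            acc |= rec(ch)
        sets[id(node)] = acc
        return acc

    rec(tree.tree)
    out = []
    for node in tree.tree.postorder(include_self=False):
        out.append((sets[id(node)], node.length))
    return out


class TestBranchProfiles:
    def test_hand_abundance_accumulation(self, three_leaf_tree):
        table = OtuTable(["s"], ["A", "B", "C"], [[5, 5, 0]])
        prof = branch_profiles(three_leaf_tree, to_proportions(table), to_presence(table))
        # postorder: A, B, I, C
        np.testing.assert_allclose(prof.abundance[0], [0.5, 0.5, 1.0, 0.0])

    def test_hand_richness_accumulation(self, three_leaf_tree):
        table = OtuTable(["s"], ["A", "B", "C"], [[5, 5, 0]])
        prof = branch_profiles(three_leaf_tree, to_proportions(table), to_presence(table))
        np.testing.assert_allclose(prof.richness[0], [1, 1, 2, 0])

    def test_all_zero_sample(self, three_leaf_tree):
        table = OtuTable(["s", "t"], ["A", "B", "C"], [[0, 0, 0], [1, 1, 1]])
        prof = branch_profiles(three_leaf_tree, to_proportions(table), to_presence(table))
        assert prof.abundance[0].sum() == 0
        assert prof.richness[0].sum() == 0

    def test_unmatched_otu_errors(self, three_leaf_tree):
        table = OtuTable(["s"], ["A", "B", "X"], [[1, 1, 1]])
        with pytest.raises(ValidationError, match="X"):
            branch_profiles(three_leaf_tree, to_proportions(table), to_presence(table))

    def test_conservation_against_brute_force(self, random_tree_tables):
        # abundance at a branch equals the sum of leaf proportions below it
        for tree, table in random_tree_tables:
            props = to_proportions(table)
            prof = branch_profiles(tree, props, to_presence(table))
            oracle = brute_force_branch_leafsets(tree)
            col = {o: i for i, o in enumerate(table.otu_ids)}
            for l, (leafset, length) in enumerate(oracle):
                idx = [col[o] for o in leafset]
                np.testing.assert_allclose(
                    prof.abundance[:, l], props.values[:, idx].sum(axis=1), atol=1e-12
                )
                assert prof.branch_lengths[l] == length


class TestPairwiseHandValues:
    def test_bray_curtis(self):
        assert bray_curtis([0.5, 0.5, 0], [0, 0.5, 0.5]) == pytest.approx(0.5)

    def test_bray_curtis_identity_and_disjoint(self):
        p = np.array([0.2, 0.8, 0.0])
        assert bray_curtis(p, p) == 0
        assert bray_curtis([1, 0], [0, 1]) == 1

    def test_bray_curtis_both_zero_errors(self):
        with pytest.raises(ValidationError):
            bray_curtis([0, 0], [0, 0])

    def test_jaccard(self):
        assert jaccard([1, 1, 0], [0, 1, 1]) == pytest.approx(2 / 3)
        assert jaccard([1, 0], [1, 0]) == 0
        assert jaccard([1, 0], [0, 1]) == 1

    def test_jaccard_empty_errors(self):
        with pytest.raises(ValidationError):
            jaccard([0, 0], [0, 0])

    def test_weighted_unifrac_three_sevenths(self, three_leaf_profile):
        assert weighted_unifrac(three_leaf_profile, 0, 1) == pytest.approx(3 / 7, abs=1e-12)

    def test_unweighted_unifrac_half(self, three_leaf_profile):
        assert unweighted_unifrac(three_leaf_profile, 0, 1) == pytest.approx(0.5, abs=1e-12)

    def test_generalized_alpha0(self, three_leaf_profile):
        assert generalized_unifrac(three_leaf_profile, 0, 1, 0.0) == pytest.approx(7 / 12, abs=1e-12)

    def test_presence_weighted_alpha0(self, three_leaf_profile):
        assert presence_weighted_unifrac(three_leaf_profile, 0, 1, 0.0) == pytest.approx(7 / 12, abs=1e-12)

    def test_presence_weighted_alpha1(self, three_leaf_profile):
        assert presence_weighted_unifrac(three_leaf_profile, 0, 1, 1.0) == pytest.approx(3 / 7, abs=1e-12)

    def test_self_distance_zero(self, three_leaf_profile):
        assert weighted_unifrac(three_leaf_profile, 0, 0) == 0
        assert presence_weighted_unifrac(three_leaf_profile, 1, 1, 0.5) == 0

    def test_alpha_out_of_range(self, three_leaf_profile):
        with pytest.raises(ValidationError):
            generalized_unifrac(three_leaf_profile, 0, 1, 1.5)
        with pytest.raises(ValidationError):
            presence_weighted_unifrac(three_leaf_profile, 0, 1, -0.1)

    def test_disjoint_subtrees_weighted_is_one(self):
        tree = PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        table = OtuTable(["j", "k"], ["A", "B", "C", "D"], [[5, 5, 0, 0], [0, 0, 5, 5]])
        prof = branch_profiles(tree, to_proportions(table), to_presence(table))
        assert weighted_unifrac(prof, 0, 1) == pytest.approx(1.0)


class TestProperties:
    def test_alpha1_reduces_to_weighted(self, random_tree_tables):
        for tree, table in random_tree_tables:
            prof = branch_profiles(tree, to_proportions(table), to_presence(table))
            for j, k in itertools.combinations(range(table.n_samples), 2):
                gw = generalized_unifrac(prof, j, k, 1.0)
                w = weighted_unifrac(prof, j, k)
                assert gw == pytest.approx(w, abs=1e-12)

    def test_bray_curtis_on_presence_equals_closed_form(self, random_tree_tables):
        # D_BC on 0/1 data = n01 / (n01 + 2*n11), exactly
        for _, table in random_tree_tables:
            pres = to_presence(table).values
            for j, k in itertools.combinations(range(table.n_samples), 2):
                a, b = pres[j], pres[k]
                n11 = int(((a == 1) & (b == 1)).sum())
                n01 = int((a != b).sum())
                if n01 + n11 == 0:
                    continue
                assert bray_curtis(a, b) == pytest.approx(n01 / (n01 + 2 * n11), abs=1e-12)

    def test_symmetry_bounds_identity(self, random_tree_tables):
        tree, table = random_tree_tables[0]
        prof = branch_profiles(tree, to_proportions(table), to_presence(table))
        funcs = [
            lambda j, k: weighted_unifrac(prof, j, k),
            lambda j, k: unweighted_unifrac(prof, j, k),
            lambda j, k: generalized_unifrac(prof, j, k, 0.5),
            lambda j, k: presence_weighted_unifrac(prof, j, k, 0.5),
        ]
        for f in funcs:
            for j, k in itertools.combinations(range(table.n_samples), 2):
                d = f(j, k)
                assert 0 <= d <= 1
                assert f(k, j) == pytest.approx(d, abs=1e-12)
            assert f(0, 0) == 0

    def test_pw_and_gw_agree_on_proportional_profiles(self, three_leaf_tree):
        # if each sample's presence counts are proportional to its branch
        # proportions (uniform abundance over present leaves), the relative
        # differences coincide at alpha because the common scale cancels
        table = OtuTable(["j", "k"], ["A", "B", "C"], [[1, 1, 0], [1, 0, 1]])
        prof = branch_profiles(three_leaf_tree, to_proportions(table), to_presence(table))
        for alpha in (0.0, 0.5, 1.0):
            # richness = 2 * abundance for both samples here
            gw = generalized_unifrac(prof, 0, 1, alpha)
            pw = presence_weighted_unifrac(prof, 0, 1, alpha)
            assert pw == pytest.approx(gw, abs=1e-12)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_random_matrices_valid(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 20, size=(4, 6))
        counts[:, 0] += 1
        table = OtuTable([f"s{i}" for i in range(4)], [f"O{i}" for i in range(6)], counts)
        dm = distance_matrix(table, DistanceSpec("bray_curtis"))
        assert (dm.values >= 0).all() and (dm.values <= 1).all()


class TestMatrixDispatch:
    def test_identical_samples_zero_matrix(self, three_leaf_tree):
        table = OtuTable(["a", "b"], ["A", "B", "C"], [[3, 3, 0], [3, 3, 0]])
        for spec in [DistanceSpec("bray_curtis"), DistanceSpec("w_unifrac"), DistanceSpec("pw_unifrac", 0.0)]:
            dm = distance_matrix(table, spec, three_leaf_tree)
            np.testing.assert_allclose(dm.values, 0.0, atol=1e-12)

    def test_matrix_matches_pairwise_calls(self, three_leaf_tree, three_otu_table):
        dm = distance_matrix(three_otu_table, DistanceSpec("bray_curtis"))
        p = to_proportions(three_otu_table).values
        assert dm.values[0, 1] == pytest.approx(bray_curtis(p[0], p[1]), abs=1e-12)
        dm2 = distance_matrix(three_otu_table, DistanceSpec("pw_unifrac", 0.0), three_leaf_tree)
        prof = branch_profiles(
            three_leaf_tree, to_proportions(three_otu_table), to_presence(three_otu_table)
        )
        assert dm2.values[0, 1] == pytest.approx(
            presence_weighted_unifrac(prof, 0, 1, 0.0), abs=1e-12
        )

    def test_pw1_on_binary_differs_from_uw(self, three_leaf_tree, three_otu_table):
        # counterexample from the 3-leaf fixture: 3/7 vs 1/2
        pw1 = distance_matrix(three_otu_table, DistanceSpec("pw_unifrac", 1.0), three_leaf_tree)
        uw = distance_matrix(three_otu_table, DistanceSpec("uw_unifrac"), three_leaf_tree)
        assert pw1.values[0, 1] != pytest.approx(uw.values[0, 1])

    def test_missing_tree_errors(self, three_otu_table):
        with pytest.raises(ValidationError, match="tree"):
            distance_matrix(three_otu_table, DistanceSpec("w_unifrac"))

    def test_zero_total_sample_dropped_with_warning(self, three_leaf_tree):
        table = OtuTable(["a", "b", "z"], ["A", "B", "C"], [[3, 3, 0], [3, 0, 3], [0, 0, 0]])
        with pytest.warns(UserWarning, match="zero-total"):
            dm = distance_matrix(table, DistanceSpec("bray_curtis"))
        assert dm.sample_ids == ["a", "b"]

    def test_spec_parsing(self):
        spec = DistanceSpec.parse("pw_unifrac:0.5")
        assert spec.name == "pw_unifrac" and spec.alpha == 0.5
        with pytest.raises(ValidationError):
            DistanceSpec.parse("nonsense")
        with pytest.raises(ValidationError):
            DistanceSpec("w_unifrac", 0.5)
        with pytest.raises(ValidationError):
            DistanceSpec("gw_unifrac")


class TestCrossCheckScikitBio:
    """Dual-route checks against scikit-bio's implementations."""

    def test_weighted_unifrac_matches_skbio(self, random_tree_tables):
        from skbio.diversity import beta_diversity

        tree, table = random_tree_tables[0]
        # skbio requires the root to have no length issues; use counts directly
        sk = beta_diversity(
            "weighted_unifrac",
            table.counts,
            ids=table.sample_ids,
            taxa=table.otu_ids,
            tree=tree.tree,
            normalized=True,
        )
        dm = distance_matrix(table, DistanceSpec("w_unifrac"), tree)
        np.testing.assert_allclose(dm.values, sk.data, atol=1e-10)

    def test_bray_curtis_matches_skbio(self, random_tree_tables):
        from skbio.diversity import beta_diversity

        _, table = random_tree_tables[1]
        props = to_proportions(table).values
        sk = beta_diversity("braycurtis", props, ids=table.sample_ids)
        dm = distance_matrix(table, DistanceSpec("bray_curtis"))
        np.testing.assert_allclose(dm.values, sk.data, atol=1e-10)

    def test_unweighted_unifrac_matches_skbio_up_to_denominator(self, random_tree_tables):
        # skbio divides by the branch length occupied by either sample; the
        # literal formula here divides by total branch length
        from skbio.diversity import beta_diversity

        tree, table = random_tree_tables[2]
        sk = beta_diversity(
            "unweighted_unifrac",
            table.counts,
            ids=table.sample_ids,
            taxa=table.otu_ids,
            tree=tree.tree,
        )
        dm = distance_matrix(table, DistanceSpec("uw_unifrac"), tree)
        _, lengths = leaf_descendant_matrix(tree, table.otu_ids)
        total = lengths.sum()
        prof = branch_profiles(tree, to_proportions(table), to_presence(table))
        occ = prof.richness > 0
        for j in range(table.n_samples):
            for k in range(j + 1, table.n_samples):
                union = lengths[occ[j] | occ[k]].sum()
                assert dm.values[j, k] * total == pytest.approx(sk.data[j, k] * union, abs=1e-10)
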