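import itertools

import numpy as np
import pandas as pd
import pytest

from cazytrait.conservation import (
    TreeIndex,
    abouheif_proximity,
    cmean,
    filter_for_phylogeny,
    find_positive_clades,
    identity_from_tau,
    permutation_test_tau,
    run_conservation_suite,
    tau_D,
)
from cazytrait.io_formats import GenomeMetadata
from cazytrait.synthetic import simulate_tree

from conftest import tree_from_newick
from oracles import (
    brute_cmean,
    brute_abouheif_proximity,
    brute_positive_clades,
    brute_tau,
    random_tree,
    leaf_labels,
)


class TestPhylogenyFilter:
    def test_single_copy_high_quality_kept(self):
        meta = [
            GenomeMetadata("a", "P", "soil", "high", 1),
            GenomeMetadata("b", "P", "soil", "high", 0),
            GenomeMetadata("c", "P", "soil", "high", 2),
            GenomeMetadata("d", "P", "soil", "other", 1),
        ]
        assert filter_for_phylogeny(meta) == ["a"]

    def test_empty(self):
        assert filter_for_phylogeny([]) == []


class TestAbouheifProximity:
    def test_two_tip(self):
        w = abouheif_proximity(tree_from_newick("(A:1,B:1);"))
        assert w.loc["A", "B"] == 0.5 and w.loc["A", "A"] == 0.0

    def test_balanced_four_tip(self, balanced4):
        w = abouheif_proximity(balanced4)
        assert w.loc["A", "B"] == pytest.approx(0.25)   # same cherry
        assert w.loc["A", "C"] == pytest.approx(0.125)  # opposite cherries

    @pytest.mark.parametrize("k", [3, 5, 8])
    def test_star_tree(self, k):
        newick = "(" + ",".join(f"T{i}:1" for i in range(k)) + ");"
        w = abouheif_proximity(tree_from_newick(newick)).to_numpy()
        off = w[~np.eye(k, dtype=bool)]
        assert np.allclose(off, 1.0 / k)

    def test_matches_brute_force_on_random_trees(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            t = random_tree(int(rng.integers(4, 12)), rng)
            mine = abouheif_proximity(t)
            ref = brute_abouheif_proximity(t)
            assert np.allclose(mine.to_numpy(), ref, atol=1e-12)
            assert list(mine.index) == leaf_labels(t)

    def test_symmetric_bounded(self):
        rng = np.random.default_rng(1)
        t = random_tree(20, rng)
        w = abouheif_proximity(t).to_numpy()
        assert np.allclose(w, w.T)
        off = w[~np.eye(20, dtype=bool)]
        assert (off > 0).all() and (off <= 0.5).all()


class TestCmean:
    def test_two_tip_antisymmetric(self):
        res = cmean(tree_from_newick("(A:1,B:1);"), {"A": 1.0, "B": 0.0},
                    n_perm=19, seed=0)
        assert res.cmean == pytest.approx(-1.0)

    def test_matches_dense_moran_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(15):
            n = int(rng.integers(4, 50))
            t = random_tree(n, rng)
            x = rng.random(n)
            res = cmean(t, dict(zip(leaf_labels(t), x)), n_perm=9, seed=0)
            assert res.cmean == pytest.approx(brute_cmean(t, x), abs=1e-10)

    def test_clustered_trait_positive_and_significant(self):
        tree = simulate_tree(64, seed=5, mean_depth=0.1)
        idx = TreeIndex(tree)
        # paint one deep half of the tree positive
        half = set(idx.tips_below[idx.children[0][0]])
        trait = {l: (t in half) for t, l in enumerate(idx.tip_labels)}
        res = cmean(idx, trait, n_perm=199, seed=3)
        assert res.cmean > 0
        assert res.p_value <= 0.05

    def test_constant_trait_rejected(self, balanced4):
        with pytest.raises(ValueError, match="no variance"):
            cmean(balanced4, {"A": 1, "B": 1, "C": 1, "D": 1}, n_perm=9, seed=0)

    def test_deterministic(self, balanced4):
        t = {"A": 1, "B": 0, "C": 1, "D": 0}
        a = cmean(balanced4, t, n_perm=99, seed=9)
        b = cmean(balanced4, t, n_perm=99, seed=9)
        assert a.p_value == b.p_value


class TestPositiveClades:
    def test_all_positive_is_root(self, balanced4):
        clades = find_positive_clades(balanced4, {"A": 1, "B": 1, "C": 1, "D": 1})
        assert len(clades) == 1 and clades[0].n_tips == 4

    def test_none_positive_empty(self, balanced4):
        assert find_positive_clades(balanced4, {"A": 0, "B": 0, "C": 0, "D": 0}) == []

    def test_positive_cherry_only(self, balanced4):
        clades = find_positive_clades(balanced4, {"A": 1, "B": 1, "C": 0, "D": 0})
        assert len(clades) == 1
        assert sorted(clades[0].tip_labels) == ["A", "B"]
        assert clades[0].depth == pytest.approx(1.0)

    def test_exhaustive_against_brute_force_small_trees(self):
        """Every trait assignment on random 4-8 tip trees matches the oracle."""
        rng = np.random.default_rng(3)
        for n in range(4, 9):
            for _ in range(2):
                t = random_tree(n, rng)
                idx = TreeIndex(t)
                labels = leaf_labels(t)
                for bits in itertools.product([0, 1], repeat=n):
                    trait = dict(zip(labels, bits))
                    mine = find_positive_clades(idx, trait)
                    got_clades = {frozenset(c.tip_labels) for c in mine
                                  if not c.is_singleton}
                    got_single = sorted(c.tip_labels[0] for c in mine
                                        if c.is_singleton)
                    ref_clades, ref_single = brute_positive_clades(t, trait, 0.90)
                    assert got_clades == set(ref_clades)
                    assert got_single == sorted(ref_single)


class TestTauD:
    def test_all_positive_mean_root_depth(self, balanced4):
        res = tau_D(balanced4, {"A": 1, "B": 1, "C": 1, "D": 1})
        assert res.tau_D == pytest.approx(2.0)
        assert res.n_positive_clades == 1 and res.n_singletons == 0

    def test_positive_cherry(self, balanced4):
        res = tau_D(balanced4, {"A": 1, "B": 1, "C": 0, "D": 0})
        assert res.tau_D == pytest.approx(1.0)

    def test_singleton_half_terminal_branch(self, balanced4):
        res = tau_D(balanced4, {"A": 1, "B": 0, "C": 0, "D": 0})
        assert res.tau_D == pytest.approx(0.5)
        assert res.n_singletons == 1

    def test_no_positive_tips_error(self, balanced4):
        with pytest.raises(ValueError, match="no positive"):
            tau_D(balanced4, {"A": 0, "B": 0, "C": 0, "D": 0})

    def test_matches_brute_force_random_traits(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            n = int(rng.integers(4, 9))
            t = random_tree(n, rng)
            labels = leaf_labels(t)
            bits = rng.integers(0, 2, size=n)
            if bits.sum() == 0:
                bits[0] = 1
            trait = dict(zip(labels, bits.tolist()))
            mine = tau_D(t, trait)
            assert mine.tau_D == pytest.approx(brute_tau(t, trait, 0.90, 0.5), abs=1e-12)

    def test_monotone_in_clade_depth(self):
        """Painting a strictly deeper (superset) clade never decreases tau_D."""
        tree = simulate_tree(32, seed=6, mean_depth=0.1)
        idx = TreeIndex(tree)
        node = idx.children[0][0]
        while len(idx.tips_below[node]) < 4:
            node = idx.children[0][0] if len(idx.tips_below[idx.children[0][0]]) >= 4 else idx.children[0][1]
        shallow_node = idx.children[node][0]
        deep_tips = set(idx.tips_below[node])
        shallow_tips = set(idx.tips_below[shallow_node])
        t_shallow = {l: (t in shallow_tips) for t, l in enumerate(idx.tip_labels)}
        t_deep = {l: (t in deep_tips) for t, l in enumerate(idx.tip_labels)}
        assert tau_D(idx, t_deep).tau_D >= tau_D(idx, t_shallow).tau_D


class TestPermutationTest:
    def test_all_positive_p_one(self, balanced4):
        res = permutation_test_tau(balanced4, {"A": 1, "B": 1, "C": 1, "D": 1},
                                   n_perm=50, seed=0)
        assert res.p_value == 1.0

    def test_deep_minority_clade_significant(self):
        tree = simulate_tree(64, seed=7, mean_depth=0.1)
        idx = TreeIndex(tree)
        # deepest clade holding 12-32 tips: conserved but not tree-wide
        cands = [i for i in range(idx.n_nodes) if 12 <= idx.n_tips_below[i] <= 32]
        node = max(cands, key=lambda i: idx.mean_depth[i])
        members = set(idx.tips_below[node])
        trait = {l: (t in members) for t, l in enumerate(idx.tip_labels)}
        res = permutation_test_tau(idx, trait, n_perm=200, seed=1)
        assert res.p_value <= 0.05

    def test_positive_count_preserved_and_deterministic(self, balanced4):
        t = {"A": 1, "B": 0, "C": 1, "D": 0}
        a = permutation_test_tau(balanced4, t, n_perm=99, seed=5)
        b = permutation_test_tau(balanced4, t, n_perm=99, seed=5)
        assert a.p_value == b.p_value

    def test_plus_one_variant_never_zero(self):
        tree = simulate_tree(32, seed=8, mean_depth=0.1)
        idx = TreeIndex(tree)
        half = set(idx.tips_below[idx.children[0][0]])
        trait = {l: (t in half) for t, l in enumerate(idx.tip_labels)}
        res = permutation_test_tau(idx, trait, n_perm=100, seed=2, plus_one=True)
        assert res.p_value >= 1 / 101


class TestIdentityTransform:
    @pytest.mark.parametrize(
        "tau,identity,divergence",
        [(0.0, 1.0, 0.0), (0.05, 0.90, 10.0), (0.015, 0.97, 3.0), (0.1, 0.8, 20.0)],
    )
    def test_formula(self, tau, identity, divergence):
        ident, div = identity_from_tau(tau)
        assert ident == pytest.approx(identity)
        assert div == pytest.approx(divergence)

    def test_consistency_invariant(self):
        for tau in np.linspace(0, 0.4, 21):
            ident, div = identity_from_tau(tau)
            assert ident + div / 100 == pytest.approx(1.0)


class TestSuite:
    def _fixture(self, n_tips=24, seed=0):
        trees = {
            "phylum_A": simulate_tree(n_tips, seed=seed, mean_depth=0.1),
            "phylum_B": simulate_tree(10, seed=seed + 1, mean_depth=0.1),
        }
        rng = np.random.default_rng(seed)
        genomes = []
        for t in trees.values():
            genomes += [l.taxon.label for l in t.leaf_node_iter()]
        # relabel tips uniquely per phylum
        for name, t in trees.items():
            for l in t.leaf_node_iter():
                l.taxon.label = f"{name}_{l.taxon.label}"
        genomes = [f"{n}_{g}" for n in trees for g in []]
        index = [l.taxon.label for t in trees.values() for l in t.leaf_node_iter()]
        traits = pd.DataFrame(
            rng.random((len(index), 3)) < 0.5,
            index=index, columns=["cellulases", "chitinases/chitosanases", "mannanases"],
        )
        traits.iloc[:, 2] = True  # constant all-positive activity
        return trees, traits

    def test_small_phylum_skipped_with_reason(self):
        trees, traits = self._fixture()
        out = run_conservation_suite(trees, traits, min_tips=21, n_perm=20, seed=0)
        skipped = out[out.phylum == "phylum_B"]
        assert len(skipped) == 1
        assert "skipped" in skipped.status.iloc[0]

    def test_row_enumeration(self):
        trees, traits = self._fixture()
        out = run_conservation_suite(trees, traits, min_tips=2, n_perm=20, seed=0)
        # one row per (phylum, activity); no skips at min_tips=2
        assert len(out) == 2 * 3
        ok = out[(out.phylum == "phylum_A") & (out.activity == "cellulases")].iloc[0]
        assert 0 <= ok.p_value <= 1 and ok.n_positive > 0

    def test_all_positive_activity_flagged_for_cmean(self):
        trees, traits = self._fixture()
        out = run_conservation_suite(trees, traits, min_tips=2, n_perm=20, seed=0)
        row = out[(out.phylum == "phylum_A") & (out.activity == "mannanases")].iloc[0]
        assert np.isnan(row.cmean)
        assert row.tau_D == pytest.approx(TreeIndex(trees["phylum_A"]).root_mean_depth)
        assert row.p_value == 1.0

    def test_deterministic_under_seed(self):
        trees, traits = self._fixture()
        a = run_conservation_suite(trees, traits, min_tips=2, n_perm=50, seed=3)
        b = run_conservation_suite(trees, traits, min_tips=2, n_perm=50, seed=3)
        pd.testing.assert_frame_equal(a, b)
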