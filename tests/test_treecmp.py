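import math

import dendropy
import numpy as np
import pandas as pd
import pytest

from podopan.io_formats import parse_newick, write_newick
from podopan.treecmp import (
    bipartitions,
    consensus_extended_majority,
    content_dendrograms,
    gene_content_distance,
    nmds,
    robinson_foulds,
    tree_distance_matrix,
)

from conftest import random_binary_tree


def dendropy_rf_oracle(t1, t2):
    """Independent RF via dendropy's bipartition machinery on a shared
    taxon namespace."""
    ns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(data=write_newick(t1), schema="newick", taxon_namespace=ns)
    b = dendropy.Tree.get(data=write_newick(t2), schema="newick", taxon_namespace=ns)
    a.encode_bipartitions()
    b.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(a, b)


class TestBipartitions:
    def test_four_leaf_tree_single_split(self):
        tree = parse_newick("((A,B),(C,D));")
        assert bipartitions(tree) == {frozenset({"C", "D"})}

    def test_star_tree_empty(self):
        assert bipartitions(parse_newick("(A,B,C,D,E);")) == set()

    def test_binary_tree_split_count(self):
        rng = np.random.default_rng(0)
        for n in (5, 6, 8):
            tree = random_binary_tree(rng, [f"t{i}" for i in range(n)])
            assert len(bipartitions(tree)) == n - 3


class TestRobinsonFoulds:
    def test_identical_trees_zero(self):
        rng = np.random.default_rng(1)
        tree = random_binary_tree(rng, list("ABCDEFG"))
        assert robinson_foulds(tree, tree) == 0

    def test_four_taxon_alternative_topologies(self):
        t1 = parse_newick("((A,B),(C,D));")
        t2 = parse_newick("((A,C),(B,D));")
        assert robinson_foulds(t1, t2) == 2

    def test_matches_dendropy_oracle_on_random_trees(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            n = int(rng.integers(4, 9))
            labels = [f"t{i}" for i in range(n)]
            t1 = random_binary_tree(rng, labels)
            t2 = random_binary_tree(rng, labels)
            assert robinson_foulds(t1, t2) == dendropy_rf_oracle(t1, t2)

    def test_upper_bound_and_metric_properties(self):
        rng = np.random.default_rng(3)
        labels = [f"t{i}" for i in range(8)]
        trees = [random_binary_tree(rng, labels) for _ in range(6)]
        for a in trees:
            for b in trees:
                d = robinson_foulds(a, b)
                assert 0 <= d <= 2 * (8 - 3)
                assert d == robinson_foulds(b, a)
        for a in trees:
            for b in trees:
                for c in trees:
                    assert robinson_foulds(a, c) <= (
                        robinson_foulds(a, b) + robinson_foulds(b, c)
                    )

    def test_differing_leaf_sets_rejected(self):
        with pytest.raises(ValueError, match="leaf sets"):
            robinson_foulds(parse_newick("((A,B),(C,D));"), parse_newick("((A,B),(C,E));"))


class TestConsensus:
    def test_identical_inputs_full_support(self):
        tree = parse_newick("((A,B),(C,D),(E,F));")
        cons = consensus_extended_majority([tree, tree, tree])
        assert robinson_foulds(cons, tree) == 0
        supports = [
            n.support for n in cons.preorder_internal_node_iter()
            if getattr(n, "support", None) is not None
        ]
        assert supports and all(s == 100.0 for s in supports)

    def test_single_tree_is_itself(self):
        tree = parse_newick("((A,B),(C,D),(E,F));")
        assert robinson_foulds(consensus_extended_majority([tree]), tree) == 0

    def test_two_thirds_split_included(self):
        t1 = parse_newick("((A,B),(C,D),(E,F));")
        t2 = parse_newick("((A,B),(C,E),(D,F));")
        cons = consensus_extended_majority([t1, t2, t1])
        splits = bipartitions(cons)
        assert frozenset({"C", "D"}) in splits
        supports = {
            frozenset(l.taxon.label for l in n.leaf_iter()): n.support
            for n in cons.preorder_internal_node_iter()
            if getattr(n, "support", None) is not None
        }
        assert any(abs(s - 200 / 3) < 0.01 for s in supports.values())

    def test_matches_frequency_and_compatibility_oracle(self):
        rng = np.random.default_rng(4)
        labels = [f"t{i}" for i in range(7)]
        for _ in range(10):
            pool = [random_binary_tree(rng, labels) for _ in range(3)]
            trees = [pool[int(rng.integers(0, 3))] for _ in range(7)]
            cons = consensus_extended_majority(trees)
            got = bipartitions(cons)
            # oracle: count split frequencies, then apply the stated rule
            counts = {}
            for t in trees:
                for s in bipartitions(t):
                    counts[s] = counts.get(s, 0) + 1

            def compat(a, b):
                return a <= b or b <= a or not (a & b)

            expected = [s for s, c in counts.items() if c / len(trees) > 0.5]
            rest = sorted(
                (s for s, c in counts.items() if c / len(trees) <= 0.5),
                key=lambda s: (-counts[s], sorted(s)),
            )
            for s in rest:
                if all(compat(s, t) for t in expected):
                    expected.append(s)
            assert got == set(expected)
            # supports record the actual frequencies
            leaves = frozenset(labels)
            smallest = min(leaves)
            for node in cons.preorder_internal_node_iter():
                sup = getattr(node, "support", None)
                if sup is None:
                    continue
                clade = frozenset(l.taxon.label for l in node.leaf_iter())
                side = clade if smallest not in clade else leaves - clade
                if side in counts:
                    assert math.isclose(sup, 100.0 * counts[side] / len(trees))

    def test_leaf_set_mismatch_rejected(self):
        with pytest.raises(ValueError):
            consensus_extended_majority(
                [parse_newick("((A,B),(C,D));"), parse_newick("((A,B),(C,E));")]
            )


class TestTreeDistanceMatrix:
    def test_copies_give_zero_matrix(self):
        t = parse_newick("((A,B),(C,D));")
        D = tree_distance_matrix({"x": t, "y": t})
        assert (D.to_numpy() == 0).all()

    def test_cells_match_pairwise_calls(self):
        rng = np.random.default_rng(5)
        labels = [f"t{i}" for i in range(8)]
        trees = {f"tr{i}": random_binary_tree(rng, labels) for i in range(15)}
        D = tree_distance_matrix(trees)
        names = list(trees)
        assert np.allclose(D.to_numpy(), D.to_numpy().T)
        assert (np.diag(D.to_numpy()) == 0).all()
        for i, a in enumerate(names):
            for j in range(i + 1, len(names)):
                assert D.iat[i, j] == robinson_foulds(trees[a], trees[names[j]])


class TestNMDS:
    def test_recovers_planar_configuration(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(6, 2))
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        labels = [f"p{i}" for i in range(6)]
        res = nmds(pd.DataFrame(D, index=labels, columns=labels), seed=0)
        assert res.stress < 1e-3

    def test_scale_invariance_of_rank_stress(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(7, 3))
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        labels = [f"p{i}" for i in range(7)]
        r1 = nmds(pd.DataFrame(D, index=labels, columns=labels), seed=3, restarts=5)
        r2 = nmds(pd.DataFrame(2 * D, index=labels, columns=labels), seed=3, restarts=5)
        assert math.isclose(r1.stress, r2.stress, abs_tol=1e-9)

    def test_degenerate_all_zero(self):
        labels = list("abc")
        res = nmds(pd.DataFrame(np.zeros((3, 3)), index=labels, columns=labels), seed=0)
        assert res.degenerate
        assert (res.coordinates.to_numpy() == 0).all()

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(8)
        D = np.abs(rng.normal(size=(6, 6)))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        labels = [f"p{i}" for i in range(6)]
        df = pd.DataFrame(D, index=labels, columns=labels)
        r1 = nmds(df, seed=5, restarts=3)
        r2 = nmds(df, seed=5, restarts=3)
        assert np.array_equal(r1.coordinates.to_numpy(), r2.coordinates.to_numpy())


class TestGeneContentDistance:
    def test_identical_rows_zero_both_methods(self):
        mat = pd.DataFrame([[1, 0, 1], [1, 0, 1]], index=["a", "b"])
        for method in ("jaccard", "cfn"):
            assert gene_content_distance(mat, method=method).loc["a", "b"] == 0.0

    def test_cfn_closed_form(self):
        # 1 discordant column of 5 -> p = 0.2
        mat = pd.DataFrame([[1, 1, 0, 0, 1], [1, 1, 0, 0, 0]], index=["a", "b"])
        d = gene_content_distance(mat, method="cfn").loc["a", "b"]
        assert math.isclose(d, -0.5 * math.log(0.6))

    def test_jaccard_disjoint_rows(self):
        mat = pd.DataFrame([[1, 1, 0, 0], [0, 0, 1, 1]], index=["a", "b"])
        assert gene_content_distance(mat).loc["a", "b"] == 1.0

    def test_cfn_undefined_raises_without_clamp(self):
        mat = pd.DataFrame([[1, 1, 0, 0], [0, 0, 1, 1]], index=["a", "b"])
        with pytest.raises(ValueError, match="p >= 0.5"):
            gene_content_distance(mat, method="cfn", clamp=False)


class TestContentDendrograms:
    def test_identical_accessory_rows_zero_height_join(self):
        mat = pd.DataFrame(
            [[1, 1, 0], [1, 1, 0], [0, 0, 1]],
            index=["a", "b", "c"], columns=["x", "y", "z"],
        )
        phage_tree, _ = content_dendrograms(mat)
        pdm = phage_tree.phylogenetic_distance_matrix()
        ta = phage_tree.taxon_namespace.get_taxon("a")
        tb = phage_tree.taxon_namespace.get_taxon("b")
        assert pdm.patristic_distance(ta, tb) == 0.0

    def test_output_round_trips_through_newick(self, default_sim, truth_cogs):
        from podopan.pangenome import presence_absence

        genomes, _, _ = default_sim
        mat = presence_absence(truth_cogs, [g.id for g in genomes])
        acc = [c.cog_id for c in truth_cogs if c.category == "accessory"]
        phage_tree, gene_tree = content_dendrograms(mat[acc])
        for tree in (phage_tree, gene_tree):
            back = parse_newick(write_newick(tree))
            assert {l.taxon.label for l in back.leaf_node_iter()} == {
                l.taxon.label for l in tree.leaf_node_iter()
            }
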