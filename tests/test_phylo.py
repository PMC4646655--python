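import math

import numpy as np
import pandas as pd
import pytest

from podopan.io_formats import SequenceRecord
from podopan.phylo import (
    Alignment,
    bootstrap_tree,
    concatenate_core,
    neighbor_joining,
    progressive_msa,
    protein_distance,
    trim_blocks,
    upgma,
)
from podopan.treecmp import bipartitions, robinson_foulds

from conftest import patristic_matrix, random_binary_tree

AA = "ACDEFGHIKLMNPQRSTVWY"


def global_pairwise_oracle(a, b, gap_open=11, gap_extend=1):
    """Brute-force global (Needleman-Wunsch-Gotoh) score with terminal gaps
    penalized; gap of length k costs open + k*extend."""
    from Bio.Align import substitution_matrices

    B = substitution_matrices.load("BLOSUM62")
    m, n = len(a), len(b)
    NEG = -1e30
    H = [[NEG] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    H[0][0] = 0.0
    for j in range(1, n + 1):
        E[0][j] = -gap_open - gap_extend * j
        H[0][j] = E[0][j]
    for i in range(1, m + 1):
        F[i][0] = -gap_open - gap_extend * i
        H[i][0] = F[i][0]
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(E[i][j - 1] - gap_extend, H[i][j - 1] - gap_open - gap_extend)
            F[i][j] = max(F[i - 1][j] - gap_extend, H[i - 1][j] - gap_open - gap_extend)
            H[i][j] = max(H[i - 1][j - 1] + B[a[i - 1]][b[j - 1]], E[i][j], F[i][j])
    return H[m][n]


def score_alignment(rows, gap_open=11, gap_extend=1):
    from Bio.Align import substitution_matrices

    B = substitution_matrices.load("BLOSUM62")
    a, b = rows
    score, in_gap = 0.0, None
    for x, y in zip(a, b):
        if x == "-" or y == "-":
            which = 0 if x == "-" else 1
            score -= gap_extend
            if in_gap != which:
                score -= gap_open
            in_gap = which
        else:
            score += B[x][y]
            in_gap = None
    return score


class TestProgressiveMSA:
    def test_identical_sequences_gap_free(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list(AA), 80))
        aln = progressive_msa([SequenceRecord(id=f"s{i}", residues=seq) for i in range(5)])
        assert all(r == seq for r in aln.rows)

    def test_two_sequences_equal_optimal_global_score(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            a = "".join(rng.choice(list(AA), int(rng.integers(30, 60))))
            b = "".join(rng.choice(list(AA), int(rng.integers(30, 60))))
            aln = progressive_msa(
                [SequenceRecord(id="a", residues=a), SequenceRecord(id="b", residues=b)]
            )
            assert math.isclose(
                score_alignment(aln.rows), global_pairwise_oracle(a, b)
            )

    def test_rows_ungap_to_inputs(self):
        rng = np.random.default_rng(2)
        seqs = [
            SequenceRecord(id=f"s{i}", residues="".join(rng.choice(list(AA), 50)))
            for i in range(6)
        ]
        aln = progressive_msa(seqs)
        assert aln.ids == [s.id for s in seqs]
        for i, s in enumerate(seqs):
            assert aln.ungapped(i) == s.residues
        assert aln.n_cols >= max(len(s.residues) for s in seqs)

    def test_single_sequence_and_empty_input(self):
        rec = SequenceRecord(id="x", residues="MKLV")
        aln = progressive_msa([rec])
        assert aln.rows == ["MKLV"]
        with pytest.raises(ValueError):
            progressive_msa([])


class TestTrimBlocks:
    def test_fully_conserved_unchanged(self):
        aln = Alignment(ids=["a", "b"], rows=["MKLVWAARNDC", "MKLVWAARNDC"])
        trimmed, kept = trim_blocks(aln, min_block=5)
        assert trimmed.rows == aln.rows
        assert kept == list(range(11))

    def test_gappy_column_removed(self):
        # column 10 has 60% gaps; the rest is conserved
        base = "MKLVWAARND"
        rows = [base + ("-" if i < 3 else "C") for i in range(5)]
        aln = Alignment(ids=[f"s{i}" for i in range(5)], rows=rows)
        trimmed, kept = trim_blocks(aln)
        assert trimmed.n_cols == 10
        assert 10 not in kept

    def test_matches_per_column_rule_oracle(self):
        rng = np.random.default_rng(3)
        n, L = 6, 80
        rows = [
            "".join(rng.choice(list(AA + "-"), L, p=[0.03] * 20 + [0.4]))
            for _ in range(n)
        ]
        aln = Alignment(ids=[f"s{i}" for i in range(n)], rows=rows)
        max_gap, min_cons, min_block = 0.5, 0.5, 3
        ok = []
        for j in range(L):
            col = [r[j] for r in rows]
            gapfrac = col.count("-") / n
            residues = [c for c in col if c != "-"]
            modal = max((residues.count(c) for c in set(residues)), default=0)
            ok.append(gapfrac <= max_gap and modal / n >= min_cons)
        expected, run = [], []
        for j in range(L + 1):
            if j < L and ok[j]:
                run.append(j)
            else:
                if len(run) >= min_block:
                    expected.extend(run)
                run = []
        if expected:
            _, kept = trim_blocks(aln, max_gap, min_cons, min_block)
            assert kept == expected
        else:
            with pytest.raises(ValueError):
                trim_blocks(aln, max_gap, min_cons, min_block)

    def test_all_removed_is_error(self):
        aln = Alignment(ids=["a", "b"], rows=["MK--", "--LV"])
        with pytest.raises(ValueError, match="empty after trimming"):
            trim_blocks(aln)


class TestConcatenate:
    def make_alignments(self, rng, genomes, lengths):
        alns = {}
        for idx, L in enumerate(lengths):
            rows = ["".join(rng.choice(list(AA), L)) for _ in genomes]
            alns[f"cog{idx:02d}"] = Alignment(ids=list(genomes), rows=rows)
        return alns

    def test_length_is_sum_and_map_reconstructs(self):
        rng = np.random.default_rng(4)
        genomes = [f"g{i}" for i in range(4)]
        lengths = [12, 30, 7]
        alns = self.make_alignments(rng, genomes, lengths)
        supermatrix, smap = concatenate_core(alns, genomes)
        assert supermatrix.n_cols == sum(lengths)
        for cog_id, (start, stop) in smap.ranges.items():
            sub = [r[start:stop] for r in supermatrix.rows]
            assert sub == alns[cog_id].rows

    def test_distances_invariant_to_concatenation_order(self):
        rng = np.random.default_rng(5)
        genomes = [f"g{i}" for i in range(4)]
        alns = self.make_alignments(rng, genomes, [20, 20, 20])
        sm1, _ = concatenate_core(alns, genomes)
        renamed = {f"z{k}": v for k, v in alns.items()}  # different sort order
        sm2, _ = concatenate_core(renamed, genomes)
        D1 = protein_distance(sm1, model="p")
        D2 = protein_distance(sm2, model="p")
        assert np.allclose(D1.to_numpy(), D2.to_numpy())

    def test_missing_genome_rejected(self):
        aln = Alignment(ids=["g0"], rows=["MKLVW"])
        with pytest.raises(ValueError, match="missing"):
            concatenate_core({"c": aln}, ["g0", "g1"])


class TestProteinDistance:
    def test_identical_rows_zero(self):
        aln = Alignment(ids=["a", "b"], rows=["MKLV", "MKLV"])
        assert protein_distance(aln).loc["a", "b"] == 0.0

    def test_quarter_p_distance_and_poisson(self):
        aln = Alignment(ids=["a", "b"], rows=["MKLV", "MKLI"])
        assert protein_distance(aln, model="p").loc["a", "b"] == 0.25
        d = protein_distance(aln, model="poisson").loc["a", "b"]
        assert math.isclose(d, -math.log(0.75))

    def test_gap_columns_excluded(self):
        aln = Alignment(ids=["a", "b"], rows=["MK-V", "MKLI"])
        assert protein_distance(aln, model="p").loc["a", "b"] == pytest.approx(1 / 3)

    def test_no_comparable_columns_error(self):
        aln = Alignment(ids=["a", "b"], rows=["MK--", "--LV"])
        with pytest.raises(ValueError, match="comparable"):
            protein_distance(aln)


class TestNeighborJoining:
    def test_recovers_additive_tree(self):
        rng = np.random.default_rng(6)
        tree = random_binary_tree(rng, list("ABCDEF"))
        D = patristic_matrix(tree)
        rebuilt = neighbor_joining(D)
        assert robinson_foulds(tree, rebuilt) == 0
        assert np.allclose(
            patristic_matrix(rebuilt).to_numpy(), D.to_numpy(), atol=1e-9
        )

    def test_label_order_invariance(self):
        rng = np.random.default_rng(7)
        tree = random_binary_tree(rng, list("ABCDE"))
        D = patristic_matrix(tree)
        perm = ["C", "A", "E", "B", "D"]
        t1 = neighbor_joining(D)
        t2 = neighbor_joining(D.loc[perm, perm])
        assert robinson_foulds(t1, t2) == 0

    def test_ultrametric_input_matches_upgma_topology(self):
        rng = np.random.default_rng(8)
        # ultrametric distances from a random UPGMA-style hierarchy
        D = patristic_matrix(upgma(patristic_matrix(random_binary_tree(rng, list("ABCDEF")))))
        njt = neighbor_joining(D)
        upt = upgma(D)
        assert robinson_foulds(njt, upt) == 0

    def test_too_few_labels(self):
        D = pd.DataFrame([[0.0, 1.0], [1.0, 0.0]], index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError):
            neighbor_joining(D)


class TestUpgma:
    def test_three_taxon_hand_agglomeration(self):
        D = pd.DataFrame(
            [[0, 2, 6], [2, 0, 6], [6, 6, 0]],
            index=list("abc"), columns=list("abc"), dtype=float,
        )
        tree = upgma(D)
        # heights: {a,b} join at 1, root at 3
        pdm = patristic_matrix(tree)
        assert pdm.loc["a", "b"] == pytest.approx(2.0)
        assert pdm.loc["a", "c"] == pytest.approx(6.0)

    def test_ultrametricity(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(8, 3))
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        labels = [f"t{i}" for i in range(8)]
        tree = upgma(pd.DataFrame(D, index=labels, columns=labels))
        depths = []
        for leaf in tree.leaf_node_iter():
            d, node = 0.0, leaf
            while node.parent_node is not None:
                d += node.edge.length
                node = node.parent_node
            depths.append(d)
        assert np.allclose(depths, depths[0])

    def test_wpgma_equals_upgma_on_balanced_merges(self):
        # four taxa with perfect two-pair structure: every merge is between
        # equal-size clusters, so weighted and unweighted averaging coincide
        D = pd.DataFrame(
            [[0, 1, 8, 8], [1, 0, 8, 8], [8, 8, 0, 1], [8, 8, 1, 0]],
            index=list("abcd"), columns=list("abcd"), dtype=float,
        )
        t1, t2 = upgma(D, "upgma"), upgma(D, "wpgma")
        assert np.allclose(
            patristic_matrix(t1).to_numpy(), patristic_matrix(t2).to_numpy()
        )

    def test_matches_scipy_linkage_heights(self):
        from scipy.cluster.hierarchy import average
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(10)
        pts = rng.normal(size=(7, 4))
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        labels = [f"t{i}" for i in range(7)]
        tree = upgma(pd.DataFrame(D, index=labels, columns=labels))
        heights = sorted(
            round(h, 9)
            for h in _node_heights(tree)
        )
        link = average(squareform(D, checks=False))
        expected = sorted(round(h / 2, 9) for h in link[:, 2])
        assert heights == expected


def _node_heights(tree):
    out = []
    for node in tree.preorder_internal_node_iter():
        leaf = next(node.leaf_iter())
        d, cur = 0.0, leaf
        while cur is not node:
            d += cur.edge.length
            cur = cur.parent_node
        out.append(d)
    return out


class TestBootstrap:
    def test_perfect_signal_full_support(self):
        # one perfectly discriminating column pattern repeated 100x
        rows = {
            "a": "A" * 50 + "C" * 50,
            "b": "A" * 50 + "C" * 50,
            "c": "C" * 50 + "A" * 50,
            "d": "C" * 50 + "A" * 50,
        }
        # separate the pairs slightly so branch lengths are nonzero
        rows["a"] = "M" + rows["a"][1:]
        rows["c"] = "M" + rows["c"][1:]
        aln = Alignment(ids=list(rows), rows=list(rows.values()))
        tree = bootstrap_tree(aln, n_replicates=50, seed=0)
        supports = [
            n.support
            for n in tree.preorder_internal_node_iter()
            if getattr(n, "support", None) is not None
        ]
        assert supports and all(s == 100.0 for s in supports)
        assert all(0.0 <= s <= 100.0 for s in supports)

    def test_point_topology_stable_across_replicate_counts(self, default_sim, truth_cogs):
        from podopan.pipeline import core_alignments, core_genome_tree

        genomes, genes, _ = default_sim
        alns = core_alignments(truth_cogs, genes)
        ids = [g.id for g in genomes]
        _, _, t_small = core_genome_tree(alns, ids, n_bootstrap=5, seed=1)
        _, _, t_large = core_genome_tree(alns, ids, n_bootstrap=25, seed=99)
        assert robinson_foulds(t_small, t_large) == 0
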