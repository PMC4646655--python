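"""Core-gene phylogenomics: progressive multiple alignment, divergent-block
trimming, supermatrix concatenation, protein distances, and distance-based
tree inference (neighbor joining, UPGMA/WPGMA) with nonparametric bootstrap.

The aligner is a deterministic Clustal-class progressive method: a 3-mer
guide tree (UPGMA on fractional shared-k-mer distances) ordering
profile-profile global alignments under BLOSUM62 with affine gaps
(open 11, extend 1).  For two sequences it reduces exactly to optimal global
pairwise alignment.  Tree inference is canonical neighbor joining on
p- or Poisson-corrected distances; negative branch-length estimates are
clamped to zero and ties are broken lexically so results are reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from . import _kernels
from .io_formats import SequenceRecord
from .similarity import _matrix

__all__ = [
    "Alignment",
    "progressive_msa",
    "trim_blocks",
    "SupermatrixMap",
    "concatenate_core",
    "protein_distance",
    "neighbor_joining",
    "upgma",
    "bootstrap_tree",
]

_GAP = "-"
_AA20 = "ARNDCQEGHILKMFPSTWYV"
_AA_INDEX = {a: i for i, a in enumerate(_AA20)}


@dataclass
class Alignment:
    """A gapped multiple sequence alignment: parallel ``ids`` and equal-length
    ``rows`` over the amino-acid alphabet plus ``-``."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids in alignment")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"ragged alignment rows: lengths {sorted(lengths)}")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def ungapped(self, idx: int) -> str:
        return self.rows[idx].replace(_GAP, "")

    def codes(self) -> np.ndarray:
        """uint8 residue codes, gap/unknown = 255."""
        arr = np.full((self.n_rows, self.n_cols), 255, np.uint8)
        for i, row in enumerate(self.rows):
            for j, c in enumerate(row):
                arr[i, j] = _AA_INDEX.get(c, 255)
        return arr


# ---------------------------------------------------------------------------
# Progressive multiple alignment


def _kmer_distance(seqs: list[str], k: int = 3) -> np.ndarray:
    sets = [
        {s[i : i + k] for i in range(max(0, len(s) - k + 1))} if len(s) >= k else {s}
        for s in seqs
    ]
    n = len(seqs)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = len(sets[i] & sets[j])
            denom = min(len(sets[i]), len(sets[j]))
            D[i, j] = D[j, i] = 1.0 - shared / denom if denom else 1.0
    return D


def _profile(rows: list[str]) -> np.ndarray:
    """(L, 20) residue frequencies per column, gaps excluded and renormalized;
    all-gap columns are zero vectors."""
    L = len(rows[0])
    F = np.zeros((L, 20), np.float64)
    for row in rows:
        for j, c in enumerate(row):
            idx = _AA_INDEX.get(c)
            if idx is not None:
                F[j, idx] += 1.0
    totals = F.sum(axis=1, keepdims=True)
    np.divide(F, totals, out=F, where=totals > 0)
    return F


def _merge_alignments(
    a: Alignment, b: Alignment, M20: np.ndarray, gap_open: float, gap_extend: float
) -> Alignment:
    F1 = _profile(a.rows)
    F2 = _profile(b.rows)
    S = (F1 @ M20) @ F2.T
    H, E, F = _kernels.profile_global(S, float(gap_open), float(gap_extend))
    ops = _decode_global_path(S, H, E, F, gap_open, gap_extend)
    rows_a = ["" for _ in a.rows]
    rows_b = ["" for _ in b.rows]
    ia = ib = 0
    for p in ops:
        if p in (1, 2):
            for r in range(len(a.rows)):
                rows_a[r] += a.rows[r][ia]
            ia += 1
        else:
            for r in range(len(a.rows)):
                rows_a[r] += _GAP
        if p in (1, 3):
            for r in range(len(b.rows)):
                rows_b[r] += b.rows[r][ib]
            ib += 1
        else:
            for r in range(len(b.rows)):
                rows_b[r] += _GAP
    return Alignment(ids=a.ids + b.ids, rows=rows_a + rows_b)


def _decode_global_path(S, H, E, F, gap_open, gap_extend, tol=1e-9):
    """Trace one optimal global path from the filled Gotoh matrices.

    Gap runs are walked in full through the affine state (a run of length r
    costs open + r*extend), which a cell-local pointer cannot express.
    Ops: 1 = column pair, 2 = gap in the second profile, 3 = gap in the
    first."""
    m, n = S.shape
    first = gap_open + gap_extend
    ops: list[int] = []
    i, j = m, n
    while i > 0 or j > 0:
        if i == 0:
            ops.extend([3] * j)
            break
        if j == 0:
            ops.extend([2] * i)
            break
        h = H[i][j]
        if abs(h - (H[i - 1][j - 1] + S[i - 1, j - 1])) <= tol:
            ops.append(1)
            i -= 1
            j -= 1
        elif abs(h - E[i][j]) <= tol:
            run = 1
            while j - run > 0 and abs(
                E[i][j] - (H[i][j - run] - first - gap_extend * (run - 1))
            ) > tol:
                run += 1
            ops.extend([3] * run)
            j -= run
        else:
            run = 1
            while i - run > 0 and abs(
                F[i][j] - (H[i - run][j] - first - gap_extend * (run - 1))
            ) > tol:
                run += 1
            ops.extend([2] * run)
            i -= run
        if len(ops) > 4 * (m + n):
            raise RuntimeError("alignment traceback failed to terminate")
    ops.reverse()
    return ops


def progressive_msa(
    seqs: list[SequenceRecord],
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    k: int = 3,
) -> Alignment:
    """Progressive profile alignment along a k-mer UPGMA guide tree.

    Deterministic for a fixed input order; a single sequence is returned as a
    one-row alignment, empty input is an error.
    """
    if not seqs:
        raise ValueError("no sequences to align")
    if len(seqs) == 1:
        return Alignment(ids=[seqs[0].id], rows=[seqs[0].residues])
    M20 = np.array(
        [[float(_matrix(matrix)[_rescode(x), _rescode(y)]) for y in _AA20] for x in _AA20]
    )
    D = _kmer_distance([s.residues for s in seqs], k=k)
    order = _upgma_merge_order(D, [s.id for s in seqs])
    nodes: dict[int, Alignment] = {
        i: Alignment(ids=[s.id], rows=[s.residues]) for i, s in enumerate(seqs)
    }
    next_id = len(seqs)
    for left, right in order:
        nodes[next_id] = _merge_alignments(
            nodes.pop(left), nodes.pop(right), M20, gap_open, gap_extend
        )
        next_id += 1
    (aln,) = nodes.values()
    # restore input row order
    pos = {sid: i for i, sid in enumerate(aln.ids)}
    ids_sorted = [s.id for s in seqs]
    return Alignment(ids=ids_sorted, rows=[aln.rows[pos[sid]] for sid in ids_sorted])


def _rescode(aa: str) -> int:
    from .similarity import _CODE

    return _CODE[aa]


def _upgma_merge_order(D: np.ndarray, labels: list[str]) -> list[tuple[int, int]]:
    """UPGMA agglomeration order on a condensed view of D; returns merge pairs
    as node indices (leaves 0..n-1, internal nodes numbered onwards).
    Ties are broken by the lexically smallest (min leaf label) pair."""
    n = D.shape[0]
    active: dict[int, tuple[np.ndarray, int, str]] = {}
    # each active node: (distance row indexed by node id map), size, min label
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = D[i, j]
    sizes = {i: 1 for i in range(n)}
    minlab = {i: labels[i] for i in range(n)}
    alive = set(range(n))
    merges = []
    nxt = n
    while len(alive) > 1:
        best = None
        for i in sorted(alive):
            for j in sorted(alive):
                if i >= j:
                    continue
                d = dist[(i, j)]
                key = (d, *sorted((minlab[i], minlab[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        merges.append((i, j))
        for x in alive:
            if x in (i, j):
                continue
            dix = dist[(min(i, x), max(i, x))]
            djx = dist[(min(j, x), max(j, x))]
            dnew = (sizes[i] * dix + sizes[j] * djx) / (sizes[i] + sizes[j])
            dist[(min(nxt, x), max(nxt, x))] = dnew
        sizes[nxt] = sizes[i] + sizes[j]
        minlab[nxt] = min(minlab[i], minlab[j])
        alive.discard(i)
        alive.discard(j)
        alive.add(nxt)
        nxt += 1
    return merges


# ---------------------------------------------------------------------------
# Trimming and concatenation


def trim_blocks(
    alignment: Alignment,
    max_gap_fraction: float = 0.5,
    min_conservation: float = 0.5,
    min_block: int = 5,
) -> tuple[Alignment, list[int]]:
    """Remove divergent alignment blocks.

    Columns with gap fraction above ``max_gap_fraction`` or modal-residue
    frequency below ``min_conservation`` are dropped; surviving runs shorter
    than ``min_block`` columns are dropped too.  Returns the trimmed
    alignment and the retained source-column indices (0-based).
    """
    if alignment.n_cols == 0:
        raise ValueError("empty alignment")
    codes = alignment.codes()
    n = alignment.n_rows
    keep_mask = np.zeros(alignment.n_cols, dtype=bool)
    for j in range(alignment.n_cols):
        col = codes[:, j]
        gaps = int((col == 255).sum())
        if gaps / n > max_gap_fraction:
            continue
        residues = col[col != 255]
        modal = np.bincount(residues).max() if residues.size else 0
        if modal / n < min_conservation:
            continue
        keep_mask[j] = True
    # drop runs shorter than min_block
    kept: list[int] = []
    run: list[int] = []
    for j in range(alignment.n_cols + 1):
        if j < alignment.n_cols and keep_mask[j]:
            run.append(j)
        else:
            if len(run) >= min_block:
                kept.extend(run)
            run = []
    if not kept:
        raise ValueError("alignment empty after trimming")
    rows = ["".join(row[j] for j in kept) for row in alignment.rows]
    return Alignment(ids=list(alignment.ids), rows=rows), kept


@dataclass
class SupermatrixMap:
    """Column ranges (0-based, half-open) of each concatenated gene alignment
    and the genome -> row mapping of the supermatrix."""

    ranges: dict[str, tuple[int, int]] = field(default_factory=dict)
    genome_rows: dict[str, int] = field(default_factory=dict)


def concatenate_core(
    alignments: dict[str, Alignment], genomes: list[str]
) -> tuple[Alignment, SupermatrixMap]:
    """Concatenate per-COG alignments (one row per genome each) into a
    supermatrix, in sorted COG-id order."""
    rows = {g: [] for g in genomes}
    smap = SupermatrixMap(genome_rows={g: i for i, g in enumerate(genomes)})
    offset = 0
    for cog_id in sorted(alignments):
        aln = alignments[cog_id]
        missing = sorted(set(genomes) - set(aln.ids))
        if missing:
            raise ValueError(
                f"{cog_id}: genome(s) {missing} missing from a core alignment"
            )
        row_of = dict(zip(aln.ids, aln.rows))
        for g in genomes:
            rows[g].append(row_of[g])
        smap.ranges[cog_id] = (offset, offset + aln.n_cols)
        offset += aln.n_cols
    supermatrix = Alignment(
        ids=list(genomes), rows=["".join(rows[g]) for g in genomes]
    )
    return supermatrix, smap


# ---------------------------------------------------------------------------
# Distances


def protein_distance(
    alignment: Alignment,
    model: str = "p",
    clamp: bool = False,
    max_distance: float = 5.0,
) -> pd.DataFrame:
    """Pairwise sequence distances over columns where neither row is gapped.

    ``model="p"`` gives the proportion of differing sites; ``"poisson"``
    applies -ln(1 - p).  A pair with no comparable columns, or p >= 1 under
    the Poisson model, is an error unless ``clamp`` is set, in which case the
    distance is capped at ``max_distance``.
    """
    if alignment.n_rows < 2:
        raise ValueError("need at least two rows")
    if model not in {"p", "poisson"}:
        raise ValueError(f"unknown model {model!r}")
    codes = alignment.codes()
    n = alignment.n_rows
    pair_i, pair_j = np.triu_indices(n, k=1)
    cols = np.arange(alignment.n_cols, dtype=np.int64)
    p, comp = _kernels.pdist_pairs(
        codes, pair_i.astype(np.int64), pair_j.astype(np.int64), cols
    )
    D = np.zeros((n, n))
    for idx in range(pair_i.size):
        i, j = pair_i[idx], pair_j[idx]
        if comp[idx] == 0:
            if not clamp:
                raise ValueError(
                    f"no comparable columns between {alignment.ids[i]!r} "
                    f"and {alignment.ids[j]!r}"
                )
            d = max_distance
        elif model == "p":
            d = p[idx]
        else:
            if p[idx] >= 1.0:
                if not clamp:
                    raise ValueError(
                        f"Poisson distance undefined (p >= 1) for pair "
                        f"{alignment.ids[i]!r}, {alignment.ids[j]!r}"
                    )
                d = max_distance
            else:
                d = min(-math.log(1.0 - p[idx]), max_distance) if clamp else -math.log(
                    1.0 - p[idx]
                )
        D[i, j] = D[j, i] = d
    return pd.DataFrame(D, index=alignment.ids, columns=alignment.ids)


def _check_distance_matrix(D: pd.DataFrame) -> None:
    A = D.to_numpy(dtype=float)
    if not np.allclose(A, A.T, atol=1e-9):
        raise ValueError("distance matrix is not symmetric")
    if not np.allclose(np.diag(A), 0.0, atol=1e-9):
        raise ValueError("distance matrix has nonzero diagonal")
    if (A < -1e-12).any():
        raise ValueError("distance matrix has negative entries")


# ---------------------------------------------------------------------------
# Tree building


class _Node:
    __slots__ = ("label", "children", "lengths", "minleaf")

    def __init__(self, label=None, children=None, lengths=None, minleaf=None):
        self.label = label
        self.children = children or []
        self.lengths = lengths or []
        self.minleaf = minleaf if minleaf is not None else label


def _to_dendropy(root: _Node, rooted: bool) -> dendropy.Tree:
    ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=ns)

    def build(node: _Node, dnode: dendropy.Node) -> None:
        if not node.children:
            dnode.taxon = ns.require_taxon(label=node.label)
            return
        for child, length in zip(node.children, node.lengths):
            dchild = dnode.new_child(edge_length=max(0.0, float(length)))
            build(child, dchild)

    build(root, tree.seed_node)
    tree.is_rooted = rooted
    return tree


def neighbor_joining(D: pd.DataFrame) -> dendropy.Tree:
    """Canonical neighbor joining with the Q criterion.

    Deterministic: ties in Q are resolved toward the lexically smallest pair
    of cluster labels (each cluster labelled by its smallest leaf).  Negative
    branch-length estimates are clamped to zero.  The result is unrooted
    (the dendropy seed node is a trifurcation where possible).
    """
    _check_distance_matrix(D)
    labels = [str(l) for l in D.index]
    if len(labels) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes = {i: _Node(label=lab) for i, lab in enumerate(labels)}
    dist = {
        (i, j): float(D.iat[i, j])
        for i in range(len(labels))
        for j in range(i + 1, len(labels))
    }

    def d(i: int, j: int) -> float:
        return dist[(i, j) if i < j else (j, i)]

    alive = set(nodes)
    nxt = len(labels)
    while len(alive) > 3:
        r = {i: sum(d(i, k) for k in alive if k != i) for i in alive}
        m = len(alive)
        best = None
        for i in sorted(alive):
            for j in sorted(alive):
                if i >= j:
                    continue
                q = (m - 2) * d(i, j) - r[i] - r[j]
                key = (q, *sorted((nodes[i].minleaf, nodes[j].minleaf)))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = 0.5 * d(i, j) + (r[i] - r[j]) / (2 * (m - 2))
        lj = d(i, j) - li
        li, lj = max(0.0, li), max(0.0, lj)
        new = _Node(
            children=[nodes[i], nodes[j]],
            lengths=[li, lj],
            minleaf=min(nodes[i].minleaf, nodes[j].minleaf),
        )
        for k in alive:
            if k in (i, j):
                continue
            dnew = 0.5 * (d(i, k) + d(j, k) - d(i, j))
            dist[(min(nxt, k), max(nxt, k))] = max(0.0, dnew)
        nodes[nxt] = new
        alive.discard(i)
        alive.discard(j)
        alive.add(nxt)
        nxt += 1
    a, b, c = sorted(alive)
    la = 0.5 * (d(a, b) + d(a, c) - d(b, c))
    lb = 0.5 * (d(a, b) + d(b, c) - d(a, c))
    lc = 0.5 * (d(a, c) + d(b, c) - d(a, b))
    root = _Node(
        children=[nodes[a], nodes[b], nodes[c]],
        lengths=[la, lb, lc],
        minleaf=min(nodes[x].minleaf for x in (a, b, c)),
    )
    return _to_dendropy(root, rooted=False)


def upgma(D: pd.DataFrame, weighting: str = "upgma") -> dendropy.Tree:
    """Agglomerative average-linkage clustering as a rooted tree.

    ``weighting="upgma"`` uses arithmetic (size-weighted) averaging of the
    merged clusters' distances; ``"wpgma"`` uses the simple mean.  Join
    heights are halved into branch lengths, so the UPGMA tree is ultrametric.
    """
    if weighting not in {"upgma", "wpgma"}:
        raise ValueError(f"unknown weighting {weighting!r}")
    _check_distance_matrix(D)
    labels = [str(l) for l in D.index]
    if len(labels) < 2:
        raise ValueError("need at least 2 labels")
    nodes = {i: _Node(label=lab) for i, lab in enumerate(labels)}
    heights = {i: 0.0 for i in range(len(labels))}
    sizes = {i: 1 for i in range(len(labels))}
    dist = {
        (i, j): float(D.iat[i, j])
        for i in range(len(labels))
        for j in range(i + 1, len(labels))
    }
    alive = set(nodes)
    nxt = len(labels)
    while len(alive) > 1:
        best = None
        for i in sorted(alive):
            for j in sorted(alive):
                if i >= j:
                    continue
                key = (
                    dist[(i, j)],
                    *sorted((nodes[i].minleaf, nodes[j].minleaf)),
                )
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        h = dist[(i, j)] / 2.0
        new = _Node(
            children=[nodes[i], nodes[j]],
            lengths=[h - heights[i], h - heights[j]],
            minleaf=min(nodes[i].minleaf, nodes[j].minleaf),
        )
        for k in alive:
            if k in (i, j):
                continue
            dik = dist[(min(i, k), max(i, k))]
            djk = dist[(min(j, k), max(j, k))]
            if weighting == "upgma":
                dnew = (sizes[i] * dik + sizes[j] * djk) / (sizes[i] + sizes[j])
            else:
                dnew = 0.5 * (dik + djk)
            dist[(min(nxt, k), max(nxt, k))] = dnew
        nodes[nxt] = new
        heights[nxt] = h
        sizes[nxt] = sizes[i] + sizes[j]
        alive.discard(i)
        alive.discard(j)
        alive.add(nxt)
        nxt += 1
    (root_idx,) = alive
    return _to_dendropy(nodes[root_idx], rooted=True)


def bootstrap_tree(
    alignment: Alignment,
    n_replicates: int = 1000,
    seed: int | None = None,
    model: str = "poisson",
    method: str = "nj",
) -> dendropy.Tree:
    """Distance tree with bootstrap supports.

    The point-estimate tree is built from the full alignment; each replicate
    resamples columns with replacement and rebuilds the tree, and the support
    of every internal edge of the point tree is the percentage of replicates
    whose tree contains that bipartition.
    """
    from .treecmp import bipartitions as _bipartitions

    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if alignment.n_cols < 2:
        raise ValueError("alignment has fewer than 2 columns")
    builder = neighbor_joining if method == "nj" else upgma
    if method not in {"nj", "upgma"}:
        raise ValueError(f"unknown method {method!r}")

    codes = alignment.codes()
    n = alignment.n_rows
    pair_i, pair_j = (x.astype(np.int64) for x in np.triu_indices(n, k=1))

    def tree_from_cols(cols: np.ndarray) -> dendropy.Tree:
        p, comp = _kernels.pdist_pairs(codes, pair_i, pair_j, cols)
        Dm = np.zeros((alignment.n_rows, alignment.n_rows))
        for idx in range(pair_i.size):
            i, j = pair_i[idx], pair_j[idx]
            if comp[idx] == 0:
                d = 5.0
            elif model == "poisson":
                d = -math.log(1.0 - min(p[idx], 0.99))
            else:
                d = p[idx]
            Dm[i, j] = Dm[j, i] = d
        return builder(pd.DataFrame(Dm, index=alignment.ids, columns=alignment.ids))

    all_cols = np.arange(alignment.n_cols, dtype=np.int64)
    point = tree_from_cols(all_cols)
    point_splits = _bipartitions(point)
    counts = {s: 0 for s in point_splits}
    rng = np.random.default_rng(seed)
    for _ in range(n_replicates):
        cols = rng.integers(0, alignment.n_cols, size=alignment.n_cols).astype(np.int64)
        rep_splits = _bipartitions(tree_from_cols(cols))
        for s in point_splits:
            if s in rep_splits:
                counts[s] += 1
    # attach supports to internal nodes of the point tree
    leafset = frozenset(l.taxon.label for l in point.leaf_node_iter())
    smallest = min(leafset)
    for node in point.preorder_internal_node_iter():
        if node is point.seed_node:
            continue
        clade = frozenset(l.taxon.label for l in node.leaf_iter())
        side = clade if smallest not in clade else leafset - clade
        if len(side) < 2 or len(leafset - side) < 2:
            continue
        if side in counts:
            node.support = 100.0 * counts[side] / n_replicates
    return point
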