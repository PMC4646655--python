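"""Tree comparison: bipartitions, Robinson-Foulds (symmetric-difference)
distances, extended-majority-rule consensus, non-metric multidimensional
scaling of tree-space distances, and gene-content dendrograms.

A bipartition is canonicalised as the frozenset of leaf labels on the side
*not* containing the lexically smallest leaf; trivial splits (a single leaf
on either side) are excluded everywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import pdist, squareform

from .phylo import _Node, _check_distance_matrix, _to_dendropy, upgma

__all__ = [
    "bipartitions",
    "robinson_foulds",
    "consensus_extended_majority",
    "tree_distance_matrix",
    "NMDSResult",
    "nmds",
    "gene_content_distance",
    "content_dendrograms",
]


def leaf_labels(tree: dendropy.Tree) -> frozenset[str]:
    return frozenset(l.taxon.label for l in tree.leaf_node_iter())


def bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Nontrivial bipartitions of the leaf set induced by internal edges."""
    leaves = leaf_labels(tree)
    if len(leaves) < 4:
        return set()
    smallest = min(leaves)
    splits: set[frozenset[str]] = set()
    for node in tree.preorder_internal_node_iter():
        if node is tree.seed_node:
            continue
        clade = frozenset(l.taxon.label for l in node.leaf_iter())
        side = clade if smallest not in clade else leaves - clade
        if 2 <= len(side) <= len(leaves) - 2:
            splits.add(side)
    return splits


def robinson_foulds(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Symmetric-difference (Robinson-Foulds) distance between two trees on
    the same leaf set."""
    l1, l2 = leaf_labels(t1), leaf_labels(t2)
    if l1 != l2:
        raise ValueError(
            f"leaf sets differ: only in first {sorted(l1 - l2)}, "
            f"only in second {sorted(l2 - l1)}"
        )
    return len(bipartitions(t1) ^ bipartitions(t2))


def _compatible(a: frozenset[str], b: frozenset[str]) -> bool:
    # both sides exclude the same reference leaf, so splits are compatible
    # iff nested or disjoint
    return a <= b or b <= a or not (a & b)


def consensus_extended_majority(trees: list[dendropy.Tree]) -> dendropy.Tree:
    """Extended-majority-rule consensus.

    All bipartitions with frequency > 50% are included; remaining
    bipartitions are added greedily in descending frequency (ties broken by
    canonical lexical order) when compatible with everything already
    included.  Split frequencies are attached as percent supports.
    """
    if not trees:
        raise ValueError("no input trees")
    leaves = leaf_labels(trees[0])
    for t in trees[1:]:
        if leaf_labels(t) != leaves:
            raise ValueError("input trees have differing leaf sets")
    counts: dict[frozenset[str], int] = {}
    for t in trees:
        for s in bipartitions(t):
            counts[s] = counts.get(s, 0) + 1
    n = len(trees)
    included: list[tuple[frozenset[str], float]] = []
    majority = [s for s, c in counts.items() if c / n > 0.5]
    rest = [s for s, c in counts.items() if c / n <= 0.5]
    for s in majority:
        included.append((s, 100.0 * counts[s] / n))
    rest.sort(key=lambda s: (-counts[s], sorted(s)))
    for s in rest:
        if all(_compatible(s, t) for t, _ in included):
            included.append((s, 100.0 * counts[s] / n))
    return _tree_from_splits(leaves, included)


def _tree_from_splits(
    leaves: frozenset[str], splits: list[tuple[frozenset[str], float]]
) -> dendropy.Tree:
    """Build the rooted-representation tree containing exactly the given
    pairwise-compatible splits (sides excluding the smallest leaf)."""
    ordered = sorted(splits, key=lambda sf: (-len(sf[0]), sorted(sf[0])))
    root = _Node(minleaf=min(leaves))
    node_sets: list[tuple[frozenset[str], _Node]] = [(leaves, root)]
    support_of: dict[int, float] = {}
    for side, freq in ordered:
        parent = root
        parent_set = leaves
        for s, nd in node_sets:
            if side < s and len(s) < len(parent_set):
                parent, parent_set = nd, s
        child = _Node(minleaf=min(side))
        support_of[id(child)] = freq
        parent.children.append(child)
        parent.lengths.append(1.0)
        node_sets.append((side, child))
    for leaf in sorted(leaves):
        parent, parent_set = root, leaves
        for s, nd in node_sets[1:]:
            if leaf in s and len(s) < len(parent_set):
                parent, parent_set = nd, s
        parent.children.append(_Node(label=leaf))
        parent.lengths.append(1.0)
    tree = _to_dendropy(root, rooted=False)
    # re-attach supports by matching clades
    smallest = min(leaves)
    freq_by_side = {side: freq for side, freq in splits}
    for node in tree.preorder_internal_node_iter():
        if node is tree.seed_node:
            continue
        clade = frozenset(l.taxon.label for l in node.leaf_iter())
        side = clade if smallest not in clade else leaves - clade
        if side in freq_by_side:
            node.support = freq_by_side[side]
    return tree


def tree_distance_matrix(trees: dict[str, dendropy.Tree]) -> pd.DataFrame:
    """Pairwise Robinson-Foulds distances between named trees."""
    if len(trees) < 2:
        raise ValueError("need at least two trees")
    names = list(trees)
    splits = {name: bipartitions(trees[name]) for name in names}
    leaves = {name: leaf_labels(trees[name]) for name in names}
    D = np.zeros((len(names), len(names)))
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            b = names[j]
            if leaves[a] != leaves[b]:
                raise ValueError(f"leaf sets differ between {a!r} and {b!r}")
            D[i, j] = D[j, i] = len(splits[a] ^ splits[b])
    return pd.DataFrame(D, index=names, columns=names)


# ---------------------------------------------------------------------------
# Non-metric multidimensional scaling


@dataclass
class NMDSResult:
    coordinates: pd.DataFrame  # items x dims, centred at the origin
    stress: float  # Kruskal stress-1 of the best restart
    iterations: int
    restarts: int
    seed: int | None
    degenerate: bool = False


def nmds(
    D: pd.DataFrame,
    dims: int = 2,
    restarts: int = 20,
    seed: int | None = None,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> NMDSResult:
    """Kruskal non-metric MDS by SMACOF majorization.

    Each restart starts from a random configuration; per iteration the
    configuration distances are monotonically regressed onto the
    dissimilarity ranks (pool-adjacent-violators) and the configuration is
    updated by the Guttman transform.  Stress-1 =
    sqrt(sum (d - dhat)^2 / sum d^2) is minimized; the best restart is
    returned, centred at the origin.
    """
    _check_distance_matrix(D)
    n = D.shape[0]
    if n < 3:
        raise ValueError("need at least 3 items")
    labels = [str(l) for l in D.index]
    diss = squareform(D.to_numpy(dtype=float), checks=False)
    if np.all(diss == 0):
        coords = pd.DataFrame(np.zeros((n, dims)), index=labels)
        return NMDSResult(coords, 0.0, 0, restarts, seed, degenerate=True)
    order = np.argsort(diss, kind="stable")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, restarts)):
        X = rng.normal(scale=diss.max(), size=(n, dims))
        last_stress = np.inf
        it = 0
        for it in range(1, max_iter + 1):
            d = pdist(X)
            dhat = np.empty_like(d)
            dhat[order] = isotonic_regression(d[order]).x
            norm = (d**2).sum()
            if norm == 0:
                break
            stress = math.sqrt(((d - dhat) ** 2).sum() / norm)
            if abs(last_stress - stress) < tol:
                last_stress = stress
                break
            last_stress = stress
            # Guttman transform with disparities dhat
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(d > 0, dhat / d, 0.0)
            B = -squareform(ratio)
            np.fill_diagonal(B, -B.sum(axis=1))
            X = (B @ X) / n
        if best is None or last_stress < best[0]:
            best = (last_stress, X - X.mean(axis=0), it)
    stress, X, iters = best
    return NMDSResult(
        coordinates=pd.DataFrame(
            X, index=labels, columns=[f"dim{i + 1}" for i in range(dims)]
        ),
        stress=float(stress),
        iterations=iters,
        restarts=restarts,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Gene-content distances and dendrograms


def gene_content_distance(
    matrix: pd.DataFrame, method: str = "jaccard", clamp: bool = True,
    max_distance: float = 5.0,
) -> pd.DataFrame:
    """Pairwise genome distances from a binary presence/absence matrix.

    ``"jaccard"``: 1 - |intersection| / |union| of family presence.
    ``"cfn"``: two-state maximum-likelihood correction d = -0.5 ln(1 - 2p)
    with p the fraction of discordant columns; p >= 0.5 is undefined and
    either raises or (with ``clamp``, the default) caps at ``max_distance``.
    """
    if matrix.shape[0] < 2:
        raise ValueError("need at least two genomes")
    M = matrix.to_numpy(dtype=bool)
    n = M.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if method == "jaccard":
                union = (M[i] | M[j]).sum()
                inter = (M[i] & M[j]).sum()
                d = 1.0 - inter / union if union else 0.0
            elif method == "cfn":
                p = (M[i] != M[j]).mean()
                if p >= 0.5:
                    if not clamp:
                        raise ValueError(
                            f"CFN distance undefined (p >= 0.5) for pair "
                            f"{matrix.index[i]!r}, {matrix.index[j]!r}"
                        )
                    d = max_distance
                else:
                    d = -0.5 * math.log(1.0 - 2.0 * p)
            else:
                raise ValueError(f"unknown method {method!r}")
            D[i, j] = D[j, i] = d
    return pd.DataFrame(D, index=matrix.index, columns=matrix.index)


def content_dendrograms(
    matrix: pd.DataFrame, method: str = "jaccard"
) -> tuple[dendropy.Tree, dendropy.Tree]:
    """Dendrograms of a presence/absence matrix: genomes clustered by WPGMA
    on row (gene-content) distances, gene families by UPGMA on column
    distances.  Typically run on the accessory columns only."""
    phage_tree = upgma(gene_content_distance(matrix, method=method), "wpgma")
    gene_tree = upgma(gene_content_distance(matrix.T, method=method), "upgma")
    return phage_tree, gene_tree
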