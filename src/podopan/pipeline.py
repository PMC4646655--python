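"""End-to-end orchestration: genomes -> all-vs-all search -> COG clustering ->
pan-genome statistics -> core-gene and gene-content phylogenies -> tree-space
comparison.  Each stage is also usable on its own; this module wires the
default path used by the command-line interface and the analysis scripts.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .io_formats import PairwiseHit, SequenceRecord
from .orthology import (
    COG,
    OrthologyThresholds,
    build_ortholog_graph,
    cluster_cogs,
)
from .pangenome import (
    AccumulationCurve,
    GenomeFractions,
    RegressionResult,
    accumulation_curves,
    classify_cogs,
    genome_fractions,
    linear_regression,
    pairwise_shared_fraction,
    presence_absence,
)
from .phylo import (
    Alignment,
    SupermatrixMap,
    bootstrap_tree,
    concatenate_core,
    neighbor_joining,
    progressive_msa,
    protein_distance,
    trim_blocks,
)
from .sequence_core import GeneFeature
from .similarity import ScoringParams, all_vs_all
from .treecmp import (
    NMDSResult,
    bipartitions,
    content_dendrograms,
    nmds,
    tree_distance_matrix,
)

__all__ = [
    "cluster_genomes",
    "core_alignments",
    "core_genome_tree",
    "core_gene_trees",
    "core_identity_matrix",
    "shared_fraction_regression",
    "clade_recovered",
    "adjusted_rand_index",
    "PipelineResult",
    "run_full",
]


def cluster_genomes(
    genes: list[GeneFeature],
    thresholds: OrthologyThresholds | None = None,
    engine: str = "blast",
    mode: str = "reciprocal",
    params: ScoringParams | None = None,
) -> tuple[list[COG], list[PairwiseHit]]:
    """All-vs-all search plus reciprocal-hit clustering of gene features
    (whose ``protein`` attributes carry the sequences).  Returns classified
    COGs and the raw hit list."""
    proteins = [(g.genome_id, g.gene_id, g.protein) for g in genes]
    hits = all_vs_all(proteins, params=params, engine=engine)
    lengths = {g.gene_id: len(g.protein) for g in genes}
    genomes_of = {g.gene_id: g.genome_id for g in genes}
    graph = build_ortholog_graph(
        hits, lengths, thresholds, mode=mode, gene_genomes=genomes_of
    )
    cogs = cluster_cogs(graph, [(g.genome_id, g.gene_id) for g in genes])
    n_genomes = len({g.genome_id for g in genes})
    classify_cogs(cogs, n_genomes)
    return cogs, hits


def core_alignments(
    cogs: list[COG],
    genes: list[GeneFeature],
    trim: bool = True,
) -> dict[str, Alignment]:
    """Align every core COG across genomes (rows keyed by genome id).

    If transitive clustering placed more than one gene of a genome in a core
    COG, the lexically first gene id represents that genome.
    """
    protein_of = {g.gene_id: g.protein for g in genes}
    out: dict[str, Alignment] = {}
    for cog in cogs:
        if cog.category != "core":
            continue
        rep: dict[str, str] = {}
        for genome_id, gene_id in sorted(cog.members, key=lambda m: m[1]):
            rep.setdefault(genome_id, gene_id)
        seqs = [
            SequenceRecord(id=genome_id, residues=protein_of[gene_id])
            for genome_id, gene_id in sorted(rep.items())
        ]
        aln = progressive_msa(seqs)
        if trim:
            aln, _ = trim_blocks(aln)
        out[cog.cog_id] = aln
    return out


def core_genome_tree(
    alignments: dict[str, Alignment],
    genomes: list[str],
    n_bootstrap: int = 1000,
    seed: int | None = None,
    model: str = "poisson",
) -> tuple[Alignment, SupermatrixMap, dendropy.Tree]:
    """Concatenated-core-gene distance tree with bootstrap supports."""
    supermatrix, smap = concatenate_core(alignments, genomes)
    tree = bootstrap_tree(
        supermatrix, n_replicates=n_bootstrap, seed=seed, model=model, method="nj"
    )
    return supermatrix, smap, tree


def core_gene_trees(
    alignments: dict[str, Alignment], model: str = "poisson"
) -> dict[str, dendropy.Tree]:
    """One NJ tree per core COG alignment."""
    trees = {}
    for cog_id, aln in alignments.items():
        D = protein_distance(aln, model=model, clamp=True)
        trees[cog_id] = neighbor_joining(D)
    return trees


def core_identity_matrix(
    alignments: dict[str, Alignment]
) -> pd.DataFrame:
    """Mean percent identity of core genes between every genome pair,
    averaged over COGs (pairwise-deletion identity per alignment)."""
    total = None
    count = None
    for aln in alignments.values():
        D = protein_distance(aln, model="p", clamp=True)
        ident = 100.0 * (1.0 - D)
        if total is None:
            total = ident
            count = 1
        else:
            total = total + ident.loc[total.index, total.columns]
            count += 1
    if total is None:
        raise ValueError("no core alignments")
    mat = total / count
    np.fill_diagonal(mat.values, 100.0)
    return mat


def shared_fraction_regression(
    matrix: pd.DataFrame,
    identity: pd.DataFrame,
    denominator: str = "mean",
) -> RegressionResult:
    """Regress the pairwise shared-gene fraction on the mean core-gene
    identity across genome pairs."""
    shared = pairwise_shared_fraction(matrix, denominator=denominator)
    idx = list(matrix.index)
    xs, ys = [], []
    for i in range(len(idx)):
        for j in range(i + 1, len(idx)):
            xs.append(float(identity.loc[idx[i], idx[j]]))
            ys.append(float(shared.loc[idx[i], idx[j]]))
    return linear_regression(xs, ys)


def clade_recovered(tree: dendropy.Tree, members: set[str]) -> bool:
    """True when the member set forms one side of a bipartition of the tree
    (i.e. the planted group is recovered as a clade)."""
    leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    members = frozenset(members)
    if not members <= leaves:
        raise ValueError("members are not a subset of the tree's leaves")
    smallest = min(leaves)
    side = members if smallest not in members else leaves - members
    return side in bipartitions(tree)


def adjusted_rand_index(
    partition_a: dict[str, str], partition_b: dict[str, str]
) -> float:
    """Adjusted Rand index between two partitions keyed by gene id."""
    from sklearn.metrics import adjusted_rand_score

    keys = sorted(partition_a)
    if set(keys) != set(partition_b):
        raise ValueError("partitions cover different gene sets")
    return float(
        adjusted_rand_score(
            [partition_a[k] for k in keys], [partition_b[k] for k in keys]
        )
    )


@dataclass
class PipelineResult:
    cogs: list[COG]
    hits: list[PairwiseHit]
    matrix: pd.DataFrame
    curve: AccumulationCurve
    fractions: GenomeFractions
    alignments: dict[str, Alignment]
    supermatrix: Alignment
    core_tree: dendropy.Tree
    gene_trees: dict[str, dendropy.Tree]
    rf_matrix: pd.DataFrame
    nmds: NMDSResult
    content_phage_tree: dendropy.Tree
    content_gene_tree: dendropy.Tree
    regression: RegressionResult

    @property
    def category_counts(self) -> dict[str, int]:
        counts = {"core": 0, "accessory": 0, "unique": 0}
        for cog in self.cogs:
            counts[cog.category] += 1
        return counts


def run_full(
    genomes: list[SequenceRecord],
    genes: list[GeneFeature],
    seed: int = 0,
    engine: str = "blast",
    mode: str = "reciprocal",
    thresholds: OrthologyThresholds | None = None,
    n_permutations: int = 1000,
    n_bootstrap: int = 100,
) -> PipelineResult:
    """Run the whole comparative pipeline on a genome set."""
    genome_ids = [g.id for g in genomes]
    cogs, hits = cluster_genomes(genes, thresholds, engine=engine, mode=mode)
    matrix = presence_absence(cogs, genome_ids)
    curve = accumulation_curves(matrix, n_permutations=n_permutations, seed=seed)
    fractions = genome_fractions(
        cogs, genes, {g.id: len(g.residues) for g in genomes}
    )
    alignments = core_alignments(cogs, genes)
    supermatrix, _, core_tree_ = core_genome_tree(
        alignments, genome_ids, n_bootstrap=n_bootstrap, seed=seed
    )
    gene_trees_ = core_gene_trees(alignments)
    rf = tree_distance_matrix(gene_trees_)
    nm = nmds(rf, seed=seed)
    accessory_cols = [c.cog_id for c in cogs if c.category == "accessory"]
    phage_tree, gene_tree = content_dendrograms(matrix[accessory_cols])
    regression = shared_fraction_regression(matrix, core_identity_matrix(alignments))
    return PipelineResult(
        cogs=cogs,
        hits=hits,
        matrix=matrix,
        curve=curve,
        fractions=fractions,
        alignments=alignments,
        supermatrix=supermatrix,
        core_tree=core_tree_,
        gene_trees=gene_trees_,
        rf_matrix=rf,
        nmds=nm,
        content_phage_tree=phage_tree,
        content_gene_tree=gene_tree,
        regression=regression,
    )
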