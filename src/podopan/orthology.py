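"""Reciprocal-hit orthology assignment and clustering into COGs.

A gene pair is orthologous when the similarity hits in *both* directions meet
an e-value cutoff (default 1e-5) and the alignment covers at least half of
the shorter sequence.  For short sequences (< 100 aa) the e-value requirement
is waived in favour of a percent-identity floor (35%), because short genes
rarely achieve significant e-values; the coverage requirement still applies.
COGs (clustered orthologous groups) are the connected components of the
resulting undirected ortholog graph, so every input gene — including genes
with no orthologs — belongs to exactly one COG.

Two readings of "reciprocal hits" are provided: the literal one (hits in
both directions each meeting the cutoffs; default) and reciprocal *best*
hits (additionally each gene must be the other's best-scoring hit in its
genome).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .io_formats import PairwiseHit

__all__ = [
    "OrthologyThresholds",
    "COG",
    "ortholog_pair",
    "best_hits_by_pair",
    "build_ortholog_graph",
    "cluster_cogs",
    "merge_by_profile_hits",
]


@dataclass(frozen=True)
class OrthologyThresholds:
    evalue_max: float = 1e-5
    coverage_min: float = 0.50  # of the shorter sequence
    short_length: int = 100  # aa; below this the short-sequence rule applies
    short_identity_min: float = 35.0  # percent
    profile_evalue_max: float = 1e-5

    def __post_init__(self) -> None:
        if not (0 < self.coverage_min <= 1):
            raise ValueError("coverage_min must be in (0, 1]")
        if min(self.evalue_max, self.short_length, self.short_identity_min,
               self.profile_evalue_max) <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class COG:
    """A clustered orthologous group: member genes across genomes."""

    cog_id: str
    members: frozenset[tuple[str, str]]  # (genome_id, gene_id)
    category: str | None = None  # core | accessory | unique

    @property
    def genome_count(self) -> int:
        return len({g for g, _ in self.members})


def ortholog_pair(
    hit_ab: PairwiseHit | None,
    hit_ba: PairwiseHit | None,
    len_a: int,
    len_b: int,
    thresholds: OrthologyThresholds | None = None,
) -> bool:
    """Apply the reciprocal-hit orthology rule to one gene pair.

    Both directional hits must be present (a missing direction is simply not
    orthologous).  Both must cover >= ``coverage_min`` of the shorter
    sequence, and either both pass the e-value cutoff or — when the shorter
    sequence is below ``short_length`` — both pass the identity floor.
    """
    if len_a <= 0 or len_b <= 0:
        raise ValueError("sequence lengths must be positive")
    if hit_ab is None or hit_ba is None:
        return False
    t = thresholds or OrthologyThresholds()
    shorter = min(len_a, len_b)
    need_cols = t.coverage_min * shorter
    if hit_ab.alignment_length < need_cols or hit_ba.alignment_length < need_cols:
        return False
    if hit_ab.e_value <= t.evalue_max and hit_ba.e_value <= t.evalue_max:
        return True
    if shorter < t.short_length:
        return (
            hit_ab.percent_identity >= t.short_identity_min
            and hit_ba.percent_identity >= t.short_identity_min
        )
    return False


def best_hits_by_pair(
    hits: list[PairwiseHit],
) -> dict[tuple[str, str], PairwiseHit]:
    """Best hit per ordered (query, subject) pair: lowest e-value, ties
    broken by highest bit score."""
    best: dict[tuple[str, str], PairwiseHit] = {}
    for h in hits:
        key = (h.query_id, h.subject_id)
        cur = best.get(key)
        if (
            cur is None
            or h.e_value < cur.e_value
            or (h.e_value == cur.e_value and h.bit_score > cur.bit_score)
        ):
            best[key] = h
    return best


def build_ortholog_graph(
    hits: list[PairwiseHit],
    gene_lengths: dict[str, int],
    thresholds: OrthologyThresholds | None = None,
    mode: str = "reciprocal",
    gene_genomes: dict[str, str] | None = None,
) -> nx.Graph:
    """Build the undirected ortholog graph from directional hits.

    ``mode="reciprocal"`` (default) follows the literal rule; ``mode="best"``
    additionally requires each gene to be the other's best hit within its
    genome (reciprocal best hits), which needs ``gene_genomes``.
    """
    referenced = {h.query_id for h in hits} | {h.subject_id for h in hits}
    unknown = sorted(referenced - set(gene_lengths))
    if unknown:
        raise ValueError(f"hits reference unknown gene id(s): {unknown[:5]}")
    t = thresholds or OrthologyThresholds()
    best = best_hits_by_pair(hits)

    allowed: set[frozenset[str]] | None = None
    if mode == "best":
        if gene_genomes is None:
            raise ValueError("mode='best' requires gene_genomes")
        # best hit per (query gene, subject genome)
        top: dict[tuple[str, str], PairwiseHit] = {}
        for h in best.values():
            key = (h.query_id, gene_genomes[h.subject_id])
            cur = top.get(key)
            if (
                cur is None
                or h.e_value < cur.e_value
                or (h.e_value == cur.e_value and h.bit_score > cur.bit_score)
            ):
                top[key] = h
        allowed = set()
        for h in top.values():
            back = top.get((h.subject_id, gene_genomes[h.query_id]))
            if back is not None and back.subject_id == h.query_id:
                allowed.add(frozenset((h.query_id, h.subject_id)))
    elif mode != "reciprocal":
        raise ValueError(f"unknown mode {mode!r}")

    graph = nx.Graph()
    graph.add_nodes_from(gene_lengths)
    for (q, s), h in best.items():
        if q >= s:
            continue  # handle each unordered pair once, from its sorted side
        if q == s:
            continue
        back = best.get((s, q))
        if back is None:
            continue
        if allowed is not None and frozenset((q, s)) not in allowed:
            continue
        if ortholog_pair(h, back, gene_lengths[q], gene_lengths[s], t):
            graph.add_edge(q, s)
    return graph


def cluster_cogs(
    graph: nx.Graph,
    all_genes: list[tuple[str, str]],
) -> list[COG]:
    """Connected components of the ortholog graph as COGs.

    ``all_genes`` is the full (genome_id, gene_id) inventory; genes absent
    from the graph become singleton COGs.  COG ids are assigned in sorted
    order of each component's smallest gene id.
    """
    genome_of = {g: gn for gn, g in all_genes}
    missing = sorted(set(graph.nodes) - set(genome_of))
    if missing:
        raise ValueError(f"graph contains gene(s) not in the inventory: {missing[:5]}")
    components = [set(c) for c in nx.connected_components(graph)]
    clustered = set().union(*components) if components else set()
    components.extend({g} for gn, g in all_genes if g not in clustered)
    components.sort(key=lambda c: min(c))
    cogs = []
    for idx, comp in enumerate(components, start=1):
        cogs.append(
            COG(
                cog_id=f"COG{idx:04d}",
                members=frozenset((genome_of[g], g) for g in comp),
            )
        )
    return cogs


def merge_by_profile_hits(
    cogs: list[COG],
    profile_hits: list[tuple[str, str, float]],
    thresholds: OrthologyThresholds | None = None,
) -> list[COG]:
    """Merge COGs linked by significant profile-search hits.

    ``profile_hits`` rows are ``(gene_id, target_cog_id, e_value)``; a hit
    with e-value <= ``profile_evalue_max`` unions the gene's COG with the
    target COG.  Merging is computed as connected components over the merge
    relation, so the outcome is independent of row order.
    """
    t = thresholds or OrthologyThresholds()
    cog_of_gene = {g: c.cog_id for c in cogs for _, g in c.members}
    cog_by_id = {c.cog_id: c for c in cogs}
    merge_graph = nx.Graph()
    merge_graph.add_nodes_from(cog_by_id)
    for gene_id, target_cog, e in profile_hits:
        if gene_id not in cog_of_gene:
            raise ValueError(f"profile hit references unknown gene {gene_id!r}")
        if target_cog not in cog_by_id:
            raise ValueError(f"profile hit references unknown COG {target_cog!r}")
        if e <= t.profile_evalue_max:
            merge_graph.add_edge(cog_of_gene[gene_id], target_cog)
    merged_sets = [
        frozenset().union(*(cog_by_id[c].members for c in comp))
        for comp in nx.connected_components(merge_graph)
    ]
    merged_sets.sort(key=lambda ms: min(g for _, g in ms))
    return [
        COG(cog_id=f"COG{idx:04d}", members=ms)
        for idx, ms in enumerate(merged_sets, start=1)
    ]
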