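"""Synthetic phage genome sets with planted ground truth.

The generator emulates the architecture of a small marine cyanopodovirus
collection: 20 genomes of 42-48 kb carrying ~50-60 genes each, a planted
core of 15 gene families present everywhere, accessory families laid out in
cluster- and subcluster-specific blocks, unique genes, two phylogenetic
clusters (one of 5 genomes, one of 15 split into four subclusters),
host-group-specific G+C composition (a low-G+C group of 11 genomes at 39%
and a high-G+C group of 9 at 50%), sequence divergence growing with
phylogenetic distance, and a subset of core families (default 5 of 15) that
evolve on an alternative, host-group-structured guide tree to emulate
recombinant phylogenetic incongruence.

Protein evolution is i.i.d. per-site substitution with per-branch expected
mismatch fractions; presence/absence is set combinatorially (no gain/loss
process) so ground-truth categories are exact.  Nucleotide sequences are
produced by back-translating each protein with greedy synonymous-codon
steering toward the genome's G+C target, and genes are laid out colinearly
(shared families in a common order) to emulate synteny.  Everything is
deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .io_formats import SequenceRecord, write_fasta
from .phylo import _Node, _to_dendropy
from .io_formats import write_newick
from .sequence_core import GeneFeature, reverse_complement

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_genome_set",
    "mutate_protein",
    "write_simulation",
]

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_AA_ARR = np.array(list(_AA20))

# table-11 sense codons per amino acid (M restricted to ATG keeps planted
# genes discoverable by the ORF caller)
_BASES = "TCAG"
_TAB11 = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
_AA2CODONS: dict[str, list[str]] = {}
for _i, _b1 in enumerate(_BASES):
    for _j, _b2 in enumerate(_BASES):
        for _k, _b3 in enumerate(_BASES):
            _aa = _TAB11[16 * _i + 4 * _j + _k]
            if _aa != "*":
                _AA2CODONS.setdefault(_aa, []).append(_b1 + _b2 + _b3)
for _aa in _AA2CODONS:
    _AA2CODONS[_aa].sort()
_STOPS = ["TAA", "TAG", "TGA"]


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters of the synthetic genome set.

    Defaults plant the 349-family architecture (15 core + 99 accessory +
    235 unique over 20 genomes) with two clusters (5 + 15 genomes) and four
    subclusters inside the second cluster.
    """

    n_genomes: int = 20
    cluster_sizes: tuple[int, int] = (5, 15)
    subcluster_sizes: tuple[int, ...] = (5, 4, 3, 3)
    n_core: int = 15
    n_recombinant_core: int = 5
    unique_counts: tuple[int, ...] | None = None  # default: 235 total
    core_len_median: int = 480  # codons
    core_len_sigma: float = 0.25
    other_len_median: int = 170
    other_len_sigma: float = 0.35
    min_protein_len: int = 60
    gc_low: float = 0.39
    gc_high: float = 0.50
    genome_window: tuple[int, int] = (42000, 48000)
    rate_scale: float = 1.0
    minus_strand_fraction: float = 0.3

    def __post_init__(self) -> None:
        if sum(self.cluster_sizes) != self.n_genomes:
            raise ValueError("cluster sizes must sum to n_genomes")
        if sum(self.subcluster_sizes) != self.cluster_sizes[1]:
            raise ValueError("subcluster sizes must sum to the second cluster size")
        if self.n_core < 0 or self.n_recombinant_core > self.n_core:
            raise ValueError("bad core gene counts")
        if not (0 < self.gc_low < 1 and 0 < self.gc_high < 1):
            raise ValueError("G+C targets must be in (0, 1)")

    def genome_ids(self) -> list[str]:
        return [f"g{i + 1:02d}" for i in range(self.n_genomes)]

    def cluster_labels(self) -> dict[str, str]:
        ids = self.genome_ids()
        labels = {}
        for i, g in enumerate(ids[: self.cluster_sizes[0]]):
            labels[g] = "A"
        pos = self.cluster_sizes[0]
        for sub_idx, size in enumerate(self.subcluster_sizes, start=1):
            for g in ids[pos : pos + size]:
                labels[g] = f"B{sub_idx}"
            pos += size
        return labels

    def host_groups(self) -> dict[str, str]:
        """Low-G+C vs high-G+C host association (11 low + 9 high at defaults,
        deliberately not congruent with the cluster split)."""
        labels = self.cluster_labels()
        groups = {}
        a_members = [g for g, c in labels.items() if c == "A"]
        for i, g in enumerate(a_members):
            groups[g] = "low" if i < 2 else "high"
        for g, c in labels.items():
            if c in ("B1", "B2"):
                groups[g] = "low"
            elif c in ("B3", "B4"):
                groups[g] = "high"
        return groups

    def default_unique_counts(self) -> tuple[int, ...]:
        if self.unique_counts is not None:
            return self.unique_counts
        if self.n_genomes == 20:
            # 15 genomes with 12 unique genes + 5 with 11 -> 235 total
            return tuple([12] * 15 + [11] * 5)
        return tuple([12] * self.n_genomes)

    def accessory_blocks(self) -> list[tuple[tuple[int, ...], int]]:
        """(genome-index subset, number of families) accessory block plan.

        The default plan places 99 families / ~525 gene occurrences in
        cluster-, subcluster- and pair-specific blocks, balancing each
        genome's accessory complement near 26 families.
        """
        labels = self.cluster_labels()
        ids = self.genome_ids()
        by = lambda *names: tuple(
            i for i, g in enumerate(ids) if labels[g] in names
        )
        A, B1, B2, B3, B4 = by("A"), by("B1"), by("B2"), by("B3"), by("B4")
        plan = [
            (A, 23),
            (A + B4, 3),
            (B1, 7),
            (B1 + B2, 8),
            (B1 + B2 + B3, 9),
            (B2, 6),
            (B2 + B3, 2),
            (B3, 6),
            (B3 + B4, 8),
            (B4, 13),
        ]
        pairs = [
            (0, 5), (1, 6), (2, 7), (3, 8), (4, 9),
            (10, 15), (11, 16), (12, 17), (13, 18), (14, 19),
            (0, 10), (5, 14), (9, 17), (2, 19),
        ]
        n = self.n_genomes
        for a, b in pairs:
            if a < n and b < n and a != b:
                plan.append(((a, b), 1))
        return [(tuple(s), k) for s, k in plan if s]


@dataclass
class GroundTruth:
    """Planted truth of a simulated genome set."""

    membership: dict[str, str]  # gene_id -> family id
    categories: dict[str, str]  # family id -> core | accessory | unique
    tree_newick: str
    alt_tree_newick: str
    core_guide: dict[str, str]  # core family id -> "true" | "alt"
    cluster_of: dict[str, str]
    host_group_of: dict[str, str]

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        return cls(**json.loads(text))


def mutate_protein(seq: str, expected_fraction: float, rng) -> str:
    """Substitute each site independently with the given probability; the
    replacement is drawn uniformly from the 19 other residues."""
    if not (0 <= expected_fraction < 1):
        raise ValueError("expected_fraction must be in [0, 1)")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    arr = np.array(list(seq))
    mask = rng.random(arr.size) < expected_fraction
    if mask.any():
        idx = np.flatnonzero(mask)
        current = arr[idx]
        repl = _AA_ARR[rng.integers(0, 19, idx.size)]
        # shift draws that collide with the current residue
        collide = repl == current
        while collide.any():
            repl[collide] = _AA_ARR[
                (np.searchsorted(_AA_ARR, repl[collide]) + 1) % 20
            ]
            collide = repl == current
        arr[idx] = repl
    return "".join(arr)


# ---------------------------------------------------------------------------
# Guide trees


def _caterpillar(leaves: list[str], leaf_rate: float, internal_rate: float):
    """Nested-pair (caterpillar) subtree over the given leaves."""
    node = ("leaf", leaves[0], leaf_rate)
    for leaf in leaves[1:]:
        node = ("node", [node, ("leaf", leaf, leaf_rate)], internal_rate)
    return node


def _true_tree(cfg: SimConfig):
    labels = cfg.cluster_labels()
    groups: dict[str, list[str]] = {}
    for g in cfg.genome_ids():
        groups.setdefault(labels[g], []).append(g)
    cat = lambda key: _caterpillar(groups[key], 0.03, 0.02)
    sub = lambda key: ("node", [cat(key)], 0.05)
    b12 = ("node", [sub("B1"), sub("B2")], 0.03)
    b34 = ("node", [sub("B3"), sub("B4")], 0.03)
    a = ("node", [cat("A")], 0.08)
    b = ("node", [b12, b34], 0.04)
    return ("node", [a, b], 0.0)


def _alt_tree(cfg: SimConfig):
    """Host-group-structured alternative guide tree with reversed
    within-subcluster arrangements: topologically distant from the true tree
    at every level."""
    labels = cfg.cluster_labels()
    hosts = cfg.host_groups()
    groups: dict[str, list[str]] = {}
    for g in cfg.genome_ids():
        groups.setdefault(labels[g], []).append(g)
    a_low = [g for g in groups["A"] if hosts[g] == "low"]
    a_high = [g for g in groups["A"] if hosts[g] == "high"]
    rcat = lambda leaves: _caterpillar(list(reversed(leaves)), 0.03, 0.02)
    low = (
        "node",
        [
            ("node", [rcat(a_low)], 0.05),
            ("node", [("node", [rcat(groups["B1"])], 0.05),
                      ("node", [rcat(groups["B2"])], 0.05)], 0.03),
        ],
        0.08,
    )
    high = (
        "node",
        [
            ("node", [rcat(a_high)], 0.05),
            ("node", [("node", [rcat(groups["B3"])], 0.05),
                      ("node", [rcat(groups["B4"])], 0.05)], 0.03),
        ],
        0.04,
    )
    return ("node", [low, high], 0.0)


def _tree_to_newick(tree) -> str:
    def build(node) -> _Node:
        kind = node[0]
        if kind == "leaf":
            return _Node(label=node[1])
        children = [build(c) for c in node[1]]
        out = _Node(children=children, lengths=[c_rate(c) for c in node[1]])
        out.minleaf = min(ch.minleaf for ch in children)
        return out

    def c_rate(node) -> float:
        return node[2]

    root = build(tree)
    return write_newick(_to_dendropy(root, rooted=True))


def _evolve(tree, ancestral: str, rate_mult: float, rng) -> dict[str, str]:
    """Evolve a protein down a guide tree; returns genome_id -> sequence."""
    out: dict[str, str] = {}

    def walk(node, seq: str) -> None:
        kind = node[0]
        rate = min(0.8, node[2] * rate_mult)
        if rate > 0:
            # the initiator methionine is kept fixed so every planted gene
            # remains a callable ORF
            seq = "M" + mutate_protein(seq, rate, rng)[1:]
        if kind == "leaf":
            out[node[1]] = seq
        else:
            for child in node[1]:
                walk(child, seq)

    # root branch has rate 0; children evolve independently from the root seq
    for child in tree[1]:
        walk(child, ancestral)
    return out


# ---------------------------------------------------------------------------
# Back-translation with G+C steering


class _GCSteerer:
    """Greedy synonymous-codon chooser tracking a genome-wide running G+C
    count against a target fraction."""

    def __init__(self, target: float):
        self.target = target
        self.gc = 0
        self.total = 0

    def _pick(self, candidates: list[str]) -> str:
        best = None
        for codon in candidates:
            gcc = codon.count("G") + codon.count("C")
            err = abs(self.target - (self.gc + gcc) / (self.total + 3))
            if best is None or err < best[0] - 1e-12:
                best = (err, codon, gcc)
        _, codon, gcc = best
        self.gc += gcc
        self.total += 3
        return codon

    def codon(self, aa: str) -> str:
        return self._pick(_AA2CODONS[aa])

    def stop(self) -> str:
        return self._pick(_STOPS)

    def spacer(self, length: int, rng) -> str:
        gc_mask = rng.random(length) < self.target
        halves = rng.random(length) < 0.5
        bases = np.where(gc_mask, np.where(halves, "G", "C"), np.where(halves, "A", "T"))
        self.gc += int(gc_mask.sum())
        self.total += length
        return "".join(bases)


def _back_translate(protein: str, steerer: _GCSteerer) -> str:
    codons = [steerer.codon(aa) for aa in protein]
    codons.append(steerer.stop())
    return "".join(codons)


def _fit_lengths_to_window(cfg, ids, blocks, core_lens, block_lens, unique_lens):
    """Rescale drawn protein lengths, if necessary, so that every genome's
    coding total fits the genome-size window once minimal/maximal spacers
    are added.  Raises when the configuration cannot fit at all."""

    def per_genome_coding(cl, bl, ul):
        coding = {g: sum(3 * (L + 1) for L in cl) for g in ids}
        counts = {g: len(cl) for g in ids}
        for (subset, _), lens in zip(blocks, bl):
            for i in subset:
                coding[ids[i]] += sum(3 * (L + 1) for L in lens)
                counts[ids[i]] += len(lens)
        for g, lens in zip(ids, ul):
            coding[g] += sum(3 * (L + 1) for L in lens)
            counts[g] += len(lens)
        return coding, counts

    coding, counts = per_genome_coding(core_lens, block_lens, unique_lens)
    lo_w, hi_w = cfg.genome_window
    scale = 1.0
    for g in ids:
        n_gaps = counts[g] + 1
        hi_budget = hi_w - 6 * n_gaps
        lo_budget = lo_w - 120 * n_gaps
        if coding[g] > hi_budget:
            scale = min(scale, hi_budget / coding[g])
        if coding[g] < lo_budget and scale == 1.0:
            scale = max(scale, lo_budget / coding[g])
    if scale != 1.0:
        resize = lambda L: max(cfg.min_protein_len, int(round(L * scale)))
        core_lens = [resize(L) for L in core_lens]
        block_lens = [[resize(L) for L in lens] for lens in block_lens]
        unique_lens = [[resize(L) for L in lens] for lens in unique_lens]
        coding, counts = per_genome_coding(core_lens, block_lens, unique_lens)
        for g in ids:
            n_gaps = counts[g] + 1
            if coding[g] > hi_w - 5 * n_gaps or coding[g] + 130 * n_gaps < lo_w:
                raise ValueError(
                    f"{g}: {counts[g]} genes ({coding[g]} nt coding) cannot fit "
                    f"the genome-size window {cfg.genome_window}"
                )
    return core_lens, block_lens, unique_lens


# ---------------------------------------------------------------------------
# Main generator


def simulate_genome_set(
    config: SimConfig | None = None, seed: int = 0
) -> tuple[list[SequenceRecord], list[GeneFeature], GroundTruth]:
    """Generate a genome set with planted COG architecture.

    Returns ``(genomes, genes, truth)``: genome nucleotide records, gene
    features carrying the encoded proteins, and the machine-readable ground
    truth (family partition, categories, guide trees, cluster and host-group
    labels).
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng(seed)
    ids = cfg.genome_ids()
    labels = cfg.cluster_labels()
    hosts = cfg.host_groups()
    true_tree = _true_tree(cfg)
    alt_tree = _alt_tree(cfg)

    def draw_len(median: int, sigma: float) -> int:
        val = int(round(rng.lognormal(np.log(median), sigma)))
        return int(np.clip(val, cfg.min_protein_len, 3 * median))

    def ancestral(length: int) -> str:
        seq = "".join(_AA_ARR[rng.integers(0, 20, length)])
        return "M" + seq[1:]

    # --- draw all protein lengths up front so genome-size feasibility can
    # be enforced globally (a lognormal tail must not overflow the window)
    blocks = cfg.accessory_blocks()
    unique_counts = cfg.default_unique_counts()
    core_lens = [draw_len(cfg.core_len_median, cfg.core_len_sigma)
                 for _ in range(cfg.n_core)]
    block_lens = [
        [draw_len(cfg.other_len_median, cfg.other_len_sigma) for _ in range(k)]
        for _, k in blocks
    ]
    unique_lens = [
        [draw_len(cfg.other_len_median, cfg.other_len_sigma) for _ in range(k)]
        for k in unique_counts
    ]
    core_lens, block_lens, unique_lens = _fit_lengths_to_window(
        cfg, ids, blocks, core_lens, block_lens, unique_lens
    )
    block_len_iter = iter(block_lens)
    unique_len_iter = iter(unique_lens)

    families: list[dict] = []  # fam_id, members (genome ids), seqs, category
    categories: dict[str, str] = {}
    core_guide: dict[str, str] = {}

    # core families; the first n_recombinant_core evolve on the alt tree
    recomb = set(range(cfg.n_recombinant_core))
    for c in range(cfg.n_core):
        fam_id = f"famC{c + 1:02d}"
        length = core_lens[c]
        anc = ancestral(length)
        mult = float(np.clip(rng.lognormal(0.0, 0.25), 0.6, 1.6)) * cfg.rate_scale
        guide = alt_tree if c in recomb else true_tree
        seqs = _evolve(guide, anc, mult, rng)
        families.append({"fam": fam_id, "members": list(ids), "seqs": seqs})
        categories[fam_id] = "core"
        core_guide[fam_id] = "alt" if c in recomb else "true"

    # accessory blocks
    acc_idx = 0
    for (subset, n_fams), lens in zip(blocks, block_len_iter):
        member_ids = [ids[i] for i in subset]
        for length in lens:
            acc_idx += 1
            fam_id = f"famA{acc_idx:03d}"
            anc = ancestral(length)
            mult = float(np.clip(rng.lognormal(0.0, 0.25), 0.6, 1.6)) * cfg.rate_scale
            seqs = _evolve(true_tree, anc, mult, rng)
            families.append(
                {"fam": fam_id, "members": member_ids, "seqs": seqs}
            )
            categories[fam_id] = "accessory" if len(member_ids) > 1 else "unique"

    # unique genes
    unq_idx = 0
    unique_of: dict[str, list[tuple[str, str]]] = {g: [] for g in ids}
    for g, lens in zip(ids, unique_len_iter):
        for length in lens:
            unq_idx += 1
            fam_id = f"famU{unq_idx:03d}"
            unique_of[g].append((fam_id, ancestral(length)))
            categories[fam_id] = "unique"

    # shared synteny: one global rank per family; unique genes interleave
    fam_rank = {f["fam"]: rng.random() for f in families}
    fam_strand = {
        f["fam"]: "-" if rng.random() < cfg.minus_strand_fraction else "+"
        for f in families
    }

    genomes: list[SequenceRecord] = []
    genes: list[GeneFeature] = []
    membership: dict[str, str] = {}

    for g in ids:
        entries = []  # (rank, fam_id, protein, strand)
        for f in families:
            if g in f["members"]:
                entries.append((fam_rank[f["fam"]], f["fam"], f["seqs"][g], fam_strand[f["fam"]]))
        for fam_id, prot in unique_of[g]:
            strand = "-" if rng.random() < cfg.minus_strand_fraction else "+"
            entries.append((rng.random(), fam_id, prot, strand))
        entries.sort(key=lambda e: e[0])

        coding = sum(3 * (len(p) + 1) for _, _, p, _ in entries)
        n_gaps = len(entries) + 1
        lo = max(cfg.genome_window[0], coding + 5 * n_gaps)
        hi = min(cfg.genome_window[1], coding + 130 * n_gaps)
        if lo > hi:
            raise ValueError(
                f"{g}: {len(entries)} genes ({coding} nt coding) cannot fit the "
                f"genome-size window {cfg.genome_window}"
            )
        target_size = int(rng.uniform(lo, hi))
        spacer_total = target_size - coding
        spacer_lens = rng.multinomial(
            spacer_total - 5 * n_gaps, np.full(n_gaps, 1.0 / n_gaps)
        ) + 5

        target_gc = cfg.gc_low if hosts[g] == "low" else cfg.gc_high
        steer = _GCSteerer(target_gc)
        parts = []
        pos = 0
        for k, (_, fam_id, prot, strand) in enumerate(entries):
            spacer = steer.spacer(int(spacer_lens[k]), rng)
            parts.append(spacer)
            pos += len(spacer)
            cds = _back_translate(prot, steer)
            start = pos + 1
            end = pos + len(cds)
            parts.append(cds if strand == "+" else reverse_complement(cds))
            pos = end
            gene_id = f"{g}_{k + 1:03d}"
            genes.append(
                GeneFeature(
                    genome_id=g,
                    gene_id=gene_id,
                    start=start,
                    end=end,
                    strand=strand,
                    protein=prot,
                )
            )
            membership[gene_id] = fam_id
        parts.append(steer.spacer(int(spacer_lens[-1]), rng))
        genomes.append(
            SequenceRecord(
                id=g,
                residues="".join(parts),
                description=f"simulated phage genome cluster={labels[g]} host={hosts[g]}",
            )
        )

    truth = GroundTruth(
        membership=membership,
        categories=categories,
        tree_newick=_tree_to_newick(true_tree),
        alt_tree_newick=_tree_to_newick(alt_tree),
        core_guide=core_guide,
        cluster_of=labels,
        host_group_of=hosts,
    )
    return genomes, genes, truth


def write_simulation(
    out_dir: str,
    genomes: list[SequenceRecord],
    genes: list[GeneFeature],
    truth: GroundTruth,
) -> None:
    """Write a simulation bundle: genomes.fna, proteins.faa, genes.tsv,
    truth.json."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    write_fasta(genomes, os.path.join(out_dir, "genomes.fna"))
    write_fasta(
        [SequenceRecord(id=f.gene_id, residues=f.protein) for f in genes],
        os.path.join(out_dir, "proteins.faa"),
    )
    with open(os.path.join(out_dir, "genes.tsv"), "w") as fh:
        fh.write("genome_id\tgene_id\tstart\tend\tstrand\n")
        for f in genes:
            fh.write(f"{f.genome_id}\t{f.gene_id}\t{f.start}\t{f.end}\t{f.strand}\n")
    with open(os.path.join(out_dir, "truth.json"), "w") as fh:
        fh.write(truth.to_json())
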