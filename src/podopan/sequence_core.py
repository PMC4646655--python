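"""Minimal gene calling, translation (genetic code table 11) and the
compositional statistics used to summarise phage genome collections.

The open-reading-frame caller is a deterministic surrogate for trained gene
finders: it scans all six frames, and within every stop-to-stop region
reports the longest ORF that begins at an allowed start codon.  That is
enough to give realistic gene complements on ~45 kb phage genomes, which is
what the downstream clustering machinery needs; it is not a competitive gene
predictor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats

from .io_formats import SequenceRecord

__all__ = [
    "GeneFeature",
    "GroupGCSummary",
    "gc_content",
    "translate",
    "find_orfs",
    "reverse_complement",
    "group_gc_summary",
    "welch_t_test",
    "START_CODONS",
    "STOP_CODONS",
]

START_CODONS = frozenset({"ATG", "GTG", "TTG"})
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

# NCBI translation table 11 (bacterial/plastid); stop rendered as "*".
_CODON_TABLE = {}
_BASES = "TCAG"
_AA = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
for _i, _b1 in enumerate(_BASES):
    for _j, _b2 in enumerate(_BASES):
        for _k, _b3 in enumerate(_BASES):
            _CODON_TABLE[_b1 + _b2 + _b3] = _AA[16 * _i + 4 * _j + _k]

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

_NUCLEOTIDES = frozenset("ACGT")
_AMBIGUITY = frozenset("RYSWKMBDHVN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def gc_content(residues: str) -> float:
    """Fraction (G + C) / (A + C + G + T); ambiguity codes are excluded from
    both numerator and denominator.  Empty input or zero unambiguous bases is
    an error."""
    if not residues:
        raise ValueError("empty sequence")
    seq = residues.upper()
    bad = set(seq) - _NUCLEOTIDES - _AMBIGUITY
    if bad:
        raise ValueError(f"non-nucleotide characters: {sorted(bad)}")
    gc = seq.count("G") + seq.count("C")
    total = gc + seq.count("A") + seq.count("T")
    if total == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return gc / total


def translate(codons: str, initiator: bool = False, strict: bool = False) -> str:
    """Translate a nucleotide string under table 11.

    A trailing stop codon is dropped.  With ``initiator`` set, a first codon
    in the allowed start set renders M regardless of its ordinary meaning
    (e.g. GTG -> M).  With ``strict`` set an internal stop raises an error.
    """
    seq = codons.upper()
    if len(seq) % 3 != 0:
        raise ValueError(f"sequence length {len(seq)} not divisible by 3")
    aas = []
    n_codons = len(seq) // 3
    for i in range(n_codons):
        codon = seq[3 * i : 3 * i + 3]
        try:
            aa = _CODON_TABLE[codon]
        except KeyError:
            raise ValueError(f"unrecognised codon {codon!r} at position {3 * i + 1}")
        if aa == "*":
            if i == n_codons - 1:
                break  # trailing stop dropped
            if strict:
                raise ValueError(f"internal stop codon at position {3 * i + 1}")
        aas.append(aa)
    if initiator and aas and seq[:3] in START_CODONS:
        aas[0] = "M"
    return "".join(aas)


@dataclass
class GeneFeature:
    """A protein-coding gene on a genome.  ``start``/``end`` are 1-based
    inclusive forward-strand nucleotide positions; for strand ``-`` the coding
    sequence is the reverse complement of that span."""

    genome_id: str
    gene_id: str
    start: int
    end: int
    strand: str
    protein: str

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"bad strand {self.strand!r}")
        if self.start < 1 or self.start > self.end:
            raise ValueError(f"bad coordinates {self.start}..{self.end}")
        if (self.end - self.start + 1) % 3 != 0:
            raise ValueError("gene span not divisible by 3")

    @property
    def length_nt(self) -> int:
        return self.end - self.start + 1


def find_orfs(
    genome: SequenceRecord,
    min_codons: int = 30,
    start_codons: frozenset[str] = START_CODONS,
) -> list[GeneFeature]:
    """Six-frame ORF scan of a linear genome.

    For each stop-to-stop region in each frame, report the longest ORF that
    begins at an allowed start codon and ends at a stop, provided it spans at
    least ``min_codons`` codons (stop included).  Reverse-strand ORFs are
    reported with forward-strand coordinates and strand ``-``.  Proteins are
    translated with table 11, initiator rendered M.
    """
    if min_codons < 2:
        raise ValueError("min_codons must be >= 2")
    seq = genome.residues.upper()
    bad = set(seq) - _NUCLEOTIDES
    if bad:
        raise ValueError(f"non-nucleotide characters in {genome.id!r}: {sorted(bad)}")
    n = len(seq)
    orfs: list[GeneFeature] = []

    def scan(strand_seq: str, strand: str) -> None:
        for frame in range(3):
            region_start = frame  # 0-based codon-aligned start of current region
            i = frame
            while i + 3 <= len(strand_seq):
                codon = strand_seq[i : i + 3]
                if codon in STOP_CODONS:
                    _emit(strand_seq, strand, region_start, i + 3)
                    region_start = i + 3
                i += 3
            # trailing stop-less region yields no ORF (no terminating stop)

    def _emit(strand_seq: str, strand: str, lo: int, hi: int) -> None:
        # region [lo, hi) ends with a stop codon at hi-3; find first start
        for j in range(lo, hi - 3, 3):
            if strand_seq[j : j + 3] in start_codons:
                if (hi - j) // 3 >= min_codons:
                    _record(strand_seq, strand, j, hi)
                return

    def _record(strand_seq: str, strand: str, j: int, hi: int) -> None:
        cds = strand_seq[j:hi]
        protein = translate(cds, initiator=True)
        if strand == "+":
            start, end = j + 1, hi
        else:
            start, end = n - hi + 1, n - j
        orfs.append(
            GeneFeature(
                genome_id=genome.id,
                gene_id=f"{genome.id}_orf{len(orfs) + 1:04d}",
                start=start,
                end=end,
                strand=strand,
                protein=protein,
            )
        )

    scan(seq, "+")
    scan(reverse_complement(seq), "-")
    orfs.sort(key=lambda f: (f.start, f.end, f.strand))
    for idx, f in enumerate(orfs, start=1):
        f.gene_id = f"{genome.id}_orf{idx:04d}"
    return orfs


@dataclass
class GroupGCSummary:
    """Per-group %G+C summary: sample statistics over genomes in the group."""

    group: str
    n: int
    mean_gc: float
    sd_gc: float
    min_gc: float
    max_gc: float


def group_gc_summary(
    values_or_genomes,
    groups: dict[str, str],
) -> list[GroupGCSummary]:
    """Summarise percent G+C by group.

    ``values_or_genomes`` is either a mapping ``genome_id -> percent G+C``
    (printed-table input) or a list of :class:`SequenceRecord` whose G+C is
    computed from sequence.  Every genome must be assigned a group.  The
    standard deviation uses the n-1 (sample) denominator; values are kept at
    full precision and rounded only at reporting time.
    """
    if isinstance(values_or_genomes, dict):
        values = dict(values_or_genomes)
    else:
        values = {g.id: 100.0 * gc_content(g.residues) for g in values_or_genomes}
    missing = sorted(set(values) - set(groups))
    if missing:
        raise ValueError(f"genomes not assigned to any group: {missing}")
    by_group: dict[str, list[float]] = {}
    for gid, val in values.items():
        by_group.setdefault(groups[gid], []).append(val)
    out = []
    for label in sorted(by_group):
        vals = np.asarray(by_group[label], dtype=float)
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        out.append(
            GroupGCSummary(
                group=label,
                n=int(vals.size),
                mean_gc=float(vals.mean()),
                sd_gc=sd,
                min_gc=float(vals.min()),
                max_gc=float(vals.max()),
            )
        )
    return out


def welch_t_test(x, y) -> tuple[float, float, float]:
    """Welch's unequal-variance two-sample t-test.

    Returns ``(t, df, two_sided_p)`` with Welch-Satterthwaite degrees of
    freedom.  Both groups need n >= 2; if both groups are constant and equal
    the test is degenerate and ``(0, df, 1)`` is returned.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least two observations")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            return 0.0, float(x.size + y.size - 2), 1.0
        raise ValueError("zero variance in both groups with unequal means")
    se2 = vx / x.size + vy / y.size
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2**2 / (
        (vx / x.size) ** 2 / (x.size - 1) + (vy / y.size) ** 2 / (y.size - 1)
    )
    p = 2.0 * _stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)
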