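"""All-vs-all protein similarity search.

Two engines sit behind one interface:

* ``engine="blast"`` (default) shells out to NCBI BLAST+ (``makeblastdb`` /
  ``blastp``) with BLOSUM62, gap open 11 / extend 1, word size 3, no
  low-complexity filtering and no composition-based statistics — the classic
  proteome-vs-proteome configuration for small phage gene sets.
* ``engine="exact"`` computes exact optimal Smith-Waterman-Gotoh local
  alignments in-process and derives bit scores and e-values from fixed
  gapped Karlin-Altschul constants (lambda = 0.267, K = 0.041) with the
  pairwise search space m*n.  No database-wide effective-length correction
  is applied, so exact agreement with BLAST e-values is not promised; the
  downstream orthology thresholds are robust to the difference.
"""

from __future__ import annotations

import math
import os
import shutil
import subprocess
import tempfile
from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices

from . import _kernels
from .io_formats import PairwiseHit, SequenceRecord, write_fasta

__all__ = [
    "ScoringParams",
    "AlignmentResult",
    "align_local",
    "bit_score",
    "evalue",
    "all_vs_all",
]

_PROTEIN_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"


@dataclass(frozen=True)
class ScoringParams:
    """Scoring scheme for local protein alignment and e-value calibration.

    ``lam`` and ``k`` are the gapped Karlin-Altschul constants for
    BLOSUM62(11,1).
    """

    matrix: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = 0.267
    k: float = 0.041

    def __post_init__(self) -> None:
        if not (self.gap_open >= self.gap_extend >= 0):
            raise ValueError("require gap_open >= gap_extend >= 0")
        if self.lam <= 0 or self.k <= 0:
            raise ValueError("Karlin-Altschul constants must be positive")


_MATRIX_CACHE: dict[str, np.ndarray] = {}
_CODE = {aa: i for i, aa in enumerate(_PROTEIN_ALPHABET)}


def _matrix(name: str) -> np.ndarray:
    if name not in _MATRIX_CACHE:
        m = substitution_matrices.load(name)
        size = len(_PROTEIN_ALPHABET)
        arr = np.zeros((size, size), np.int32)
        for i, a in enumerate(_PROTEIN_ALPHABET):
            for j, b in enumerate(_PROTEIN_ALPHABET):
                arr[i, j] = int(m[a][b])
        _MATRIX_CACHE[name] = arr
    return _MATRIX_CACHE[name]


def encode_protein(seq: str) -> np.ndarray:
    try:
        return np.array([_CODE[c] for c in seq.upper()], dtype=np.uint8)
    except KeyError:
        bad = sorted(set(seq.upper()) - set(_PROTEIN_ALPHABET))
        raise ValueError(f"residues outside the substitution-matrix alphabet: {bad}")


@dataclass
class AlignmentResult:
    """Best local alignment of an ordered sequence pair.  Spans are 1-based
    inclusive; ``alignment_length`` counts columns, gaps included."""

    raw_score: int
    bit_score: float
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    e_value: float


def bit_score(raw_score: float, params: ScoringParams | None = None) -> float:
    """Normalized score: (lambda * S - ln K) / ln 2."""
    params = params or ScoringParams()
    return (params.lam * raw_score - math.log(params.k)) / math.log(2.0)


def evalue(bits: float, m: int, n: int) -> float:
    """Expected hit count in a search space of m*n: E = m*n / 2**bits."""
    if m <= 0 or n <= 0:
        raise ValueError("sequence lengths must be positive")
    return m * n * math.pow(2.0, -bits)


def align_local(
    a: str,
    b: str,
    params: ScoringParams | None = None,
) -> AlignmentResult | None:
    """Exact optimal local alignment of two proteins under affine gaps.

    Returns ``None`` when the optimal local score is 0 (no positive-scoring
    segment pair).  Empty sequences and residues outside the matrix alphabet
    raise ``ValueError``.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    params = params or ScoringParams()
    S = _matrix(params.matrix)
    ea, eb = encode_protein(a), encode_protein(b)
    score, bi, bj, H, E, F, ptr = _kernels.gotoh_local(
        ea, eb, S, params.gap_open, params.gap_extend
    )
    if score <= 0:
        return None
    # traceback from (bi, bj)
    i, j = bi, bj
    matches = mismatches = gap_opens = length = 0
    prev = 0  # 1 diag, 2 up, 3 left
    while i > 0 and j > 0 and H[i][j] > 0:
        p = ptr[i][j]
        if p == 0:
            break
        length += 1
        if p == 1:
            if ea[i - 1] == eb[j - 1]:
                matches += 1
            else:
                mismatches += 1
            i -= 1
            j -= 1
        elif p == 2:
            # gap in b; walk the whole gap run using the F recurrence
            run = 1
            first = params.gap_open + params.gap_extend
            while (
                i - run > 0
                and F[i][j] != H[i - run][j] - first - params.gap_extend * (run - 1)
            ):
                run += 1
            length += run - 1
            i -= run
            gap_opens += 1
        else:
            run = 1
            first = params.gap_open + params.gap_extend
            while (
                j - run > 0
                and E[i][j] != H[i][j - run] - first - params.gap_extend * (run - 1)
            ):
                run += 1
            length += run - 1
            j -= run
            gap_opens += 1
    q_start, s_start = i + 1, j + 1
    bits = bit_score(score, params)
    return AlignmentResult(
        raw_score=int(score),
        bit_score=bits,
        percent_identity=100.0 * matches / length if length else 0.0,
        alignment_length=length,
        mismatches=mismatches,
        gap_opens=gap_opens,
        q_start=q_start,
        q_end=bi,
        s_start=s_start,
        s_end=bj,
        e_value=evalue(bits, len(a), len(b)),
    )


def _hit_from_alignment(qid: str, sid: str, aln: AlignmentResult) -> PairwiseHit:
    return PairwiseHit(
        query_id=qid,
        subject_id=sid,
        percent_identity=aln.percent_identity,
        alignment_length=aln.alignment_length,
        mismatches=aln.mismatches,
        gap_opens=aln.gap_opens,
        q_start=aln.q_start,
        q_end=aln.q_end,
        s_start=aln.s_start,
        s_end=aln.s_end,
        e_value=aln.e_value,
        bit_score=aln.bit_score,
    )


def _mirror(hit: PairwiseHit) -> PairwiseHit:
    return PairwiseHit(
        query_id=hit.subject_id,
        subject_id=hit.query_id,
        percent_identity=hit.percent_identity,
        alignment_length=hit.alignment_length,
        mismatches=hit.mismatches,
        gap_opens=hit.gap_opens,
        q_start=hit.s_start,
        q_end=hit.s_end,
        s_start=hit.q_start,
        s_end=hit.q_end,
        e_value=hit.e_value,
        bit_score=hit.bit_score,
    )


def all_vs_all(
    proteins: list[tuple[str, str, str]],
    params: ScoringParams | None = None,
    engine: str = "blast",
    evalue_cutoff: float | None = 1e-3,
    threads: int = 1,
) -> list[PairwiseHit]:
    """All-vs-all similarity search over ``(genome_id, gene_id, sequence)``
    triples.  Self-hits are excluded; output order is deterministic
    (query id, then subject id, then e-value).

    With ``engine="exact"`` every ordered pair is aligned optimally and pairs
    whose best local alignment scores above 0 (and passes ``evalue_cutoff``
    if one is given) are reported.  With ``engine="blast"`` the pre-installed
    BLAST+ binaries perform the search at the same scoring parameters and
    ``evalue_cutoff`` (required; defaults to the classic 1e-3 search cutoff).
    """
    gene_ids = [g for _, g, _ in proteins]
    if len(set(gene_ids)) != len(gene_ids):
        dupes = sorted({g for g in gene_ids if gene_ids.count(g) > 1})
        raise ValueError(f"duplicate gene id(s): {dupes}")
    params = params or ScoringParams()
    if engine == "exact":
        hits = _all_vs_all_exact(proteins, params, evalue_cutoff)
    elif engine == "blast":
        if evalue_cutoff is None:
            raise ValueError("the blast engine requires an e-value cutoff")
        hits = _all_vs_all_blast(proteins, params, evalue_cutoff, threads)
    else:
        raise ValueError(f"unknown engine {engine!r}")
    hits.sort(key=lambda h: (h.query_id, h.subject_id, h.e_value, -h.bit_score))
    return hits


def _all_vs_all_exact(
    proteins: list[tuple[str, str, str]],
    params: ScoringParams,
    evalue_cutoff: float | None,
) -> list[PairwiseHit]:
    hits: list[PairwiseHit] = []
    for i in range(len(proteins)):
        _, gi, si = proteins[i]
        for j in range(i + 1, len(proteins)):
            _, gj, sj = proteins[j]
            aln = align_local(si, sj, params)
            if aln is None:
                continue
            if evalue_cutoff is not None and aln.e_value > evalue_cutoff:
                continue
            hit = _hit_from_alignment(gi, gj, aln)
            hits.append(hit)
            hits.append(_mirror(hit))
    return hits


def _all_vs_all_blast(
    proteins: list[tuple[str, str, str]],
    params: ScoringParams,
    evalue_cutoff: float,
    threads: int,
) -> list[PairwiseHit]:
    for tool in ("makeblastdb", "blastp"):
        if shutil.which(tool) is None:
            raise RuntimeError(
                f"{tool} not found on PATH; use engine='exact' instead"
            )
    with tempfile.TemporaryDirectory(prefix="podopan_blast_") as tmp:
        faa = os.path.join(tmp, "proteins.faa")
        write_fasta(
            [SequenceRecord(id=g, residues=s) for _, g, s in proteins], faa
        )
        db = os.path.join(tmp, "db")
        subprocess.run(
            ["makeblastdb", "-in", faa, "-dbtype", "prot", "-out", db],
            check=True,
            capture_output=True,
        )
        out = os.path.join(tmp, "hits.tsv")
        subprocess.run(
            [
                "blastp",
                "-query", faa,
                "-db", db,
                "-out", out,
                "-outfmt", "6",
                "-evalue", str(evalue_cutoff),
                "-word_size", "3",
                "-matrix", params.matrix,
                "-gapopen", str(params.gap_open),
                "-gapextend", str(params.gap_extend),
                "-seg", "no",
                "-comp_based_stats", "0",
                "-max_target_seqs", str(max(500, 2 * len(proteins))),
                "-num_threads", str(max(1, threads)),
            ],
            check=True,
            capture_output=True,
        )
        from .io_formats import parse_hits_table

        hits = parse_hits_table(out)
    return [h for h in hits if h.query_id != h.subject_id]
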