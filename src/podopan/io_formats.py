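"""Readers and writers for the external representations used across the pipeline.

Sequences travel as FASTA, pairwise similarity hits as the classic 12-column
tab-separated table, trees as Newick (supports stored as internal-node labels,
``label:length`` order), and matrices as TSV with row/column labels.  All readers
validate rather than coerce: malformed input raises :class:`FormatError` with a
file position where one exists.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass

import dendropy
import pandas as pd

__all__ = [
    "FormatError",
    "SequenceRecord",
    "PairwiseHit",
    "read_fasta",
    "write_fasta",
    "parse_hits_table",
    "write_hits_table",
    "parse_newick",
    "write_newick",
    "read_matrix_tsv",
    "write_matrix_tsv",
]


class FormatError(ValueError):
    """Malformed external input (bad FASTA, hit table, Newick or matrix)."""


@dataclass
class SequenceRecord:
    """A named sequence: ``id`` is the token up to the first whitespace of the
    FASTA header, ``description`` the remainder, ``residues`` the uppercased
    sequence with line wrapping removed."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        if not self.residues:
            raise FormatError(f"sequence record {self.id!r} has empty sequence")
        self.residues = self.residues.upper()

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class PairwiseHit:
    """One row of a 12-column similarity-search table.

    Coordinates are 1-based inclusive, as in the tabular dialect itself;
    ``alignment_length`` counts alignment columns, gaps included.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    e_value: float
    bit_score: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.percent_identity <= 100.0):
            raise FormatError(
                f"hit {self.query_id}->{self.subject_id}: percent identity "
                f"{self.percent_identity} outside [0, 100]"
            )
        if self.alignment_length < 1:
            raise FormatError(
                f"hit {self.query_id}->{self.subject_id}: alignment length < 1"
            )
        if self.q_start > self.q_end or self.s_start > self.s_end:
            raise FormatError(
                f"hit {self.query_id}->{self.subject_id}: reversed coordinates"
            )
        if self.e_value < 0:
            raise FormatError(
                f"hit {self.query_id}->{self.subject_id}: negative e-value"
            )

    def as_row(self) -> str:
        return "\t".join(
            [
                self.query_id,
                self.subject_id,
                f"{self.percent_identity:.2f}",
                str(self.alignment_length),
                str(self.mismatches),
                str(self.gap_opens),
                str(self.q_start),
                str(self.q_end),
                str(self.s_start),
                str(self.s_end),
                f"{self.e_value:.3g}",
                f"{self.bit_score:.1f}",
            ]
        )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | os.PathLike) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    The id is the header token up to the first whitespace; wrapped sequence
    lines are concatenated and uppercased.  An empty file yields an empty
    list.  Duplicate ids, empty sequences and non-FASTA leading content raise
    :class:`FormatError`.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    header: str | None = None
    chunks: list[str] = []
    header_line = 0

    def flush() -> None:
        if header is None:
            return
        tokens = header.split(None, 1)
        if not tokens:
            raise FormatError(f"{path}:{header_line}: empty FASTA header")
        rid = tokens[0]
        desc = tokens[1] if len(tokens) > 1 else ""
        if rid in seen:
            raise FormatError(f"{path}:{header_line}: duplicate sequence id {rid!r}")
        seen.add(rid)
        residues = "".join(chunks)
        if not residues:
            raise FormatError(f"{path}:{header_line}: record {rid!r} has no sequence")
        records.append(SequenceRecord(id=rid, residues=residues, description=desc))

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise FormatError(
                        f"{path}:{lineno}: expected '>' as first non-blank character"
                    )
                chunks.append(line)
    flush()
    return records


def write_fasta(records: list[SequenceRecord], path: str | os.PathLike, width: int = 70) -> None:
    """Write records as FASTA, wrapping sequence lines at ``width`` columns."""
    with open(path, "w") as fh:
        for rec in records:
            head = f">{rec.id} {rec.description}".rstrip()
            fh.write(head + "\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# 12-column hit tables

_HIT_COLUMNS = 12


def parse_hits_table(path: str | os.PathLike) -> list[PairwiseHit]:
    """Parse a 12-column tab-separated similarity hit table.

    Scientific-notation e-values are accepted.  A wrong column count or an
    unparsable numeric field raises :class:`FormatError` naming the line.
    """
    path = os.fspath(path)
    hits: list[PairwiseHit] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != _HIT_COLUMNS:
                raise FormatError(
                    f"{path}:{lineno}: expected {_HIT_COLUMNS} tab-separated "
                    f"columns, found {len(fields)}"
                )
            try:
                hit = PairwiseHit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    percent_identity=float(fields[2]),
                    alignment_length=int(fields[3]),
                    mismatches=int(fields[4]),
                    gap_opens=int(fields[5]),
                    q_start=int(fields[6]),
                    q_end=int(fields[7]),
                    s_start=int(fields[8]),
                    s_end=int(fields[9]),
                    e_value=float(fields[10]),
                    bit_score=float(fields[11]),
                )
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: unparsable field ({exc})") from None
            hits.append(hit)
    return hits


def write_hits_table(hits: list[PairwiseHit], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for hit in hits:
            fh.write(hit.as_row() + "\n")


# ---------------------------------------------------------------------------
# Newick trees (dendropy-backed)


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string into a dendropy tree.

    Internal-node labels in [0, 100] are interpreted as bipartition supports
    (bootstrap or consensus frequencies).  Unbalanced parentheses and
    duplicate leaf labels raise :class:`FormatError`.
    """
    if text.count("(") != text.count(")"):
        raise FormatError("unbalanced parentheses in Newick string")
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parser error types
        raise FormatError(f"Newick parse error: {exc}") from None
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise FormatError(f"duplicate leaf label(s): {sorted(dupes)}")
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.label is None:
            continue
        try:
            support = float(node.label)
        except ValueError:
            continue
        if 0.0 <= support <= 100.0:
            node.support = support  # type: ignore[attr-defined]
    return tree


def write_newick(tree: dendropy.Tree, precision: int = 6) -> str:
    """Serialize a tree to Newick, emitting supports as internal-node labels."""
    for node in tree.preorder_node_iter():
        support = getattr(node, "support", None)
        if support is not None and not node.is_leaf():
            node.label = format_float(support, precision)
        if node.edge.length is not None:
            node.edge.length = float(format_float(node.edge.length, precision))
    text = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    ).strip()
    return text


def format_float(x: float, sig: int = 6) -> str:
    """Format to ``sig`` significant digits without exponent clutter for 0."""
    if x == 0:
        return "0"
    if float(x).is_integer() and abs(x) < 10 ** sig:
        return str(int(x))
    return f"{x:.{sig}g}"


# ---------------------------------------------------------------------------
# Labelled matrices


def write_matrix_tsv(matrix, row_labels, col_labels, path: str | os.PathLike) -> None:
    """Write a labelled matrix as TSV (first column = row labels)."""
    if len(set(row_labels)) != len(list(row_labels)):
        raise FormatError("duplicate row labels")
    if len(set(col_labels)) != len(list(col_labels)):
        raise FormatError("duplicate column labels")
    df = pd.DataFrame(matrix, index=list(row_labels), columns=list(col_labels))
    df.to_csv(path, sep="\t", index_label="")


def read_matrix_tsv(path: str | os.PathLike):
    """Read a labelled TSV matrix; returns ``(ndarray, row_labels, col_labels)``.

    Ragged rows and duplicated labels raise :class:`FormatError`.
    """
    path = os.fspath(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty matrix file")
    ncol = len(lines[0].split("\t"))
    for lineno, ln in enumerate(lines, start=1):
        if len(ln.split("\t")) != ncol:
            raise FormatError(f"{path}:{lineno}: ragged row")
    df = pd.read_csv(io.StringIO("\n".join(lines)), sep="\t", index_col=0)
    if df.index.has_duplicates:
        dupes = sorted(set(df.index[df.index.duplicated()]))
        raise FormatError(f"{path}: duplicated row label(s) {dupes}")
    if df.columns.has_duplicates:
        raise FormatError(f"{path}: duplicated column label(s)")
    return df.to_numpy(), [str(i) for i in df.index], [str(c) for c in df.columns]
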