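"""Pan/core-genome analysis: COG category classification, rarefaction
(accumulation) curves over genome sampling orders, per-genome gene-category
fractions, pairwise shared-gene fractions and the shared-fraction vs
core-identity regression.

Categories follow the usual pan-genome convention for N genomes: *core* =
present in all N, *unique* = present in exactly one, *accessory* =
everything in between.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .orthology import COG
from .sequence_core import GeneFeature

__all__ = [
    "classify_cogs",
    "presence_absence",
    "AccumulationCurve",
    "accumulation_curves",
    "GenomeFractions",
    "genome_fractions",
    "pairwise_shared_fraction",
    "RegressionResult",
    "linear_regression",
]


def classify_cogs(cogs: list[COG], n_genomes: int) -> list[COG]:
    """Assign core / accessory / unique categories in place and return the list."""
    for cog in cogs:
        gc = cog.genome_count
        if gc > n_genomes:
            raise ValueError(
                f"{cog.cog_id}: genome_count {gc} exceeds n_genomes {n_genomes}"
            )
        if gc == n_genomes:
            cog.category = "core"
        elif gc == 1:
            cog.category = "unique"
        else:
            cog.category = "accessory"
    return cogs


def presence_absence(cogs: list[COG], genomes: list[str]) -> pd.DataFrame:
    """Binary genomes x COGs matrix (DataFrame; rows = genome labels)."""
    mat = pd.DataFrame(
        0, index=list(genomes), columns=[c.cog_id for c in cogs], dtype=int
    )
    for cog in cogs:
        for genome_id, _ in cog.members:
            if genome_id not in mat.index:
                raise ValueError(f"{cog.cog_id} references unknown genome {genome_id!r}")
            mat.loc[genome_id, cog.cog_id] = 1
    return mat


@dataclass
class AccumulationCurve:
    """Pan- and core-genome size distributions vs number of genomes sampled.

    Arrays are indexed by k-1 for k = 1..N.  ``lo``/``hi`` are 2.5/97.5
    percentile bounds across sampling-order permutations.
    """

    k: np.ndarray
    pan_mean: np.ndarray
    pan_lo: np.ndarray
    pan_hi: np.ndarray
    core_mean: np.ndarray
    core_lo: np.ndarray
    core_hi: np.ndarray
    n_permutations: int
    seed: int | None

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": self.k,
                "pan_mean": self.pan_mean,
                "pan_lo": self.pan_lo,
                "pan_hi": self.pan_hi,
                "core_mean": self.core_mean,
                "core_lo": self.core_lo,
                "core_hi": self.core_hi,
            }
        )


def accumulation_curves(
    matrix: pd.DataFrame,
    n_permutations: int = 1000,
    seed: int | None = None,
    exhaustive: bool = False,
) -> AccumulationCurve:
    """Rarefaction of pan- and core-genome sizes over genome sampling orders.

    For each random permutation of the genome order, the pan size at prefix
    length k is the number of COGs present in at least one of the first k
    genomes and the core size the number present in all of them.  With
    ``exhaustive=True`` all N! orders are enumerated instead (small N only).
    """
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise ValueError("empty presence/absence matrix")
    M = matrix.to_numpy(dtype=bool)
    n = M.shape[0]
    if exhaustive:
        from itertools import permutations

        orders = np.array(list(permutations(range(n))), dtype=int)
    else:
        if n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        rng = np.random.default_rng(seed)
        orders = np.array([rng.permutation(n) for _ in range(n_permutations)])
    pan = np.empty((len(orders), n), dtype=np.int64)
    core = np.empty((len(orders), n), dtype=np.int64)
    for r, order in enumerate(orders):
        rows = M[order]
        pan[r] = np.logical_or.accumulate(rows, axis=0).sum(axis=1)
        core[r] = np.logical_and.accumulate(rows, axis=0).sum(axis=1)
    return AccumulationCurve(
        k=np.arange(1, n + 1),
        pan_mean=pan.mean(axis=0),
        pan_lo=np.percentile(pan, 2.5, axis=0),
        pan_hi=np.percentile(pan, 97.5, axis=0),
        core_mean=core.mean(axis=0),
        core_lo=np.percentile(core, 2.5, axis=0),
        core_hi=np.percentile(core, 97.5, axis=0),
        n_permutations=len(orders),
        seed=seed,
    )


@dataclass
class GenomeFractions:
    """Per-genome core/accessory/unique fractions by gene count, plus the
    fraction of the genome length occupied by core genes."""

    table: pd.DataFrame  # index: genome; columns: core, accessory, unique, core_length

    def mean_count_fractions(self) -> tuple[float, float, float]:
        m = self.table[["core", "accessory", "unique"]].mean()
        return float(m["core"]), float(m["accessory"]), float(m["unique"])


def genome_fractions(
    cogs: list[COG],
    genes: list[GeneFeature],
    genome_lengths: dict[str, int],
) -> GenomeFractions:
    """Per-genome category fractions.

    Count fractions use the number of genes per category over the genome's
    gene total; the length fraction sums core-gene nucleotide spans over the
    genome length.  Every gene must belong to a classified COG.
    """
    category_of_gene: dict[str, str] = {}
    for cog in cogs:
        if cog.category is None:
            raise ValueError(f"{cog.cog_id} has no category; run classify_cogs first")
        for _, gene_id in cog.members:
            category_of_gene[gene_id] = cog.category
    rows = {}
    for gene in genes:
        if gene.gene_id not in category_of_gene:
            raise ValueError(f"gene {gene.gene_id!r} not assigned to any COG")
        rec = rows.setdefault(
            gene.genome_id, {"core": 0, "accessory": 0, "unique": 0, "core_nt": 0}
        )
        rec[category_of_gene[gene.gene_id]] += 1
        if category_of_gene[gene.gene_id] == "core":
            rec["core_nt"] += gene.length_nt
    out = {}
    for genome_id, rec in rows.items():
        total = rec["core"] + rec["accessory"] + rec["unique"]
        out[genome_id] = {
            "core": rec["core"] / total,
            "accessory": rec["accessory"] / total,
            "unique": rec["unique"] / total,
            "core_length": rec["core_nt"] / genome_lengths[genome_id],
        }
    table = pd.DataFrame.from_dict(out, orient="index").sort_index()
    return GenomeFractions(table=table)


def pairwise_shared_fraction(
    matrix: pd.DataFrame, denominator: str = "mean"
) -> pd.DataFrame:
    """Fraction of gene families shared between every genome pair.

    ``denominator="mean"`` divides the intersection size by the mean of the
    two genomes' family counts (symmetric, bounded by 1); ``"union"`` gives
    the Jaccard index instead.  Diagonal is 1.
    """
    if matrix.shape[0] < 2:
        raise ValueError("need at least two genomes")
    M = matrix.to_numpy(dtype=bool)
    inter = (M[:, None, :] & M[None, :, :]).sum(axis=2).astype(float)
    sizes = M.sum(axis=1).astype(float)
    if denominator == "mean":
        denom = (sizes[:, None] + sizes[None, :]) / 2.0
    elif denominator == "union":
        denom = (M[:, None, :] | M[None, :, :]).sum(axis=2).astype(float)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    frac = inter / denom
    np.fill_diagonal(frac, 1.0)
    return pd.DataFrame(frac, index=matrix.index, columns=matrix.index)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n: int


def linear_regression(x, y) -> RegressionResult:
    """Ordinary least squares of y on x; r^2 is the squared Pearson r."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.all(x == x[0]):
        raise ValueError("x is constant")
    res = _stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n=int(x.size),
    )
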