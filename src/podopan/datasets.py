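"""Packaged reference data.

The published summary table of the 20 marine cyanopodovirus genomes
(phage name, GenBank accession, MPP cluster, host genus and clade, genome
size, ORF count, %G+C) ships with the package so the compositional
statistics can be reproduced without network access.  Genome *sequences* are
not packaged; they are fetched by accession or simulated.
"""

from __future__ import annotations

import importlib.resources

import pandas as pd

__all__ = ["load_genome_table"]


def load_genome_table() -> pd.DataFrame:
    """Return the published 20-genome summary table as a DataFrame.

    Columns: ``phage``, ``accession``, ``cluster`` (MPP-A / MPP-B / outlier),
    ``host`` (Prochlorococcus / Synechococcus), ``host_clade``,
    ``genome_size_bp``, ``n_orfs``, ``gc_percent``.
    """
    ref = importlib.resources.files("podopan.data").joinpath(
        "cyanopodovirus_genomes.tsv"
    )
    with ref.open() as fh:
        return pd.read_csv(fh, sep="\t")
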