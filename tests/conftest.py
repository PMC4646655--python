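import numpy as np
import pandas as pd
import pytest

from podopan.orthology import COG
from podopan.pangenome import classify_cogs
from podopan.phylo import _Node, _to_dendropy
from podopan.simulate import simulate_genome_set


@pytest.fixture(scope="session")
def default_sim():
    """One default 20-genome simulation shared across the suite."""
    return simulate_genome_set(seed=1)


@pytest.fixture(scope="session")
def truth_cogs(default_sim):
    """COGs built from the planted ground-truth partition, classified."""
    genomes, genes, truth = default_sim
    gen_of = {g.gene_id: g.genome_id for g in genes}
    fams = {}
    for gid, fam in truth.membership.items():
        fams.setdefault(fam, set()).add((gen_of[gid], gid))
    cogs = [COG(cog_id=f, members=frozenset(m)) for f, m in sorted(fams.items())]
    classify_cogs(cogs, len(genomes))
    return cogs


def random_binary_tree(rng, labels, min_len=0.5, max_len=2.0):
    """Random binary tree over the given leaf labels with positive branch
    lengths, built by sequential random attachment."""
    nodes = [_Node(label=l) for l in labels]
    lengths = [float(rng.uniform(min_len, max_len)) for _ in labels]
    items = list(zip(nodes, lengths))
    rng.shuffle(items)
    while len(items) > 3:
        i, j = sorted(rng.choice(len(items), size=2, replace=False))
        (na, la), (nb, lb) = items[i], items[j]
        parent = _Node(children=[na, nb], lengths=[la, lb],
                       minleaf=min(na.minleaf, nb.minleaf))
        rest = [items[k] for k in range(len(items)) if k not in (i, j)]
        items = rest + [(parent, float(rng.uniform(min_len, max_len)))]
    root = _Node(
        children=[n for n, _ in items],
        lengths=[l for _, l in items],
        minleaf=min(n.minleaf for n, _ in items),
    )
    return _to_dendropy(root, rooted=False)


def patristic_matrix(tree):
    """Leaf-to-leaf path-length matrix of a dendropy tree as a DataFrame."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    D = pd.DataFrame(0.0, index=labels, columns=labels)
    for i, ti in enumerate(taxa):
        for tj in taxa[i + 1 :]:
            d = pdm.patristic_distance(ti, tj)
            D.loc[ti.label, tj.label] = D.loc[tj.label, ti.label] = d
    return D
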