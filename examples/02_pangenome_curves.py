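"""Pan/core-genome rarefaction and per-genome gene-category fractions.

Prints the expected pan- and core-genome sizes as genomes are sampled in
random orders (with 95% percentile bands), and the average fraction of each
genome devoted to core, accessory and unique genes.
"""

from podopan.orthology import COG
from podopan.pangenome import (
    accumulation_curves,
    classify_cogs,
    genome_fractions,
    presence_absence,
)
from podopan.simulate import simulate_genome_set

genomes, genes, truth = simulate_genome_set(seed=2)

# build COGs straight from the planted truth: this example is about the
# pan-genome arithmetic, not the clustering (see example 01 for that)
gen_of = {g.gene_id: g.genome_id for g in genes}
members = {}
for gene_id, fam in truth.membership.items():
    members.setdefault(fam, set()).add((gen_of[gene_id], gene_id))
cogs = classify_cogs(
    [COG(fam, frozenset(m)) for fam, m in sorted(members.items())], len(genomes)
)

matrix = presence_absence(cogs, [g.id for g in genomes])
curve = accumulation_curves(matrix, n_permutations=500, seed=2)
print("k   pan(mean)  [2.5%,97.5%]   core(mean)")
for k in (1, 5, 10, 15, 20):
    i = k - 1
    print(
        f"{k:>2}  {curve.pan_mean[i]:8.1f}  "
        f"[{curve.pan_lo[i]:.0f},{curve.pan_hi[i]:.0f}]      "
        f"{curve.core_mean[i]:6.1f}"
    )
# the pan curve keeps climbing (open pan-genome) while the core curve
# flattens at the planted 15 families

fr = genome_fractions(cogs, genes, {g.id: len(g.residues) for g in genomes})
core, acc, unq = fr.mean_count_fractions()
print(f"mean gene fractions: core {core:.0%}, accessory {acc:.0%}, unique {unq:.0%}")
print(f"core genes span {fr.table['core_length'].mean():.0%} of genome length")
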