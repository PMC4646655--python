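# Methods

This note documents the models, rules and numerical choices behind
`podopan`, and what the synthetic-data validation does and does not
establish.

## Orthology assignment and COG clustering

Genes are compared all-vs-all at the protein level.  Two genes are called
orthologous when the similarity hits in **both** directions satisfy

* e-value ≤ 1e-5, and
* alignment length (columns, gaps included) ≥ 50% of the shorter sequence;

for pairs whose shorter sequence is under 100 aa the e-value condition is
replaced by a percent-identity floor of 35% — short genes rarely reach
significant e-values — while the coverage condition is retained.  When a
direction has several hits, the lowest-e-value (ties: highest bit score)
hit is used.  "Reciprocal hits" is read literally: hits in both directions
each meeting the cutoffs.  A stricter reciprocal-*best*-hit mode (each gene
must additionally be the other's best hit within its genome) is available
behind `mode="best"`, because the literal reading can join within-genome
paralog chains by transitivity.

COGs (clustered orthologous groups) are the connected components of the
resulting undirected graph; genes with no orthologs form singleton COGs, so
the COGs always partition the gene inventory.  An optional merge step
unions COGs linked by external profile-search hits at e ≤ 1e-5; the merge is
computed as connected components over the merge relation and is therefore
independent of row order.  Profile construction itself is out of scope; the
hit table is an input.

For a collection of N genomes, a COG present in all N is *core*, in exactly
one *unique*, otherwise *accessory*.

## Similarity search

The default engine shells out to NCBI BLAST+ (`blastp`, word size 3,
BLOSUM62, gap open 11 / extend 1, SEG and composition-based statistics off)
at the classic search cutoff e ≤ 1e-3, and parses the 12-column tabular
output.  An in-process engine computes exact optimal Smith–Waterman–Gotoh
local alignments (same scoring scheme; a gap of length k costs
`open + k·extend`) and converts raw scores with fixed gapped
Karlin–Altschul constants (λ = 0.267, K = 0.041 for BLOSUM62(11,1)):
`bits = (λS − ln K)/ln 2`, `E = m·n·2^−bits` with the pairwise search space
`m·n` rather than database-wide effective lengths.  The two engines do not
produce numerically identical e-values; the downstream thresholds are
robust to the difference (asserted on diverged synthetic families), and the
exact engine is the one tested cell-for-cell against a brute-force dynamic
program.  Hits beyond the 1e-3 search cutoff cannot satisfy the orthology
rule, so the cutoff does not affect clustering.

## Pan/core rarefaction

Accumulation curves average running pan (union) and core (intersection)
gene-family counts over random permutations of the genome order
(default 1000, seeded).  The confidence band is the 2.5/97.5 percentile
interval across permutations — a distribution-free choice.  For N ≤ 5 the
permutation estimator is verified against exhaustive subset enumeration.
The pairwise shared-gene fraction divides the intersection size by the mean
of the two genomes' family counts (symmetric, bounded by 1); a Jaccard
(union) denominator is available as a switch, since the field uses both.

## Alignments and trees

The progressive aligner builds a guide tree by UPGMA on fractional shared
3-mer distances, then merges profiles by global affine alignment (BLOSUM62,
open 11 / extend 1, terminal gaps penalized).  Profile columns are residue
frequency vectors with gaps excluded and renormalized; the column-pair
score is the frequency-weighted expected substitution score.  For two
sequences this reduces exactly to optimal global pairwise alignment, which
is how it is tested.  The aligner is deterministic and seed-free.

Block trimming drops columns with gap fraction > 0.5 or modal-residue
frequency < 0.5, then drops surviving runs shorter than 5 columns, and
records the retained column indices.  These are deliberately simple
Gblocks-style defaults, exposed as parameters.

Distances are pairwise-deletion p-distances, optionally Poisson-corrected
(−ln(1−p)).  Neighbor joining uses the canonical Q criterion with negative
branch estimates clamped to zero and lexical tie-breaking (each cluster
labelled by its smallest leaf), making results independent of input order.
UPGMA/WPGMA agglomerate with arithmetic/simple averaging; join heights are
halved into branch lengths, so UPGMA trees are ultrametric by construction.
Bootstrap supports resample alignment columns with replacement (default
1000 replicates for the concatenated core tree, 100 for single genes) and
report, for each internal edge of the point tree, the percentage of
replicate trees containing that bipartition.  Within bootstrap replicates a
Poisson distance with p ≥ 1 is capped rather than raised, since column
resampling can transiently saturate a pair.

Distance trees stand in for likelihood inference throughout: the analysis
surface is cluster/subcluster recovery and topological comparison, not
branch-length or model-parameter estimates.

## Tree comparison

Bipartitions are canonicalised as the leaf set on the side not containing
the lexically smallest leaf; trivial splits are excluded.  Robinson–Foulds
distance is the size of the symmetric difference of the two split sets.
Extended-majority consensus includes all splits above 50% frequency, then
greedily adds compatible splits in descending frequency (ties broken by
canonical lexical order, so the consensus is deterministic rather than
input-order-dependent).  Split frequencies are attached as percent
supports.

NMDS minimises Kruskal stress-1 by SMACOF majorization: configuration
distances are isotonically regressed onto the dissimilarity order
(pool-adjacent-violators), followed by a Guttman transform; 20 random
restarts (seeded), at most 500 iterations, convergence at stress change
< 1e-6, best restart reported centred at the origin.  An all-zero distance
matrix returns a flagged degenerate result.

Gene-content distances over presence/absence rows offer Jaccard (default
for dendrograms) and a two-state CFN maximum-likelihood correction
d = −½·ln(1 − 2p); p ≥ 0.5 is undefined and is capped (flagged) or raised.
The published analysis used an unspecified "ML distance" for its content
dendrogram, so both documented options are provided and the acceptance
surface is cluster recovery, not branch lengths.  Phages are clustered by
WPGMA and gene families by UPGMA, conventionally on the accessory columns.

## Synthetic genome sets

The generator plants a known architecture and emits machine-readable truth,
so every pipeline stage can be validated end to end without downloads.
Defaults emulate a 20-genome marine cyanopodovirus collection:

* **Architecture**: 15 core families present everywhere; 99 accessory
  families in cluster-, subcluster- and pair-specific blocks totalling
  ~525 gene occurrences (~26 accessory genes per genome); 235 unique genes
  (11–12 per genome).  Per-genome category fractions come out near
  28/50/22% by count and core genes near 50% of genome length.
* **Phylogeny**: two clusters of 5 + 15 genomes, the larger split into four
  subclusters (5/4/3/3), with binary (caterpillar) structure inside every
  group so that per-gene trees are resolvable.  Per-branch expected
  substitution fractions range from 0.02 (within subclusters) to 0.08
  (cluster stems); per-family lognormal rate multipliers are clipped to
  [0.6, 1.6].  Maximum pairwise protein divergence stays near 40%, well
  inside the orthology rule's detection range.
* **Incongruence**: 5 of the 15 core families evolve on an alternative
  guide tree structured by host group (with reversed within-group
  arrangements), emulating recombinant gene histories; these should appear
  as outliers in the RF/NMDS embedding of per-gene trees.
* **Composition**: genomes are assigned to a low-G+C host group (11
  genomes, target 39%) or a high-G+C group (9 genomes, target 50%),
  deliberately not congruent with the cluster split.  Proteins are
  back-translated with greedy synonymous-codon steering toward the genome
  target; intergenic spacers follow the same target.  Realized genome G+C
  lands within ±2 points of target.
* **Genes and genomes**: protein lengths are lognormal — median 480 codons
  for core families and 170 for the rest (chosen so core genes occupy half
  the genome, as in real cyanopodoviruses), floored at 60 codons.  Shared
  families keep one global order across genomes (synteny); ~30% of families
  sit on the minus strand; every gene starts ATG and ends at a stop with no
  internal stops, so a six-frame ORF caller can rediscover it.  Genome
  sizes are steered into a 42–48 kb window by spacer allocation; when a
  seed's length draws would overflow (or underfill) the window for any
  genome, all protein lengths are rescaled once by a common factor before
  sequences are generated, and a configuration that cannot fit even then
  raises an error.
* **Determinism**: a fixed seed reproduces the bundle byte for byte.

Protein evolution is i.i.d. per-site substitution (uniform replacement
excluding the current residue) without a rate matrix, and presence/absence
is combinatorial — there is no gene gain/loss process, no indels by
default, no codon-usage or amino-acid compositional realism, and no
nucleotide-level homology structure.  Passing tests therefore demonstrate
that the pipeline's rules and algorithms recover planted structure under
realistic sizes and divergences; they do not demonstrate robustness to
alignment-hostile real sequences, domain fusions, or horizontal transfer
of core genes beyond the planted pattern.

## Validation problem sizes

The repeated-seed checks run the full sequence→search→cluster route on 20
default-size simulations, and the tree-level checks (cluster clades in 20
seeds, incongruence outliers in 10) on ground-truth family assignments —
clustering recovery is validated separately, and this separation keeps each
check attributable to one mechanism.  The published-table statistics
(host-group %G+C means/SDs/ranges, Welch t-test, genome-size span) are
recomputed from the packaged 20-genome summary table at full scale.

## Known limitations

* The ORF caller reports the longest ORF per stop-to-stop region; it will
  extend a real gene upstream when an earlier in-frame start exists, and
  its counts are not comparable gene-for-gene with trained gene finders.
* E-values from the exact engine are calibrated for ranking and
  thresholding, not for agreement with BLAST's composition- and
  length-corrected values.
* The consensus builder resolves ties lexically; reference implementations
  that break ties by input order can emit a different (equally valid)
  consensus when frequencies tie exactly.
* `gene_content_distance(method="cfn")` saturates at p ≥ 0.5, which can
  occur for genomes with disjoint accessory complements; the Jaccard
  default does not saturate.
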