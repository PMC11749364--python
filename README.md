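# editome

Comparative analysis of the A-to-I RNA editome from RNA-seq read evidence:
discovery of A-to-G editing sites through a stringent filter cascade,
editome annotation and enrichment, differential editing between cell
states, miRNA target gain/loss at edited 3ʹUTR positions, and weighted
co-editing network modules. The package is aimed at computational
biologists studying ADAR-mediated editing — for example across pluripotent
cells and their differentiated derivatives — and ships a synthetic-data
generator with planted ground truth so every stage can be exercised and
validated without any external download.

## The analysis

**Site discovery.** A candidate variant needs ≥ 5 qualified RNA reads
(BAQ ≥ 25, MAPQ ≥ 20) of which ≥ 2 carry the most frequent non-reference
base; bases in the first 6 read positions are excluded (random-hexamer
priming artifacts). Candidates are removed when the variant appears in
genomic DNA reads, when the position is a catalogued SNP, and — outside
Alu elements only — when the editing level is < 0.1, the site lies within
4 bp of a splice junction, inside a homopolymer run ≥ 5 bp, or in a
genome-similarity mask. Strand is assigned only when all overlapping gene
models agree, re-expressing genomic T>C as A>G. The *editing level* of a
site is edited / total qualified reads.

**Differential editing.** A site qualifies in a sample with ≥ 5 reads.
Between two cell states, replicates must first agree (two-sided Fisher
exact test, p ≥ α within each group), then pooled counts are compared with
the exact conditional rate test — given K = k₁+k₂ edited reads,
k₁ ~ Binomial(K, n₁/(n₁+n₂)) under equal editing rates — with
Benjamini–Hochberg correction, plus a ≥ 2-fold change of the pooled
levels. Larger sample sets are confirmed per site with a two-sided
Wilcoxon rank-sum test under BH correction.

**miRNA retargeting.** For each 3ʹUTR site two 61-nt transcript-sense
queries (A and G allele) are scanned against mature miRNAs with a
seed-weighted Smith–Waterman complementarity score (match +5, G:U +2,
mismatch −3, affine gaps −9/−4, miRNA positions 2–8 scaled ×4) gated by a
nearest-neighbor duplex-energy estimate; a hit needs score ≥ 155 and
ΔG ≤ −20 kcal/mol and must cover the edited base. A miRNA covering only
the G allele is a *target gain*; only the A allele, a *target loss*.

**Co-editing network.** From a sites × samples editing-level matrix,
adjacency a_ij = |cor(x_i, x_j)|¹², topological overlap TOM, average-
linkage clustering of 1 − TOM, branch cut with a minimum module size of
30, module merging at eigen-profile dissimilarity 0.25, module
eigen-profiles (first principal component of the standardized module
submatrix), module membership MM(i) = cor(x_i, E^q), and hubs at
MM > 0.9.

## Worked example

The `demo` subcommand simulates a complete dataset (20 kb genome, 80
planted A-to-G sites, SNPs and read artifacts, a 9-sample level matrix
with two planted modules and 20 differential sites, and planted miRNA
gain/loss events), runs discovery → differential editing → retargeting →
network, and compares everything against the planted truth:

```sh
editome demo --seed 7 --out demo/
```

prints

```json
{
  "des":       {"called": 13, "planted": 20, "true_positive": 13},
  "discovery": {"planted": 80, "recovered": 78, "true_positive": 78},
  "mirna":     {"correct": 6, "events": 6},
  "network":   {"adjusted_rand_index": 0.789, "n_modules": 2},
  "seed": 7,
  "version": "0.1.0"
}
```

Discovery recovers 78 of 80 planted sites with no false calls (the two
misses are low-level sites below the 2-variant-read rule); all 13 called
differentially edited sites are planted ones (the remainder fall to the
conservative exact test and fold gate at this depth); all 6 planted
gain/loss events classify correctly; and the module labels agree with the
planted modules at adjusted Rand index 0.79 with 60 unstructured
background sites present. Re-running with the same seed reproduces the
report byte for byte.

Each stage is also exposed as its own subcommand (`simulate`, `call`,
`annotate`, `summary`, `des`, `des-confirm`, `mirna`, `network`) over the
standard file formats (FASTA, BED12, BED, VCF, TSV), and as an importable
library (`editome.discovery`, `editome.differential`, `editome.mirna`,
`editome.network`, …). The network stage additionally offers a fit-style
estimator:

```python
from editome.network import CoEditingNetwork
model = CoEditingNetwork(beta=12, min_module_size=30).fit(levels)
model.labels_        # module label per site (0 = unassigned)
model.membership_    # sites x modules MM matrix
```

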