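# Methods

This note documents the models and procedures implemented in `editome`,
the defaults and the reasoning behind them, what the synthetic-data
generator does and does not emulate, and the numerical choices a
maintainer would want recorded. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Site discovery

A column of qualified read observations (BAQ ≥ 25, MAPQ ≥ 20, base ≠ N)
becomes a candidate when qualified depth ≥ 5 and the most frequent
non-reference base has ≥ 2 qualified supporting reads. Base qualities are
consumed as already BAQ-recalibrated; no BAQ computation is performed.

*Hexamer exclusion.* Random-hexamer priming inflates mismatches at the
start of reads, so observations with read position ≤ 6 (1-based from the
5ʹ end) are excluded **before** counting, rather than removing whole sites
afterwards: site-level removal would discard sites with mixed support.
A consequence is that the level/frequency filter operates on
post-exclusion depth.

*Genomic evidence.* A candidate passes only when DNA qualified depth ≥ 5
**and** no DNA read carries the variant (both configurable). Candidates
with insufficient DNA coverage are removed: absence of the variant from
the genome is a positive claim that requires coverage to assess. The
hexamer exclusion is not applied to DNA reads — the artifact is specific
to randomly primed RNA-seq libraries.

*Known variants.* Exclusion is position-level: any catalogued allele at
the position disqualifies the candidate. Allele-aware exclusion would
retain A>G candidates at positions with, say, a known C>T SNP; with no
strong reason to assume catalogue completeness per allele, the
conservative position rule is used.

*Non-Alu filters.* Sites inside the Alu mask are exempt from exactly four
filters — frequency (< 0.1), splice proximity (≤ 4 bp), homopolymer
(run ≥ 5 covering the site), and the genome-similarity mask — because the
A-to-G signal in inverted Alu repeats is overwhelming and these filters
mainly guard against artifacts in unique sequence. Core thresholds apply
everywhere. Splice distance is measured for intronic positions only, as
min(distance to the flanking exon boundaries), with distance 1 meaning
immediately adjacent; ≤ 4 fails. The homopolymer rule extends left and
right from the site over bases equal to the reference base at the site —
a run that covers the site necessarily consists of that base. Genome
similarity is consumed as a precomputed BED mask; mappability computation
is out of scope.

*Tie-break.* When two non-reference bases tie in count, the base with the
higher summed base quality wins; a tie in both drops the column with a log
message. Deterministic and conservative.

*Strand.* Assigned only when every overlapping gene model is on one
strand; the substitution type is then re-expressed on that strand (genomic
T>C inside a minus-strand gene is reported A>G). Otherwise the strand
stays unknown and the substitution genomic.

## Annotation and enrichment

Region classes follow the precedence CDS > UTR3 > UTR5 > ncRNA_exonic >
intronic > ncRNA_intronic > intergenic when several gene models overlap.
UTR3 outranks UTR5 so that dual-UTR overlaps resolve toward the class of
primary biological interest here; multi-class positions are logged.
Coverage-normalised enrichment per category uses a 2×2 Fisher exact test
of {edited, covered-not-edited} × {in category, elsewhere}, with the
background defined as adenosines (transcript-sense) having qualified
coverage ≥ 5, and BH correction across categories. Editing-level
histograms use ten equal bins on [0, 1]; for the chi-square comparison,
bins whose smaller-row expected count falls below 5 are merged rightward
(standard validity rule). Gene-set over-representation is a one-sided
hypergeometric test over a user-supplied universe with BH correction; no
ontology is bundled.

## Differential editing

A site is qualified in a sample at ≥ 5 qualified reads. The two-stage
caller: (1) replicate concordance — every within-group replicate pair
must give two-sided Fisher p ≥ α (α = 0.05, configurable; sites failing
are *ineligible*, never "not differential", so absence of evidence stays
explicit); (2) pooled counts per group enter the exact conditional rate
test: conditional on K = k₁+k₂, k₁ ~ Binomial(K, n₁/(n₁+n₂)) under equal
rates, two-sided by summing outcomes no more probable than the observed
one (the standard exact construction for two Poisson/binomial rates with
unequal exposure — "normalised against read coverage"). BH correction is
applied across eligible sites (raw p available via `adjust=False`), and a
differential call additionally needs a ≥ 2-fold ratio of the pooled
levels. Fold change of two zero levels is 1; of one zero level, infinite.
The exact test is conservative: on all-null data its size is below the
nominal α, which the test suite verifies on 2000 null sites.

The large-set confirmation applies a per-site two-sided rank-sum test
with BH. Note the granularity limit: with 6 vs 3 samples the smallest
achievable two-sided exact p is 2/C(9,3) ≈ 0.024, so the BH threshold can
only be cleared when a sufficient fraction of the family carries a shift;
recovery is therefore validated on a 126-site family with 66 shifted
sites, the regime in which this analysis is informative.

## miRNA retargeting

Queries are 61-nt transcript-sense windows centred on the edited base
(offset adjusted and flagged at contig ends); the edited query carries G
at the site. The scanner follows the two-phase architecture of
complementarity alignment plus energy gate, as an independent
implementation: a Smith–Waterman local alignment of the miRNA (3ʹ→5ʹ)
against the query (5ʹ→3ʹ), scoring Watson–Crick +5, G:U wobble +2,
mismatch −3, affine gaps −9/−4, with substitution scores at miRNA 5ʹ
positions 2–8 multiplied by 4 (gap penalties unscaled). Thresholds: score
≥ 155, energy ≤ −20 kcal/mol, and the hit must cover the edited position.
Parity with any specific external scanner release is not claimed;
thresholds are interpreted on this scorer's scale. Duplex energy is a
nearest-neighbor sum over consecutive paired positions using the ten
published Watson–Crick stack free energies (37 °C) with duplex-rotation
symmetry, one helix-initiation term (+4.09), a pooled value (−1.2) for
any stack involving a G:U pair, and a flat +3.0 per helix interruption —
deliberately simple, dependency-free, and monotone in pairing, not a
secondary-structure prediction. T and U are interchangeable on input.
Alignment ties resolve deterministically (first-reached cell in scan
order; traceback prefers pairing over gaps).

## Co-editing network

Unsigned adjacency |cor|^β with β = 12 (signed networks are an
alternative; unsigned is the conventional default and treats
anti-correlated editing as connected), topological overlap
TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij), and
average-linkage clustering of 1 − TOM. The published dynamic hybrid tree
cut is replaced by a documented simplification with the same intent:

1. **Adaptive branch cut.** A fixed grid of heights (0.95–0.9975, step
   0.0025) is scanned and the lowest height yielding the most branches of
   ≥ 30 sites is used (an explicit `cut_height` forces a static cut).
   A single static height is fragile: small modules lose cohesion below
   it, while above it modules merge.
2. **Eigen refinement with hysteresis.** Module eigen-profiles (unit-norm
   first right singular vector of the standardized member submatrix,
   sign-oriented so mean member correlation is positive) are alternated
   with reassignment of every site to its best-correlated module until
   stable. A site *keeps* its module while |r| exceeds the 95% null
   critical value for the sample count, but *joins* a new module only
   above the 99% value — admitting a site demands stronger evidence than
   retaining one, which both limits absorption of unrelated sites and
   prevents erosion cascades. Sites below the floors stay unassigned
   (label 0).
3. **Merging.** Modules whose eigen-profiles cluster below height 0.25
   (1 − cor) under average linkage are merged, iterating to a fixpoint so
   a second pass is a no-op.

Module membership is MM(i) = cor(x_i, E^q); hubs are own-module sites
with MM > 0.9. Module labels are deterministic: ordered by decreasing
size, ties by smallest member key. Zero-variance profiles are dropped
with a warning before correlation.

With few samples (nine in the reference configuration) chance correlation
is substantial: an unstructured profile exceeds |r| = 0.67 with a given
eigen-profile 5% of the time. Perfect separation of weakly attached
members from chance-correlated background is therefore impossible in
principle at this sample count, and occasional merging of modules whose
latent factors happen to correlate above 0.75 across nine samples is
irreducible at the fixed merge height.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
with planted, disjoint truth classes so per-filter attribution is exact:

- a random genome with Alu-like intervals (default 30% of 100 kb),
  stranded multi-exon gene models with CDS/UTRs, stamped homopolymer
  runs, and a genome-similarity mask;
- planted A-to-G sites (97% in Alu by default) with levels from
  Beta(2, 5) — right-skewed, median ≈ 0.26, near observed editome
  medians — truncated below a configurable floor; genic non-Alu sites are
  planted transcript-sense and above the 0.1 frequency floor so they are
  discoverable by design;
- read observations: per-position Poisson coverage (λ = 30), binomial
  edited-read counts at the planted level, germline SNPs variant in both
  DNA and RNA (70% heterozygous), hexamer artifacts whose variant reads
  sit only at read positions 1–6, uniform sequencing errors (0.001) that
  avoid planted positions (attribution would otherwise be ambiguous), and
  BAQ/MAPQ draws with 8% / 5% below threshold;
- level matrices: per-module one-factor models x_i = w_i f + √(1−w_i²) ε
  with w = √0.8 for a within-module pairwise correlation of 0.8 (hubs at
  w = 0.98), independent background sites, and differential sites whose
  lower group rate is drawn U(0.2, 0.35) — the observed median editing
  range — with the fold-higher rate assigned to a random group and counts
  drawn binomially at Poisson(50) depths; a separate small-noise
  single-factor fixture (noise sd 0.1) isolates eigen-profile and hub
  behaviour from module-detection noise;
- miRNA fixtures: for each gain event a miRNA is built as the reverse
  complement of the edited query with the site in the seed, mutated at
  2–3 non-seed positions and verified through the actual scanner (the
  reference allele must fail); losses are symmetric; neutral sites are
  verified to hit nothing. Bounded retries, error on failure.

Not emulated: quality-by-cycle error profiles, splice-aware reads,
fragment-level read simulation (read ids are synthesized), isoform
structure, batch effects, or biological replicate overdispersion in the
differential model (replicates share the site's true level, so count
noise is purely binomial). Passing tests therefore demonstrate
correctness of the statistical machinery and filter logic under the
stated generative model, not robustness to real-library artifacts beyond
those modelled.

Determinism: all randomness flows from one integer seed through numpy
`default_rng`; identical config + seed gives byte-identical outputs, and
the end-to-end demo reproduces its report exactly.

## Problem sizes

The test suite and acceptance script run at desk scale, chosen to finish
in minutes on one CPU while keeping estimator noise small relative to the
bounds they check: discovery on 100 kb genomes with 300 planted sites at
λ = 30 (sensitivity averaged over three datasets, since one 300-site draw
has ~1.2% binomial noise); differential calibration on 2000 null and
3×200 shifted sites at depth 50 with 2+2 replicates; network recovery on
60/40/30-site modules over nine samples across ten seeds; retargeting on
30 planted events. The demo uses a 20 kb genome.

## Known limitations

- The region annotator is gene-level, not isoform-resolved.
- The duplex-energy model is a monotone approximation, not a
  thermodynamic folding computation; absolute energies should not be
  compared with structure-prediction tools.
- The exact conditional rate test is conservative at low counts; with a
  measured-fold gate at 2 and true fold 2.5, fold-measurement noise at
  depth ~100 per group leaves roughly one in ten true sites below the
  gate.
- Module detection at nine samples is near the information limit for
  background separation (see above); more samples, not better heuristics,
  is the remedy.
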