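# Methods

## Data model and conventions

Somatic variants are single-base substitutions with 1-based positions;
multi-allelic VCF records are split and each allele classified independently,
indel alleles are tallied separately, and alleles containing N/IUPAC codes
are skipped with a logged count (they cannot be assigned a substitution
class). Duplicate (chrom, pos, ref, alt) records are deduplicated — spectra
count unique somatic events. Chromosome-name dialects are normalized by
stripping a configurable prefix (default `chr`). Variant calling itself
(tumor/normal subtraction, depth/VAF filtering) is upstream of this package;
real-data users must pre-filter their calls.

Spectra follow the COSMIC pyrimidine-strand convention: purine-ref variants
are complemented (with reverse-complemented context) before labelling, so
G>T counts as C>A. Channel order is the canonical 96: blocks C>A, C>G, C>T,
T>A, T>C, T>G; within a block the 5′ then 3′ flanking base run
alphabetically. A variant with unusable context (chromosome edge, N in
context) stays in the 6-class counts but is excluded from the 96-channel
counts and tallied in `n_excluded`; a variant whose recorded ref contradicts
the reference genome is dropped entirely, since the call is unreliable.
Relative frequencies are raw observation fractions; no genome-composition
normalization is applied (cohort C>A percentages are plain event fractions).

## Signature refitting

Contributions are fitted on absolute counts, so they come out in mutation
units; relative contributions are derived afterwards. NNLS is solved by the
Lawson–Hanson active-set algorithm (exact KKT solution, deterministic).
The "strict" refit prunes low contributors by greedy backward elimination:
repeatedly drop the lowest-contributing retained signature, refit, and accept
the removal while the reconstruction cosine falls by less than `max_delta`
relative to the previously accepted model; stop at the first rejected
removal. `max_delta` defaults to 0.004, the strict-refit convention in the
signature-analysis field; no published threshold exists for this cohort, so
the value is a config knob, as is an optional relative-contribution floor
(default off). Dominant-signature ties break toward the earlier name in the
matrix and are flagged.

Clustering of samples uses Euclidean distance on relative contribution
vectors with complete linkage (both configurable; no linkage is canonical
for this analysis). Leaf order is deterministic given input order; trees
export to Newick. The packaged signature matrix is a **synthetic fixture**
of five distinguishable pseudo-signatures — PS18/PS36 are C>A-dominant
(0.85 of mass in the C>A block, different context profiles) standing in for
the oxidative-damage signatures SBS18/SBS36; PS1 is CpG-deamination-like,
PS5 a broad T>C profile, PS40 flat background. Real COSMIC tab-delimited
files load through the same reader and are validated (all 96 channels
present exactly once, non-negative, columns sum to 1 within 1e-6) and
re-ordered to canonical channel order.

## Copy-number groups and group tests

Gene-level loss is a strict inequality, CBS < −0.5; a score of exactly −0.5
is not a loss. Groups are disjoint: samples losing both glycosylases are
flagged BOTH, reported separately and excluded from the two-group CNL-vs-WT
tests. Group comparisons are two-sided; the Welch statistic uses
Welch–Satterthwaite degrees of freedom. With both sample variances zero and
equal means the test returns p = 1 (no evidence, not an error). The clonal
knockout contrast defaults to the plain Student variant (pooled variance)
with Welch available by flag; cohort contrasts default to Welch.

## Survival

Kaplan–Meier estimation is the standard product-limit estimator with right
censoring (delegated to lifelines). The two-group log-rank test is
implemented as a vectorized per-event-time sum of observed-minus-expected
deaths with the hypergeometric (tie-correct) variance and a chi-square
(1 df) p-value; vectorization over splits is what makes scanning every
cutoff across hundreds of replicate cohorts tractable, and the
implementation is verified in the test suite against both a brute-force
per-event-time oracle and lifelines. The Kaplan scan tests every distinct
covariate value whose induced high (≥ cutoff) and low (< cutoff) groups both
reach `min_group` (default 8 — the platform bound used for the original
analysis is unpublished, so this is a config knob), takes the minimum raw p
(first value on ties), and multiplies by the number of cutoffs actually
tested (capped at 1). The high group is always covariate ≥ cutoff. No
permutation p-values in this version.

## Clonal accumulation

Accrual is one-sided: the accumulated set is subclone minus clone by exact
(chrom, pos, ref, alt) match; clone variants missing from the subclone are
logged but never subtracted, since the design measures mutations gained
during outgrowth. Rates are per genome per day — division rate is unknown
and not modelled. The total rate uses the full accumulated set; class rates
and fractions come from its 6-class spectrum. An empty accumulated set
yields zero rates with a flag.

## Synthetic study generator

The generator emulates the structure the analysis assumes, with defaults
fixed once:

- **Reference**: uniform-random A/C/G/T genome (default analyses use
  0.3–1 Mb; all 64 trinucleotide contexts occur thousands of times).
- **Cohort**: 86 tumors; group fractions 0.15 MUTYH-CNL, 0.25 OGG1-CNL,
  0.02 dual, rest WT; mutations per tumor lognormal with median 2000
  (a realistic whole-genome burden for this tumor type); CBS scores
  N(−0.8, 0.15) for lost genes, N(0, 0.1) for neutral (truncated at the
  −0.5 cutoff so generated labels are the calls' ground truth).
- **Mixtures**: per-group signature weights give a total C>A mass of ≈0.55
  for CNL-like tumors and ≈0.27 for WT-like, matching the separation the
  analysis is designed to detect. Cohort loss groups are PS18-led — a strong
  SBS36-like component in tumors is essentially confined to biallelic MUTYH
  inactivation, so MUTYH-CNL tumors carry PS36 only as a secondary
  component — whereas the engineered biallelic MUTYH knockout clones are
  PS36-dominant.
- **Placement**: each mutation samples a channel from its group mixture and
  lands at a position drawn uniformly among all genome sites whose forward-
  or reverse-strand context matches the channel (equivalent to rejection
  sampling, implemented by direct indexing of a context→positions table);
  spectra recomputed from the reference therefore recover the generating
  mixture. Position collisions within a sample are collapsed by catalog
  deduplication (a loss of well under 1% at default burdens).
- **Survival**: exponential hazard h₀·exp(β·C>A-fraction) with h₀ = 0.002
  per month and β = 6 (hazard ratio ≈ 5 between the group means), uniform
  administrative censoring on 24–120 months — the simplest model with the
  assumed monotone hazard.
- **Clones**: 2 replicates per genotype; culture duration uniform on 88–126
  days; accrual 1.0 substitutions/genome/day for WT and NUDT1-KO versus 2.5
  for MUTYH-KO and OGG1-KO; accrued C>A mass 0.50 for glycosylase knockouts
  versus 0.27 for WT/NUDT1-KO; clone background ~1000 pre-existing variants.

What the generator does **not** emulate: mutation clustering and kataegis,
chromatin- or replication-timing-dependent mutation density, real genome
trinucleotide composition, copy-number segmentation noise structure, subclonal
VAF structure, or correlated clinical covariates beyond a simple stage/C>A
link. Passing tests therefore demonstrate correctness of the computations and
power under the assumed effect sizes, not performance on real tumor genomes.

## Numerical and design choices

- Deterministic everywhere: one root seed, per-stage streams derived by
  hashing (kept below 2³¹); same seed ⇒ byte-identical generated files.
- Zero-count spectra produce flagged all-zero relative vectors rather than
  NaN; refit and cosine similarity on all-zero vectors raise.
- p-values are clamped into (0, 1] (a degenerate zero-variance difference
  reports the smallest positive float rather than 0).
- Validation studies run on a 300 kb single-chromosome reference with the
  default cohort and clone parameters; replicate counts are 50 (refit
  recovery), 500 (null scan), 100 (cohort separation, clonal contrast).

## Known limitations

- The log-rank p uses the asymptotic chi-square; at very small event counts
  it is approximate (as in standard practice).
- The strict-refit elimination order is by absolute contribution; with
  near-collinear signatures the retained set is not unique, only the
  reconstruction quality is guaranteed.
- The Kaplan scan's Bonferroni correction is conservative under the strong
  dependence between neighbouring cutoffs; the null family-wise error rate
  sits well below the nominal 0.05.
- Indels are counted, never spectrum-classified; indel signatures are out of
  scope, as is de novo signature extraction.
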