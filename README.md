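# oxosig

Analysis pipeline for quantifying **C>A substitution burden** in tumor somatic
SNV catalogs and linking it to **defects in 8-oxo-guanine repair** — the
situation in neuroblastoma, where copy-number loss (CNL) of the DNA
glycosylases *MUTYH* (1p) and *OGG1* (3p) leaves oxidized guanine lesions
unrepaired, drives cytosine>adenine substitutions (signatures SBS18/SBS36),
and correlates with poor survival.

The package is aimed at cancer-genomics analysts who have per-sample somatic
SNV calls (VCF), gene-level copy-number segmentation scores, and clinical
follow-up, and want to run the whole chain: mutational spectra → signature
refitting → CNL grouping → survival cutoff scan → clone/subclone mutation
rates. A synthetic study generator reproduces the statistical structure of
such a cohort so that every stage is testable without access to protected
patient data.

## What it computes

- **Trinucleotide spectra.** Each SNV is collapsed onto the pyrimidine strand
  (G>T ≡ C>A with reverse-complemented context), giving 6 substitution
  classes and 96 context channels `X[R>A]Y`. Relative frequencies are raw
  observation fractions, with no correction for genome trinucleotide content.
- **Strict signature refitting.** An observed spectrum *m* is decomposed as
  *m* ≈ *P·c*, *c* ≥ 0, by non-negative least squares (Lawson–Hanson), then
  low-contributing signatures are pruned by greedy backward elimination:
  remove the smallest contributor while the reconstruction cosine
  cos(*m*, *P·c*) drops by less than `max_delta` (default 0.004). Samples are
  clustered hierarchically on their relative contribution vectors.
- **Copy-number-loss groups.** A gene is lost when its circular-binary-
  segmentation score satisfies CBS < −0.5 (strict); samples are assigned to
  MUTYH-CNL / OGG1-CNL / WT (dual losses reported separately) and group C>A
  fractions compared by two-sided Welch *t*-tests.
- **Kaplan scan.** Every admissible cutoff of the C>A fraction (both groups
  ≥ `min_group`, default 8) is tested as a high-vs-low survival split with a
  log-rank test; the best split is reported with Bonferroni correction over
  the number of cutoffs actually scanned.
- **Clonal accumulation.** Variants private to a subclone relative to its
  parental clone, divided by the culture duration, give substitutions per
  genome per day; knockout-vs-wild-type contrasts use an unpaired two-sided
  *t*-test (Student for the knockout contrast, Welch elsewhere).

## Worked example

Run the numbered analysis scripts in order (they write summary tables under
`results/`, bulky intermediates under `scratch/study/`):

```sh
python analysis/01_simulate_study.py
python analysis/02_mutational_spectra.py
python analysis/04_cnl_groups.py
python analysis/05_survival_scan.py
```

On the default synthetic cohort of 86 tumors (seed 1), stage 04 prints

```
MUTYH_CNL_vs_WT: mean 0.552 vs 0.267, Welch t = 81.29, p = 3.87e-23
OGG1_CNL_vs_WT: mean 0.555 vs 0.267, Welch t = 112.78, p = 8.64e-47
```

i.e. tumors with a glycosylase loss carry ≈55% C>A substitutions versus
≈27% in copy-number-neutral tumors, and stage 05 prints

```
scanned 71 cutoffs; best split at C>A fraction >= 0.272 (52 high vs 34 low)
log-rank raw p = 2.52e-10; Bonferroni-corrected p = 1.79e-08
```

so the high-C>A half of the cohort has significantly worse overall survival
even after correcting for the 71 cutoffs tried. Stage 06 shows knockout
clones accruing ~2.3–2.7 substitutions/genome/day at ~50% C>A versus
~0.9–1.0/day at ~30% C>A for wild-type clones (knockout contrast
p = 0.0079).

The same stages are available as a CLI (`oxosig simulate|spectra|refit|
cluster|cnl|survival|clonal|report`), each writing a run manifest with the
config hash and seed.

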