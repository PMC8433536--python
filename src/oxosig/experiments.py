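"""Replicated validation studies run on the synthetic study generator.

These drivers wire the generator and the analysis stages together into the
repeated-simulation experiments that characterize the pipeline: signature
parameter recovery, family-wise error control of the cutoff scan, cohort-level
group separation, and clone-accrual calibration.  Both the test suite and the
reproduction script call these functions; every experiment takes an explicit
seed and is deterministic given it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .clonal import accrual_rates, genotype_contrast
from .cn_groups import welch_t_test
from .signatures import SignatureMatrix, cluster_by_contributions, nnls_refit, strict_refit
from .spectra import build_spectrum, classify_substitution, relative_spectrum
from .survival import kaplan_scan
from .synthetic import (
    CloneSpec,
    CohortSpec,
    make_reference,
    pseudo_signature_matrix,
    simulate_clonal_pairs,
    simulate_cohort,
)
from .variant_io import ReferenceContextSource


def _child_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def ras_mapk_ca_percent(n_ca: int = 7, n_total: int = 15) -> float:
    """C>A percentage among a set of pathway-altering SNV events.

    In the published relapse cohort, 7 of the 15 tumor-evolution SNV events in
    RAS-MAPK pathway genes were C>A substitutions; the event counts are the
    input and the percentage is computed by classifying one representative
    substitution per event (C>A events are represented on both strands, i.e.
    as C>A and as G>T calls).
    """
    events = []
    for i in range(n_ca):  # alternate strand representation of the C>A events
        events.append(("C", "A") if i % 2 == 0 else ("G", "T"))
    others = [("C", "T"), ("T", "C"), ("C", "G"), ("T", "A"), ("A", "G"), ("G", "A"), ("T", "G")]
    for i in range(n_total - n_ca):
        events.append(others[i % len(others)])
    classes = [classify_substitution(ref, alt) for ref, alt in events]
    return 100.0 * sum(c == "C>A" for c in classes) / len(classes)


@dataclass
class RecoveryResult:
    mean_abs_error: float
    n_replicates: int
    n_mutations: int


def refit_recovery(
    seed: int, n_replicates: int = 50, n_mutations: int = 5000
) -> RecoveryResult:
    """Relative-contribution recovery from catalogs of a known 3-signature mix.

    Each replicate samples ``n_mutations`` channels from a fixed mixture of
    three pseudo-signatures, refits by NNLS, and the mean absolute error of
    the relative contributions is averaged over replicates.
    """
    rng = np.random.default_rng(seed)
    full = pseudo_signature_matrix()
    matrix = full.subset(["PS1", "PS5", "PS18"])
    w_true = np.array([0.2, 0.3, 0.5])
    probs = matrix.P @ w_true
    errors = []
    for _ in range(n_replicates):
        counts = rng.multinomial(n_mutations, probs).astype(float)
        c = nnls_refit(counts, matrix)
        rel = c / c.sum()
        errors.append(np.abs(rel - w_true).mean())
    return RecoveryResult(float(np.mean(errors)), n_replicates, n_mutations)


@dataclass
class NullScanResult:
    fwer: float
    n_replicates: int
    bound: float  #: 0.05 + 2 binomial standard errors


def null_scan_fwer(
    seed: int, n_replicates: int = 500, n_samples: int = 86, min_group: int = 8
) -> NullScanResult:
    """Family-wise rejection rate of the Bonferroni-corrected cutoff scan
    when the covariate is independent of survival (hazard slope beta = 0)."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_replicates):
        spec = CohortSpec(
            n_samples=n_samples, survival_beta=0.0, seed=_child_seed(rng)
        )
        cohort = simulate_cohort(spec, reference=None, place_variants=False)
        result = kaplan_scan(
            cohort.survival_records, covariate="ca_fraction", min_group=min_group
        )
        rejections += result.bonferroni_p < 0.05
    fwer = rejections / n_replicates
    bound = 0.05 + 2 * np.sqrt(0.05 * 0.95 / n_replicates)
    return NullScanResult(float(fwer), n_replicates, float(bound))


@dataclass
class SeparationResult:
    welch_rejection_rate: float
    n_cohorts: int
    cluster_accuracy: float  #: two-cluster cut vs generator CNL/WT labels
    scan_bonferroni_p: float  #: Kaplan scan on the first (default) cohort


def measured_ca_fractions(cohort, reference) -> dict[str, float]:
    """Per-sample C>A fraction recomputed from the generated variants."""
    out = {}
    for catalog in cohort.catalogs:
        rel = relative_spectrum(build_spectrum(catalog, reference))
        out[catalog.sample_id] = float(rel.freq6[0])
    return out


def cohort_separation(
    seed: int,
    reference: ReferenceContextSource,
    n_cohorts: int = 100,
    alpha: float = 0.05,
) -> SeparationResult:
    """End-to-end separation of CNL-like and WT-like tumors.

    For each simulated cohort the per-sample C>A fraction is measured from
    the generated VCs via the spectrum builder and the pooled CNL group is
    tested against WT with a Welch t-test; on the first cohort the samples
    are additionally refitted, clustered on relative contributions, and the
    two-cluster cut is compared with the generating labels, and the survival
    cutoff scan is run on the measured C>A fraction.
    """
    rng = np.random.default_rng(seed)
    matrix = pseudo_signature_matrix()
    rejections = 0
    cluster_accuracy = float("nan")
    scan_p = float("nan")
    for i in range(n_cohorts):
        spec = CohortSpec(seed=_child_seed(rng))
        cohort = simulate_cohort(spec, reference, matrix)
        ca = measured_ca_fractions(cohort, reference)
        truth = cohort.truth.set_index("sample_id")
        cnl = [ca[s] for s, g in truth["group"].items() if g in ("MUTYH_CNL", "OGG1_CNL")]
        wt = [ca[s] for s, g in truth["group"].items() if g == "WT"]
        if len(cnl) >= 2 and len(wt) >= 2:
            rejections += welch_t_test(cnl, wt).p < alpha

        if i == 0:
            refits = [
                strict_refit(build_spectrum(c, reference).counts96, matrix, sample_id=c.sample_id)
                for c in cohort.catalogs
            ]
            clustering = cluster_by_contributions(refits)
            labels = clustering.cut(2)
            is_cnl = truth["group"] != "WT"
            agree = sum(
                (labels[s] == 1) == bool(is_cnl[s]) for s in labels
            )
            cluster_accuracy = max(agree, len(labels) - agree) / len(labels)

            for rec in cohort.survival_records:
                rec.covariates["ca_fraction"] = ca[rec.sample_id]
            scan_p = kaplan_scan(cohort.survival_records).bonferroni_p
    return SeparationResult(
        welch_rejection_rate=rejections / n_cohorts,
        n_cohorts=n_cohorts,
        cluster_accuracy=float(cluster_accuracy),
        scan_bonferroni_p=float(scan_p),
    )


@dataclass
class ClonalCalibration:
    accrued_counts: list[int]
    poisson_mean: float
    max_abs_deviation_sigma: float
    contrast_rejection_rate: float
    n_replicates: int


def clonal_calibration(
    seed: int, reference: ReferenceContextSource, n_replicates: int = 100
) -> ClonalCalibration:
    """Accrual-count calibration and genotype-contrast power.

    A fixed-rate configuration (1.0 substitution/day, 100-day culture) checks
    that measured accrued counts stay within 3 sigma of Poisson(100); the
    default knockout/wild-type configuration is then replicated to estimate
    how often the glycosylase-knockout contrast rejects at alpha = 0.05.
    """
    rng = np.random.default_rng(seed)
    matrix = pseudo_signature_matrix()

    fixed = CloneSpec(
        accrual_rates={"WT": 1.0, "NUDT1_KO": 1.0, "OGG1_KO": 1.0, "MUTYH_KO": 1.0},
        days_low=100.0,
        days_high=100.0,
        seed=_child_seed(rng),
    )
    pairs, _ = simulate_clonal_pairs(fixed, reference, matrix)
    counts = [len(accrual_rates(p, reference).accumulated) for p in pairs]
    lam = 100.0
    max_dev = max(abs(c - lam) for c in counts) / np.sqrt(lam)

    rejections = 0
    for _ in range(n_replicates):
        spec = CloneSpec(seed=_child_seed(rng))
        pairs, _ = simulate_clonal_pairs(spec, reference, matrix)
        results = [accrual_rates(p, reference) for p in pairs]
        ko = [r for r in results if r.genotype in ("MUTYH_KO", "OGG1_KO")]
        wt = [r for r in results if r.genotype == "WT"]
        comparison = welch_t_test(
            [r.class_fractions[0] for r in ko],
            [r.class_fractions[0] for r in wt],
            welch=False,
        )
        rejections += comparison.p < 0.05
    return ClonalCalibration(
        accrued_counts=counts,
        poisson_mean=lam,
        max_abs_deviation_sigma=float(max_dev),
        contrast_rejection_rate=rejections / n_replicates,
        n_replicates=n_replicates,
    )
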