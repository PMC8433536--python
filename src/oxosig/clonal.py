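"""Mutation accumulation between a clone and its derived subclone.

A single-cell clone is expanded in culture for a known number of days and
re-subcloned; variants private to the subclone measure the mutations that
accumulated during the expansion.  Rates are expressed per genome per day
(division rate is not modelled).  Accrual is one-sided: variants present in
the clone but missing from the subclone are reported but never subtracted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .cn_groups import GroupComparison, welch_t_test
from .spectra import SUB_CLASSES, Spectrum, build_spectrum
from .variant_io import MutationCatalog

logger = logging.getLogger(__name__)


@dataclass
class ClonalPair:
    clone: MutationCatalog
    subclone: MutationCatalog
    days: float
    genotype: str = ""

    def __post_init__(self) -> None:
        if self.days <= 0:
            raise ValueError("culture duration must be positive")


@dataclass
class AccrualResult:
    """Per-day substitution accrual of one clone/subclone pair."""

    pair_id: str
    genotype: str
    days: float
    accumulated: MutationCatalog
    total_rate: float  #: substitutions per genome per day
    class_rates: np.ndarray  #: per-day rate for each of the 6 classes
    class_fractions: np.ndarray  #: relative 6-class fractions of the accrued set
    indel_delta: int
    n_lost: int  #: clone variants absent from the subclone (reported only)
    empty: bool = False


def accumulated_variants(pair: ClonalPair) -> MutationCatalog:
    """Variants present in the subclone and absent from the clone.

    Matching is on (chrom, pos, ref, alt).  Clone variants missing from the
    subclone are logged but never produce negative accrual.
    """
    clone_keys = pair.clone.variant_keys()
    sub_df = pair.subclone.df
    mask = [
        (c, int(p), r, a) not in clone_keys
        for c, p, r, a in sub_df.itertuples(index=False)
    ]
    accrued = sub_df[np.asarray(mask, dtype=bool)]
    n_lost = len(clone_keys - pair.subclone.variant_keys())
    if n_lost:
        logger.warning(
            "%s: %d clone variant(s) absent from subclone (ignored)",
            pair.subclone.sample_id,
            n_lost,
        )
    return MutationCatalog(pair.subclone.sample_id, accrued.copy())


def accrual_rates(pair: ClonalPair, reference) -> AccrualResult:
    """Absolute and relative per-day substitution rates for one pair."""
    accrued = accumulated_variants(pair)
    n_lost = len(pair.clone.variant_keys() - pair.subclone.variant_keys())
    spectrum = build_spectrum(accrued, reference)
    total = int(spectrum.counts6.sum())
    fractions = spectrum.counts6 / total if total else np.zeros(6)
    return AccrualResult(
        pair_id=pair.subclone.sample_id,
        genotype=pair.genotype,
        days=pair.days,
        accumulated=accrued,
        total_rate=len(accrued) / pair.days,
        class_rates=spectrum.counts6 / pair.days,
        class_fractions=fractions,
        indel_delta=pair.subclone.n_indels - pair.clone.n_indels,
        n_lost=n_lost,
        empty=len(accrued) == 0,
    )


def genotype_contrast(
    results: list[AccrualResult],
    genotype_a: str,
    genotype_b: str,
    statistic: str = "ca_fraction",
    welch: bool = False,
) -> GroupComparison:
    """Two-sided unpaired t-test between genotypes on a per-pair statistic.

    The knockout-vs-wild-type contrast uses the plain Student variant by
    default (``welch=False``); pass ``welch=True`` for the Welch correction.
    ``statistic`` is ``"ca_fraction"`` (relative C>A fraction of the accrued
    set) or ``"total_rate"`` (substitutions per genome per day).
    """
    def value(r: AccrualResult) -> float:
        if statistic == "ca_fraction":
            return float(r.class_fractions[0])
        if statistic == "total_rate":
            return float(r.total_rate)
        raise ValueError(f"unknown statistic {statistic!r}")

    a = [value(r) for r in results if r.genotype == genotype_a]
    b = [value(r) for r in results if r.genotype == genotype_b]
    if len(a) < 2 or len(b) < 2:
        raise ValueError(
            f"need >= 2 replicates per genotype, got {len(a)} {genotype_a!r} "
            f"and {len(b)} {genotype_b!r}"
        )
    return welch_t_test(a, b, labels=(genotype_a, genotype_b), welch=welch)
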