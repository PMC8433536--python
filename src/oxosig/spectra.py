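"""Substitution classification and trinucleotide mutational spectra.

Somatic single-nucleotide variants are collapsed onto the pyrimidine strand
(COSMIC convention): a G>T call is counted as C>A on the opposite strand,
together with the reverse complement of its trinucleotide context.  This
yields six substitution classes (C>A, C>G, C>T, T>A, T>C, T>G) and, with the
flanking bases, 96 context channels.  Relative spectra are raw observation
fractions; no correction for the genome-wide trinucleotide distribution is
applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_CODE = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

SUB_CLASSES: tuple[str, ...] = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: Canonical 96-channel order: substitution blocks C>A..T>G; within a block the
#: 5' then 3' flanking bases run alphabetically (A, C, G, T).
CHANNELS_96: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}" for sub in SUB_CLASSES for five in BASES for three in BASES
)
CHANNEL_INDEX = {ch: i for i, ch in enumerate(CHANNELS_96)}

# Substitution-class index for a pyrimidine ref (rows: ref code, cols: alt code).
_SUB_IDX = np.full((4, 4), -1, dtype=np.int64)
_SUB_IDX[1, 0] = 0  # C>A
_SUB_IDX[1, 2] = 1  # C>G
_SUB_IDX[1, 3] = 2  # C>T
_SUB_IDX[3, 0] = 3  # T>A
_SUB_IDX[3, 1] = 4  # T>C
_SUB_IDX[3, 2] = 5  # T>G


class ClassificationError(ValueError):
    """Raised for bases outside A/C/G/T or a ref == alt call."""


def classify_substitution(ref: str, alt: str) -> str:
    """Return the pyrimidine-strand class of a single-base substitution.

    Purine refs (A, G) are complemented together with the alt, so e.g.
    G>T maps to C>A and A>C maps to T>G.
    """
    if ref not in _BASE_CODE or alt not in _BASE_CODE:
        raise ClassificationError(f"non-ACGT substitution {ref!r}>{alt!r}")
    if ref == alt:
        raise ClassificationError(f"ref equals alt ({ref!r})")
    if ref in "AG":
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return f"{ref}>{alt}"


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


class ContextMismatchError(ValueError):
    """Raised when the middle base of a trinucleotide context is not the ref."""


def trinucleotide_channel(context3: str, ref: str, alt: str) -> str | None:
    """Map a variant and its reference trinucleotide context to a 96-channel label.

    Purine-ref contexts are reverse-complemented before labelling.  Returns
    ``None`` when any context base is not A/C/G/T (the variant is excluded
    from the 96-channel spectrum but can still carry a 6-class count).
    """
    if len(context3) != 3:
        raise ContextMismatchError(f"context {context3!r} is not length 3")
    sub = classify_substitution(ref, alt)  # validates ref/alt
    if any(b not in _BASE_CODE for b in context3):
        return None
    if context3[1] != ref:
        raise ContextMismatchError(
            f"context middle base {context3[1]!r} does not match ref {ref!r}"
        )
    if ref in "AG":
        context3 = revcomp(context3)
    return f"{context3[0]}[{sub}]{context3[2]}"


@dataclass
class Spectrum:
    """Absolute 6-class and 96-channel mutation counts for one sample.

    ``counts6`` counts every classifiable SNV; ``counts96`` only those with an
    unambiguous full trinucleotide context, so ``counts6`` marginalizes
    ``counts96`` exactly when ``n_excluded`` is zero.
    """

    sample_id: str
    counts96: np.ndarray
    counts6: np.ndarray
    n_excluded: int = 0

    def __post_init__(self) -> None:
        self.counts96 = np.asarray(self.counts96, dtype=np.int64)
        self.counts6 = np.asarray(self.counts6, dtype=np.int64)
        if self.counts96.shape != (96,):
            raise ValueError("counts96 must have exactly 96 entries")
        if self.counts6.shape != (6,):
            raise ValueError("counts6 must have exactly 6 entries")
        if (self.counts96 < 0).any() or (self.counts6 < 0).any():
            raise ValueError("spectrum counts must be non-negative")

    @property
    def ca_fraction(self) -> float:
        """Fraction of classified substitutions that are C>A."""
        total = int(self.counts6.sum())
        return float(self.counts6[0] / total) if total else 0.0


@dataclass
class RelativeSpectrum:
    sample_id: str
    freq96: np.ndarray
    freq6: np.ndarray
    zero96: bool = False  #: counts96 summed to zero; freq96 is all-zero
    zero6: bool = False

    def __post_init__(self) -> None:
        self.freq96 = np.asarray(self.freq96, dtype=float)
        self.freq6 = np.asarray(self.freq6, dtype=float)


def _codes(values: pd.Series | np.ndarray) -> np.ndarray:
    """Base letters -> codes A=0,C=1,G=2,T=3; anything else -> 4."""
    arr = np.asarray(values, dtype="U1")
    out = np.full(arr.shape, 4, dtype=np.int64)
    for base, code in _BASE_CODE.items():
        out[arr == base] = code
    return out


def classify_codes(ref_codes: np.ndarray, alt_codes: np.ndarray) -> np.ndarray:
    """Vectorized 6-class index for coded base arrays; -1 where unclassifiable."""
    ref = ref_codes.copy()
    alt = alt_codes.copy()
    valid = (ref < 4) & (alt < 4) & (ref != alt)
    purine = valid & ((ref == 0) | (ref == 2))
    ref[purine] = 3 - ref[purine]
    alt[purine] = 3 - alt[purine]
    out = np.full(ref.shape, -1, dtype=np.int64)
    out[valid] = _SUB_IDX[ref[valid], alt[valid]]
    return out


def channel_codes(
    left: np.ndarray, ref: np.ndarray, right: np.ndarray, alt: np.ndarray
) -> np.ndarray:
    """Vectorized 96-channel index; -1 where context or substitution is invalid.

    ``left``/``right`` are the 5'/3' flanking base codes on the reference
    strand; purine-ref entries are reverse-complemented internally.
    """
    sub = classify_codes(ref, alt)
    l, r = left.copy(), right.copy()
    purine = (ref == 0) | (ref == 2)
    lp = l[purine]
    l[purine] = np.where(r[purine] < 4, 3 - r[purine], 4)
    r[purine] = np.where(lp < 4, 3 - lp, 4)
    valid = (sub >= 0) & (l < 4) & (r < 4)
    out = np.full(ref.shape, -1, dtype=np.int64)
    out[valid] = 16 * sub[valid] + 4 * l[valid] + r[valid]
    return out


def build_spectrum(catalog, reference) -> Spectrum:
    """Count a catalog's SNVs into 6-class and 96-channel spectra.

    ``reference`` is a :class:`~oxosig.variant_io.ReferenceContextSource` (or
    anything exposing ``context_codes(chroms, positions)``).  Variants whose
    full context is unavailable (chromosome edge, N in context) or whose
    context middle base mismatches the recorded ref are excluded from
    ``counts96`` only and tallied in ``n_excluded``; context-mismatched
    variants are additionally dropped from ``counts6`` since their ref call is
    unreliable.
    """
    df = catalog.df
    if len(df) == 0:
        return Spectrum(catalog.sample_id, np.zeros(96, int), np.zeros(6, int), 0)

    ref_c = _codes(df["ref"].to_numpy())
    alt_c = _codes(df["alt"].to_numpy())
    left, mid, right = reference.context_codes(
        df["chrom"].to_numpy(), df["pos"].to_numpy(np.int64)
    )

    mismatch = (mid < 4) & (ref_c < 4) & (mid != ref_c)
    n_mismatch = int(mismatch.sum())
    if n_mismatch:
        logger.warning(
            "%s: %d variant(s) with reference-context mismatch dropped",
            catalog.sample_id,
            n_mismatch,
        )

    sub6 = classify_codes(ref_c, alt_c)
    sub6[mismatch] = -1
    ch96 = channel_codes(left, ref_c, right, alt_c)
    ch96[mismatch] = -1

    counts6 = np.bincount(sub6[sub6 >= 0], minlength=6)
    counts96 = np.bincount(ch96[ch96 >= 0], minlength=96)
    n_excluded = int(((sub6 >= 0) & (ch96 < 0)).sum())
    return Spectrum(catalog.sample_id, counts96, counts6, n_excluded)


def relative_spectrum(spectrum: Spectrum) -> RelativeSpectrum:
    """Raw observation fractions of the 6-class and 96-channel counts.

    A zero count vector is returned as all zeros with a flag rather than NaN.
    """
    t96 = spectrum.counts96.sum()
    t6 = spectrum.counts6.sum()
    freq96 = spectrum.counts96 / t96 if t96 else np.zeros(96)
    freq6 = spectrum.counts6 / t6 if t6 else np.zeros(6)
    return RelativeSpectrum(
        spectrum.sample_id, freq96, freq6, zero96=t96 == 0, zero6=t6 == 0
    )


def spectra_frame(spectra: list[Spectrum], relative: bool = False) -> pd.DataFrame:
    """Samples x channels table of 96-channel counts (or fractions)."""
    rows = {}
    for s in spectra:
        if relative:
            rows[s.sample_id] = relative_spectrum(s).freq96
        else:
            rows[s.sample_id] = s.counts96
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(CHANNELS_96))
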