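"""Substitution classification, trinucleotide channels, and spectrum building."""

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from oxosig.spectra import (
    CHANNELS_96,
    SUB_CLASSES,
    ClassificationError,
    ContextMismatchError,
    Spectrum,
    build_spectrum,
    classify_substitution,
    relative_spectrum,
    revcomp,
    trinucleotide_channel,
)
from oxosig.synthetic import ContextIndex, place_channel_draws
from oxosig.variant_io import MutationCatalog, SomaticVariant

BASES = "ACGT"


@pytest.mark.parametrize(
    "ref,alt,expected",
    [
        ("C", "A", "C>A"),
        ("G", "T", "C>A"),  # purine strand collapses to pyrimidine
        ("A", "C", "T>G"),
        ("T", "G", "T>G"),
        ("C", "T", "C>T"),
        ("G", "A", "C>T"),
        ("A", "G", "T>C"),
        ("T", "A", "T>A"),
    ],
)
def test_pyrimidine_strand_classification(ref, alt, expected):
    assert classify_substitution(ref, alt) == expected


@pytest.mark.parametrize("ref,alt", [("C", "C"), ("N", "A"), ("C", "N"), ("c", "a")])
def test_classification_rejects_invalid_bases(ref, alt):
    with pytest.raises(ClassificationError):
        classify_substitution(ref, alt)


@given(
    st.sampled_from(BASES),
    st.sampled_from(BASES),
    st.sampled_from(BASES),
    st.sampled_from(BASES),
)
@settings(deadline=None)
def test_strand_involution(left, ref, right, alt):
    """A variant and its reverse-complement representation share one channel."""
    if ref == alt:
        return
    ctx = left + ref + right
    fwd = trinucleotide_channel(ctx, ref, alt)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    rev = trinucleotide_channel(revcomp(ctx), comp[ref], comp[alt])
    assert fwd == rev
    assert fwd in CHANNELS_96


@pytest.mark.parametrize(
    "ctx,ref,alt,expected",
    [
        ("ACA", "C", "A", "A[C>A]A"),
        ("TGT", "G", "T", "A[C>A]A"),  # reverse complement of TGT is ACA
        ("GCT", "C", "G", "G[C>G]T"),
    ],
)
def test_trinucleotide_channel(ctx, ref, alt, expected):
    assert trinucleotide_channel(ctx, ref, alt) == expected


def test_ambiguous_context_excluded():
    assert trinucleotide_channel("ACN", "C", "T") is None
    assert trinucleotide_channel("NCA", "C", "T") is None


def test_context_middle_mismatch_raises():
    with pytest.raises(ContextMismatchError):
        trinucleotide_channel("AAA", "C", "T")


def test_canonical_channel_order():
    assert len(CHANNELS_96) == 96
    assert CHANNELS_96[0] == "A[C>A]A"
    assert CHANNELS_96[1] == "A[C>A]C"
    assert CHANNELS_96[4] == "C[C>A]A"
    assert CHANNELS_96[16] == "A[C>G]A"
    assert CHANNELS_96[95] == "T[T>G]T"
    blocks = [ch[2:5] for ch in CHANNELS_96]
    assert blocks == [s for s in SUB_CLASSES for _ in range(16)]


def _catalog_on_reference(reference, channel_counts, seed=1):
    """Place given per-channel counts onto the session reference genome."""
    index = ContextIndex(reference)
    rng = np.random.default_rng(seed)
    channel_ids = np.repeat(np.arange(96), channel_counts)
    df = place_channel_draws(channel_ids, index, rng)
    return MutationCatalog("T1", df)


def test_build_spectrum_counts_classes(reference):
    counts = np.zeros(96, dtype=int)
    counts[0] = 3  # A[C>A]A
    counts[32] = 1  # A[C>T]A
    catalog = _catalog_on_reference(reference, counts)
    spectrum = build_spectrum(catalog, reference)
    assert spectrum.counts6.tolist() == [3, 0, 1, 0, 0, 0]
    assert spectrum.counts96.sum() == 4
    assert spectrum.n_excluded == 0


def test_empty_catalog_gives_zero_spectrum(reference):
    spectrum = build_spectrum(MutationCatalog("E"), reference)
    assert spectrum.counts6.sum() == 0
    assert spectrum.counts96.sum() == 0
    rel = relative_spectrum(spectrum)
    assert rel.zero6 and rel.zero96
    assert not rel.freq6.any()


def test_edge_variant_excluded_from_96_only(reference):
    """A variant at position 1 has no 5' context: dropped from counts96 only."""
    codes = "ACGT"
    first = codes[reference._chrom_codes("1")[0]]
    alt = "A" if first != "A" else "C"
    catalog = MutationCatalog.from_variants("edge", [SomaticVariant("1", 1, first, alt)])
    spectrum = build_spectrum(catalog, reference)
    assert spectrum.counts6.sum() == 1
    assert spectrum.counts96.sum() == 0
    assert spectrum.n_excluded == 1


def test_uniform_channels_within_binomial_bounds(reference):
    """1000 uniform-channel draws: each channel within binomial 99.9% bounds.

    Oracle: two-sided binomial(1000, 1/96) quantiles, Bonferroni-style wide
    band so the deterministic seed passes with margin.
    """
    rng = np.random.default_rng(77)
    draws = rng.integers(0, 96, size=1000)
    channel_counts = np.bincount(draws, minlength=96)
    catalog = _catalog_on_reference(reference, channel_counts, seed=78)
    spectrum = build_spectrum(catalog, reference)
    lo = scipy.stats.binom.ppf(0.0005, 1000, 1 / 96)
    hi = scipy.stats.binom.ppf(0.9995, 1000, 1 / 96)
    # placement dedup can shave a few counts; compare against the drawn counts
    assert (spectrum.counts96 <= channel_counts).all()
    assert (channel_counts - spectrum.counts96).sum() <= 10
    assert (spectrum.counts96 >= lo - 3).all() and (spectrum.counts96 <= hi).all()


def test_marginalization_of_96_onto_6(reference):
    counts = np.zeros(96, dtype=int)
    rng = np.random.default_rng(5)
    counts[rng.integers(0, 96, size=40)] += 5
    catalog = _catalog_on_reference(reference, counts, seed=6)
    spectrum = build_spectrum(catalog, reference)
    assert spectrum.n_excluded == 0
    marg = spectrum.counts96.reshape(6, 16).sum(axis=1)
    assert (marg == spectrum.counts6).all()
    rel = relative_spectrum(spectrum)
    np.testing.assert_allclose(rel.freq96.reshape(6, 16).sum(axis=1), rel.freq6, atol=1e-12)


def test_relative_spectrum_fractions():
    spectrum = Spectrum("s", np.zeros(96, int), np.array([3, 0, 1, 0, 0, 0]))
    rel = relative_spectrum(spectrum)
    np.testing.assert_allclose(rel.freq6, [0.75, 0, 0.25, 0, 0, 0])
    assert rel.freq6.sum() == pytest.approx(1.0, abs=1e-9)
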