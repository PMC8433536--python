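"""The synthetic study generator: determinism, placement fidelity, truth tables."""

import numpy as np
import pytest
import scipy.stats

from oxosig.signatures import cosine_similarity
from oxosig.spectra import build_spectrum, relative_spectrum
from oxosig.synthetic import (
    CloneSpec,
    CohortSpec,
    ContextIndex,
    GROUP_WEIGHTS,
    make_reference,
    mixture_channel_probs,
    place_channel_draws,
    pseudo_signature_matrix,
    simulate_clonal_pairs,
    simulate_cohort,
    simulate_survival_times,
    write_cohort,
)
from oxosig.variant_io import ReferenceContextSource


def test_make_reference_deterministic(tmp_path):
    a = make_reference(tmp_path / "a.fa", 1, 5000, seed=7)
    b = make_reference(tmp_path / "b.fa", 1, 5000, seed=7)
    assert a.read_bytes() == b.read_bytes()
    c = make_reference(tmp_path / "c.fa", 1, 5000, seed=8)
    assert a.read_bytes() != c.read_bytes()


def test_make_reference_min_length(tmp_path):
    with pytest.raises(ValueError):
        make_reference(tmp_path / "x.fa", 1, 2, seed=1)
    path = make_reference(tmp_path / "x.fa", 1, 3, seed=1)
    ref = ReferenceContextSource(path)
    assert len(ref.lookup("1", 2)) == 3


def test_reference_gc_content_binomial_bounds(tmp_path):
    """Uniform base model: GC of a 200 kb genome within ±4 binomial SD of 0.5."""
    path = make_reference(tmp_path / "gc.fa", 1, 200_000, seed=3)
    ref = ReferenceContextSource(path)
    codes = ref._chrom_codes("1")
    gc = ((codes == 1) | (codes == 2)).mean()
    sd = 0.5 / np.sqrt(200_000)
    assert abs(gc - 0.5) < 4 * sd


def test_pseudo_signature_matrix_properties(matrix):
    assert matrix.P.shape == (96, 5)
    np.testing.assert_allclose(matrix.P.sum(axis=0), 1.0, atol=1e-9)
    ca = {n: matrix.column(n)[:16].sum() for n in matrix.names}
    assert ca["PS18"] > 0.8 and ca["PS36"] > 0.8  # the two C>A-dominant ones
    assert ca["PS1"] < 0.1
    # distinguishable: no two signatures nearly identical
    for i, a in enumerate(matrix.names):
        for b in matrix.names[i + 1 :]:
            assert cosine_similarity(matrix.column(a), matrix.column(b)) < 0.95


def test_group_mixture_ca_masses(matrix):
    """Generator defaults: CNL-like mixtures ~0.55 C>A mass, WT-like ~0.27."""
    for group, expected in [("WT", 0.27), ("MUTYH_CNL", 0.55), ("OGG1_CNL", 0.55)]:
        probs = mixture_channel_probs(GROUP_WEIGHTS[group], matrix)
        assert probs[:16].sum() == pytest.approx(expected, abs=0.02)


def test_placement_matches_channel_context(reference, matrix, rng):
    """Placed variants, re-classified from the genome, recover their channel."""
    index = ContextIndex(reference)
    channel_ids = rng.integers(0, 96, size=500)
    df = place_channel_draws(channel_ids, index, rng)
    from oxosig.variant_io import MutationCatalog

    catalog = MutationCatalog("place", df)
    spectrum = build_spectrum(catalog, reference)
    drawn = np.bincount(channel_ids, minlength=96)
    assert spectrum.n_excluded == 0
    assert (spectrum.counts96 <= drawn).all()  # dedup can only shave
    assert spectrum.counts96.sum() >= 0.98 * len(channel_ids)


def test_unsatisfiable_channel_raises(tmp_path):
    path = make_reference(tmp_path / "tiny.fa", 1, 3, seed=1)
    ref = ReferenceContextSource(path)
    index = ContextIndex(ref)  # only one context exists in a 3-base genome
    from oxosig.synthetic import UnsatisfiableChannelError, _channel_sites

    # find a channel whose fwd and rev contexts are both absent
    for ch in range(96):
        fwd, rev, _, _ = _channel_sites(ch)
        if len(index.positions_for(fwd)[0]) == 0 and len(index.positions_for(rev)[0]) == 0:
            with pytest.raises(UnsatisfiableChannelError):
                place_channel_draws(np.array([ch]), index, np.random.default_rng(0))
            return
    pytest.skip("3-base genome unexpectedly covers all contexts")


def test_cohort_ca_fraction_binomial_bounds(reference, matrix):
    """A CNL mixture at ~0.55 C>A mass, 2000 draws: observed within ±0.03."""
    probs = mixture_channel_probs(GROUP_WEIGHTS["OGG1_CNL"], matrix)
    rng = np.random.default_rng(5)
    index = ContextIndex(reference)
    channel_ids = rng.choice(96, size=2000, p=probs)
    df = place_channel_draws(channel_ids, index, rng)
    from oxosig.variant_io import MutationCatalog

    spectrum = build_spectrum(MutationCatalog("x", df), reference)
    rel = relative_spectrum(spectrum)
    assert rel.freq6[0] == pytest.approx(probs[:16].sum(), abs=0.03)


def test_large_sample_spectrum_matches_mixture(reference, matrix):
    """Empirical 96-spectrum of a 10,000-mutation sample: cosine >= 0.98."""
    probs = mixture_channel_probs(GROUP_WEIGHTS["WT"], matrix)
    rng = np.random.default_rng(11)
    index = ContextIndex(reference)
    channel_ids = rng.choice(96, size=10_000, p=probs)
    df = place_channel_draws(channel_ids, index, rng)
    from oxosig.variant_io import MutationCatalog

    spectrum = build_spectrum(MutationCatalog("big", df), reference)
    assert cosine_similarity(spectrum.counts96, probs) >= 0.98


def test_cohort_determinism_and_files(tmp_path, reference, matrix):
    spec = CohortSpec(n_samples=6, seed=21)
    a = simulate_cohort(spec, reference, matrix)
    b = simulate_cohort(spec, reference, matrix)
    assert a.truth.equals(b.truth)
    assert all(x == y for x, y in zip(a.catalogs, b.catalogs))
    paths_a = write_cohort(a, tmp_path / "runA")
    paths_b = write_cohort(b, tmp_path / "runB")
    for key in ("cbs", "clinical", "truth"):
        assert paths_a[key].read_bytes() == paths_b[key].read_bytes()
    vcf_a = sorted(paths_a["vcf_dir"].glob("*.vcf"))
    assert len(vcf_a) == 6
    for pa in vcf_a:
        assert pa.read_bytes() == (paths_b["vcf_dir"] / pa.name).read_bytes()


def test_cohort_truth_consistency(reference, matrix):
    spec = CohortSpec(n_samples=8, seed=33)
    cohort = simulate_cohort(spec, reference, matrix)
    truth = cohort.truth
    assert len(truth) == 8
    assert set(truth["group"]) <= {"WT", "MUTYH_CNL", "OGG1_CNL", "BOTH"}
    # CBS scores respect group labels through the strict -0.5 cutoff
    from oxosig.cn_groups import assign_groups, call_cnl

    calls = call_cnl([r for r in cohort.cbs_records if r.gene in ("MUTYH", "OGG1")])
    groups = assign_groups(calls)
    assert groups == dict(zip(truth["sample_id"], truth["group"]))
    # survival records carry the true C>A fraction as covariate
    for rec, (_, row) in zip(cohort.survival_records, truth.iterrows()):
        assert rec.covariates["ca_fraction"] == pytest.approx(row["ca_fraction_true"])


def test_null_survival_is_independent_of_covariate():
    """With beta=0 the hazard ignores the C>A fraction by construction."""
    rng = np.random.default_rng(1)
    ca = rng.uniform(0.1, 0.8, size=4000)
    time, event = simulate_survival_times(ca, rng, beta=0.0, h0=0.01)
    high, low = time[ca > 0.45], time[ca <= 0.45]
    # equal exponential scale in both halves: medians agree within 10%
    assert abs(np.median(high) - np.median(low)) / np.median(low) < 0.1


def test_clonal_pairs_superset_and_poisson(reference, matrix):
    spec = CloneSpec(seed=9, clone_background=300.0)
    pairs, truth = simulate_clonal_pairs(spec, reference, matrix)
    assert len(pairs) == 2 * len(spec.genotype_weights)
    for pair, (_, row) in zip(pairs, truth.iterrows()):
        assert 88 <= pair.days <= 126
        assert pair.clone.variant_keys() <= pair.subclone.variant_keys()
        drawn = row["n_accrued_drawn"]
        lam = row["rate_true"] * pair.days
        assert abs(drawn - lam) <= 4 * np.sqrt(lam)


def test_cohort_spec_validation():
    with pytest.raises(ValueError):
        CohortSpec(frac_mutyh_cnl=0.7, frac_ogg1_cnl=0.5)
    with pytest.raises(ValueError):
        CloneSpec(days_low=0)
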