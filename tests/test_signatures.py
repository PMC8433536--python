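"""NNLS refitting, strict backward elimination, cosine similarity, clustering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oxosig.signatures import (
    SignatureMatrix,
    ZeroSpectrumError,
    cluster_by_contributions,
    cosine_similarity,
    dominant_signature,
    nnls_refit,
    strict_refit,
)


def test_cosine_hand_values():
    u = np.zeros(96); u[0] = 1
    v = np.zeros(96); v[0] = 1; v[1] = 1
    # by hand: 1 / (1 * sqrt(2))
    assert cosine_similarity(u, v) == pytest.approx(0.70710678, abs=1e-8)
    assert cosine_similarity(u, u) == pytest.approx(1.0, abs=1e-12)
    w = np.zeros(96); w[2] = 5
    assert cosine_similarity(u, w) == 0.0


def test_cosine_zero_vector_error():
    with pytest.raises(ZeroSpectrumError):
        cosine_similarity(np.zeros(96), np.ones(96))


@given(st.floats(min_value=0.01, max_value=100.0))
@settings(deadline=None)
def test_cosine_scale_invariance(scale):
    rng = np.random.default_rng(9)
    u = rng.random(96)
    v = rng.random(96)
    assert cosine_similarity(scale * u, v) == pytest.approx(cosine_similarity(u, v), abs=1e-9)


@pytest.fixture(scope="module")
def identity_like():
    """96 'signatures', each concentrated on one channel."""
    return SignatureMatrix(names=[f"E{i}" for i in range(96)], P=np.eye(96))


def test_nnls_identity_basis(identity_like, rng):
    m = rng.integers(0, 50, size=96).astype(float)
    c = nnls_refit(m, identity_like)
    np.testing.assert_allclose(c, m, atol=1e-9)


def test_nnls_recovers_known_mixture(matrix, rng):
    c_true = np.array([120.0, 0.0, 800.0, 55.0, 230.0])
    m = matrix.P @ c_true
    c = nnls_refit(m, matrix)
    np.testing.assert_allclose(c, c_true, atol=1e-6)


def test_nnls_unrepresentable_mass_residual():
    """Closed form: mass on a channel where all signatures are zero stays as
    residual; the representable part is fitted exactly."""
    P = np.zeros((96, 2))
    P[0, 0] = P[1, 1] = 1.0
    toy = SignatureMatrix(names=["a", "b"], P=P)
    m = np.zeros(96)
    m[0], m[1], m[2] = 3.0, 4.0, 5.0  # channel 2 unrepresentable
    c = nnls_refit(m, toy)
    residual = np.linalg.norm(m - P @ c)
    assert residual == pytest.approx(5.0, abs=1e-9)
    np.testing.assert_allclose(c, [3.0, 4.0], atol=1e-9)


def test_nnls_zero_spectrum_error(matrix):
    with pytest.raises(ZeroSpectrumError):
        nnls_refit(np.zeros(96), matrix)


def test_nnls_determinism(matrix, rng):
    m = rng.poisson(20, size=96).astype(float)
    c1 = nnls_refit(m, matrix)
    c2 = nnls_refit(m.copy(), matrix)
    assert (c1 == c2).all()


def test_residual_never_increases_with_more_signatures(matrix, rng):
    m = rng.poisson(30, size=96).astype(float)
    full = np.linalg.norm(m - matrix.P @ nnls_refit(m, matrix))
    for drop in matrix.names:
        sub = matrix.subset([n for n in matrix.names if n != drop])
        r = np.linalg.norm(m - sub.P @ nnls_refit(m, sub))
        assert full <= r + 1e-9


def test_strict_refit_noiseless_support(matrix):
    """A noiseless 2-signature mixture: retained ⊆ true support, cosine = 1."""
    c_true = np.zeros(5)
    c_true[matrix.names.index("PS18")] = 700.0
    c_true[matrix.names.index("PS1")] = 300.0
    m = matrix.P @ c_true
    result = strict_refit(m, matrix)
    assert set(result.retained) <= {"PS18", "PS1"}
    assert result.recon_cosine >= 1 - 1e-9
    for name, contrib in zip(result.signature_names, result.contributions):
        if name not in result.retained:
            assert contrib == 0.0
    assert result.relative_contributions.sum() == pytest.approx(1.0)


def test_strict_refit_max_delta_zero(matrix):
    """Strictest setting: only lossless removals allowed."""
    rng = np.random.default_rng(12)
    m = rng.poisson(matrix.P @ np.array([200.0, 200, 200, 200, 200]))
    m = m.astype(float)
    full = nnls_refit(m, matrix)
    result = strict_refit(m, matrix, max_delta=0.0)
    cos_full = cosine_similarity(m, matrix.P @ full)
    assert result.recon_cosine >= cos_full - 1e-12


def test_strict_refit_single_signature():
    P = np.full((96, 1), 1 / 96)
    single = SignatureMatrix(names=["only"], P=P)
    result = strict_refit(np.ones(96) * 5, single)
    assert result.retained == ["only"]
    assert result.relative_contributions[0] == pytest.approx(1.0)


def test_dominant_signature_and_ties(matrix):
    from oxosig.signatures import RefitResult

    r = RefitResult("s", ["SBS1", "SBS18"], np.array([0.2, 0.8]), ["SBS1", "SBS18"], 1.0)
    assert dominant_signature(r) == ("SBS18", False)
    tie = RefitResult("s", ["SBS18", "SBS36"], np.array([0.5, 0.5]), ["SBS18", "SBS36"], 1.0)
    name, flagged = dominant_signature(tie)
    assert name == "SBS18" and flagged


def _refits_from(matrix, weights_list, seed=0, n=3000):
    from oxosig.signatures import RefitResult

    rng = np.random.default_rng(seed)
    out = []
    for i, w in enumerate(weights_list):
        probs = matrix.P @ np.asarray(w)
        m = rng.multinomial(n, probs).astype(float)
        out.append(strict_refit(m, matrix, sample_id=f"s{i}"))
    return out


def test_cluster_identical_vectors_merge_at_zero(matrix):
    from oxosig.signatures import RefitResult

    refits = [
        RefitResult(f"s{i}", matrix.names, np.array([0.5, 0.5, 0, 0, 0]), matrix.names, 1.0)
        for i in range(2)
    ]
    clustering = cluster_by_contributions(refits)
    assert clustering.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)
    assert clustering.similarity.to_numpy()[0, 1] == pytest.approx(1.0)


def test_cluster_two_mixtures_recovered(matrix):
    """Samples from C>A-dominant vs CpG-dominant mixtures split cleanly at k=2."""
    w18 = [0.1, 0.1, 0.7, 0.0, 0.1]  # PS18-dominant (names PS1,PS5,PS18,PS36,PS40)
    w1 = [0.7, 0.1, 0.1, 0.0, 0.1]  # PS1-dominant
    refits = _refits_from(matrix, [w18] * 5 + [w1] * 5, seed=4)
    clustering = cluster_by_contributions(refits)
    labels = clustering.cut(2)
    first = {labels[f"s{i}"] for i in range(5)}
    second = {labels[f"s{i}"] for i in range(5, 10)}
    assert len(first) == 1 and len(second) == 1 and first != second


def test_cluster_permutation_invariant(matrix):
    refits = _refits_from(matrix, [[0.2, 0.2, 0.2, 0.2, 0.2]] * 4 + [[0.0, 0.0, 1.0, 0.0, 0.0]] * 3, seed=8)
    a = cluster_by_contributions(refits)
    perm = [refits[i] for i in [3, 0, 6, 1, 5, 2, 4]]
    b = cluster_by_contributions(perm)
    assert a.cut(2) == b.cut(2)
    assert sorted(a.leaf_order) == sorted(b.leaf_order)


def test_cluster_requires_two_samples(matrix):
    refits = _refits_from(matrix, [[0.2, 0.2, 0.2, 0.2, 0.2]])
    with pytest.raises(ValueError):
        cluster_by_contributions(refits)


def test_newick_export(matrix):
    refits = _refits_from(matrix, [[1, 0, 0, 0, 0], [0, 1, 0, 0, 0], [0, 0, 1, 0, 0]], seed=2)
    tree = cluster_by_contributions(refits).to_newick()
    assert tree.count("(") >= 1
    for refit in refits:
        assert refit.sample_id in tree


def test_similarity_matrix_symmetric_unit_diagonal(matrix):
    refits = _refits_from(matrix, [[0.5, 0.5, 0, 0, 0], [0, 0, 0.5, 0.5, 0], [0.2] * 5], seed=3)
    S = cluster_by_contributions(refits).similarity.to_numpy()
    np.testing.assert_allclose(S, S.T, atol=1e-12)
    np.testing.assert_allclose(np.diag(S), 1.0, atol=1e-12)
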