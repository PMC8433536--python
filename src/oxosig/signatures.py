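"""Signature refitting by non-negative least squares, and contribution clustering.

An observed 96-channel spectrum m is decomposed as m ≈ P·c with c ≥ 0, where
the columns of P are known single-base-substitution signatures (probability
distributions over the 96 channels).  The strict refit then prunes
low-contributing signatures by greedy backward elimination: the signature
with the smallest contribution is tentatively dropped and the removal is kept
while the cosine similarity between the observed spectrum and its
reconstruction falls by less than ``max_delta`` (default 0.004) relative to
the previously accepted model.  De novo signature extraction is out of scope;
only refitting against a given matrix is supported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.optimize

from .spectra import CHANNELS_96


class ZeroSpectrumError(ValueError):
    """Refit or similarity requested for an all-zero vector."""


@dataclass
class SignatureMatrix:
    """96 x K per-channel signature probabilities, one column per signature."""

    names: list[str]
    P: np.ndarray
    channels: tuple[str, ...] = CHANNELS_96

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        if self.P.shape != (96, len(self.names)):
            raise ValueError(
                f"signature matrix must be 96 x {len(self.names)}, got {self.P.shape}"
            )
        neg = np.argwhere(self.P < 0)
        if len(neg):
            r, c = neg[0]
            raise ValueError(
                f"negative entry at channel {self.channels[r]!r}, signature {self.names[c]!r}"
            )
        sums = self.P.sum(axis=0)
        bad = np.flatnonzero(np.abs(sums - 1.0) > 1e-6)
        if len(bad):
            raise ValueError(
                f"signature column {self.names[bad[0]]!r} sums to {sums[bad[0]]:.6g}, not 1"
            )

    @property
    def k(self) -> int:
        return len(self.names)

    def subset(self, names: list[str]) -> "SignatureMatrix":
        idx = [self.names.index(n) for n in names]
        return SignatureMatrix(names=list(names), P=self.P[:, idx])

    def column(self, name: str) -> np.ndarray:
        return self.P[:, self.names.index(name)]


@dataclass
class RefitResult:
    """Outcome of (strict) signature refitting for one sample.

    ``contributions`` are in mutation-count units (the fit is against absolute
    counts); ``relative_contributions`` normalize them to sum 1.  Signatures
    eliminated during the strict refit have contribution exactly 0.
    """

    sample_id: str
    signature_names: list[str]
    contributions: np.ndarray
    retained: list[str]
    recon_cosine: float

    def __post_init__(self) -> None:
        self.contributions = np.asarray(self.contributions, dtype=float)

    @property
    def relative_contributions(self) -> np.ndarray:
        total = self.contributions.sum()
        return self.contributions / total if total > 0 else np.zeros_like(self.contributions)


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """dot(u, v) / (‖u‖‖v‖); in [0, 1] for non-negative inputs."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ZeroSpectrumError("cosine similarity undefined for a zero vector")
    return float(u @ v / (nu * nv))


def nnls_refit(spectrum_counts: np.ndarray, matrix: SignatureMatrix) -> np.ndarray:
    """Non-negative least squares fit of signature contributions.

    Solved with the Lawson–Hanson active-set algorithm, so the result is the
    exact KKT solution and deterministic for fixed input.
    """
    m = np.asarray(spectrum_counts, dtype=float)
    if m.shape != (96,):
        raise ValueError("spectrum must be a 96-vector")
    if not m.any():
        raise ZeroSpectrumError("cannot refit an all-zero spectrum")
    c, _ = scipy.optimize.nnls(matrix.P, m)
    return c


def strict_refit(
    spectrum_counts: np.ndarray,
    matrix: SignatureMatrix,
    max_delta: float = 0.004,
    min_relative: float = 0.0,
    sample_id: str = "",
) -> RefitResult:
    """Refit with greedy backward elimination of low-contributing signatures.

    After each tentative removal of the lowest-contributing retained
    signature the spectrum is refitted; the removal is accepted while the
    reconstruction cosine drops by less than ``max_delta`` from the
    previously accepted model.  ``min_relative`` optionally zeroes signatures
    whose final relative contribution falls below a floor (off by default).
    """
    m = np.asarray(spectrum_counts, dtype=float)
    c = nnls_refit(m, matrix)
    retained = list(matrix.names)
    cos = cosine_similarity(m, matrix.P @ c)

    while len(retained) > 1:
        drop = retained[int(np.argmin(c))]
        trial_names = [n for n in retained if n != drop]
        trial = matrix.subset(trial_names)
        c_trial, _ = scipy.optimize.nnls(trial.P, m)
        recon = trial.P @ c_trial
        cos_trial = cosine_similarity(m, recon) if recon.any() else 0.0
        if cos - cos_trial < max_delta:
            retained = trial_names
            c = c_trial
            cos = cos_trial
        else:
            break

    full = np.zeros(matrix.k)
    for name, value in zip(retained, c):
        full[matrix.names.index(name)] = value

    if min_relative > 0 and full.sum() > 0:
        rel = full / full.sum()
        keep = [n for n, r in zip(matrix.names, rel) if r >= min_relative and full[matrix.names.index(n)] > 0]
        if keep and keep != retained:
            sub = matrix.subset(keep)
            c_sub, _ = scipy.optimize.nnls(sub.P, m)
            full = np.zeros(matrix.k)
            for name, value in zip(keep, c_sub):
                full[matrix.names.index(name)] = value
            retained = keep
            cos = cosine_similarity(m, sub.P @ c_sub)

    retained = [n for n in matrix.names if n in retained]
    return RefitResult(
        sample_id=sample_id,
        signature_names=list(matrix.names),
        contributions=full,
        retained=retained,
        recon_cosine=cos,
    )


def dominant_signature(refit: RefitResult) -> tuple[str, bool]:
    """Name of the signature with the highest relative contribution.

    Ties are broken by signature-name order in the matrix; the second return
    value flags a tie.
    """
    rel = refit.relative_contributions
    if not rel.any():
        raise ZeroSpectrumError("no positive contribution; dominant signature undefined")
    best = float(rel.max())
    winners = [n for n, r in zip(refit.signature_names, rel) if np.isclose(r, best, atol=1e-12)]
    return winners[0], len(winners) > 1


@dataclass
class ContributionClustering:
    """Hierarchical clustering of samples on relative signature contributions."""

    sample_ids: list[str]
    contributions: pd.DataFrame  #: samples x signatures relative contributions
    linkage: np.ndarray
    leaf_order: list[str]
    similarity: pd.DataFrame  #: pairwise cosine similarity of contribution vectors

    def cut(self, k: int) -> dict[str, int]:
        """Flat cluster labels (1..k) from cutting the tree into k clusters."""
        labels = sch.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.sample_ids, (int(x) for x in labels)))

    def to_newick(self) -> str:
        from skbio.tree import TreeNode

        tree = TreeNode.from_linkage_matrix(self.linkage, self.sample_ids)
        return str(tree)


def cluster_by_contributions(
    refits: list[RefitResult],
    method: str = "complete",
    metric: str = "euclidean",
) -> ContributionClustering:
    """Agglomerative clustering of samples by relative contribution vectors.

    Defaults to Euclidean distance with complete linkage; both configurable.
    Leaf order is deterministic given the input order.
    """
    if len(refits) < 2:
        raise ValueError("clustering needs at least 2 samples")
    ids = [r.sample_id for r in refits]
    X = np.vstack([r.relative_contributions for r in refits])
    Z = sch.linkage(X, method=method, metric=metric)
    order = [ids[i] for i in sch.leaves_list(Z)]
    norms = np.linalg.norm(X, axis=1)
    safe = np.where(norms == 0, 1.0, norms)
    S = (X @ X.T) / np.outer(safe, safe)
    np.fill_diagonal(S, 1.0)
    sim = pd.DataFrame(S, index=ids, columns=ids)
    contrib = pd.DataFrame(X, index=ids, columns=refits[0].signature_names)
    return ContributionClustering(ids, contrib, Z, order, sim)
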