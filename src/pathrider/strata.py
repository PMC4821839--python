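"""Population-stratification diagnostics from genotypes.

Identity-by-state (IBS) distances, complete-linkage agglomerative
clustering, and ancestry principal components (usable as covariates).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genio import GenotypeMatrix


@dataclass
class DistanceMatrix:
    subject_ids: list[str]
    values: np.ndarray  # n x n symmetric, zero diagonal, in [0, 1]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.subject_ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if np.abs(self.values - self.values.T).max() > 1e-12:
            raise ValueError("distance matrix not symmetric")
        if np.abs(np.diag(self.values)).max() != 0.0:
            raise ValueError("distance matrix diagonal must be exactly zero")


@dataclass
class AncestryComponents:
    subject_ids: list[str]
    component_scores: np.ndarray  # n x k
    eigenvalues: np.ndarray
    degenerate: bool = False


def ibs_matrix(G: GenotypeMatrix) -> DistanceMatrix:
    """Pairwise IBS distance: mean over mutually observed SNPs of |gi-gj|/2.

    This is 1 - IBS similarity in the PLINK sense for additively coded
    genotypes. Pairs sharing no observed SNP raise an error.
    """
    # dosage one-hots make |gi - gj| a sum of 9 cheap matrix products
    obs = ~G.missing_mask
    I = [((G.dosage == k) & obs).astype(float) for k in (0.0, 1.0, 2.0)]
    n_shared = obs.astype(float) @ obs.astype(float).T
    if np.any(n_shared == 0):
        raise ValueError("some subject pair shares no non-missing SNP")
    diff_sum = np.zeros_like(n_shared)
    for a in range(3):
        for b in range(3):
            w = abs(a - b) / 2.0
            if w:
                diff_sum += w * (I[a] @ I[b].T)
    D = diff_sum / n_shared
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(list(G.subject_ids), D)


def complete_linkage(
    D: DistanceMatrix, n_clusters: int
) -> tuple[np.ndarray, list[tuple[frozenset, frozenset, float]]]:
    """Agglomerative clustering with maximum (complete) linkage.

    Returns integer labels (0..n_clusters-1, numbered by order of each
    cluster's first subject) and the merge history as
    (members_a, members_b, height) tuples with non-decreasing heights.
    """
    n = len(D.subject_ids)
    if not 1 <= n_clusters <= n:
        raise ValueError(f"n_clusters must be in [1, {n}]")
    clusters: dict[int, set[int]] = {i: {i} for i in range(n)}
    dist = D.values.copy().astype(float)
    np.fill_diagonal(dist, np.inf)
    active = list(range(n))
    history: list[tuple[frozenset, frozenset, float]] = []
    while len(clusters) > n_clusters:
        sub = dist[np.ix_(active, active)]
        flat = np.argmin(sub)
        i_, j_ = np.unravel_index(flat, sub.shape)
        a, b = active[i_], active[j_]
        if a > b:
            a, b = b, a
        h = dist[a, b]
        history.append((frozenset(clusters[a]), frozenset(clusters[b]), h))
        clusters[a] |= clusters.pop(b)
        # complete linkage: distance to the merged cluster is the max
        for k in active:
            if k not in (a, b):
                dist[a, k] = dist[k, a] = max(dist[a, k], dist[b, k])
        active.remove(b)
        dist[b, :] = np.inf
        dist[:, b] = np.inf
    labels = np.empty(n, dtype=int)
    order = sorted(clusters.values(), key=min)
    for lab, members in enumerate(order):
        for m in members:
            labels[m] = lab
    return labels, history


def ancestry_pcs(
    G: GenotypeMatrix, k: int, basis: str = "ibs-distance"
) -> AncestryComponents:
    """Top-k ancestry principal components.

    basis "ibs-distance": classical scaling (double-centering of squared IBS
    distances) of the IBS distance matrix. basis "standardized-relationship":
    eigenvectors of Z Z^T / p with Z the per-SNP standardized dosage matrix.
    Each component is oriented so its score on the first subject is >= 0.
    """
    n = G.n_subjects
    if k > n:
        raise ValueError(f"k={k} exceeds number of subjects {n}")
    if G.missing_mask.any():
        raise ValueError("impute missing genotypes before ancestry PCA")
    if basis == "ibs-distance":
        D = ibs_matrix(G).values
        J = np.eye(n) - np.ones((n, n)) / n
        B = -0.5 * J @ (D**2) @ J
        eigval, eigvec = np.linalg.eigh((B + B.T) / 2.0)
    elif basis == "standardized-relationship":
        mean = G.dosage.mean(axis=0)
        sd = G.dosage.std(axis=0, ddof=0)
        keep = sd > 0
        Z = (G.dosage[:, keep] - mean[keep]) / sd[keep]
        K = Z @ Z.T / max(int(keep.sum()), 1)
        eigval, eigvec = np.linalg.eigh((K + K.T) / 2.0)
    else:
        raise ValueError(f"unknown basis {basis!r}")
    order = np.argsort(eigval)[::-1][:k]
    eigval = eigval[order]
    scores = eigvec[:, order] * np.sqrt(np.maximum(eigval, 0.0))
    for j in range(scores.shape[1]):
        if scores[0, j] < 0:
            scores[:, j] *= -1
    degenerate = bool(np.all(np.abs(eigval) < 1e-10 * n))
    return AncestryComponents(list(G.subject_ids), scores, eigval, degenerate)
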