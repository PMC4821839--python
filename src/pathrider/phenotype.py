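"""Covariate adjustment and PCA reduction of a multivariate phenotype."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class PhenotypeMatrix:
    subject_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray  # n x q, no missing values

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.subject_ids), len(self.feature_ids)):
            raise ValueError("values shape inconsistent with id lists")
        if not np.isfinite(self.values).all():
            raise ValueError("phenotype contains missing / non-finite values")


@dataclass
class ReducedPhenotype:
    subject_ids: list[str]
    component_scores: np.ndarray  # n x k
    component_loadings: np.ndarray  # k x q
    explained_variance: np.ndarray  # k eigenvalues, non-increasing
    k: int


def residualize(
    Y: PhenotypeMatrix, C: pd.DataFrame, which: list[str]
) -> PhenotypeMatrix:
    """Replace each phenotype column with its least-squares residual on
    intercept + the named covariates.

    The covariate table must carry a ``subject_id`` column; rows are aligned
    to the phenotype's subject order. Residuals are orthogonal to every
    selected covariate and to the intercept (so they are mean-centered).
    """
    missing = [w for w in which if w not in C.columns]
    if missing:
        raise ValueError(f"covariates not present: {missing}")
    C_idx = C.set_index(C["subject_id"].astype(str))
    try:
        rows = C_idx.loc[[str(s) for s in Y.subject_ids]]
    except KeyError as e:
        raise ValueError(f"covariate rows missing for subjects: {e}") from None
    X = np.column_stack(
        [np.ones(len(Y.subject_ids))] + [rows[w].to_numpy(dtype=float) for w in which]
    )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the first covariate whose addition does not raise the rank
        culprits = []
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, : j + 1]) == np.linalg.matrix_rank(X[:, :j]):
                culprits.append(which[j - 1])
        raise ValueError(f"rank-deficient covariate design; collinear: {culprits}")
    beta, *_ = np.linalg.lstsq(X, Y.values, rcond=None)
    resid = Y.values - X @ beta
    return PhenotypeMatrix(list(Y.subject_ids), list(Y.feature_ids), resid)


def select_components_elbow(eigenvalues) -> int:
    """Scree-plot elbow: 1-based index maximizing the perpendicular distance
    to the chord joining the first and last eigenvalue points.

    Ties (including flat or linear spectra) break toward the smallest index.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.size < 2:
        raise ValueError("need at least 2 eigenvalues")
    if (lam < 0).any():
        raise ValueError("eigenvalues must be non-negative")
    if (np.diff(lam) > 1e-12 * max(1.0, lam[0])).any():
        raise ValueError("eigenvalues must be non-increasing")
    m = lam.size
    x = np.arange(1, m + 1, dtype=float)
    # distance from (x, lam) to the line through (1, lam[0]) and (m, lam[-1])
    dx, dy = m - 1.0, lam[-1] - lam[0]
    norm = np.hypot(dx, dy)
    if norm == 0:
        return 1
    dist = np.abs(dy * (x - 1.0) - dx * (lam - lam[0])) / norm
    return int(np.argmax(dist)) + 1  # argmax returns the first maximizer


def pca_reduce(Y: PhenotypeMatrix, k="auto") -> ReducedPhenotype:
    """Column-centered SVD reduction to k components.

    ``k="auto"`` picks the scree elbow of the full eigenvalue spectrum.
    ``explained_variance`` holds squared singular values / (n - 1).
    """
    n, q = Y.values.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")
    Xc = Y.values - Y.values.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eig = s**2 / (n - 1)
    if k == "auto":
        k = select_components_elbow(eig)
    k = int(k)
    if k > min(n, q):
        raise ValueError(f"k={k} exceeds min(n, q)={min(n, q)}")
    # deterministic sign: make the largest-magnitude loading of each
    # component positive
    for j in range(k):
        pivot = np.argmax(np.abs(Vt[j]))
        if Vt[j, pivot] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    scores = U[:, :k] * s[:k]
    return ReducedPhenotype(
        subject_ids=list(Y.subject_ids),
        component_scores=scores,
        component_loadings=Vt[:k],
        explained_variance=eig[:k],
        k=k,
    )
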