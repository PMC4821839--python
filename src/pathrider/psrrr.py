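"""Rank-1 sparse reduced-rank regression with a pathway group penalty.

Fits Y ~ X b a^T with a group-lasso penalty on b over (possibly
duplicated-column) pathway groups, tunes per-pathway weights against the
selection bias observed under null responses, and ranks pathways by
stability selection over subject subsamples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genio import PathwayGroups


@dataclass
class PsRRRConfig:
    lambda_fraction: float = 0.99
    n_subsamples: int = 100
    subsample_fraction: float = 0.5
    tuning_iterations: int = 20
    tuning_fits_per_iteration: int = 200
    tuning_damping: float = 0.1
    max_alt_iterations: int = 30
    tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.lambda_fraction <= 1.0):
            raise ValueError("lambda_fraction must be in (0, 1]")
        if not (0.0 < self.tuning_damping <= 1.0):
            raise ValueError("tuning_damping must be in (0, 1]")
        for name in ("n_subsamples", "tuning_fits_per_iteration", "max_alt_iterations"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.tuning_iterations < 0:
            raise ValueError("tuning_iterations must be >= 0")
        if not (0.0 < self.subsample_fraction <= 1.0):
            raise ValueError("subsample_fraction must be in (0, 1]")


@dataclass
class PathwayWeights:
    group_ids: list[str]
    weights: np.ndarray  # positive, aligned with group_ids
    provenance: str = "initial"  # "initial" | "tuned"
    tuning_history: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if (self.weights <= 0).any():
            raise ValueError("pathway weights must be positive")


def initial_weights(groups: PathwayGroups) -> PathwayWeights:
    """sqrt(group size) weights, the usual group-lasso normalization."""
    return PathwayWeights(
        group_ids=list(groups.group_ids),
        weights=np.sqrt(groups.group_sizes.astype(float)),
    )


@dataclass
class RankOneFit:
    snp_coefficients: np.ndarray  # expanded design width
    trait_loadings: np.ndarray  # unit norm (zero vector if empty fit)
    selected_pathways: set[str]
    objective_trace: list[float]
    converged: bool


@dataclass
class SelectionFrequencies:
    group_ids: list[str]
    frequencies: np.ndarray  # in [0, 1]
    mean_abs_correlation: np.ndarray  # NaN where never selected
    n_subsamples: int


@dataclass
class PathwayRanking:
    group_ids: list[str]  # ordered, best first
    empirical_frequencies: np.ndarray
    null_frequencies: np.ndarray
    mean_abs_correlation: np.ndarray


# ---------------------------------------------------------------------------
# Group lasso solver (block proximal coordinate descent)


def _group_lipschitz(X: np.ndarray, groups: PathwayGroups) -> np.ndarray:
    L = np.empty(groups.n_groups)
    for gi, idx in enumerate(groups.group_index_lists):
        Xg = X[:, idx]
        if idx.size <= X.shape[0]:
            gram = Xg.T @ Xg
        else:
            gram = Xg @ Xg.T
        L[gi] = max(float(np.linalg.eigvalsh(gram)[-1]), 1e-12)
    return L


def group_lasso_objective(
    X: np.ndarray,
    y: np.ndarray,
    groups: PathwayGroups,
    weights: PathwayWeights,
    lam: float,
    b: np.ndarray,
) -> float:
    r = y - X @ b
    pen = sum(
        weights.weights[gi] * np.linalg.norm(b[idx])
        for gi, idx in enumerate(groups.group_index_lists)
    )
    return 0.5 * float(r @ r) + lam * pen


def group_lasso_solve(
    X: np.ndarray,
    y: np.ndarray,
    groups: PathwayGroups,
    weights: PathwayWeights,
    lam: float,
    max_iter: int = 2000,
    tol: float = 1e-10,
    L: np.ndarray | None = None,
) -> np.ndarray:
    """Minimize 0.5 ||y - X b||^2 + lam * sum_g w_g ||b_g||_2.

    Cyclic block proximal-gradient descent with per-group Lipschitz steps;
    handles rank-deficient (duplicated-column) groups. At the solution the
    KKT conditions hold: ||X_g^T r|| <= lam w_g for zero groups and
    X_g^T r = lam w_g b_g / ||b_g|| for active groups.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in X or y")
    if lam < 0:
        raise ValueError("lam must be >= 0")
    if L is None:
        L = _group_lipschitz(X, groups)
    b = np.zeros(groups.n_expanded)
    r = y.copy()
    w = weights.weights
    for _it in range(max_iter):
        max_change = 0.0
        for gi, idx in enumerate(groups.group_index_lists):
            Xg = X[:, idx]
            bg = b[idx]
            grad = Xg.T @ r  # gradient of -0.5||r||^2 wrt b_g is -grad
            active = np.linalg.norm(bg) > 0
            if not active and np.linalg.norm(grad) <= lam * w[gi]:
                continue  # exact zero-stationarity, skip
            u = bg + grad / L[gi]
            nu = np.linalg.norm(u)
            t = lam * w[gi] / L[gi]
            if nu <= t:
                new = np.zeros_like(bg)
            else:
                new = (1.0 - t / nu) * u
            delta = new - bg
            change = np.abs(delta).max() if delta.size else 0.0
            if change > 0:
                r -= Xg @ delta
                b[idx] = new
                max_change = max(max_change, change)
        if max_change <= tol * (1.0 + np.abs(b).max(initial=0.0)):
            break
    return b


def kkt_residual(
    X: np.ndarray,
    y: np.ndarray,
    groups: PathwayGroups,
    weights: PathwayWeights,
    lam: float,
    b: np.ndarray,
) -> float:
    """Relative KKT violation of a group-lasso solution (0 = exact)."""
    r = y - X @ b
    scale = max(lam, np.linalg.norm(X.T @ y, ord=np.inf), 1e-12)
    worst = 0.0
    for gi, idx in enumerate(groups.group_index_lists):
        grad = X[:, idx].T @ r
        bg = b[idx]
        nb = np.linalg.norm(bg)
        t = lam * weights.weights[gi]
        if nb == 0:
            worst = max(worst, max(np.linalg.norm(grad) - t, 0.0))
        else:
            worst = max(worst, np.linalg.norm(grad - t * bg / nb))
    return worst / scale


def lambda_max(
    X: np.ndarray, y: np.ndarray, groups: PathwayGroups, weights: PathwayWeights
) -> float:
    """Smallest lam for which b = 0 solves the group lasso."""
    return max(
        float(np.linalg.norm(X[:, idx].T @ y)) / weights.weights[gi]
        for gi, idx in enumerate(groups.group_index_lists)
    )


# ---------------------------------------------------------------------------
# Rank-1 alternating fit


def _leading_right_singular(Y: np.ndarray) -> np.ndarray:
    _, _, Vt = np.linalg.svd(Y, full_matrices=False)
    a = Vt[0]
    pivot = np.argmax(np.abs(a))
    return a if a[pivot] >= 0 else -a


def fit_rank1(
    X: np.ndarray,
    Y: np.ndarray,
    groups: PathwayGroups,
    weights: PathwayWeights,
    config: PsRRRConfig,
    L: np.ndarray | None = None,
) -> RankOneFit:
    """Alternating rank-1 fit of Y ~ X b a^T.

    b-step: group lasso on the scalarized response Y a at
    lam = lambda_fraction * lam_max(a); a-step: cross-covariance direction
    Y^T X b normalized to unit length. Stops on relative objective change
    < tol; if the objective would increase (lam is data-dependent), the
    previous iterate is kept. An all-zero b yields an empty selection.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if L is None:
        L = _group_lipschitz(X, groups)
    a = _leading_right_singular(Y) if Y.shape[1] > 1 else np.ones(1)
    b = np.zeros(groups.n_expanded)
    trace: list[float] = []
    converged = False
    prev_obj = np.inf
    yfro2 = float((Y**2).sum())

    def joint_objective(b_, a_, lam_) -> float:
        # 0.5 ||Y - X b a^T||_F^2 + lam * sum_g w_g ||b_g||
        z_ = X @ b_
        pen = sum(
            weights.weights[gi] * np.linalg.norm(b_[idx])
            for gi, idx in enumerate(groups.group_index_lists)
        )
        return 0.5 * (yfro2 - 2.0 * float(a_ @ (Y.T @ z_)) + float(z_ @ z_)) + lam_ * pen

    for _it in range(config.max_alt_iterations):
        ytil = Y @ a
        lam = config.lambda_fraction * lambda_max(X, ytil, groups, weights)
        b_new = group_lasso_solve(X, ytil, groups, weights, lam, L=L)
        if not np.any(b_new):
            b = b_new
            trace.append(joint_objective(b, a, lam))
            converged = True
            break
        av = Y.T @ (X @ b_new)
        norm_av = np.linalg.norm(av)
        a_new = av / norm_av if norm_av > 0 else a
        obj = joint_objective(b_new, a_new, lam)
        if obj > prev_obj * (1.0 + 1e-12):
            converged = True  # lam is data-dependent; keep the previous iterate
            break
        b, a = b_new, a_new
        trace.append(obj)
        if prev_obj - obj <= config.tol * max(abs(prev_obj), 1.0):
            converged = True
            break
        prev_obj = obj
    selected = {
        groups.group_ids[gi]
        for gi, idx in enumerate(groups.group_index_lists)
        if np.linalg.norm(b[idx]) > 0
    }
    if not np.any(b):
        a_out = np.zeros(Y.shape[1])
    else:
        a_out = a
    return RankOneFit(
        snp_coefficients=b,
        trait_loadings=a_out,
        selected_pathways=selected,
        objective_trace=trace,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# Weight tuning against null-response selection bias


def _null_response(Y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    return Y[rng.permutation(Y.shape[0])]


def tune_weights(
    X: np.ndarray,
    Y: np.ndarray,
    groups: PathwayGroups,
    config: PsRRRConfig,
    rng: np.random.Generator | None = None,
) -> PathwayWeights:
    """Adapt sqrt-size weights so pathways are selected uniformly under a
    null (row-permuted) response.

    Per iteration, ``tuning_fits_per_iteration`` single rank-1 fits are run
    on freshly permuted responses; each pathway's weight is scaled by
    ((f_g + eps) / (mean f + eps)) ** damping, with eps = 1 / (2 * fits).
    Zero iterations returns the sqrt-size initialization unchanged.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    weights = initial_weights(groups)
    if config.tuning_iterations == 0:
        return weights
    L = _group_lipschitz(X, groups)
    history: list[np.ndarray] = []
    fits = config.tuning_fits_per_iteration
    eps = 1.0 / (2.0 * fits)
    gid_index = {g: i for i, g in enumerate(groups.group_ids)}
    w = weights.weights.copy()
    log_w_path: list[np.ndarray] = []
    for _it in range(config.tuning_iterations):
        counts = np.zeros(groups.n_groups)
        current = PathwayWeights(weights.group_ids, w, "tuned")
        for _f in range(fits):
            Yn = _null_response(Y, rng)
            fit = fit_rank1(X, Yn, groups, current, config, L=L)
            for g in fit.selected_pathways:
                counts[gid_index[g]] += 1
        freq = counts / fits
        history.append(freq)
        # selection probabilities react steeply to weight changes near
        # lam_max, so clip each multiplicative step to avoid oscillation
        factor = ((freq + eps) / (freq.mean() + eps)) ** config.tuning_damping
        factor = np.clip(factor, 0.9, 1.1)
        w = w * factor
        log_w_path.append(np.log(w))
    # geometric mean over the trailing half of the trajectory damps any
    # residual oscillation around the equalizing weights
    tail = max(1, len(log_w_path) // 2)
    w_final = np.exp(np.mean(log_w_path[-tail:], axis=0))
    return PathwayWeights(
        group_ids=list(groups.group_ids),
        weights=w_final,
        provenance="tuned",
        tuning_history=history,
    )


# ---------------------------------------------------------------------------
# Stability selection and ranking


def stability_select(
    X: np.ndarray,
    Y: np.ndarray,
    groups: PathwayGroups,
    weights: PathwayWeights,
    config: PsRRRConfig,
    null_mode: bool = False,
    rng: np.random.Generator | None = None,
) -> SelectionFrequencies:
    """Pathway selection frequencies over subject subsamples.

    Each of ``n_subsamples`` draws floor(subsample_fraction * n) subjects
    without replacement, re-standardizes the design, and runs one rank-1
    fit. In null mode the response rows are independently permuted per
    subsample, destroying the genotype-phenotype linkage.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = X.shape[0]
    m = int(np.floor(config.subsample_fraction * n))
    if m < 10:
        raise ValueError(f"subsample of {m} subjects is too small (< 10)")
    counts = np.zeros(groups.n_groups)
    corr_sums = np.zeros(groups.n_groups)
    gid_index = {g: i for i, g in enumerate(groups.group_ids)}
    for _s in range(config.n_subsamples):
        rows = rng.choice(n, size=m, replace=False)
        Xs = X[rows]
        sd = Xs.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        Xs = (Xs - Xs.mean(axis=0)) / sd
        Ys = Y[rows]
        if null_mode:
            Ys = Ys[rng.permutation(m)]
        Ys = Ys - Ys.mean(axis=0)
        fit = fit_rank1(Xs, Ys, groups, weights, config)
        if not fit.selected_pathways:
            continue
        ya = Ys @ fit.trait_loadings
        for g in fit.selected_pathways:
            gi = gid_index[g]
            counts[gi] += 1
            idx = groups.group_index_lists[gi]
            score = Xs[:, idx] @ fit.snp_coefficients[idx]
            if score.std() > 0 and ya.std() > 0:
                corr_sums[gi] += abs(float(np.corrcoef(score, ya)[0, 1]))
    freq = counts / config.n_subsamples
    with np.errstate(invalid="ignore"):
        mean_corr = np.where(counts > 0, corr_sums / np.maximum(counts, 1), np.nan)
    return SelectionFrequencies(
        group_ids=list(groups.group_ids),
        frequencies=freq,
        mean_abs_correlation=mean_corr,
        n_subsamples=config.n_subsamples,
    )


def rank_pathways(
    emp: SelectionFrequencies, null: SelectionFrequencies
) -> PathwayRanking:
    """Order pathways by empirical frequency, then mean |correlation|,
    then id; attach null frequencies for reporting."""
    if set(emp.group_ids) != set(null.group_ids):
        raise ValueError("empirical and null rankings cover different pathways")
    null_by_id = dict(zip(null.group_ids, null.frequencies))
    corr = np.nan_to_num(emp.mean_abs_correlation, nan=-1.0)
    order = sorted(
        range(len(emp.group_ids)),
        key=lambda i: (-emp.frequencies[i], -corr[i], emp.group_ids[i]),
    )
    ids = [emp.group_ids[i] for i in order]
    return PathwayRanking(
        group_ids=ids,
        empirical_frequencies=emp.frequencies[order],
        null_frequencies=np.array([null_by_id[g] for g in ids]),
        mean_abs_correlation=emp.mean_abs_correlation[order],
    )
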