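"""Graph guided group lasso over the genes of a single pathway.

A gene-group lasso augmented with a network fusion penalty on a GO-term
similarity graph. Variant 1 pulls the mean signed SNP effects of connected
genes together ("similar effects"); variant 2 pulls their size-normalized
group norms together ("similar selection", sign-free).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class GeneNetwork:
    gene_ids: list[str]
    adjacency: np.ndarray  # symmetric, non-negative, in [0, 1], zero diagonal

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency, dtype=float)
        n = len(self.gene_ids)
        if A.shape != (n, n):
            raise ValueError("adjacency shape mismatch")
        if np.abs(A - A.T).max() > 1e-12:
            raise ValueError("adjacency must be symmetric")
        if A.min() < 0 or A.max() > 1 + 1e-12:
            raise ValueError("adjacency weights must lie in [0, 1]")
        if np.abs(np.diag(A)).max() > 0:
            raise ValueError("adjacency diagonal must be zero")
        self.adjacency = A


@dataclass
class GGGLConfig:
    mu: float = 1.0
    lambda_fraction: float = 0.5
    variant: str = "GGGL-1"
    n_subsamples: int = 100
    subsample_fraction: float = 0.5
    selection_threshold: float = 0.4
    top_k_snps: int = 30
    max_iter: int = 2000
    tol: float = 1e-10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        if not (0.0 < self.lambda_fraction <= 1.0):
            raise ValueError("lambda_fraction must be in (0, 1]")
        if self.variant not in ("GGGL-1", "GGGL-2"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if not (0.0 < self.selection_threshold < 1.0):
            raise ValueError("selection_threshold must be in (0, 1)")


@dataclass
class GGGLFit:
    snp_coefficients: np.ndarray
    selected_genes: set[str]
    objective: float


@dataclass
class GeneSelectionProbabilities:
    gene_ids: list[str]
    probabilities: np.ndarray  # in [0, 1]
    genes_above_threshold: set[str]
    n_subsamples: int


@dataclass
class SNPRanking:
    snp_ids: list[str]  # ordered, best first
    selection_frequencies: np.ndarray
    mean_abs_coefficients: np.ndarray


# ---------------------------------------------------------------------------
# GO-term similarity network


def go_adjacency(
    gene_go_table: dict[str, set[str]],
    measure: str = "dice",
    gene_ids: list[str] | None = None,
) -> GeneNetwork:
    """Set-overlap similarity of per-gene GO term sets.

    jaccard: |A & B| / |A | B|; dice: 2 |A & B| / (|A| + |B|).
    """
    if measure not in ("jaccard", "dice"):
        raise ValueError(f"unknown measure {measure!r}")
    if gene_ids is None:
        gene_ids = sorted(gene_go_table)
    sets = []
    for g in gene_ids:
        terms = set(gene_go_table[g])
        if not terms:
            raise ValueError(f"gene {g!r} has an empty GO term set")
        sets.append(terms)
    m = len(gene_ids)
    A = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            inter = len(sets[i] & sets[j])
            if measure == "jaccard":
                sim = inter / len(sets[i] | sets[j])
            else:
                sim = 2.0 * inter / (len(sets[i]) + len(sets[j]))
            A[i, j] = A[j, i] = sim
    return GeneNetwork(gene_ids=list(gene_ids), adjacency=A)


# ---------------------------------------------------------------------------
# Solver


def _check_partition(gene_groups: dict[str, np.ndarray], p: int) -> None:
    seen = np.concatenate([np.asarray(v) for v in gene_groups.values()])
    if len(seen) != p or len(np.unique(seen)) != p or seen.min() != 0 or seen.max() != p - 1:
        raise ValueError("gene_groups must partition the design columns")


def gggl_objective(
    X: np.ndarray,
    y: np.ndarray,
    gene_groups: dict[str, np.ndarray],
    net: GeneNetwork,
    config: GGGLConfig,
    lam: float,
    beta: np.ndarray,
) -> float:
    """0.5||y - X beta||^2 + lam sum_g w_g ||beta_g|| + mu * network term."""
    r = y - X @ beta
    obj = 0.5 * float(r @ r)
    sizes = np.array([len(gene_groups[g]) for g in net.gene_ids], dtype=float)
    summary = np.empty(len(net.gene_ids))
    for gi, g in enumerate(net.gene_ids):
        bg = beta[gene_groups[g]]
        obj += lam * np.sqrt(sizes[gi]) * np.linalg.norm(bg)
        if config.variant == "GGGL-1":
            summary[gi] = bg.mean()
        else:
            summary[gi] = np.linalg.norm(bg) / np.sqrt(sizes[gi])
    A = net.adjacency
    diff = summary[:, None] - summary[None, :]
    obj += 0.5 * config.mu * float((A * diff**2).sum())  # i<j pairs counted once
    return obj


def gggl_solve(
    X: np.ndarray,
    y: np.ndarray,
    gene_groups: dict[str, np.ndarray],
    net: GeneNetwork,
    config: GGGLConfig,
    lam: float | None = None,
) -> GGGLFit:
    """Block coordinate descent for the network-fused gene-group lasso.

    The quadratic network term is absorbed into each gene block's smooth
    part (variant 1) or handled in closed form on the block norm (variant
    2). ``lam`` defaults to lambda_fraction times the plain group-lasso
    zero threshold. mu = 0 reduces both variants to the gene-group lasso.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in X or y")
    _check_partition(gene_groups, X.shape[1])
    missing = [g for g in net.gene_ids if g not in gene_groups]
    if missing:
        raise ValueError(f"genes missing from gene_groups: {missing}")
    gids = net.gene_ids
    idx = [np.asarray(gene_groups[g], dtype=int) for g in gids]
    sizes = np.array([v.size for v in idx], dtype=float)
    w = np.sqrt(sizes)
    if lam is None:
        lam0 = max(
            float(np.linalg.norm(X[:, v].T @ y)) / w[gi] for gi, v in enumerate(idx)
        )
        lam = config.lambda_fraction * lam0
    A = net.adjacency
    deg = A.sum(axis=1)
    mu = config.mu
    m = len(gids)
    # Lipschitz per block: data term + (variant 1) network quadratic
    L = np.empty(m)
    for gi, v in enumerate(idx):
        Xg = X[:, v]
        gram = Xg.T @ Xg if v.size <= X.shape[0] else Xg @ Xg.T
        L[gi] = max(float(np.linalg.eigvalsh(gram)[-1]), 1e-12)
        if config.variant == "GGGL-1":
            L[gi] += 2.0 * mu * deg[gi] / sizes[gi]

    beta = np.zeros(X.shape[1])
    r = y.copy()
    summary = np.zeros(m)  # s_g (variant 1) or ||beta_g||/sqrt(|g|) (variant 2)
    for _it in range(config.max_iter):
        max_change = 0.0
        for gi, v in enumerate(idx):
            Xg = X[:, v]
            bg = beta[v]
            grad = -(Xg.T @ r)  # gradient of the data term
            if config.variant == "GGGL-1" and mu > 0:
                # d/d beta_g of mu * sum_j A_gj (s_g - s_j)^2, s = mean(beta_g)
                net_pull = 2.0 * mu * (deg[gi] * summary[gi] - A[gi] @ summary)
                grad = grad + net_pull / sizes[gi]
            u = bg - grad / L[gi]
            nu = np.linalg.norm(u)
            if config.variant == "GGGL-2" and mu > 0:
                # block subproblem on t = ||beta_g||:
                # L/2 (t - ||u||)^2 + lam w t + (mu deg/|g|) t^2
                #   - (2 mu / sqrt|g|) (A_g . summary_others) t
                gamma = 2.0 * mu * float(A[gi] @ summary) / np.sqrt(sizes[gi])
                alpha = mu * deg[gi] / sizes[gi]
                t = (L[gi] * nu - lam * w[gi] + gamma) / (L[gi] + 2.0 * alpha)
                new = (t / nu) * u if (t > 0 and nu > 0) else np.zeros_like(bg)
            else:
                t = lam * w[gi] / L[gi]
                new = np.zeros_like(bg) if nu <= t else (1.0 - t / nu) * u
            delta = new - bg
            change = np.abs(delta).max() if delta.size else 0.0
            if change > 0:
                r -= Xg @ delta
                beta[v] = new
                max_change = max(max_change, change)
            if config.variant == "GGGL-1":
                summary[gi] = beta[v].mean()
            else:
                summary[gi] = np.linalg.norm(beta[v]) / np.sqrt(sizes[gi])
        if max_change <= config.tol * (1.0 + np.abs(beta).max(initial=0.0)):
            break
    selected = {g for gi, g in enumerate(gids) if np.linalg.norm(beta[idx[gi]]) > 0}
    obj = gggl_objective(X, y, gene_groups, net, config, lam, beta)
    return GGGLFit(snp_coefficients=beta, selected_genes=selected, objective=obj)


def gggl_kkt_residual(
    X: np.ndarray,
    y: np.ndarray,
    gene_groups: dict[str, np.ndarray],
    net: GeneNetwork,
    config: GGGLConfig,
    lam: float,
    beta: np.ndarray,
) -> float:
    """Relative stationarity violation of a gggl_solve solution."""
    r = y - X @ beta
    gids = net.gene_ids
    idx = [np.asarray(gene_groups[g], dtype=int) for g in gids]
    sizes = np.array([v.size for v in idx], dtype=float)
    w = np.sqrt(sizes)
    A = net.adjacency
    deg = A.sum(axis=1)
    mu = config.mu
    summary = np.empty(len(gids))
    for gi, v in enumerate(idx):
        bg = beta[v]
        summary[gi] = (
            bg.mean() if config.variant == "GGGL-1" else np.linalg.norm(bg) / w[gi]
        )
    scale = max(lam, float(np.abs(X.T @ y).max()), 1e-12)
    worst = 0.0
    for gi, v in enumerate(idx):
        bg = beta[v]
        nb = np.linalg.norm(bg)
        grad = -(X[:, v].T @ r)
        if config.variant == "GGGL-1" and mu > 0:
            grad = grad + 2.0 * mu * (deg[gi] * summary[gi] - A[gi] @ summary) / sizes[gi]
            if nb == 0:
                worst = max(worst, max(np.linalg.norm(grad) - lam * w[gi], 0.0))
            else:
                worst = max(worst, np.linalg.norm(grad + lam * w[gi] * bg / nb))
        else:
            gamma = 2.0 * mu * float(A[gi] @ summary) / w[gi] if mu > 0 else 0.0
            alpha = 2.0 * mu * deg[gi] / sizes[gi] if mu > 0 else 0.0
            if nb == 0:
                # directional stationarity at 0 in the steepest direction
                worst = max(worst, max(np.linalg.norm(grad) - lam * w[gi] + gamma, 0.0))
            else:
                g_norm = grad + (lam * w[gi] + alpha * nb - gamma) * bg / nb
                worst = max(worst, np.linalg.norm(g_norm))
    return worst / scale


# ---------------------------------------------------------------------------
# Subsampling, rankings, mu stability


def gene_selection_probabilities(
    X: np.ndarray,
    y: np.ndarray,
    gene_groups: dict[str, np.ndarray],
    net: GeneNetwork,
    config: GGGLConfig,
    rng: np.random.Generator | None = None,
    return_fits: bool = False,
):
    """Per-gene selection probability over subject subsamples (without
    replacement); genes above ``selection_threshold`` are flagged."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = X.shape[0]
    m = int(np.floor(config.subsample_fraction * n))
    if m < 10:
        raise ValueError(f"subsample of {m} subjects is too small (< 10)")
    counts = dict.fromkeys(net.gene_ids, 0)
    fits: list[GGGLFit] = []
    for _s in range(config.n_subsamples):
        rows = rng.choice(n, size=m, replace=False)
        Xs = X[rows]
        sd = Xs.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        Xs = (Xs - Xs.mean(axis=0)) / sd
        ys = y[rows] - y[rows].mean()
        fit = gggl_solve(Xs, ys, gene_groups, net, config)
        fits.append(fit)
        for g in fit.selected_genes:
            counts[g] += 1
    probs = np.array([counts[g] / config.n_subsamples for g in net.gene_ids])
    above = {
        g for g, pr in zip(net.gene_ids, probs) if pr > config.selection_threshold
    }
    result = GeneSelectionProbabilities(
        gene_ids=list(net.gene_ids),
        probabilities=probs,
        genes_above_threshold=above,
        n_subsamples=config.n_subsamples,
    )
    return (result, fits) if return_fits else result


def rank_snps(
    fits: list[GGGLFit], snp_ids: list[str], top_k: int | None = None
) -> SNPRanking:
    """Order SNPs by selection frequency across fits, then mean |coefficient|,
    then id; truncate to top_k."""
    if not fits:
        raise ValueError("need at least one fit")
    p = len(snp_ids)
    count = np.zeros(p)
    coef_sum = np.zeros(p)
    for fit in fits:
        nz = fit.snp_coefficients != 0
        count += nz
        coef_sum += np.abs(fit.snp_coefficients)
    freq = count / len(fits)
    with np.errstate(invalid="ignore"):
        mean_abs = np.where(count > 0, coef_sum / np.maximum(count, 1), 0.0)
    order = sorted(range(p), key=lambda j: (-freq[j], -mean_abs[j], snp_ids[j]))
    if top_k is not None:
        order = order[:top_k]
    return SNPRanking(
        snp_ids=[snp_ids[j] for j in order],
        selection_frequencies=freq[order],
        mean_abs_coefficients=mean_abs[order],
    )


@dataclass
class MuStabilityReport:
    mu_grid: list[float]
    gene_sets: dict[float, set[str]]
    snp_lists: dict[float, list[str]]
    pairwise_snp_overlap: dict[tuple[float, float], int]
    common_snp_count: int
    gene_sets_identical: bool


def mu_stability_report(
    X: np.ndarray,
    y: np.ndarray,
    gene_groups: dict[str, np.ndarray],
    net: GeneNetwork,
    config: GGGLConfig,
    snp_ids: list[str],
    mu_grid: tuple[float, ...] = (0.1, 1.0, 10.0),
) -> MuStabilityReport:
    """Stability of gene sets and top-k SNP lists across the mu grid."""
    if not mu_grid:
        raise ValueError("mu_grid must be nonempty")
    from dataclasses import replace

    gene_sets: dict[float, set[str]] = {}
    snp_lists: dict[float, list[str]] = {}
    for mu in mu_grid:
        cfg = replace(config, mu=mu)
        probs, fits = gene_selection_probabilities(
            X, y, gene_groups, net, cfg, return_fits=True
        )
        gene_sets[mu] = probs.genes_above_threshold
        snp_lists[mu] = rank_snps(fits, snp_ids, top_k=config.top_k_snps).snp_ids
    pair_overlap = {}
    grid = list(mu_grid)
    for i in range(len(grid)):
        for j in range(i + 1, len(grid)):
            pair_overlap[(grid[i], grid[j])] = len(
                set(snp_lists[grid[i]]) & set(snp_lists[grid[j]])
            )
    common = set(snp_lists[grid[0]])
    for mu in grid[1:]:
        common &= set(snp_lists[mu])
    first = gene_sets[grid[0]]
    identical = all(gene_sets[mu] == first for mu in grid)
    return MuStabilityReport(
        mu_grid=grid,
        gene_sets=gene_sets,
        snp_lists=snp_lists,
        pairwise_snp_overlap=pair_overlap,
        common_snp_count=len(common) if len(grid) > 1 else len(snp_lists[grid[0]]),
        gene_sets_identical=identical,
    )
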