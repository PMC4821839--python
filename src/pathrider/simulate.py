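"""Synthetic imaging-genetics data with known ground truth.

Generates genotypes (LD blocks via a Gaussian copula, optional
Balding-Nichols subpopulation structure), overlapping pathway annotations
with a GO-style gene similarity network, and a multivariate phenotype
carrying a rank-1 pathway-structured genetic signal plus covariate effects
and noise.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .genio import AnnotationMap, GenotypeMatrix, make_variant_table
from .phenotype import PhenotypeMatrix


@dataclass
class SimulationConfig:
    n_subjects: int = 72
    n_snps: int = 1000
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 10
    ld_rho: float = 0.5
    n_subpops: int = 1
    fst: float = 0.0
    n_genes: int = 100
    n_pathways: int = 8
    pathway_size_range: tuple[int, int] = (5, 10)
    overlap_fraction: float = 0.1
    n_causal_pathways: int = 1
    trait_dim: int = 10
    trait_rank: int = 1
    heritability: float = 0.3
    covariate_effects: tuple[float, float] = (1.0, 1.0)
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie in (0, 0.5]: {self.maf_range}")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must be in [0, 1)")
        if not (0.0 <= self.fst < 1.0):
            raise ValueError("fst must be in [0, 1)")
        if not (0.0 <= self.heritability < 1.0):
            raise ValueError("heritability must be in [0, 1)")
        if not (0.0 <= self.overlap_fraction <= 1.0):
            raise ValueError("overlap_fraction must be a proportion")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.pathway_size_range[0] < 1:
            raise ValueError("pathway_size_range min must be >= 1")
        if self.pathway_size_range[0] > self.pathway_size_range[1]:
            raise ValueError("pathway_size_range must be ordered")
        if self.trait_rank > self.trait_dim:
            raise ValueError("trait_rank must be <= trait_dim")
        for name in ("n_subjects", "n_snps", "ld_block_size", "n_subpops",
                     "n_genes", "n_pathways", "n_causal_pathways", "trait_dim"):
            if getattr(self, name) < 1 and name != "n_causal_pathways":
                raise ValueError(f"{name} must be positive")
        if self.n_causal_pathways > self.n_pathways:
            raise ValueError("n_causal_pathways exceeds n_pathways")


@dataclass
class SimulationTruth:
    causal_pathway_ids: list[str]
    causal_snp_indices: np.ndarray
    snp_effect_vector: np.ndarray  # length n_snps, zero off causal pathways
    trait_loading_vector: np.ndarray  # unit Euclidean norm
    covariate_coefficient_matrix: np.ndarray  # n_covariates x trait_dim
    realized_heritability: float

    def to_json(self) -> str:
        d = {
            "causal_pathway_ids": self.causal_pathway_ids,
            "causal_snp_indices": self.causal_snp_indices.tolist(),
            "snp_effect_vector": self.snp_effect_vector.tolist(),
            "trait_loading_vector": self.trait_loading_vector.tolist(),
            "covariate_coefficient_matrix": self.covariate_coefficient_matrix.tolist(),
            "realized_heritability": self.realized_heritability,
        }
        return json.dumps(d, sort_keys=True)


def _subpop_labels(n: int, k: int) -> np.ndarray:
    return np.arange(n) % k


def simulate_genotypes(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, pd.DataFrame, np.ndarray]:
    """Draw an LD-blocked genotype matrix with optional subpopulations.

    Ancestral minor-allele frequencies are uniform on ``maf_range``;
    subpopulation frequencies follow the Balding-Nichols Beta construction
    with parameter ``fst``. Haplotypes are produced by thresholding an AR(1)
    Gaussian copula within each LD block, and dosages are the sum of two
    independent haplotypes. Missing calls are completely at random.
    """
    rng = np.random.default_rng([config.seed, 0])
    n, p = config.n_subjects, config.n_snps
    lo, hi = config.maf_range
    anc = rng.uniform(lo, hi, size=p)
    labels = _subpop_labels(n, config.n_subpops)
    if config.n_subpops > 1 and config.fst > 0:
        F = config.fst
        a = anc * (1 - F) / F
        b = (1 - anc) * (1 - F) / F
        freqs = rng.beta(a[None, :], b[None, :], size=(config.n_subpops, p))
        freqs = np.clip(freqs, 1e-4, 1 - 1e-4)
    else:
        freqs = np.tile(anc, (config.n_subpops, 1))
    thresh = norm.ppf(freqs)  # allele = 1 iff latent z < threshold
    block = config.ld_block_size
    rho = config.ld_rho
    dosage = np.zeros((n, p))
    for _hap in range(2):
        z = rng.standard_normal((n, p))
        if rho > 0 and block > 1:
            scale = np.sqrt(1 - rho**2)
            for start in range(0, p, block):
                end = min(start + block, p)
                for j in range(start + 1, end):
                    z[:, j] = rho * z[:, j - 1] + scale * z[:, j]
        dosage += (z < thresh[labels, :]).astype(float)
    mask = (
        rng.random((n, p)) < config.missing_rate
        if config.missing_rate > 0
        else np.zeros((n, p), dtype=bool)
    )
    dosage[mask] = 0.0
    width = len(str(p))
    snp_ids = [f"snp{j:0{width}d}" for j in range(p)]
    subject_ids = [f"subj{i:03d}" for i in range(n)]
    variants = make_variant_table(
        snp_ids, "1", np.arange(1, p + 1) * 1000, "A", "B"
    )
    G = GenotypeMatrix(subject_ids, snp_ids, dosage, mask)
    return G, variants, labels


def _pathway_memberships(config: SimulationConfig, rng) -> dict[str, list[int]]:
    """Assign gene indices to pathways with the requested overlap."""
    lo, hi = config.pathway_size_range
    sizes = rng.integers(lo, hi + 1, size=config.n_pathways)
    total = int(sizes.sum())
    f = config.overlap_fraction
    # each shared gene sits in exactly 2 pathways: unique = total - m, m/unique ~= f
    m = int(round(f * total / (1.0 + f)))
    members: dict[int, list[int]] = {i: [] for i in range(config.n_pathways)}
    remaining = sizes.astype(int).copy()
    next_gene = 0
    for _ in range(m):
        order = np.argsort(-remaining)
        a, b = int(order[0]), int(order[1])
        if remaining[a] < 1 or remaining[b] < 1:
            raise ValueError("overlap demand infeasible for the given sizes")
        members[a].append(next_gene)
        members[b].append(next_gene)
        remaining[a] -= 1
        remaining[b] -= 1
        next_gene += 1
    for i in range(config.n_pathways):
        for _ in range(int(remaining[i])):
            members[i].append(next_gene)
            next_gene += 1
    if next_gene > config.n_genes:
        raise ValueError(
            f"pathways need {next_gene} genes but n_genes={config.n_genes}"
        )
    width = len(str(config.n_pathways))
    return {f"pw{i:0{width}d}": sorted(members[i]) for i in range(config.n_pathways)}


def simulate_annotation(config: SimulationConfig):
    """Build SNP->gene and gene->pathway maps, a gene GO table, and the
    gene similarity network implied by shared GO terms.

    Returns (annotation, network, gene_go_table). SNPs are split
    into contiguous single-gene blocks; genes sharing a pathway share GO
    terms, which makes them "functionally related" in the Dice-similarity
    network. Adjacency is symmetric with a zero diagonal.
    """
    from .gggl import go_adjacency  # local import to avoid a cycle

    rng = np.random.default_rng([config.seed, 1])
    if config.n_genes > config.n_snps:
        raise ValueError("need at least one SNP per gene")
    gwidth = len(str(config.n_genes))
    gene_ids = [f"gene{i:0{gwidth}d}" for i in range(config.n_genes)]
    swidth = len(str(config.n_snps))
    bounds = np.linspace(0, config.n_snps, config.n_genes + 1).astype(int)
    snp_to_genes: dict[str, list[str]] = {}
    for gi in range(config.n_genes):
        for j in range(bounds[gi], bounds[gi + 1]):
            snp_to_genes[f"snp{j:0{swidth}d}"] = [gene_ids[gi]]
    pathways = _pathway_memberships(config, rng)
    gene_to_pathways: dict[str, list[str]] = {}
    for pid, gidx in pathways.items():
        for gi in gidx:
            gene_to_pathways.setdefault(gene_ids[gi], []).append(pid)
    ann = AnnotationMap(snp_to_genes=snp_to_genes, gene_to_pathways=gene_to_pathways)
    # GO table: pathway-level shared terms + private terms per gene
    gene_go_table: dict[str, set[str]] = {}
    for gi, gid in enumerate(gene_ids):
        terms = {f"go_private_{gid}_{t}" for t in range(2)}
        for pid in gene_to_pathways.get(gid, []):
            terms |= {f"go_{pid}_{t}" for t in range(5)}
        gene_go_table[gid] = terms
    net = go_adjacency(gene_go_table, measure="dice", gene_ids=gene_ids)
    return ann, net, gene_go_table


def _standardize(X: np.ndarray) -> np.ndarray:
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return (X - mean) / sd


def simulate_phenotype(
    G: GenotypeMatrix,
    ann: AnnotationMap,
    config: SimulationConfig,
) -> tuple[PhenotypeMatrix, pd.DataFrame, SimulationTruth]:
    """Generate Y = C Gamma + (X b) a^T + nuisance + E with b supported on
    the SNPs of the causal pathways.

    The genetic effect is scaled so that the expected variance fraction of
    the rank-1 signal within Y - C Gamma equals ``heritability``. Covariates
    ``ga`` and ``pma`` mimic gestational and postmenstrual age in weeks.
    """
    rng = np.random.default_rng([config.seed, 2])
    n, p = G.n_subjects, G.n_snps
    q = config.trait_dim
    pathway_ids = sorted({pid for v in ann.gene_to_pathways.values() for pid in v})
    if config.n_causal_pathways > len(pathway_ids):
        raise ValueError("not enough pathways to choose causal ones")
    causal_pw = sorted(
        rng.choice(pathway_ids, size=config.n_causal_pathways, replace=False).tolist()
    )
    snp_index = {s: j for j, s in enumerate(G.snp_ids)}
    causal_snps = sorted(
        {
            snp_index[s]
            for s, genes in ann.snp_to_genes.items()
            if s in snp_index
            and any(pid in causal_pw for g in genes for pid in ann.gene_to_pathways.get(g, []))
        }
    )
    causal_snps = np.array(causal_snps, dtype=int)
    if causal_snps.size == 0 and config.n_causal_pathways > 0:
        raise ValueError("causal pathways contain no SNPs")

    # covariates in weeks, loosely matching a preterm cohort
    ga = rng.uniform(23.0, 33.0, size=n)
    pma = ga + rng.uniform(6.0, 16.0, size=n)
    C = np.column_stack([ga, pma])
    Gamma = rng.standard_normal((2, q)) * np.asarray(config.covariate_effects)[:, None]

    b = np.zeros(p)
    b[causal_snps] = rng.standard_normal(causal_snps.size)
    a = rng.standard_normal(q)
    a /= np.linalg.norm(a)
    Xs = _standardize(np.where(G.missing_mask, np.nan, G.dosage))
    Xs = np.nan_to_num(Xs)
    g = Xs @ b
    gc = g - g.mean()
    v_g = float(gc @ gc) / max(n - 1, 1) / q  # mean per-entry signal variance

    h2 = config.heritability
    if h2 == 0.0:
        if config.n_causal_pathways > 0:
            warnings.warn(
                "heritability=0 with causal pathways: genetic effects are nulled",
                stacklevel=2,
            )
        c = 0.0
    else:
        c = np.sqrt(h2 / ((1.0 - h2) * max(v_g, 1e-12)))
    b_scaled = c * b
    signal = np.outer(Xs @ b_scaled, a)

    E = rng.standard_normal((n, q))
    nuisance = np.zeros((n, q))
    if config.trait_rank > 1:
        # extra orthogonal structured components carrying no genetic signal
        basis = np.linalg.qr(rng.standard_normal((q, config.trait_rank)))[0]
        for r in range(1, config.trait_rank):
            u = rng.standard_normal(n)
            nuisance += np.outer(u, basis[:, r])
    Y = C @ Gamma + signal + nuisance + E

    resid = signal + nuisance + E
    resid_c = resid - resid.mean(axis=0)
    sig_c = signal - signal.mean(axis=0)
    denom = float((resid_c**2).sum())
    realized = float((sig_c**2).sum()) / denom if denom > 0 else 0.0

    features = [f"t{j:03d}" for j in range(q)]
    Ymat = PhenotypeMatrix(list(G.subject_ids), features, Y)
    cov = pd.DataFrame(
        {"subject_id": G.subject_ids, "ga": ga, "pma": pma}
    )
    truth = SimulationTruth(
        causal_pathway_ids=causal_pw,
        causal_snp_indices=causal_snps,
        snp_effect_vector=b_scaled,
        trait_loading_vector=a,
        covariate_coefficient_matrix=Gamma,
        realized_heritability=realized,
    )
    return Ymat, cov, truth


# ---------------------------------------------------------------------------
# A compact single-pathway dataset for network-guided gene selection tests.


@dataclass
class GeneClusterDataset:
    X: np.ndarray  # standardized n x p design
    y: np.ndarray  # centered response
    snp_ids: list[str]
    gene_ids: list[str]
    gene_groups: dict[str, np.ndarray]
    gene_go_table: dict[str, set[str]]
    causal_genes: list[str]


def simulate_gene_cluster_dataset(
    n: int = 200,
    n_genes: int = 20,
    snps_per_gene: int = 4,
    n_causal_genes: int = 5,
    heritability: float = 0.5,
    seed: int = 0,
) -> GeneClusterDataset:
    """One-pathway dataset whose causal genes form a GO-term cluster.

    Causal genes share a dedicated block of GO terms (so they are tightly
    connected in the similarity network) and carry iid normal SNP effects;
    the response is scaled to the requested heritability.
    """
    rng = np.random.default_rng([seed, 7])
    p = n_genes * snps_per_gene
    X = _standardize(rng.binomial(2, 0.3, size=(n, p)).astype(float))
    gene_ids = [f"g{i:02d}" for i in range(n_genes)]
    snp_ids = [f"s{j:03d}" for j in range(p)]
    gene_groups = {
        gid: np.arange(i * snps_per_gene, (i + 1) * snps_per_gene)
        for i, gid in enumerate(gene_ids)
    }
    causal = gene_ids[:n_causal_genes]
    gene_go_table: dict[str, set[str]] = {}
    for i, gid in enumerate(gene_ids):
        terms = {f"go_self_{gid}_{t}" for t in range(2)}
        if gid in causal:
            terms |= {f"go_cluster_{t}" for t in range(6)}
        else:
            terms |= {f"go_bg_{i % 3}_{t}" for t in range(2)}
        gene_go_table[gid] = terms
    beta = np.zeros(p)
    for gid in causal:
        # magnitudes bounded away from zero so every causal gene carries signal
        mags = rng.uniform(0.5, 1.5, size=snps_per_gene)
        signs = rng.choice([-1.0, 1.0], size=snps_per_gene)
        beta[gene_groups[gid]] = mags * signs
    g = X @ beta
    g -= g.mean()
    vg = float(g @ g) / max(n - 1, 1)
    if heritability > 0:
        scale = np.sqrt(heritability / ((1 - heritability) * max(vg, 1e-12)))
    else:
        scale = 0.0
    y = scale * g + rng.standard_normal(n)
    y -= y.mean()
    return GeneClusterDataset(
        X=X,
        y=y,
        snp_ids=snp_ids,
        gene_ids=gene_ids,
        gene_groups=gene_groups,
        gene_go_table=gene_go_table,
        causal_genes=causal,
    )
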