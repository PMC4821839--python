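"""Hypergeometric over-representation tests and the end-to-end pipeline."""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from . import genio, gggl, phenotype, psrrr, simulate, strata


@dataclass
class EnrichmentResult:
    overlap: int  # k
    top_size: int  # n
    category_size: int  # K
    universe_size: int  # N
    p_value: float


def _log_binom(n: float, k: float) -> float:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), log-space summation."""
    kmax = min(K, n)
    if k <= max(0, n + K - N):
        return 1.0
    terms = [
        _log_binom(K, i) + _log_binom(N - K, n - i) - _log_binom(N, n)
        for i in range(k, kmax + 1)
        if n - i <= N - K
    ]
    if not terms:
        return 0.0
    return float(min(np.exp(logsumexp(terms)), 1.0))


def hypergeom_test(top_set: set, category_set: set, universe: set) -> EnrichmentResult:
    """Upper-tail over-representation of category members in the top list."""
    if not universe:
        raise ValueError("universe must be nonempty")
    top_set, category_set, universe = set(top_set), set(category_set), set(universe)
    if not top_set <= universe:
        raise ValueError("top_set must be a subset of the universe")
    if not category_set <= universe:
        raise ValueError("category_set must be a subset of the universe")
    k = len(top_set & category_set)
    N, K, n = len(universe), len(category_set), len(top_set)
    return EnrichmentResult(
        overlap=k,
        top_size=n,
        category_size=K,
        universe_size=N,
        p_value=hypergeom_upper_tail(k, N, K, n),
    )


def category_overrepresentation(
    ranking: psrrr.PathwayRanking, category: set, top_k: int = 30
) -> EnrichmentResult:
    """Over-representation of a pathway category among the top_k ranked
    pathways, with the full ranked list as the universe."""
    if top_k > len(ranking.group_ids):
        raise ValueError("top_k exceeds ranking length")
    top = set(ranking.group_ids[:top_k])
    universe = set(ranking.group_ids)
    return hypergeom_test(top, set(category) & universe, universe)


# ---------------------------------------------------------------------------
# Pipeline


@dataclass
class RunReport:
    config: dict
    seed: int
    version: str
    pathway_ranking: list[str]
    causal_pathways: list[str]
    top_pathway: str
    selected_genes: list[str]
    top_snps: list[str]
    enrichment: dict
    psrrr_converged: bool
    artifacts: dict[str, str] = field(default_factory=dict)  # file -> sha256

    def to_json(self) -> str:
        return json.dumps(self.__dict__, sort_keys=True, indent=2, default=str)


def _digest(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        h.update(fh.read())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


DEFAULT_PIPELINE_CONFIG: dict = {
    "seed": 0,
    "outdir": "pathrider_run",
    "simulate": {
        "n_subjects": 120,
        "n_snps": 300,
        "n_genes": 45,
        "n_pathways": 6,
        "pathway_size_range": [4, 8],
        "overlap_fraction": 0.1,
        "heritability": 0.6,
        "trait_dim": 8,
        "missing_rate": 0.01,
    },
    "qc": {"maf_min": 0.05, "call_rate_min": 0.95},
    "adjust": {"covariates": ["ga", "pma"], "ancestry": False},
    "pca": {"k": "auto"},
    "psrrr": {
        "lambda_fraction": 0.99,
        "n_subsamples": 40,
        "tuning_iterations": 2,
        "tuning_fits_per_iteration": 20,
    },
    "gggl": {"mu": 1.0, "n_subsamples": 40, "selection_threshold": 0.4, "top_k_snps": 30},
    "enrich": {"top_k": 3},
}


def _merged(base: dict, override: dict) -> dict:
    out = {}
    for key, val in base.items():
        if isinstance(val, dict):
            out[key] = _merged(val, override.get(key, {}))
        else:
            out[key] = override.get(key, val)
    return out


def run_pipeline(config: dict | str | os.PathLike) -> RunReport:
    """Execute QC -> adjust -> reduce -> strata -> pathway ranking ->
    network gene selection -> enrichment on a simulated dataset.

    ``config`` is a (possibly partial) dict merged over
    ``DEFAULT_PIPELINE_CONFIG``, or a path to a JSON file holding one.
    All randomness derives from the single master seed, so reruns with an
    identical config reproduce byte-identical artifacts.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = json.load(fh)
    cfg = _merged(DEFAULT_PIPELINE_CONFIG, config)
    seed = int(cfg["seed"])
    outdir = str(cfg["outdir"])
    os.makedirs(outdir, exist_ok=True)
    artifacts: dict[str, str] = {}

    # --- simulate inputs
    sim_cfg = dict(cfg["simulate"])
    sim_cfg["seed"] = seed
    for key in ("maf_range", "pathway_size_range", "covariate_effects"):
        if key in sim_cfg:
            sim_cfg[key] = tuple(sim_cfg[key])
    sc = simulate.SimulationConfig(**sim_cfg)
    G, variants, _labels = simulate.simulate_genotypes(sc)
    ann, net, gene_go = simulate.simulate_annotation(sc)
    Y, cov, truth = simulate.simulate_phenotype(G, ann, sc)

    # --- QC + imputation
    Gq = genio.filter_variants(G, cfg["qc"]["maf_min"], cfg["qc"]["call_rate_min"])
    Gq = genio.impute_missing(Gq, "column-mean")

    # --- stratification (recorded; ancestry adjustment is an explicit flag)
    pcs = strata.ancestry_pcs(Gq, k=min(2, Gq.n_subjects), basis="ibs-distance")
    cov = cov.assign(ancestry_pc1=pcs.component_scores[:, 0])

    # --- phenotype adjustment + reduction
    which = list(cfg["adjust"]["covariates"])
    if cfg["adjust"]["ancestry"]:
        which.append("ancestry_pc1")
    Yr = phenotype.residualize(Y, cov, which)
    red = phenotype.pca_reduce(Yr, k=cfg["pca"]["k"])

    # --- pathway model
    gene_sets = {
        pid: sorted(
            g for g, pws in ann.gene_to_pathways.items() if pid in pws
        )
        for pid in sorted({p for v in ann.gene_to_pathways.values() for p in v})
    }
    groups = genio.build_groups(ann, gene_sets, Gq.snp_ids)
    Xs = simulate._standardize(Gq.dosage)
    Xe = groups.expand_design(Xs)
    pconf_kwargs = dict(cfg["psrrr"])
    pconf = psrrr.PsRRRConfig(seed=seed, **pconf_kwargs)
    rng = np.random.default_rng([seed, 10])
    weights = psrrr.tune_weights(Xe, red.component_scores, groups, pconf, rng=rng)
    emp = psrrr.stability_select(
        Xe, red.component_scores, groups, weights, pconf,
        rng=np.random.default_rng([seed, 11]),
    )
    null = psrrr.stability_select(
        Xe, red.component_scores, groups, weights, pconf, null_mode=True,
        rng=np.random.default_rng([seed, 12]),
    )
    ranking = psrrr.rank_pathways(emp, null)
    top_pathway = ranking.group_ids[0]
    psrrr_converged = bool(np.any(emp.frequencies > 0))

    # --- network gene selection within the top pathway
    top_genes = gene_sets[top_pathway]
    snp_index = {s: j for j, s in enumerate(Gq.snp_ids)}
    gene_cols = {
        g: np.array(
            sorted(
                snp_index[s]
                for s, genes in ann.snp_to_genes.items()
                if g in genes and s in snp_index
            ),
            dtype=int,
        )
        for g in top_genes
    }
    gene_cols = {g: v for g, v in gene_cols.items() if v.size}
    sub_cols = np.concatenate([gene_cols[g] for g in sorted(gene_cols)])
    Xg = Xs[:, sub_cols]
    local = {}
    off = 0
    for g in sorted(gene_cols):
        local[g] = np.arange(off, off + gene_cols[g].size)
        off += gene_cols[g].size
    sub_net = gggl.go_adjacency(
        {g: gene_go[g] for g in sorted(gene_cols)}, measure="dice",
        gene_ids=sorted(gene_cols),
    )
    gconf = gggl.GGGLConfig(seed=seed, **cfg["gggl"])
    yg = red.component_scores[:, 0]
    probs, fits = gggl.gene_selection_probabilities(
        Xg, yg, local, sub_net, gconf,
        rng=np.random.default_rng([seed, 13]), return_fits=True,
    )
    sub_snp_ids = [Gq.snp_ids[j] for j in sub_cols]
    snp_rank = gggl.rank_snps(fits, sub_snp_ids, top_k=gconf.top_k_snps)

    # --- enrichment of the causal pathways among the top-ranked ones
    enr = category_overrepresentation(
        ranking, set(truth.causal_pathway_ids), top_k=min(cfg["enrich"]["top_k"],
                                                          len(ranking.group_ids))
    )

    # --- artifacts
    genio.write_genotypes(G, os.path.join(outdir, "genotypes.raw"), "plink-raw")
    genio.write_variant_table(variants, os.path.join(outdir, "variants.tsv"))
    genio.write_gmt(gene_sets, os.path.join(outdir, "pathways.gmt"))
    _write_tsv(cov, os.path.join(outdir, "covariates.tsv"))
    _write_tsv(
        pd.DataFrame(
            {
                "pathway": ranking.group_ids,
                "empirical_frequency": ranking.empirical_frequencies,
                "null_frequency": ranking.null_frequencies,
                "mean_abs_correlation": ranking.mean_abs_correlation,
            }
        ),
        os.path.join(outdir, "pathway_ranking.tsv"),
    )
    _write_tsv(
        pd.DataFrame(
            {"gene": probs.gene_ids, "selection_probability": probs.probabilities}
        ),
        os.path.join(outdir, "gene_selection.tsv"),
    )
    _write_tsv(
        pd.DataFrame(
            {
                "snp": snp_rank.snp_ids,
                "selection_frequency": snp_rank.selection_frequencies,
                "mean_abs_coefficient": snp_rank.mean_abs_coefficients,
            }
        ),
        os.path.join(outdir, "snp_ranking.tsv"),
    )
    _write_tsv(
        pd.DataFrame(
            [
                {
                    "overlap": enr.overlap,
                    "top_size": enr.top_size,
                    "category_size": enr.category_size,
                    "universe_size": enr.universe_size,
                    "p_value": enr.p_value,
                }
            ]
        ),
        os.path.join(outdir, "enrichment.tsv"),
    )
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        fh.write(truth.to_json())
    for name in sorted(os.listdir(outdir)):
        path = os.path.join(outdir, name)
        if os.path.isfile(path) and name != "run_report.json":
            artifacts[name] = _digest(path)

    from . import __version__

    report = RunReport(
        config=cfg,
        seed=seed,
        version=__version__,
        pathway_ranking=list(ranking.group_ids),
        causal_pathways=list(truth.causal_pathway_ids),
        top_pathway=top_pathway,
        selected_genes=sorted(probs.genes_above_threshold),
        top_snps=list(snp_rank.snp_ids),
        enrichment={
            "overlap": enr.overlap,
            "top_size": enr.top_size,
            "category_size": enr.category_size,
            "universe_size": enr.universe_size,
            "p_value": enr.p_value,
        },
        psrrr_converged=psrrr_converged,
        artifacts=artifacts,
    )
    with open(os.path.join(outdir, "run_report.json"), "w") as fh:
        fh.write(report.to_json())
    return report
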