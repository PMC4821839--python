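"""Genotype / annotation I/O, variant QC and pathway group construction.

Genotypes are held as minor-allele counts with an explicit missingness mask.
Two text dialects are supported: PLINK-style additive ``.raw`` files and a
plain additive TSV (subject id in the first column, one SNP per column,
``NA`` marking missing calls).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_RAW_META_COLS = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs minor-allele counts plus missingness mask."""

    subject_ids: list[str]
    snp_ids: list[str]
    dosage: np.ndarray  # float64, values {0,1,2} where mask is False
    missing_mask: np.ndarray  # bool, True where the call is missing

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        n, p = self.dosage.shape
        if len(self.subject_ids) != n or len(self.snp_ids) != p:
            raise ValueError("id lists inconsistent with dosage shape")
        if self.missing_mask.shape != (n, p):
            raise ValueError("mask shape inconsistent with dosage shape")
        if len(set(self.snp_ids)) != p:
            raise ValueError("duplicated snp_ids")

    @property
    def n_subjects(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def maf(self) -> np.ndarray:
        """Per-SNP minor allele frequency on non-missing calls.

        f = mean(dosage)/2 over observed entries; MAF = min(f, 1 - f).
        All-missing columns yield NaN.
        """
        obs = ~self.missing_mask
        with np.errstate(invalid="ignore"):
            f = np.where(
                obs.sum(axis=0) > 0,
                np.where(obs, self.dosage, 0.0).sum(axis=0)
                / np.maximum(obs.sum(axis=0), 1)
                / 2.0,
                np.nan,
            )
        return np.minimum(f, 1.0 - f)

    def call_rate(self) -> np.ndarray:
        """Per-SNP fraction of non-missing calls."""
        return 1.0 - self.missing_mask.mean(axis=0)

    def subset_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            subject_ids=list(self.subject_ids),
            snp_ids=[self.snp_ids[i] for i in keep],
            dosage=self.dosage[:, keep].copy(),
            missing_mask=self.missing_mask[:, keep].copy(),
        )


@dataclass
class AnnotationMap:
    """SNP -> genes and gene -> pathways multimaps."""

    snp_to_genes: dict[str, list[str]] = field(default_factory=dict)
    gene_to_pathways: dict[str, list[str]] = field(default_factory=dict)

    def genes_for_snp(self, snp_id: str) -> list[str]:
        return self.snp_to_genes.get(snp_id, [])


@dataclass
class PathwayGroups:
    """Overlapping pathway groups realized on an expanded (duplicated) design.

    Each expanded column belongs to exactly one group; ``expansion_map[j]``
    gives the original SNP column index the expanded column j duplicates.
    """

    group_ids: list[str]
    group_index_lists: list[np.ndarray]  # expanded-column indices per group
    expansion_map: np.ndarray  # expanded column -> original SNP column
    n_original: int

    @property
    def n_groups(self) -> int:
        return len(self.group_ids)

    @property
    def n_expanded(self) -> int:
        return self.expansion_map.size

    @property
    def group_sizes(self) -> np.ndarray:
        return np.array([idx.size for idx in self.group_index_lists])

    def expand_design(self, X: np.ndarray) -> np.ndarray:
        """Duplicate original columns into the expanded design."""
        return np.asarray(X)[:, self.expansion_map]

    def collapse_coefficients(self, b_expanded: np.ndarray) -> np.ndarray:
        """Sum expanded coefficients back onto original SNP columns."""
        b_expanded = np.asarray(b_expanded, dtype=float)
        out = np.zeros(self.n_original)
        np.add.at(out, self.expansion_map, b_expanded)
        return out


def make_variant_table(
    snp_ids: list[str],
    chromosome,
    position,
    allele1=None,
    allele2=None,
) -> pd.DataFrame:
    """Assemble a variant table (snp_id, chromosome, position, alleles)."""
    n = len(snp_ids)
    tbl = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chromosome": np.broadcast_to(np.asarray(chromosome), n).astype(str),
            "position": np.broadcast_to(np.asarray(position), n).astype(int),
            "allele1": np.broadcast_to(
                np.asarray(allele1 if allele1 is not None else "A"), n
            ),
            "allele2": np.broadcast_to(
                np.asarray(allele2 if allele2 is not None else "B"), n
            ),
        }
    )
    if tbl["snp_id"].duplicated().any():
        raise ValueError("duplicated snp_ids in variant table")
    if (tbl["position"] <= 0).any():
        raise ValueError("positions must be positive 1-based coordinates")
    return tbl


# ---------------------------------------------------------------------------
# Reading / writing


class GenotypeParseError(ValueError):
    pass


def _parse_dosage_token(tok: str, line_no: int, col: str):
    if tok in ("NA", "nan", ""):
        return np.nan
    try:
        v = float(tok)
    except ValueError:
        raise GenotypeParseError(
            f"line {line_no}: non-numeric dosage {tok!r} in column {col}"
        ) from None
    if v not in (0.0, 1.0, 2.0):
        raise GenotypeParseError(
            f"line {line_no}: dosage {tok!r} in column {col} not in {{0,1,2,NA}}"
        )
    return v


def read_genotypes(
    path, dialect: str = "plink-raw", variants_path=None
) -> tuple[GenotypeMatrix, pd.DataFrame | None]:
    """Read a genotype matrix from a text file.

    dialect "plink-raw": whitespace-separated .raw with the six PLINK meta
    columns; SNP headers may carry an ``_A`` allele suffix which is stripped.
    dialect "additive-tsv": tab-separated, subject id first column.

    Returns the matrix and, when ``variants_path`` is given, a variant table
    read from a .bim-like TSV (snp_id, chromosome, position, allele1, allele2).
    """
    if dialect not in ("plink-raw", "additive-tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        cols = header.split() if dialect == "plink-raw" else header.split("\t")
        if dialect == "plink-raw":
            if cols[: len(_RAW_META_COLS)] != _RAW_META_COLS:
                raise GenotypeParseError(
                    f"line 1: expected PLINK .raw header starting {_RAW_META_COLS}"
                )
            snp_cols = cols[len(_RAW_META_COLS) :]
            snp_ids = [c.rsplit("_", 1)[0] if "_" in c else c for c in snp_cols]
        else:
            snp_ids = cols[1:]
        if len(set(snp_ids)) != len(snp_ids):
            raise GenotypeParseError("line 1: duplicated snp_ids in header")
        subject_ids: list[str] = []
        rows: list[list[float]] = []
        for line_no, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            toks = line.split() if dialect == "plink-raw" else line.split("\t")
            if len(toks) != len(cols):
                raise GenotypeParseError(
                    f"line {line_no}: expected {len(cols)} fields, got {len(toks)}"
                )
            if dialect == "plink-raw":
                subject_ids.append(toks[1])
                data = toks[len(_RAW_META_COLS) :]
            else:
                subject_ids.append(toks[0])
                data = toks[1:]
            rows.append(
                [
                    _parse_dosage_token(t, line_no, snp_ids[j])
                    for j, t in enumerate(data)
                ]
            )
    dosage = np.array(rows, dtype=float)
    mask = np.isnan(dosage)
    dosage[mask] = 0.0
    G = GenotypeMatrix(subject_ids, snp_ids, dosage, mask)
    variants = None
    if variants_path is not None:
        variants = pd.read_csv(variants_path, sep="\t", dtype={"chromosome": str})
        variants = make_variant_table(
            variants["snp_id"].tolist(),
            variants["chromosome"].to_numpy(),
            variants["position"].to_numpy(),
            variants.get("allele1"),
            variants.get("allele2"),
        )
    return G, variants


def write_genotypes(G: GenotypeMatrix, path, dialect: str = "plink-raw") -> None:
    """Write a genotype matrix in the given text dialect (NA = missing)."""
    if dialect not in ("plink-raw", "additive-tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w") as fh:
        if dialect == "plink-raw":
            fh.write(" ".join(_RAW_META_COLS + [f"{s}_A" for s in G.snp_ids]) + "\n")
        else:
            fh.write("\t".join(["subject_id"] + list(G.snp_ids)) + "\n")
        sep = " " if dialect == "plink-raw" else "\t"
        for i, sid in enumerate(G.subject_ids):
            toks = [
                "NA" if G.missing_mask[i, j] else str(int(G.dosage[i, j]))
                for j in range(G.n_snps)
            ]
            if dialect == "plink-raw":
                prefix = [sid, sid, "0", "0", "0", "-9"]
            else:
                prefix = [sid]
            fh.write(sep.join(prefix + toks) + "\n")


def write_variant_table(variants: pd.DataFrame, path) -> None:
    variants.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT file: tab-separated set-id, description, member ids."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            toks = line.split("\t")
            if len(toks) < 3:
                raise ValueError(f"line {line_no}: GMT rows need >= 3 fields")
            sets[toks[0]] = [t for t in toks[2:] if t]
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for sid, members in sets.items():
            fh.write("\t".join([sid, description] + list(members)) + "\n")


# ---------------------------------------------------------------------------
# QC


def filter_variants(
    G: GenotypeMatrix, maf_min: float = 0.05, call_rate_min: float = 0.99
) -> GenotypeMatrix:
    """Retain SNPs with MAF >= maf_min and call rate >= call_rate_min.

    Both statistics are computed on non-missing calls; the subject set is
    unchanged. Defaults are the conventional 5% / 99% thresholds.
    """
    maf = G.maf()
    cr = G.call_rate()
    keep = np.flatnonzero((~np.isnan(maf)) & (maf >= maf_min) & (cr >= call_rate_min))
    if keep.size == 0:
        warnings.warn("no SNPs pass the variant filters", stacklevel=2)
    return G.subset_snps(keep)


def impute_missing(G: GenotypeMatrix, strategy: str = "column-mean") -> GenotypeMatrix:
    """Fill missing calls per SNP; column-mean gives fractional dosages."""
    if strategy not in ("column-mean", "column-mode"):
        raise ValueError(f"unknown imputation strategy {strategy!r}")
    dosage = G.dosage.copy()
    mask = G.missing_mask
    n_obs = (~mask).sum(axis=0)
    if (n_obs == 0).any():
        bad = [G.snp_ids[j] for j in np.flatnonzero(n_obs == 0)]
        raise ValueError(f"all-missing columns cannot be imputed: {bad[:5]}")
    for j in np.flatnonzero(mask.any(axis=0)):
        obs = dosage[~mask[:, j], j]
        if strategy == "column-mean":
            fill = obs.mean()
        else:
            vals, counts = np.unique(obs, return_counts=True)
            fill = vals[np.argmax(counts)]  # ties -> smallest dosage
        dosage[mask[:, j], j] = fill
    return GenotypeMatrix(
        list(G.subject_ids), list(G.snp_ids), dosage, np.zeros_like(mask)
    )


# ---------------------------------------------------------------------------
# Annotation / grouping


def map_snps_to_genes(
    variants: pd.DataFrame, genes: pd.DataFrame, window: int = 10000
) -> AnnotationMap:
    """Map each SNP to every gene whose +-window span contains it.

    A SNP at position x maps to a gene iff x in [start - window, end + window],
    inclusive on both ends. Gene spans are 1-based inclusive.
    """
    if (genes["start"] > genes["end"]).any():
        raise ValueError("gene start > end")
    snp_to_genes: dict[str, list[str]] = {}
    for chrom, vsub in variants.groupby("chromosome", sort=False):
        gsub = genes[genes["chromosome"].astype(str) == str(chrom)]
        if gsub.empty:
            continue
        starts = gsub["start"].to_numpy() - window
        ends = gsub["end"].to_numpy() + window
        gids = gsub["gene_id"].to_numpy()
        pos = vsub["position"].to_numpy()
        for sid, x in zip(vsub["snp_id"], pos):
            hits = gids[(starts <= x) & (x <= ends)]
            if hits.size:
                snp_to_genes[sid] = sorted(hits.tolist())
    return AnnotationMap(snp_to_genes=snp_to_genes)


def build_groups(
    ann: AnnotationMap,
    gene_sets: dict[str, list[str]],
    snp_ids: list[str],
    exclusions: list[str] | tuple[str, ...] = (),
) -> PathwayGroups:
    """Expand SNP->gene->pathway membership into duplicated-column groups.

    Excluded pathways are dropped, but their genes stay available to other
    pathways. A SNP whose genes belong to several retained pathways is
    duplicated into each group under a distinct expanded column index.
    Pathways with no mapped SNPs are dropped with a logged notice.
    """
    retained = {k: v for k, v in gene_sets.items() if k not in set(exclusions)}
    if not retained:
        raise ValueError("no pathways remain after exclusions")
    snp_index = {s: j for j, s in enumerate(snp_ids)}
    gene_to_snps: dict[str, list[int]] = {}
    for snp, genes in ann.snp_to_genes.items():
        j = snp_index.get(snp)
        if j is None:
            continue
        for g in genes:
            gene_to_snps.setdefault(g, []).append(j)

    group_ids: list[str] = []
    group_index_lists: list[np.ndarray] = []
    expansion: list[int] = []
    for pid in sorted(retained):
        cols: list[int] = []
        seen: set[int] = set()
        for gene in retained[pid]:
            for j in gene_to_snps.get(gene, ()):
                if j not in seen:  # one copy per SNP per pathway
                    seen.add(j)
                    cols.append(j)
        if not cols:
            logger.info("pathway %s has no mapped SNPs; dropped", pid)
            continue
        start = len(expansion)
        expansion.extend(sorted(cols))
        group_ids.append(pid)
        group_index_lists.append(np.arange(start, len(expansion)))
    if not group_ids:
        raise ValueError("every pathway is empty after SNP mapping")
    return PathwayGroups(
        group_ids=group_ids,
        group_index_lists=group_index_lists,
        expansion_map=np.array(expansion, dtype=int),
        n_original=len(snp_ids),
    )
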