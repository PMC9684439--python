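"""Single-cell TE subfamily expression: QC, aggregation and marker tests.

Cells with fewer than 200 detected features or more than 25%
mitochondrial reads are removed; genes must be detected in at least 1%
of cells and TE loci in at least 3 cells.  Counts of non-exonic TE
loci are added up per subfamily, depth-normalized to counts per 10,000
per cell and log2-transformed, and each (subfamily, cell type) pair is
tested one-vs-rest with a Wilcoxon rank-sum test, BH-corrected over
all pairs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.io import mmread
from statsmodels.stats.multitest import multipletests

from .genome_io import GeneAnnotation, TEAnnotation, overlaps
from .te_expression import GENE, TE, TE_SUBFAMILY

logger = logging.getLogger(__name__)


def read_cell_matrix(
    mtx_path: str | Path, cells_path: str | Path, features_path: str | Path
) -> ad.AnnData:
    """Load a matrix-market triplet plus cell/feature metadata TSVs."""
    X = sparse.csr_matrix(mmread(str(mtx_path)))
    obs = pd.read_csv(cells_path, sep="\t", index_col=0)
    var = pd.read_csv(features_path, sep="\t", index_col=0, keep_default_na=False)
    if X.shape != (len(obs), len(var)):
        raise ValueError(
            f"matrix shape {X.shape} does not match metadata "
            f"({len(obs)} cells, {len(var)} features)"
        )
    return ad.AnnData(X=X, obs=obs, var=var)


def _detected_per_cell(adata: ad.AnnData) -> np.ndarray:
    return np.asarray((adata.X > 0).sum(axis=1)).ravel()


def qc_cells(
    adata: ad.AnnData,
    min_features: int = 200,
    max_mito: float = 0.25,
    mode: str = "or",
) -> ad.AnnData:
    """Remove low-quality cells.

    Default (``mode='or'``): a cell is removed when it has fewer than
    ``min_features`` detected features OR a mitochondrial fraction
    above ``max_mito``; both inequalities are strict, so a cell at
    exactly the thresholds is retained.  ``mode='and'`` removes only
    cells violating both.
    """
    if mode not in ("or", "and"):
        raise ValueError(f"unknown mode {mode!r}")
    if "n_features_detected" in adata.obs:
        n_feat = adata.obs["n_features_detected"].to_numpy()
    else:
        n_feat = _detected_per_cell(adata)
    mito = adata.obs["mito_fraction"].to_numpy()
    low_feat = n_feat < min_features
    high_mito = mito > max_mito
    bad = (low_feat | high_mito) if mode == "or" else (low_feat & high_mito)
    logger.info(
        "qc_cells: removed %d cells (%d low-feature, %d high-mito)",
        int(bad.sum()),
        int(low_feat.sum()),
        int(high_mito.sum()),
    )
    out = adata[~bad].copy()
    if out.n_obs == 0:
        warnings.warn("qc_cells removed every cell", stacklevel=2)
    return out


def filter_features_sc(
    adata: ad.AnnData,
    min_gene_cell_frac: float = 0.01,
    min_te_cells: int = 3,
) -> ad.AnnData:
    """Keep genes detected in >= 1% of cells and TE loci detected in >= 3 cells."""
    detected = np.asarray((adata.X > 0).sum(axis=0)).ravel()
    kind = adata.var["kind"].to_numpy()
    n_cells = adata.n_obs
    keep = np.where(
        kind == GENE,
        detected >= min_gene_cell_frac * n_cells,
        detected >= min_te_cells,
    )
    logger.info(
        "filter_features_sc: kept %d/%d features", int(keep.sum()), adata.n_vars
    )
    return adata[:, keep].copy()


def normalize_and_aggregate(
    adata: ad.AnnData,
    tes: TEAnnotation,
    genes: GeneAnnotation,
    scale: float = 1e4,
) -> ad.AnnData:
    """Sum non-exonic TE loci per subfamily, then log-CP10K normalize.

    TE loci overlapping exons are excluded from aggregation.  The
    returned AnnData holds gene rows plus one row per subfamily;
    ``layers['counts']`` keeps the raw aggregated counts and ``X`` the
    per-cell log2(count / total * 10000 + 1) values, with the total
    taken over the full input matrix of each cell.
    """
    kind = adata.var["kind"].to_numpy()
    by_id = tes.by_locus_id()
    te_cols = np.flatnonzero(kind == TE)
    te_ids = adata.var_names[te_cols]
    exons = genes.exon_intervals()
    te_ivs = [by_id[f].interval for f in te_ids]
    exonic = {te_ids[qi] for qi, _ in overlaps(te_ivs, exons)}

    X = sparse.csc_matrix(adata.X)
    totals = np.asarray(X.sum(axis=1)).ravel()  # per-cell library, all features

    gene_cols = np.flatnonzero(kind == GENE)
    blocks = [X[:, gene_cols]]
    new_names = list(adata.var_names[gene_cols])
    new_kind = [GENE] * len(gene_cols)

    subfam_of = {f: by_id[f].subfamily for f in te_ids if f not in exonic}
    for subfam in sorted(set(subfam_of.values())):
        cols = [
            te_cols[i] for i, f in enumerate(te_ids) if subfam_of.get(f) == subfam
        ]
        blocks.append(sparse.csc_matrix(X[:, cols].sum(axis=1)))
        new_names.append(subfam)
        new_kind.append(TE_SUBFAMILY)
    counts = sparse.hstack(blocks, format="csr")

    with np.errstate(divide="ignore", invalid="ignore"):
        dense = counts.toarray().astype(float)
        safe = np.where(totals > 0, totals, 1.0)
        norm = np.log2(dense / safe[:, None] * scale + 1.0)
    out = ad.AnnData(
        X=norm,
        obs=adata.obs.copy(),
        var=pd.DataFrame(
            {"kind": new_kind}, index=pd.Index(new_names, name="feature_id")
        ),
    )
    out.layers["counts"] = counts
    return out


def wilcoxon_rank_sum(
    x: np.ndarray, y: np.ndarray, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Rank-sum test returning (W statistic of x, p).

    Uses the exact null distribution when both groups have <= 25
    observations and there are no ties; otherwise the tie-corrected
    normal approximation.  Degenerate all-tied data gives p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return float(stats.rankdata(pooled)[: len(x)].sum()), 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (max(len(x), len(y)) <= 25 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    W = float(res.statistic) + len(x) * (len(x) + 1) / 2.0  # U -> rank-sum W
    p = float(res.pvalue)
    if np.isnan(p):  # zero-variance normal approximation
        p = 1.0
    return W, min(p, 1.0)


@dataclass
class MarkerResult:
    """One-vs-rest subfamily markers per cell type."""

    table: pd.DataFrame  # subfamily, cell_type, mean_in, mean_out, W, p, adj_p


def celltype_marker_test(
    adata: ad.AnnData,
    groupby: str = "cell_type",
    alternative: str = "two-sided",
) -> MarkerResult:
    """Wilcoxon rank-sum of each subfamily, each cell type vs all others.

    Expects the normalized, aggregated AnnData from
    :func:`normalize_and_aggregate`; tests only ``te_subfamily``
    features and BH-corrects across all (subfamily, cell type) pairs.
    """
    labels = adata.obs[groupby].to_numpy()
    types = sorted(pd.unique(labels))
    if len(types) < 2:
        raise ValueError("need >= 2 cell types")
    sub_cols = np.flatnonzero(adata.var["kind"].to_numpy() == TE_SUBFAMILY)
    X = adata.X
    X = X.toarray() if sparse.issparse(X) else np.asarray(X)
    rows = []
    for j in sub_cols:
        vals = X[:, j]
        for ct in types:
            mask = labels == ct
            if mask.sum() == 0 or (~mask).sum() == 0:
                warnings.warn(f"empty group for {ct}; skipped", stacklevel=2)
                continue
            W, p = wilcoxon_rank_sum(vals[mask], vals[~mask], alternative)
            rows.append(
                (
                    adata.var_names[j],
                    ct,
                    float(vals[mask].mean()),
                    float(vals[~mask].mean()),
                    W,
                    p,
                )
            )
    table = pd.DataFrame(
        rows, columns=["subfamily", "cell_type", "mean_in", "mean_out", "W", "p"]
    )
    table["adj_p"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    return MarkerResult(table=table)


@dataclass
class AgeProfile:
    """Expressed-integrant counts and percentages per evolutionary age."""

    table: pd.DataFrame  # age_category, n_expressed, n_total, percent_expressed


def expression_summaries(
    adata: ad.AnnData, tes: TEAnnotation
) -> tuple[AgeProfile, pd.DataFrame]:
    """Expressed-locus summaries by age category and by subfamily.

    ``adata`` must be locus-level (post feature filtering, before
    aggregation): a TE locus counts as expressed iff it survived
    :func:`filter_features_sc`.  Percentages are relative to the total
    number of annotated integrants in each category / subfamily.
    """
    by_id = tes.by_locus_id()
    kind = adata.var["kind"].to_numpy()
    expressed = [f for f, k in zip(adata.var_names, kind) if k == TE]
    age_expr: dict[str, int] = {}
    sub_expr: dict[str, int] = {}
    for f in expressed:
        te = by_id[f]
        age_expr[te.age_category] = age_expr.get(te.age_category, 0) + 1
        sub_expr[te.subfamily] = sub_expr.get(te.subfamily, 0) + 1
    age_total: dict[str, int] = {}
    sub_total: dict[str, int] = {}
    for te in tes:
        age_total[te.age_category] = age_total.get(te.age_category, 0) + 1
        sub_total[te.subfamily] = sub_total.get(te.subfamily, 0) + 1
    age_tab = pd.DataFrame(
        {
            "n_expressed": pd.Series(age_expr, dtype=int),
            "n_total": pd.Series(age_total, dtype=int),
        }
    ).fillna(0).astype(int)
    age_tab["percent_expressed"] = 100.0 * age_tab["n_expressed"] / age_tab["n_total"]
    sub_tab = pd.DataFrame(
        {
            "n_expressed": pd.Series(sub_expr, dtype=int),
            "n_total": pd.Series(sub_total, dtype=int),
        }
    ).fillna(0).astype(int)
    sub_tab["percent_expressed"] = 100.0 * sub_tab["n_expressed"] / sub_tab["n_total"]
    return AgeProfile(table=age_tab.sort_index()), sub_tab.sort_index()
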