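"""Cis-regulatory activity of TE subfamilies from expression deviations.

The model: per-gene deviations in logged expression between a treatment
and a control condition are written as a linear combination of the
occurrences of TE subfamily integrants near each gene's TSS,

    dE_g = b0 + sum_s N_gs * a_s + e_g,

where N_gs counts integrants of subfamily s overlapping the window
TSS_g +/- 50 kb (exon-overlapping integrants excluded, subfamilies with
fewer than 150 gene colocalizations dropped).  The fitted coefficient
a_s is the expression deviation attributable to one nearby integrant of
subfamily s — its cis-regulatory activity.  Inference is the usual OLS
t-test per coefficient with Benjamini-Hochberg correction across
subfamilies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome_io import GeneAnnotation, TEAnnotation, overlaps

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_BP = 50_000
DEFAULT_MIN_COLOC = 150

# Right-closed activity bins used for the summary report
ACTIVITY_BIN_EDGES = (0.0, 0.01, 0.05, 0.1)
ACTIVITY_BIN_LABELS = ("<=0", "0-0.01", "0.01-0.05", "0.05-0.1", ">0.1")


@dataclass
class OccurrenceMatrix:
    """Genes x subfamilies counts of nearby TE integrants."""

    matrix: pd.DataFrame  # int counts, rows = gene ids, cols = subfamilies
    window_bp: int
    min_coloc: int
    dropped_low_coloc: dict[str, int] = field(default_factory=dict)

    @property
    def gene_ids(self) -> pd.Index:
        return self.matrix.index

    @property
    def subfamilies(self) -> pd.Index:
        return self.matrix.columns


def build_occurrence_matrix(
    genes: GeneAnnotation,
    tes: TEAnnotation,
    window_bp: int = DEFAULT_WINDOW_BP,
    min_coloc: int = DEFAULT_MIN_COLOC,
    coloc_mode: str = "pairs",
    binary: bool = False,
) -> OccurrenceMatrix:
    """Count subfamily integrants within ``window_bp`` of each coding TSS.

    The window is [TSS - window_bp, TSS + window_bp + 1); an integrant
    counts when it overlaps the window by >= 1 bp.  Integrants
    overlapping any exon are excluded.  Subfamilies whose total
    colocalization (gene-integrant pairs by default, distinct genes
    with ``coloc_mode='genes'``) is below ``min_coloc`` are dropped and
    logged.  ``binary=True`` reduces counts to presence/absence.
    """
    if coloc_mode not in ("pairs", "genes"):
        raise ValueError(f"unknown coloc_mode {coloc_mode!r}")
    coding = genes.protein_coding()
    if len(coding) == 0:
        raise ValueError("no protein-coding genes")

    exons = genes.exon_intervals()
    te_ivs = tes.intervals()
    exonic_idx = {qi for qi, _ in overlaps(te_ivs, exons)}
    clean = [te for i, te in enumerate(tes.integrants) if i not in exonic_idx]
    logger.info(
        "build_occurrence_matrix: %d/%d integrants excluded as exon-overlapping",
        len(exonic_idx),
        len(te_ivs),
    )

    # per (chrom, subfamily): independently sorted starts and ends
    index: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    groups: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for te in clean:
        groups.setdefault((te.interval.chrom, te.subfamily), []).append(
            (te.interval.start, te.interval.end)
        )
    for key, spans in groups.items():
        starts = np.sort(np.array([s for s, _ in spans], dtype=np.int64))
        ends = np.sort(np.array([e for _, e in spans], dtype=np.int64))
        index[key] = (starts, ends)

    subfamilies = sorted({s for _, s in index})
    gene_ids = [g.gene_id for g in coding]
    mat = np.zeros((len(gene_ids), len(subfamilies)), dtype=np.int64)
    col = {s: j for j, s in enumerate(subfamilies)}
    for i, g in enumerate(coding):
        ws = g.tss - window_bp
        we = g.tss + window_bp + 1
        for s in subfamilies:
            key = (g.interval.chrom, s)
            if key not in index:
                continue
            starts, ends = index[key]
            n = np.searchsorted(starts, we, side="left") - np.searchsorted(
                ends, ws, side="right"
            )
            if n > 0:
                mat[i, col[s]] = n
    if binary:
        mat = (mat > 0).astype(np.int64)

    df = pd.DataFrame(mat, index=pd.Index(gene_ids, name="gene_id"), columns=subfamilies)
    coloc = df.sum(axis=0) if coloc_mode == "pairs" else (df > 0).sum(axis=0)
    low = coloc[coloc < min_coloc]
    if len(low):
        logger.info(
            "build_occurrence_matrix: dropped %d subfamilies below %d colocalizations",
            len(low),
            min_coloc,
        )
    kept = [s for s in df.columns if s not in low.index]
    return OccurrenceMatrix(
        matrix=df[kept],
        window_bp=window_bp,
        min_coloc=min_coloc,
        dropped_low_coloc={s: int(v) for s, v in low.items()},
    )


@dataclass
class ActivityTable:
    """Per-subfamily fitted activities with OLS inference."""

    table: pd.DataFrame  # activity, std_error, t_stat, p, adj_p, n_occurrences, dropped
    intercept: float
    residual_df: int
    sigma2: float


def _drop_collinear(X: np.ndarray, totals: np.ndarray, names: list[str]) -> list[int]:
    """Indices of columns to drop so [1 | X_kept] has full column rank.

    Columns are considered in descending occurrence-total order (name
    as tie-break), greedily kept while they increase the rank; the
    lowest-occurrence members of a collinear set are therefore dropped.
    """
    order = sorted(range(X.shape[1]), key=lambda j: (-totals[j], names[j]))
    n = X.shape[0]
    basis = [np.ones(n)]
    kept: set[int] = set()
    rank = 1
    for j in order:
        cand = np.column_stack(basis + [X[:, j]])
        r = np.linalg.matrix_rank(cand)
        if r > rank:
            basis.append(X[:, j])
            kept.add(j)
            rank = r
    return [j for j in range(X.shape[1]) if j not in kept]


def estimate_activity(dE: pd.Series, N: OccurrenceMatrix) -> ActivityTable:
    """OLS fit of expression deviations on the occurrence matrix.

    Returns per-subfamily activities with standard errors, two-sided
    t-tests (df = genes - retained columns - 1) and BH-adjusted
    p-values over subfamily coefficients (intercept excluded).  Exactly
    collinear columns are dropped deterministically and flagged.  When
    the fit has zero residual, the inference columns are left undefined
    (NaN) — the coefficients are still reported.
    """
    common = N.gene_ids.intersection(dE.index)
    mat = N.matrix.loc[common]
    y = dE.loc[common].to_numpy(dtype=float)
    if not np.isfinite(y).all():
        raise ValueError("non-finite response values")
    names = list(mat.columns)
    X = mat.to_numpy(dtype=float)
    G, S = X.shape
    if G < S + 2:
        raise ValueError(f"need >= {S + 2} genes for {S} subfamilies, have {G}")

    totals = mat.sum(axis=0).to_numpy()
    dropped_idx = _drop_collinear(X, totals, names)
    kept_idx = [j for j in range(S) if j not in dropped_idx]
    if G <= len(kept_idx) + 1:
        raise ValueError("fewer genes than retained columns")
    Xk = np.column_stack([np.ones(G)] + [X[:, j] for j in kept_idx])
    XtX = Xk.T @ Xk
    beta = np.linalg.solve(XtX, Xk.T @ y)
    resid = y - Xk @ beta
    rss = float(resid @ resid)
    df_resid = G - len(kept_idx) - 1
    sigma2 = rss / df_resid
    scale = max(float(y @ y), 1.0)
    zero_resid = rss <= 1e-12 * scale

    act = pd.Series(np.nan, index=names, dtype=float)
    se = pd.Series(np.nan, index=names, dtype=float)
    tval = pd.Series(np.nan, index=names, dtype=float)
    p = pd.Series(np.nan, index=names, dtype=float)
    for pos, j in enumerate(kept_idx, start=1):
        act.iloc[j] = beta[pos]
    if not zero_resid:
        cov = sigma2 * np.linalg.inv(XtX)
        for pos, j in enumerate(kept_idx, start=1):
            se.iloc[j] = np.sqrt(cov[pos, pos])
            tval.iloc[j] = beta[pos] / se.iloc[j]
            p.iloc[j] = 2 * stats.t.sf(abs(tval.iloc[j]), df_resid)
    adj = pd.Series(np.nan, index=names, dtype=float)
    tested = p.dropna()
    if len(tested):
        adj.loc[tested.index] = multipletests(tested.to_numpy(), method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "activity": act,
            "std_error": se,
            "t_stat": tval,
            "p": p,
            "adj_p": adj,
            "n_occurrences": totals,
            "dropped": [j in dropped_idx for j in range(S)],
        },
        index=pd.Index(names, name="subfamily"),
    )
    if dropped_idx:
        logger.info(
            "estimate_activity: dropped collinear columns %s",
            [names[j] for j in dropped_idx],
        )
    return ActivityTable(
        table=table,
        intercept=float(beta[0]),
        residual_df=df_resid,
        sigma2=sigma2 if not zero_resid else 0.0,
    )


def rank_activities(
    result: ActivityTable,
    bin_edges: tuple[float, ...] = ACTIVITY_BIN_EDGES,
) -> tuple[pd.DataFrame, pd.Series]:
    """Volcano-ready ranking plus an activity-bin summary.

    Rows are sorted by adjusted p then |activity| (descending) and gain
    a ``neg_log10_adj_p`` column.  The bin summary counts activities in
    right-closed bins (<=0, 0-0.01, 0.01-0.05, 0.05-0.1, >0.1 with the
    default edges); an activity exactly on an edge falls in the lower
    bin.
    """
    tab = result.table[~result.table["dropped"]].copy()
    if tab.empty:
        raise ValueError("empty activity table")
    tab["neg_log10_adj_p"] = -np.log10(tab["adj_p"])
    tab["_abs"] = tab["activity"].abs()
    tab = tab.sort_values(["adj_p", "_abs"], ascending=[True, False]).drop(columns="_abs")
    edges = [-np.inf, *bin_edges, np.inf]
    labels = ACTIVITY_BIN_LABELS if bin_edges == ACTIVITY_BIN_EDGES else None
    cats = pd.cut(tab["activity"], bins=edges, right=True, labels=labels)
    bins = cats.value_counts().sort_index()
    return tab, bins
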