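"""Bulk TE/gene expression quantification.

Implements the filtering, normalization and testing rules used for
TE-aware bulk RNA-seq: features must reach 3 reads in at least one
sample, TE loci overlapping exons are discarded, between-sample scaling
uses trimmed-mean-of-M-values (TMM) factors computed on gene counts
only (gene counts also serve as the library size), differential calls
require fold change > 2 with p < 0.05, locus counts are added up per
subfamily (optionally restricted to intergenic loci, i.e. outside
protein-coding gene bodies extended by 10 kb), and per-subfamily
over-representation of upregulated loci is scored with one-sided
hypergeometric tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome_io import GeneAnnotation, TEAnnotation, GenomicInterval, overlaps

logger = logging.getLogger(__name__)

GENE = "gene"
TE = "te"
TE_SUBFAMILY = "te_subfamily"


@dataclass
class CountMatrix:
    """Non-negative integer feature x sample counts with metadata.

    ``feature_kind`` labels each feature as ``gene``, ``te`` (locus) or
    ``te_subfamily``; ``conditions`` maps each sample to its condition.
    """

    counts: pd.DataFrame
    feature_kind: pd.Series
    conditions: pd.Series

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate feature ids")
        if not self.feature_kind.index.equals(self.counts.index):
            self.feature_kind = self.feature_kind.reindex(self.counts.index)
        if self.feature_kind.isna().any():
            raise ValueError("every feature needs a kind label")
        missing = [s for s in self.counts.columns if s not in self.conditions.index]
        if missing:
            raise ValueError(f"samples without condition label: {missing}")
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def kind_mask(self, kind: str) -> pd.Series:
        return self.feature_kind == kind

    def subset_features(self, feature_ids) -> "CountMatrix":
        return CountMatrix(
            self.counts.loc[feature_ids],
            self.feature_kind.loc[feature_ids],
            self.conditions,
        )

    @classmethod
    def concat(cls, a: "CountMatrix", b: "CountMatrix") -> "CountMatrix":
        """Column-wise concatenation of two sample sets over identical features."""
        if not a.counts.index.equals(b.counts.index):
            raise ValueError("feature sets differ")
        counts = pd.concat([a.counts, b.counts], axis=1)
        conditions = pd.concat([a.conditions, b.conditions])
        return cls(counts, a.feature_kind, conditions)

    def write_tsv(self, counts_path: str | Path, design_path: str | Path) -> None:
        out = self.counts.copy()
        out.insert(0, "kind", self.feature_kind)
        out.to_csv(counts_path, sep="\t", index_label="feature")
        self.conditions.rename("condition").to_csv(
            design_path, sep="\t", index_label="sample"
        )

    @classmethod
    def read_tsv(cls, counts_path: str | Path, design_path: str | Path) -> "CountMatrix":
        df = pd.read_csv(counts_path, sep="\t", index_col="feature")
        kind = df.pop("kind")
        design = pd.read_csv(design_path, sep="\t", index_col="sample")["condition"]
        return cls(df, kind, design)


@dataclass
class NormalizationFactors:
    """Per-sample gene library sizes and TMM scaling factors."""

    gene_library_size: pd.Series
    tmm_factor: pd.Series
    reference_sample: str

    def effective_library_size(self) -> pd.Series:
        return self.gene_library_size * self.tmm_factor


@dataclass
class DEResult:
    """Per-feature differential expression table.

    ``de`` applies the printed rule (|log2FC| > 1 and raw p < 0.05);
    ``de_adj`` applies the same fold rule with BH-adjusted p.
    """

    table: pd.DataFrame  # columns: log2FC, p, adj_p, de, de_adj
    contrast: tuple[str, str]


def filter_features(
    counts: CountMatrix,
    tes: TEAnnotation,
    genes: GeneAnnotation,
    min_reads: int = 3,
) -> CountMatrix:
    """Discard exon-overlapping TE loci and features never reaching ``min_reads``.

    A feature (gene or TE locus) is kept only if at least one sample
    has >= ``min_reads`` counts; TE loci overlapping any exon by >= 1 bp
    are removed regardless of counts.
    """
    by_id = tes.by_locus_id()
    te_ids = [f for f, k in counts.feature_kind.items() if k == TE]
    unknown = [f for f in te_ids if f not in by_id]
    if unknown:
        raise ValueError(f"TE feature ids without annotation: {unknown[:5]}")
    exons = genes.exon_intervals()
    te_ivs = [by_id[f].interval for f in te_ids]
    exonic = {te_ids[qi] for qi, _ in overlaps(te_ivs, exons)}

    reached = (counts.counts >= min_reads).any(axis=1)
    keep = [
        f
        for f in counts.counts.index
        if reached[f] and f not in exonic
    ]
    n_exonic = len(exonic)
    n_low = int((~reached).sum())
    logger.info(
        "filter_features: removed %d exon-overlapping TE loci, "
        "%d features below %d reads in every sample",
        n_exonic,
        n_low,
        min_reads,
    )
    return counts.subset_features(keep)


def _choose_reference(y: np.ndarray, lib: np.ndarray) -> int:
    # sample whose upper-quartile count fraction is closest to the mean
    f75 = np.array(
        [np.percentile(y[:, j][y[:, j] > 0] / lib[j], 75) if (y[:, j] > 0).any() else 0
         for j in range(y.shape[1])]
    )
    return int(np.argmin(np.abs(f75 - f75.mean())))


def _tmm_pair(
    yk: np.ndarray,
    yr: np.ndarray,
    nk: float,
    nr: float,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
) -> float:
    mask = (yk > 0) & (yr > 0)
    yk, yr = yk[mask].astype(float), yr[mask].astype(float)
    if yk.size == 0:
        return 1.0
    m = np.log2((yk / nk) / (yr / nr))
    a = 0.5 * np.log2((yk / nk) * (yr / nr))
    w = (nk - yk) / (nk * yk) + (nr - yr) / (nr * yr)
    n = m.size
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * sum_trim) + 1
    hi_a = n + 1 - lo_a
    rm = stats.rankdata(m)
    ra = stats.rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any() or w[keep].sum() == 0:
        return 1.0
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    if not np.isfinite(f) or abs(f) < 1e-6:
        f = 0.0
    return float(2.0**f)


def tmm_normalize(counts: CountMatrix) -> NormalizationFactors:
    """TMM scaling factors computed on gene features with gene library sizes.

    M values are trimmed by 30%, A values by 5%, and the trimmed mean is
    precision-weighted (delta-method weights); factors are rescaled to
    geometric mean 1.
    """
    if len(counts.samples) < 2:
        raise ValueError("TMM needs >= 2 samples")
    gene_counts = counts.counts.loc[counts.kind_mask(GENE)].to_numpy(dtype=float)
    lib = gene_counts.sum(axis=0)
    if (lib <= 0).any():
        bad = [s for s, v in zip(counts.samples, lib) if v <= 0]
        raise ValueError(f"samples with zero gene counts: {bad}")
    ref = _choose_reference(gene_counts, lib)
    factors = np.array(
        [
            _tmm_pair(gene_counts[:, j], gene_counts[:, ref], lib[j], lib[ref])
            for j in range(gene_counts.shape[1])
        ]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    return NormalizationFactors(
        gene_library_size=pd.Series(lib, index=counts.samples),
        tmm_factor=pd.Series(factors, index=counts.samples),
        reference_sample=counts.samples[ref],
    )


def normalized_log_counts(
    counts: CountMatrix, factors: NormalizationFactors, prior: float = 0.5
) -> pd.DataFrame:
    """log2 counts rescaled to a common effective library size, + prior."""
    eff = factors.effective_library_size().loc[counts.samples].to_numpy(float)
    scale = np.exp(np.mean(np.log(eff)))
    norm = counts.counts.to_numpy(float) / eff[None, :] * scale
    return pd.DataFrame(
        np.log2(norm + prior), index=counts.counts.index, columns=counts.samples
    )


def differential_expression(
    counts: CountMatrix,
    factors: NormalizationFactors,
    contrast: tuple[str, str] = ("treatment", "control"),
    prior: float = 0.5,
) -> DEResult:
    """Welch t-test on log normalized counts, treatment vs control.

    log2FC is the difference of group means of log2(normalized + prior);
    p-values are two-sided and BH-adjusted across all tested features.
    """
    treat, ctrl = contrast
    cond = counts.conditions
    t_samples = [s for s in counts.samples if cond[s] == treat]
    c_samples = [s for s in counts.samples if cond[s] == ctrl]
    if len(t_samples) < 2 or len(c_samples) < 2:
        raise ValueError("need >= 2 replicates per condition")
    logged = normalized_log_counts(counts, factors, prior)
    x1 = logged[t_samples].to_numpy()
    x0 = logged[c_samples].to_numpy()
    n1, n0 = x1.shape[1], x0.shape[1]
    m1, m0 = x1.mean(axis=1), x0.mean(axis=1)
    v1, v0 = x1.var(axis=1, ddof=1), x0.var(axis=1, ddof=1)
    lfc = m1 - m0
    with np.errstate(divide="ignore", invalid="ignore"):
        se2 = v1 / n1 + v0 / n0
        t = (m1 - m0) / np.sqrt(se2)
        df = se2**2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v0 / n0) ** 2 / (n0 - 1)
        )
    p = np.where(
        se2 == 0,
        np.where(lfc == 0, 1.0, 0.0),
        2 * stats.t.sf(np.abs(t), np.where(np.isfinite(df), df, 1.0)),
    )
    adj_p = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "log2FC": lfc,
            "p": p,
            "adj_p": adj_p,
            "de": (np.abs(lfc) > 1) & (p < 0.05),
            "de_adj": (np.abs(lfc) > 1) & (adj_p < 0.05),
        },
        index=logged.index,
    )
    return DEResult(table=table, contrast=contrast)


def aggregate_subfamily(
    locus_counts: CountMatrix,
    tes: TEAnnotation,
    genes: GeneAnnotation,
    mode: str = "all",
    flank_bp: int = 10_000,
) -> CountMatrix:
    """Add up TE locus counts per subfamily.

    ``mode='all'`` sums every locus; ``mode='intergenic'`` first removes
    loci overlapping any protein-coding gene body extended by
    ``flank_bp`` on each side, capturing only reads from TEs outside
    genes and their flanks.
    """
    if mode not in ("all", "intergenic"):
        raise ValueError(f"unknown mode {mode!r}")
    by_id = tes.by_locus_id()
    te_ids = [f for f, k in locus_counts.feature_kind.items() if k == TE]
    keep = te_ids
    if mode == "intergenic":
        bodies = []
        for g in genes.protein_coding():
            iv = g.interval
            bodies.append(
                GenomicInterval(
                    iv.chrom,
                    max(0, iv.start - flank_bp),
                    min(tes.genome[iv.chrom], iv.end + flank_bp),
                )
            )
        te_ivs = [by_id[f].interval for f in te_ids]
        genic = {te_ids[qi] for qi, _ in overlaps(te_ivs, bodies)}
        keep = [f for f in te_ids if f not in genic]
        logger.info(
            "aggregate_subfamily: %d/%d loci excluded as genic (+/- %d bp)",
            len(genic),
            len(te_ids),
            flank_bp,
        )
    sub = locus_counts.counts.loc[keep]
    labels = pd.Series({f: by_id[f].subfamily for f in keep})
    agg = sub.groupby(labels).sum().sort_index()
    kind = pd.Series(TE_SUBFAMILY, index=agg.index)
    return CountMatrix(agg, kind, locus_counts.conditions)


@dataclass
class SubfamilyEnrichment:
    """Per-subfamily over-representation of upregulated TE loci."""

    table: pd.DataFrame  # k_up, k_expressed, n_up_total, n_expressed_total,
    #                      odds_ratio, p, adj_p


def subfamily_overrepresentation(
    de: DEResult,
    tes: TEAnnotation,
    min_lfc: float = 1.0,
    use_adjusted: bool = True,
) -> SubfamilyEnrichment:
    """One-sided hypergeometric test for excess upregulated loci per subfamily.

    The universe is the TE loci present in ``de`` (i.e. expressed and
    retained by the filters); a locus is "up" when log2FC > ``min_lfc``
    and its (adjusted, by default) p-value is < 0.05.
    """
    by_id = tes.by_locus_id()
    loci = [f for f in de.table.index if f in by_id]
    if not loci:
        raise ValueError("empty TE universe")
    tab = de.table.loc[loci]
    pcol = "adj_p" if use_adjusted else "p"
    up = (tab["log2FC"] > min_lfc) & (tab[pcol] < 0.05)
    n_total = len(loci)
    n_up = int(up.sum())
    subfam = pd.Series({f: by_id[f].subfamily for f in loci})
    rows = []
    for s, members in subfam.groupby(subfam).groups.items():
        k_exp = len(members)
        k_up = int(up.loc[members].sum())
        p = stats.hypergeom.sf(k_up - 1, n_total, n_up, k_exp)
        a, b = k_up, k_exp - k_up
        c, d = n_up - k_up, (n_total - k_exp) - (n_up - k_up)
        odds = (a * d) / (b * c) if b * c > 0 else np.inf
        rows.append((s, k_up, k_exp, n_up, n_total, odds, p))
    table = pd.DataFrame(
        rows,
        columns=[
            "subfamily",
            "k_up",
            "k_expressed",
            "n_up_total",
            "n_expressed_total",
            "odds_ratio",
            "p",
        ],
    ).set_index("subfamily")
    table["adj_p"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    return SubfamilyEnrichment(table=table.sort_values("p"))
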