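import math

import numpy as np
import pandas as pd
import pytest

from tecre import te_expression as tex
from tecre.genome_io import (
    Genome,
    GenomicInterval,
    TEAnnotation,
    TEIntegrant,
)


def _count_matrix(counts: dict, kinds: dict, conditions: dict) -> tex.CountMatrix:
    df = pd.DataFrame(counts).T
    return tex.CountMatrix(df, pd.Series(kinds), pd.Series(conditions))


@pytest.fixture()
def toy_bulk(toy_annotation):
    tes, genes = toy_annotation
    counts = {
        "te_exonic": [50, 60, 70],  # exon overlap: out despite high counts
        "te_far": [0, 0, 3],  # reaches 3 reads in one sample: in
        "te_flank": [2, 2, 2],  # never 3 reads: out
        "te_low": [10, 20, 30],  # clean TE: in
    }
    cm = _count_matrix(
        counts,
        {k: "te" for k in counts},
        {0: "control", 1: "control", 2: "treatment"},
    )
    return cm, tes, genes


class TestFilters:
    def test_three_read_and_exon_rules(self, toy_bulk):
        cm, tes, genes = toy_bulk
        out = tex.filter_features(cm, tes, genes)
        assert set(out.counts.index) == {"te_far", "te_low"}

    def test_filters_commute(self, toy_bulk):
        cm, tes, genes = toy_bulk
        # min-read rule first, then exon rule (via filter with min_reads=0)
        reached = cm.counts.index[(cm.counts >= 3).any(axis=1)]
        order_a = tex.filter_features(cm.subset_features(list(reached)), tes, genes, min_reads=0)
        order_b = tex.filter_features(cm, tes, genes, min_reads=3)
        assert set(order_a.counts.index) == set(order_b.counts.index)

    def test_unknown_te_id_rejected(self, toy_annotation):
        tes, genes = toy_annotation
        cm = _count_matrix({"ghost": [5, 5, 5]}, {"ghost": "te"}, {0: "c", 1: "c", 2: "t"})
        with pytest.raises(ValueError, match="ghost"):
            tex.filter_features(cm, tes, genes)


class TestTMM:
    # frozen reference: edgeR::calcNormFactors(method="TMM") on the
    # deterministic fixture generated below (same rng draws)
    EDGER_FACTORS = np.array([1.060095, 1.054003, 0.954107, 0.938029])

    @staticmethod
    def _fixture():
        rng = np.random.default_rng(42)
        n = 1000
        base = rng.lognormal(4, 1, n)
        scales = np.array([1.0, 1.6, 0.7, 1.2])
        mu = base[:, None] * scales[None, :]
        spike = rng.choice(n, size=50, replace=False)
        mu2 = mu.copy()
        mu2[spike, 2:] *= 4.0  # 5% asymmetric DE spike-in
        size = 10.0
        counts = rng.negative_binomial(size, size / (size + mu2))
        df = pd.DataFrame(
            counts, index=[f"g{i}" for i in range(n)], columns=["s1", "s2", "s3", "s4"]
        )
        return tex.CountMatrix(
            df,
            pd.Series("gene", index=df.index),
            pd.Series({"s1": "control", "s2": "control", "s3": "treatment", "s4": "treatment"}),
        )

    def test_identical_samples_get_unit_factors(self):
        df = pd.DataFrame({"a": [10, 20, 30, 5], "b": [10, 20, 30, 5]})
        cm = tex.CountMatrix(df, pd.Series("gene", index=df.index), pd.Series({"a": "c", "b": "t"}))
        fac = tex.tmm_normalize(cm)
        assert np.allclose(fac.tmm_factor, 1.0)

    def test_doubled_library_cancels(self):
        rng = np.random.default_rng(0)
        a = rng.integers(5, 500, 200)
        df = pd.DataFrame({"a": a, "b": 2 * a})
        cm = tex.CountMatrix(df, pd.Series("gene", index=df.index), pd.Series({"a": "c", "b": "t"}))
        fac = tex.tmm_normalize(cm)
        norm = tex.normalized_log_counts(cm, fac, prior=0.0)
        assert np.allclose(norm["a"], norm["b"])

    def test_matches_edger_reference_within_2pct(self):
        fac = tex.tmm_normalize(self._fixture())
        rel = np.abs(fac.tmm_factor.to_numpy() - self.EDGER_FACTORS) / self.EDGER_FACTORS
        assert rel.max() < 0.02

    def test_factor_geometric_mean_is_one(self):
        fac = tex.tmm_normalize(self._fixture())
        assert np.exp(np.mean(np.log(fac.tmm_factor))) == pytest.approx(1.0, abs=1e-9)

    def test_library_size_uses_genes_only(self, toy_annotation):
        df = pd.DataFrame(
            {"a": [100, 50, 900], "b": [100, 50, 10]},
            index=["g1", "g2", "te1"],
        )
        cm = tex.CountMatrix(
            df,
            pd.Series({"g1": "gene", "g2": "gene", "te1": "te"}),
            pd.Series({"a": "c", "b": "t"}),
        )
        fac = tex.tmm_normalize(cm)
        assert fac.gene_library_size.tolist() == [150, 150]

    def test_zero_gene_sample_rejected(self):
        df = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
        cm = tex.CountMatrix(df, pd.Series("gene", index=df.index), pd.Series({"a": "c", "b": "t"}))
        with pytest.raises(ValueError, match="zero gene counts"):
            tex.tmm_normalize(cm)

    def test_normalization_preserves_within_sample_rank_order(self):
        cm = self._fixture()
        fac = tex.tmm_normalize(cm)
        norm = tex.normalized_log_counts(cm, fac)
        for s in cm.samples:
            # sorting by raw counts must sort the normalized values too
            assert (norm[s].to_numpy()[np.argsort(cm.counts[s].to_numpy())]
                    == np.sort(norm[s].to_numpy())).all()


class TestDifferentialExpression:
    def _cm(self, control: np.ndarray, treatment: np.ndarray, features=None):
        n = control.shape[0]
        features = features or [f"f{i}" for i in range(n)]
        df = pd.DataFrame(
            np.column_stack([control, treatment]),
            index=features,
            columns=["c1", "c2", "c3", "t1", "t2", "t3"],
        )
        cond = pd.Series(
            {"c1": "control", "c2": "control", "c3": "control",
             "t1": "treatment", "t2": "treatment", "t3": "treatment"}
        )
        return tex.CountMatrix(df, pd.Series("gene", index=df.index), cond)

    def test_identical_groups_have_zero_lfc(self):
        rng = np.random.default_rng(1)
        x = rng.integers(10, 1000, (50, 3))
        cm = self._cm(x, x)
        fac = tex.tmm_normalize(cm)
        de = tex.differential_expression(cm, fac)
        assert np.allclose(de.table["log2FC"], 0.0)

    def test_planted_fourfold_feature_detected(self):
        rng = np.random.default_rng(2)
        base = rng.poisson(10_000, (200, 3)).astype(float)
        treat = base.copy()
        treat[0] *= 4.0
        cm = self._cm(base.astype(int), treat.astype(int))
        fac = tex.tmm_normalize(cm)
        de = tex.differential_expression(cm, fac)
        row = de.table.iloc[0]
        assert row["log2FC"] == pytest.approx(2.0, abs=0.1)
        assert row["de"]
        assert de.table["de"].iloc[1:].sum() == 0

    def test_single_replicate_rejected(self):
        df = pd.DataFrame({"c1": [1, 2], "t1": [3, 4], "t2": [5, 6]})
        cm = tex.CountMatrix(
            df, pd.Series("gene", index=df.index),
            pd.Series({"c1": "control", "t1": "treatment", "t2": "treatment"}),
        )
        fac = tex.tmm_normalize(cm)
        with pytest.raises(ValueError, match="replicates"):
            tex.differential_expression(cm, fac)

    def test_de_flag_implies_fold_and_p_rule(self):
        rng = np.random.default_rng(3)
        base = rng.negative_binomial(5, 0.01, (300, 3))
        treat = rng.negative_binomial(5, 0.01, (300, 3))
        cm = self._cm(base, treat)
        fac = tex.tmm_normalize(cm)
        de = tex.differential_expression(cm, fac)
        flagged = de.table[de.table["de"]]
        assert (flagged["log2FC"].abs() > 1).all()
        assert (flagged["p"] < 0.05).all()
        assert (de.table["adj_p"] >= de.table["p"] - 1e-12).all()


class TestAggregation:
    def test_additivity_and_conservation(self, toy_annotation):
        tes, genes = toy_annotation
        counts = {
            "te_far": [10, 20],
            "te_exonic": [5, 5],
            "te_flank": [1, 2],
            "te_low": [7, 7],
        }
        cm = _count_matrix(counts, {k: "te" for k in counts}, {0: "c", 1: "t"})
        agg = tex.aggregate_subfamily(cm, tes, genes, mode="all")
        assert agg.counts.loc["SFA"].tolist() == [15, 25]
        assert agg.counts.loc["SFB"].tolist() == [8, 9]
        assert (agg.counts.sum() == cm.counts.sum()).all()

    def test_intergenic_mode_excludes_flank(self, toy_annotation):
        tes, genes = toy_annotation
        counts = {"te_far": [10, 10], "te_flank": [3, 3], "te_low": [2, 2]}
        cm = _count_matrix(counts, {k: "te" for k in counts}, {0: "c", 1: "t"})
        # te_flank starts 5 kb beyond the gene body: inside the 10 kb flank
        agg = tex.aggregate_subfamily(cm, tes, genes, mode="intergenic")
        assert agg.counts.loc["SFA"].tolist() == [10, 10]
        assert agg.counts.loc["SFB"].tolist() == [2, 2]


class TestOverrepresentation:
    @staticmethod
    def _setup(n_total=100, n_up=10, k_size=10, k_up=5):
        genome = Genome({"chr1": 10_000_000})
        tes = []
        for i in range(n_total):
            sub = "SFX" if i < k_size else f"SF{i % 7}"
            tes.append(
                TEIntegrant(
                    GenomicInterval("chr1", 1000 * i, 1000 * i + 500), f"te{i}", sub
                )
            )
        ann = TEAnnotation(genome, tes)
        lfc = np.zeros(n_total)
        p = np.ones(n_total)
        ups = list(range(k_up)) + list(range(k_size, k_size + (n_up - k_up)))
        for i in ups:
            lfc[i] = 2.0
            p[i] = 1e-6
        table = pd.DataFrame(
            {"log2FC": lfc, "p": p, "adj_p": p, "de": p < 0.05, "de_adj": p < 0.05},
            index=[f"te{i}" for i in range(n_total)],
        )
        return tex.DEResult(table=table, contrast=("t", "c")), ann

    def test_tail_matches_exhaustive_hypergeometric(self):
        de, ann = self._setup()
        res = tex.subfamily_overrepresentation(de, ann)
        # exhaustive: P(X >= 5) for N=100, K=10 up, n=10 drawn
        exact = sum(
            math.comb(10, x) * math.comb(90, 10 - x) for x in range(5, 11)
        ) / math.comb(100, 10)
        assert res.table.loc["SFX", "p"] == pytest.approx(exact, rel=1e-12)
        assert res.table.loc["SFX", "k_up"] == 5

    def test_fully_upregulated_small_subfamily_closed_form(self):
        de, ann = self._setup(n_total=100, n_up=50, k_size=4, k_up=4)
        res = tex.subfamily_overrepresentation(de, ann)
        expected = math.comb(50, 4) / math.comb(100, 4)
        assert res.table.loc["SFX", "p"] == pytest.approx(expected, rel=1e-12)

    def test_no_upregulation_gives_unit_p(self):
        de, ann = self._setup(n_up=0, k_up=0)
        res = tex.subfamily_overrepresentation(de, ann)
        assert (res.table["p"] == 1.0).all()

    def test_empty_universe_rejected(self, toy_annotation):
        tes, _ = toy_annotation
        table = pd.DataFrame(
            {"log2FC": [1.0], "p": [0.01], "adj_p": [0.01], "de": [True], "de_adj": [True]},
            index=["unrelated_gene"],
        )
        with pytest.raises(ValueError, match="universe"):
            tex.subfamily_overrepresentation(
                tex.DEResult(table=table, contrast=("t", "c")), tes
            )
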