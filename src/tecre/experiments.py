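"""End-to-end recovery, calibration and oracle experiments.

These drivers run the package on its own synthetic study conditions
and measure how well each stage recovers the planted truth (or stays
calibrated under the null).  They back both the acceptance test suite
and ``scripts/acceptance.py``, so the protocol lives in one place.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats

from . import cis_activity, peak_enrichment, sc_subfamily, synthetic_data, te_expression
from .genome_io import Genome, GenomicInterval, TEAnnotation, TEIntegrant, overlaps
from .synthetic_data import PeakSpec, SimConfig, SubfamilySpec, default_config


def _derive_seed(seed: int, offset: int) -> int:
    return int((seed * 7919 + offset) % (2**31 - 1))


# ---------------------------------------------------------------------------
# cis-activity recovery and calibration
# ---------------------------------------------------------------------------

def activity_recovery(seed: int, n_sims: int = 50, noise_sd: float = 0.3) -> dict:
    """Fit the activity model on ``n_sims`` response draws over one genome.

    The genome (2000 genes, 30 subfamilies) is simulated once; each
    replicate draws gene-level Gaussian noise around the planted linear
    predictor and refits.  Reports agreement of the OLS solution with
    an independent SVD least-squares solve, the fraction of planted
    activities within 3 reported standard errors, and 95% CI coverage.
    """
    config = default_config(seed=_derive_seed(seed, 1))
    genome, tes, genes = synthetic_data.simulate_genome(config)
    N = cis_activity.build_occurrence_matrix(genes, tes)
    X = N.matrix.to_numpy(float)
    a = np.array([config.activity.get(s, 0.0) for s in N.subfamilies])
    rng = np.random.default_rng(_derive_seed(seed, 2))
    G = X.shape[0]

    max_rel_diff = 0.0
    within_3se = 0
    covered = 0
    total = 0
    for _ in range(n_sims):
        dE = pd.Series(X @ a + rng.normal(0, noise_sd, G), index=N.gene_ids)
        fit = cis_activity.estimate_activity(dE, N)
        tab = fit.table
        # independent solve: SVD least squares on the same design
        Xd = np.column_stack([np.ones(G), X])
        beta = np.linalg.lstsq(Xd, dE.to_numpy(), rcond=None)[0]
        est = tab["activity"].to_numpy()
        rel = np.max(np.abs(est - beta[1:]) / np.maximum(np.abs(beta[1:]), 1e-8))
        max_rel_diff = max(max_rel_diff, float(rel))
        tcrit = stats.t.ppf(0.975, fit.residual_df)
        for j, s in enumerate(N.subfamilies):
            se = tab.loc[s, "std_error"]
            err = abs(tab.loc[s, "activity"] - a[j])
            total += 1
            if err <= 3 * se:
                within_3se += 1
            if err <= tcrit * se:
                covered += 1
    return {
        "ols_oracle_max_rel_diff": max_rel_diff,
        "within_3se_fraction": within_3se / total,
        "ci95_coverage": covered / total,
        "n_cases": total,
        "n_genes": G,
        "n_subfamilies": len(N.subfamilies),
    }


def null_fdr(seed: int, n_sims: int = 200, noise_sd: float = 0.3) -> dict:
    """Fraction of subfamilies called at BH 0.05 when every activity is zero."""
    config = default_config(seed=_derive_seed(seed, 3))
    genome, tes, genes = synthetic_data.simulate_genome(config)
    N = cis_activity.build_occurrence_matrix(genes, tes)
    rng = np.random.default_rng(_derive_seed(seed, 4))
    G = N.matrix.shape[0]
    fractions = []
    for _ in range(n_sims):
        dE = pd.Series(rng.normal(0, noise_sd, G), index=N.gene_ids)
        fit = cis_activity.estimate_activity(dE, N)
        fractions.append(float((fit.table["adj_p"] < 0.05).mean()))
    return {
        "mean_fraction_called": float(np.mean(fractions)),
        "n_sims": n_sims,
        "n_subfamilies": N.matrix.shape[1],
    }


# ---------------------------------------------------------------------------
# brute-force oracles for interval counting
# ---------------------------------------------------------------------------

def _random_instance(seed: int, n_genes: int, n_tes: int):
    rng = np.random.default_rng(seed)
    sizes = {"chr1": 5_000_000, "chr2": 5_000_000}
    genome = Genome(sizes)
    from .genome_io import Gene, GeneAnnotation

    genes = []
    for i in range(n_genes):
        ch = "chr1" if rng.random() < 0.5 else "chr2"
        start = int(rng.integers(0, sizes[ch] - 10_000))
        length = int(rng.integers(1_000, 10_000))
        strand = "+" if rng.random() < 0.5 else "-"
        iv = GenomicInterval(ch, start, start + length, strand)
        genes.append(Gene(f"G{i:05d}", "protein_coding", iv, (iv,)))
    tes = []
    for i in range(n_tes):
        ch = "chr1" if rng.random() < 0.5 else "chr2"
        start = int(rng.integers(0, sizes[ch] - 3_000))
        length = int(rng.integers(100, 3_000))
        sub = f"SF{int(rng.integers(8)):02d}"
        tes.append(
            TEIntegrant(GenomicInterval(ch, start, start + length), f"te{i:05d}", sub)
        )
    return genome, GeneAnnotation(genome, genes), TEAnnotation(genome, tes)


def occurrence_matrix_oracle(seed: int, n_genes: int = 1000, n_tes: int = 2000) -> dict:
    """Occurrence matrix vs a brute-force all-pairs double loop (exact)."""
    genome, genes, tes = _random_instance(_derive_seed(seed, 5), n_genes, n_tes)
    window = cis_activity.DEFAULT_WINDOW_BP
    N = cis_activity.build_occurrence_matrix(genes, tes, window_bp=window, min_coloc=0)
    # brute force: exon exclusion then every gene x integrant pair
    exons = genes.exon_intervals()
    exonic = {qi for qi, _ in overlaps(tes.intervals(), exons)}
    clean = [te for i, te in enumerate(tes.integrants) if i not in exonic]
    brute = pd.DataFrame(
        0, index=N.matrix.index, columns=N.matrix.columns, dtype=np.int64
    )
    for g in genes.protein_coding():
        ws, we = g.tss - window, g.tss + window + 1
        for te in clean:
            if (
                te.interval.chrom == g.interval.chrom
                and te.interval.start < we
                and ws < te.interval.end
            ):
                brute.loc[g.gene_id, te.subfamily] += 1
    mism = int((N.matrix != brute).to_numpy().sum())
    return {"mismatched_cells": mism, "n_cells": int(brute.size)}


def peak_overlap_oracle(seed: int, n_peaks: int = 300, n_tes: int = 2000) -> dict:
    """Per-subfamily peak overlap counts vs a brute-force double loop."""
    genome, _genes, tes = _random_instance(_derive_seed(seed, 6), 10, n_tes)
    rng = np.random.default_rng(_derive_seed(seed, 7))
    peaks = []
    for _ in range(n_peaks):
        ch = "chr1" if rng.random() < 0.5 else "chr2"
        start = int(rng.integers(0, genome.sizes[ch] - 600))
        peaks.append(GenomicInterval(ch, start, start + int(rng.integers(100, 600))))
    ps = peak_enrichment.PeakSet(peaks, genome)
    fast = peak_enrichment.count_subfamily_overlaps(ps, tes)
    brute = {s: 0 for s in tes.subfamilies}
    for iv in peaks:
        hit = set()
        for te in tes:
            if te.interval.overlaps(iv):
                hit.add(te.subfamily)
        for s in hit:
            brute[s] += 1
    mism = sum(int(fast[s] != brute[s]) for s in brute)
    return {"mismatched_subfamilies": mism, "n_subfamilies": len(brute)}


# ---------------------------------------------------------------------------
# peak-enrichment calibration and power
# ---------------------------------------------------------------------------

def _peaks_config(seed: int, enrichment: dict[str, float] | None = None) -> SimConfig:
    # sized so each subfamily expects ~100 peak overlaps under the null:
    # the fold of a calibrated subfamily then concentrates well within 25%
    subfam = {
        f"SF{i:02d}": SubfamilySpec(n_integrants=150, length_range=(800, 1600))
        for i in range(10)
    }
    return SimConfig(
        seed=seed,
        n_chroms=2,
        chrom_length=10_000_000,
        n_genes=50,
        subfamilies=subfam,
        peak_spec=PeakSpec(n_peaks=8000, peak_length=500, enrichment=enrichment or {}),
    )


def enrichment_calibration(seed: int, n_seeds: int = 20, K: int = 10) -> dict:
    """Uniform peaks: permutation fold should sit near 1 for every subfamily."""
    in_band = 0
    total = 0
    for k in range(n_seeds):
        config = _peaks_config(_derive_seed(seed, 100 + k))
        genome, tes, _genes = synthetic_data.simulate_genome(config)
        peaks, _truth = synthetic_data.simulate_peaks(genome, tes, config)
        ps = peak_enrichment.PeakSet(peaks, genome)
        res = peak_enrichment.permutation_enrichment(
            ps, tes, K=K, seed=_derive_seed(seed, 200 + k)
        )
        eligible = res[res["n_elements"] >= 50]
        total += len(eligible)
        in_band += int(eligible["fold"].between(0.8, 1.25).sum())
    return {"fraction_in_band": in_band / total, "n_cases": total}


def enrichment_power(seed: int, n_seeds: int = 20, K: int = 10) -> dict:
    """Peaks planted at 3-fold over coverage for one subfamily.

    The placement fraction is solved from the coverage null so the
    expected fold is exactly 3; detection requires fold > 2 with the
    empirical p at its floor 1/(K+1).
    """
    detected = 0
    for k in range(n_seeds):
        config = _peaks_config(_derive_seed(seed, 300 + k))
        genome, tes, _genes = synthetic_data.simulate_genome(config)
        # fraction q with (q + (1-q) p_s) / p_s = 3  =>  q = 2 p_s / (1 - p_s)
        L = config.peak_spec.peak_length
        members = tes.by_subfamily("SF00")
        p_s = min(
            1.0, sum(len(m.interval) + L - 1 for m in members) / genome.total_size
        )
        q = 2 * p_s / (1 - p_s)
        config.peak_spec.enrichment = {"SF00": q}
        peaks, _truth = synthetic_data.simulate_peaks(genome, tes, config)
        ps = peak_enrichment.PeakSet(peaks, genome)
        res = peak_enrichment.permutation_enrichment(
            ps, tes, K=K, seed=_derive_seed(seed, 400 + k)
        )
        row = res.loc["SF00"]
        if row["fold"] > 2 and row["empirical_p"] == 1.0 / (K + 1):
            detected += 1
    return {"fraction_detected": detected / n_seeds, "n_seeds": n_seeds}


# ---------------------------------------------------------------------------
# statistical primitives against exhaustive references
# ---------------------------------------------------------------------------

def wilcoxon_exact_check() -> dict:
    """Rank-sum p for {1,2,3} vs {4,5,6} against full enumeration (p = 0.1)."""
    _w, p = sc_subfamily.wilcoxon_rank_sum(
        np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])
    )
    # exhaustive reference over all 20 assignments of ranks to the first group
    ranks = range(1, 7)
    obs = 1 + 2 + 3
    sums = [sum(c) for c in itertools.combinations(ranks, 3)]
    lo = sum(1 for s in sums if s <= obs)
    hi = sum(1 for s in sums if s >= 21 - obs)  # mirror tail around the mean 10.5
    exact = min(1.0, (lo + hi) / len(sums))
    return {"p": p, "exact_reference": exact, "n_enumerated": len(sums)}


def hypergeom_tail_check(n_universe: int = 100, n_up: int = 10, k_size: int = 10) -> dict:
    """Fisher/hypergeometric tail vs explicit summation of the PMF."""
    max_diff = 0.0
    for k_up in range(k_size + 1):
        tail = float(stats.hypergeom.sf(k_up - 1, n_universe, n_up, k_size))
        explicit = sum(
            stats.hypergeom.pmf(x, n_universe, n_up, k_size)
            for x in range(k_up, min(n_up, k_size) + 1)
        )
        max_diff = max(max_diff, abs(tail - float(explicit)))
    return {"max_abs_diff": max_diff, "n_tables": k_size + 1}


# ---------------------------------------------------------------------------
# filter fixtures, conservation and determinism
# ---------------------------------------------------------------------------

def filter_fixture_check() -> dict:
    """Hand-enumerated expectations for the bulk and single-cell filters."""
    from .genome_io import Gene, GeneAnnotation

    sizes = {"chr1": 100_000}
    genome = Genome(sizes)
    gene_iv = GenomicInterval("chr1", 40_000, 50_000, "+")
    exon = GenomicInterval("chr1", 41_000, 42_000, "+")
    genes = GeneAnnotation(
        genome, [Gene("G1", "protein_coding", gene_iv, (exon,))]
    )
    tes = TEAnnotation(
        genome,
        [
            TEIntegrant(GenomicInterval("chr1", 41_500, 41_800), "te_exonic", "SFA"),
            TEIntegrant(GenomicInterval("chr1", 10_000, 10_500), "te_far", "SFA"),
            TEIntegrant(GenomicInterval("chr1", 55_000, 55_400), "te_flank", "SFB"),
            TEIntegrant(GenomicInterval("chr1", 80_000, 80_300), "te_low", "SFB"),
        ],
    )
    counts = pd.DataFrame(
        {
            "s1": [10, 0, 50, 2],
            "s2": [20, 0, 60, 2],
            "s3": [30, 3, 70, 2],
        },
        index=["te_exonic", "te_far", "te_flank", "te_low"],
    )
    cm = te_expression.CountMatrix(
        counts,
        pd.Series("te", index=counts.index),
        pd.Series({"s1": "control", "s2": "control", "s3": "treatment"}),
    )
    filtered = te_expression.filter_features(cm, tes, genes)
    # hand enumeration: te_exonic fails the exon rule, te_low never
    # reaches 3 reads, te_far reaches 3 in s3 (boundary), te_flank passes
    expected_bulk = {"te_far", "te_flank"}
    bulk_ok = set(filtered.counts.index) == expected_bulk

    agg = te_expression.aggregate_subfamily(filtered, tes, genes, mode="intergenic")
    # te_flank is 5 kb from the gene body: inside the 10 kb flank, excluded;
    # te_far (30 kb away) remains -> only SFA survives
    inter_ok = set(agg.counts.index) == {"SFA"}

    import anndata as ad
    from scipy import sparse as sp

    X = sp.csr_matrix(np.ones((4, 300)))
    obs = pd.DataFrame(
        {
            "cell_type": ["A", "A", "B", "B"],
            "n_features_detected": [150, 200, 300, 250],
            "mito_fraction": [0.10, 0.25, 0.30, 0.05],
        },
        index=[f"c{i}" for i in range(4)],
    )
    var = pd.DataFrame({"kind": ["gene"] * 300}, index=[f"g{i}" for i in range(300)])
    adata = ad.AnnData(X=X, obs=obs, var=var)
    qcd = sc_subfamily.qc_cells(adata)
    # c0 fails the feature floor, c2 the mito ceiling; c1 sits exactly on
    # both thresholds and stays
    qc_ok = list(qcd.obs_names) == ["c1", "c3"]
    return {
        "bulk_filter_ok": bool(bulk_ok),
        "intergenic_ok": bool(inter_ok),
        "qc_ok": bool(qc_ok),
    }


def conservation_determinism(seed: int, tmpdir=None) -> dict:
    """Exact conservation and byte-level determinism checks."""
    import hashlib
    import tempfile
    from pathlib import Path

    config = _peaks_config(_derive_seed(seed, 500))
    config.n_genes = 100
    genome, tes, genes = synthetic_data.simulate_genome(config)

    # subfamily aggregation conserves total TE counts exactly
    control, treatment, _truth = synthetic_data.simulate_bulk_counts(
        genome, tes, genes, config
    )
    cm = te_expression.CountMatrix.concat(control, treatment)
    te_cm = cm.subset_features([f for f, k in cm.feature_kind.items() if k == "te"])
    agg = te_expression.aggregate_subfamily(te_cm, tes, genes, mode="all")
    conservation_err = int(
        np.abs(
            agg.counts.sum().to_numpy() - te_cm.counts.sum().to_numpy()
        ).sum()
    )

    # shuffles preserve per-chromosome length multisets
    shuffled = peak_enrichment.shuffle_integrants(tes, K=5, seed=_derive_seed(seed, 501))
    violations = 0
    orig = {}
    for te in tes:
        orig.setdefault(te.interval.chrom, []).append(len(te.interval))
    for sh in shuffled.shuffles:
        got: dict[str, list[int]] = {}
        for te in sh:
            got.setdefault(te.interval.chrom, []).append(len(te.interval))
        for ch in orig:
            if sorted(orig[ch]) != sorted(got.get(ch, [])):
                violations += 1

    # identical config -> byte-identical simulator output
    def digest(cfg) -> str:
        with tempfile.TemporaryDirectory(dir=tmpdir) as d:
            synthetic_data.simulate_dataset(cfg, d)
            h = hashlib.sha256()
            for f in sorted(Path(d).iterdir()):
                h.update(f.name.encode())
                h.update(f.read_bytes())
            return h.hexdigest()

    small = _peaks_config(_derive_seed(seed, 502))
    small.n_genes = 30
    small.n_cells_per_type = {"A": 20, "B": 20}
    small.celltype_effects = {"A": {"SF00": 2.0}, "B": {}}
    identical = digest(small) == digest(small)

    # density-track mass ~ total TE bp
    track = peak_enrichment.te_density_track(tes, genome, step=100)
    total_bp = sum(len(te.interval) for te in tes)
    mass_rel_err = abs(track.total_mass() - total_bp) / total_bp
    return {
        "aggregation_conservation_abs_err": conservation_err,
        "shuffle_multiset_violations": violations,
        "simulator_byte_identical": bool(identical),
        "density_mass_rel_err": float(mass_rel_err),
        "n_integrants": len(tes),
    }
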