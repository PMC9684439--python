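"""Seeded synthetic genomes, annotations, counts and peaks with planted truth.

The generator emulates the statistical structure the downstream
analyses assume, at desk scale:

* a multi-chromosome genome carrying protein-coding genes (with exons)
  and non-overlapping TE integrants grouped into subfamilies with
  evolutionary-age labels;
* bulk control/treatment counts in which each gene's log2 expression
  shift is a planted linear combination of its nearby TE occurrences
  plus Gaussian gene-level noise, with negative-binomial replicate
  sampling;
* single-cell counts with cell-type-specific subfamily expression and
  a configurable fraction of QC-violating cells;
* accessibility peak sets with planted per-subfamily placement
  enrichment.

Everything is driven by a single integer seed: identical configs give
byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmwrite

from .genome_io import (
    Gene,
    GeneAnnotation,
    Genome,
    GenomicInterval,
    TEAnnotation,
    TEIntegrant,
    _NonOverlapTracker,
)
from .te_expression import CountMatrix, GENE, TE

PROXIMITY_WINDOW_BP = 50_000

# Desk-scale default panel: 30 subfamilies spanning the major TE classes
# and evolutionary-age categories (hominid < primate < eutherian < older).
_DEFAULT_PANEL = [
    ("LTR5Hs", "ERV", "hominid"),
    ("LTR5B", "ERV", "primate"),
    ("LTR7", "ERV", "primate"),
    ("HERVH-int", "ERV", "primate"),
    ("HERVK11", "ERV", "primate"),
    ("HERVK22", "ERV", "primate"),
    ("LTR6B", "ERV", "primate"),
    ("HERV17", "ERV", "primate"),
    ("HERVIP10FH", "ERV", "primate"),
    ("L1Hs", "LINE", "hominid"),
    ("L1PA2", "LINE", "hominid"),
    ("L1PA3", "LINE", "primate"),
    ("L1PA4", "LINE", "primate"),
    ("L2a", "LINE", "older"),
    ("AluY", "SINE", "primate"),
    ("AluYa5", "SINE", "hominid"),
    ("AluYb8", "SINE", "hominid"),
    ("AluSx", "SINE", "primate"),
    ("MIRb", "SINE", "older"),
    ("SVA_D", "SVA", "hominid"),
    ("SVA_E", "SVA", "hominid"),
    ("SVA_F", "SVA", "hominid"),
    ("MER41B", "ERV", "eutherian"),
    ("MLT1A", "ERV", "eutherian"),
    ("MLT1B", "ERV", "eutherian"),
    ("MLT2A1", "ERV", "eutherian"),
    ("THE1A", "ERV", "eutherian"),
    ("THE1B", "ERV", "eutherian"),
    ("LTR12C", "ERV", "primate"),
    ("MER57F", "ERV", "eutherian"),
]


class CapacityError(RuntimeError):
    """Requested features cannot be packed into the genome without overlap."""


@dataclass
class SubfamilySpec:
    """Placement spec for one TE subfamily."""

    n_integrants: int
    length_range: tuple[int, int] = (300, 1500)
    family_class: str = "ERV"
    age_category: str = "primate"
    gene_proximity_bias: float = 0.0  # fraction placed within 50 kb of a TSS
    bias_gene_ids: tuple[str, ...] | None = None  # None = any gene


@dataclass
class PeakSpec:
    """Accessibility peak-set spec with optional planted enrichment."""

    n_peaks: int = 500
    peak_length: int = 500
    # subfamily -> fraction of peaks centered inside its integrants
    enrichment: dict[str, float] = field(default_factory=dict)


@dataclass
class SimConfig:
    """Full configuration of one synthetic study."""

    seed: int = 0
    n_chroms: int = 4
    chrom_length: int = 10_000_000
    n_genes: int = 2000
    subfamilies: dict[str, SubfamilySpec] = field(default_factory=dict)
    # planted cis-regulatory activity a_s, log2 units per nearby integrant
    activity: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.3
    n_reps: int = 3
    dispersion: float = 0.1
    baseline_log2_range: tuple[float, float] = (3.0, 9.0)
    te_expressed_frac: float = 0.25
    te_log2fc: dict[str, float] = field(default_factory=dict)
    # single-cell block
    celltype_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    n_cells_per_type: dict[str, int] = field(default_factory=dict)
    n_sc_genes: int = 300
    te_loci_per_subfamily_sc: int = 30
    mito_beta: tuple[float, float] = (2.0, 18.0)
    qc_violation_frac: float = 0.05
    peak_spec: PeakSpec = field(default_factory=PeakSpec)

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


def default_config(seed: int = 0) -> SimConfig:
    """The study conditions used throughout: 30 subfamilies, 2000 genes.

    A handful of subfamilies carry nonzero planted activity (magnitudes
    in the 0.03-0.15 log2-per-integrant range the activity bins are
    built for); LTR5Hs and LTR5B additionally carry planted bulk
    upregulation, cell-type-specific expression and peak enrichment.
    """
    subfamilies = {
        name: SubfamilySpec(
            n_integrants=150,
            family_class=fam,
            age_category=age,
        )
        for name, fam, age in _DEFAULT_PANEL
    }
    activity = {name: 0.0 for name, _, _ in _DEFAULT_PANEL}
    activity.update(
        {
            "LTR5Hs": 0.15,
            "LTR5B": 0.10,
            "HERVK11": 0.08,
            "LTR7": 0.05,
            "MER41B": -0.05,
            "LTR6B": 0.03,
        }
    )
    te_log2fc = {"LTR5Hs": 2.0, "LTR5B": 1.5, "HERVK11": 1.5}
    celltype_effects = {
        "PGC": {"LTR5Hs": 2.0, "HERV17": 2.0},
        "Endoderm": {"LTR5B": 2.0, "HERVK11": 2.0},
        "PrimStreak": {"HERVK22": 2.0},
        "Epiblast": {},
        "Mesoderm": {},
    }
    n_cells = {
        "Epiblast": 150,
        "PrimStreak": 150,
        "PGC": 60,
        "Endoderm": 100,
        "Mesoderm": 150,
    }
    peak_spec = PeakSpec(
        n_peaks=500,
        peak_length=500,
        enrichment={"LTR5Hs": 0.08, "LTR5B": 0.06},
    )
    return SimConfig(
        seed=seed,
        subfamilies=subfamilies,
        activity=activity,
        te_log2fc=te_log2fc,
        celltype_effects=celltype_effects,
        n_cells_per_type=n_cells,
        peak_spec=peak_spec,
    )


@dataclass
class SimTruth:
    """Planted ground truth, recorded before noise is applied."""

    activity: dict[str, float] = field(default_factory=dict)
    planted_gene_lfc: dict[str, float] = field(default_factory=dict)
    expressed_te_loci: list[str] = field(default_factory=list)
    te_locus_lfc: dict[str, float] = field(default_factory=dict)
    marker_pairs: list[tuple[str, str]] = field(default_factory=list)
    qc_violator_cells: list[str] = field(default_factory=list)
    enriched_subfamilies: dict[str, float] = field(default_factory=dict)
    expected_peak_fold: dict[str, float] = field(default_factory=dict)

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))


def _rng(config: SimConfig, stream: str) -> np.random.Generator:
    # independent named substreams: each stage is reproducible in isolation
    return np.random.default_rng(
        np.random.SeedSequence([config.seed, sum(stream.encode())])
    )


def simulate_genome(config: SimConfig) -> tuple[Genome, TEAnnotation, GeneAnnotation]:
    """Place genes (with exons) and non-overlapping TE integrants.

    Gene TSSs sit on a jittered grid; each subfamily's integrants are
    placed uniformly (or, with ``gene_proximity_bias``, within 50 kb of
    a target TSS) with rejection of TE/TE overlaps.
    """
    rng = _rng(config, "genome")
    sizes = {f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)}
    genome = Genome(sizes)

    # --- genes ---
    genes: list[Gene] = []
    per_chrom = int(np.ceil(config.n_genes / config.n_chroms))
    gidx = 0
    for chrom in sizes:
        n_here = min(per_chrom, config.n_genes - gidx)
        if n_here <= 0:
            break
        slot = config.chrom_length // (n_here + 1)
        if slot < 12_000:
            raise CapacityError(f"too many genes for chromosome {chrom}")
        for k in range(n_here):
            anchor = (k + 1) * slot + int(rng.integers(-slot // 4, slot // 4 + 1))
            length = int(rng.integers(2_000, 10_001))
            start = int(np.clip(anchor, 0, config.chrom_length - length))
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = int(rng.integers(1, 5))
            bounds = np.sort(rng.choice(np.arange(1, length), 2 * n_exons, replace=False))
            exons = tuple(
                GenomicInterval(chrom, start + int(bounds[2 * e]), start + int(bounds[2 * e + 1]), strand)
                for e in range(n_exons)
                if bounds[2 * e + 1] > bounds[2 * e]
            )
            if not exons:
                exons = (GenomicInterval(chrom, start, start + length, strand),)
            genes.append(
                Gene(
                    gene_id=f"G{gidx:05d}",
                    biotype="protein_coding",
                    interval=GenomicInterval(chrom, start, start + length, strand),
                    exons=exons,
                )
            )
            gidx += 1
    gene_ann = GeneAnnotation(genome, genes)
    tss_by_gene = {g.gene_id: (g.interval.chrom, g.tss) for g in genes}
    all_gene_ids = [g.gene_id for g in genes]

    # --- TE integrants, non-overlapping ---
    trackers = {chrom: _NonOverlapTracker() for chrom in sizes}
    integrants: list[TEIntegrant] = []
    chrom_names = list(sizes)
    for subfam in sorted(config.subfamilies):
        spec = config.subfamilies[subfam]
        lmin, lmax = spec.length_range
        target_ids = list(spec.bias_gene_ids) if spec.bias_gene_ids else all_gene_ids
        for i in range(spec.n_integrants):
            length = int(rng.integers(lmin, lmax + 1))
            placed = False
            for _attempt in range(1000):
                if spec.gene_proximity_bias > 0 and rng.random() < spec.gene_proximity_bias:
                    gid = target_ids[int(rng.integers(len(target_ids)))]
                    chrom, tss = tss_by_gene[gid]
                    lo = max(0, tss - PROXIMITY_WINDOW_BP)
                    hi = min(sizes[chrom] - length, tss + PROXIMITY_WINDOW_BP - length)
                    if hi < lo:
                        continue
                    start = int(rng.integers(lo, hi + 1))
                else:
                    chrom = chrom_names[int(rng.integers(len(chrom_names)))]
                    start = int(rng.integers(0, sizes[chrom] - length + 1))
                if trackers[chrom].fits(start, start + length):
                    trackers[chrom].add(start, start + length)
                    strand = "+" if rng.random() < 0.5 else "-"
                    integrants.append(
                        TEIntegrant(
                            GenomicInterval(chrom, start, start + length, strand),
                            locus_id=f"{subfam}_{i:04d}",
                            subfamily=subfam,
                            family_class=spec.family_class,
                            age_category=spec.age_category,
                        )
                    )
                    placed = True
                    break
            if not placed:
                raise CapacityError(
                    f"could not place integrant {i} of {subfam} after 1000 tries"
                )
    return genome, TEAnnotation(genome, integrants), gene_ann


def _occurrence_counts(
    genes: GeneAnnotation,
    tes: TEAnnotation,
    window_bp: int = PROXIMITY_WINDOW_BP,
) -> pd.DataFrame:
    """Generator-side N_gs: exon-clean integrants near each coding TSS.

    Kept separate from the estimator's path on purpose; tests compare
    both against a brute-force double loop.
    """
    from .genome_io import overlaps  # local import to keep module load light

    coding = genes.protein_coding()
    exons = genes.exon_intervals()
    te_ivs = tes.intervals()
    exonic = {qi for qi, _ in overlaps(te_ivs, exons)}
    clean = [te for i, te in enumerate(tes.integrants) if i not in exonic]
    subfams = sorted({te.subfamily for te in clean})
    tmp: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for te in clean:
        tmp.setdefault((te.interval.chrom, te.subfamily), []).append(
            (te.interval.start, te.interval.end)
        )
    spans = {
        k: (
            np.sort(np.array([s for s, _ in v], dtype=np.int64)),
            np.sort(np.array([e for _, e in v], dtype=np.int64)),
        )
        for k, v in tmp.items()
    }
    mat = np.zeros((len(coding), len(subfams)), dtype=np.int64)
    col = {s: j for j, s in enumerate(subfams)}
    for i, g in enumerate(coding):
        ws, we = g.tss - window_bp, g.tss + window_bp + 1
        for s in subfams:
            key = (g.interval.chrom, s)
            if key in spans:
                st, en = spans[key]
                n = np.searchsorted(st, we) - np.searchsorted(en, ws, side="right")
                if n > 0:
                    mat[i, col[s]] = n
    return pd.DataFrame(mat, index=[g.gene_id for g in coding], columns=subfams)


def _nb_counts(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Negative-binomial draws with var = mu + dispersion * mu^2 (Poisson at 0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_bulk_counts(
    genome: Genome,
    tes: TEAnnotation,
    genes: GeneAnnotation,
    config: SimConfig,
) -> tuple[CountMatrix, CountMatrix, SimTruth]:
    """Control/treatment gene + TE-locus counts with the planted linear model.

    Per gene g:  treatment log2 mean = control log2 mean
    + sum_s N_gs * a_s + e_g with e_g ~ N(0, noise_sd^2); replicate
    counts are negative-binomial around the exponentiated means.
    Planted expressed TE loci get their own counts (with per-subfamily
    log2 fold changes) so the locus-level filters and tests have work
    to do.
    """
    rng = _rng(config, "bulk")
    occ = _occurrence_counts(genes, tes)
    act = pd.Series({s: config.activity.get(s, 0.0) for s in occ.columns})
    planted = occ.to_numpy(float) @ act.to_numpy(float)
    truth = SimTruth(
        activity={s: float(config.activity.get(s, 0.0)) for s in occ.columns},
        planted_gene_lfc={g: float(v) for g, v in zip(occ.index, planted)},
    )

    gene_ids = list(occ.index)
    n_g = len(gene_ids)
    mu0 = rng.uniform(*config.baseline_log2_range, size=n_g)
    eps = rng.normal(0.0, config.noise_sd, size=n_g) if config.noise_sd > 0 else np.zeros(n_g)
    mu1 = mu0 + planted + eps

    # planted expressed TE loci
    te_rows: list[str] = []
    te_mu0: list[float] = []
    te_lfc: list[float] = []
    for subfam in sorted({te.subfamily for te in tes.integrants}):
        members = tes.by_subfamily(subfam)
        n_expr = int(round(config.te_expressed_frac * len(members)))
        chosen = rng.choice(len(members), size=n_expr, replace=False)
        lfc = config.te_log2fc.get(subfam, 0.0)
        for idx in np.sort(chosen):
            te_rows.append(members[idx].locus_id)
            te_mu0.append(float(rng.uniform(2.0, 6.0)))
            te_lfc.append(lfc)
    truth.expressed_te_loci = list(te_rows)
    truth.te_locus_lfc = {r: float(f) for r, f in zip(te_rows, te_lfc)}

    mu0_all = np.concatenate([mu0, np.array(te_mu0)])
    mu1_all = np.concatenate([mu1, np.array(te_mu0) + np.array(te_lfc)])
    feature_ids = gene_ids + te_rows
    kind = pd.Series([GENE] * n_g + [TE] * len(te_rows), index=feature_ids)

    def draw(mu_log2: np.ndarray, label: str) -> CountMatrix:
        cols = {}
        for r in range(config.n_reps):
            cols[f"{label}_{r + 1}"] = _nb_counts(rng, 2.0**mu_log2, config.dispersion)
        df = pd.DataFrame(cols, index=feature_ids)
        cond = pd.Series(label, index=list(cols))
        return CountMatrix(df, kind, cond)

    control = draw(mu0_all, "control")
    treatment = draw(mu1_all, "treatment")
    return control, treatment, truth


def simulate_cells(
    tes: TEAnnotation,
    genes: GeneAnnotation,
    config: SimConfig,
) -> tuple[ad.AnnData, SimTruth]:
    """Sparse single-cell counts with cell-type-specific subfamily shifts.

    Features are a subset of genes plus TE loci.  Planted (subfamily,
    cell type) pairs from ``celltype_effects`` get multiplicative
    shifts of all their loci; a ``qc_violation_frac`` of cells is made
    to fail QC (too few detected features, or mitochondrial fraction
    above 25%).  Returns cells x features AnnData with ``obs`` columns
    cell_type, mito_fraction, and ``var`` column kind.
    """
    rng = _rng(config, "cells")
    known = {te.subfamily for te in tes.integrants}
    for ct, effects in config.celltype_effects.items():
        bad = set(effects) - known
        if bad:
            raise ValueError(f"celltype_effects for {ct} name unknown subfamilies {bad}")

    gene_ids = [g.gene_id for g in genes][: config.n_sc_genes]
    te_feats: list[tuple[str, str]] = []  # (locus_id, subfamily)
    for subfam in sorted(known):
        members = tes.by_subfamily(subfam)
        take = min(config.te_loci_per_subfamily_sc, len(members))
        chosen = rng.choice(len(members), size=take, replace=False)
        te_feats.extend((members[i].locus_id, subfam) for i in np.sort(chosen))
    features = gene_ids + [lid for lid, _ in te_feats]
    kind = np.array([GENE] * len(gene_ids) + [TE] * len(te_feats), dtype=object)
    subfam_of = np.array([""] * len(gene_ids) + [s for _, s in te_feats], dtype=object)

    gene_base = rng.lognormal(mean=0.0, sigma=1.0, size=len(gene_ids))
    te_base = rng.uniform(0.05, 0.4, size=len(te_feats))

    cell_types = sorted(config.n_cells_per_type)
    rows, cols, vals = [], [], []
    obs_type, obs_mito, cell_ids = [], [], []
    c = 0
    for ct in cell_types:
        eff = config.celltype_effects.get(ct, {})
        te_mean = te_base.copy()
        for subfam, log2f in eff.items():
            te_mean[[s == subfam for _, s in te_feats]] *= 2.0**log2f
        mean_vec = np.concatenate([gene_base, te_mean])
        for _ in range(config.n_cells_per_type[ct]):
            depth = float(rng.lognormal(0.0, 0.3))
            counts = rng.poisson(mean_vec * depth)
            nz = np.nonzero(counts)[0]
            rows.extend([c] * len(nz))
            cols.extend(nz.tolist())
            vals.extend(counts[nz].tolist())
            obs_type.append(ct)
            obs_mito.append(float(rng.beta(*config.mito_beta)))
            cell_ids.append(f"cell{c:05d}")
            c += 1
    X = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(c, len(features)), dtype=np.int64
    )

    # plant QC violations: half low-feature cells, half high-mito cells
    n_viol = int(round(config.qc_violation_frac * c))
    viol = rng.choice(c, size=n_viol, replace=False)
    viol = np.sort(viol)
    X = X.tolil()
    obs_mito = np.array(obs_mito)
    for k, cell in enumerate(viol):
        if k % 2 == 0:
            row = X.rows[cell]
            data = X.data[cell]
            keep = min(50, len(row))  # well under the 200-feature floor
            X.rows[cell] = row[:keep]
            X.data[cell] = data[:keep]
        else:
            obs_mito[cell] = float(rng.uniform(0.30, 0.60))
    X = X.tocsr()

    obs = pd.DataFrame(
        {
            "cell_type": obs_type,
            "mito_fraction": obs_mito,
            "n_features_detected": np.asarray((X > 0).sum(axis=1)).ravel(),
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    var = pd.DataFrame(
        {"kind": kind, "subfamily": subfam_of},
        index=pd.Index(features, name="feature_id"),
    )
    adata = ad.AnnData(X=X, obs=obs, var=var)
    truth = SimTruth(
        marker_pairs=sorted(
            (s, ct) for ct, eff in config.celltype_effects.items() for s in eff
        ),
        qc_violator_cells=[cell_ids[i] for i in viol],
    )
    return adata, truth


def simulate_peaks(
    genome: Genome,
    tes: TEAnnotation,
    config: SimConfig,
) -> tuple[list[GenomicInterval], SimTruth]:
    """Non-overlapping peaks, uniform except for planted subfamily enrichment.

    For each entry ``subfamily -> frac`` in the peak spec, that
    fraction of peaks is centered inside a random integrant of the
    subfamily; the rest are uniform over the genome.
    """
    spec = config.peak_spec
    rng = _rng(config, "peaks")
    chroms = list(genome.sizes)
    weights = np.array([genome.sizes[ch] for ch in chroms], dtype=float)
    weights /= weights.sum()
    L = spec.peak_length

    plan: list[str | None] = []
    for subfam, frac in sorted(spec.enrichment.items()):
        if not tes.by_subfamily(subfam):
            raise ValueError(f"peak enrichment names unknown subfamily {subfam}")
        plan.extend([subfam] * int(round(frac * spec.n_peaks)))
    if len(plan) > spec.n_peaks:
        raise CapacityError("enrichment fractions exceed 1")
    plan.extend([None] * (spec.n_peaks - len(plan)))

    trackers = {ch: _NonOverlapTracker() for ch in chroms}
    peaks: list[GenomicInterval] = []
    for target in plan:
        placed = False
        for _ in range(1000):
            if target is None:
                ch = chroms[int(rng.choice(len(chroms), p=weights))]
                start = int(rng.integers(0, genome.sizes[ch] - L + 1))
            else:
                members = tes.by_subfamily(target)
                te = members[int(rng.integers(len(members)))]
                center = int(rng.integers(te.interval.start, te.interval.end))
                ch = te.interval.chrom
                start = int(np.clip(center - L // 2, 0, genome.sizes[ch] - L))
            if trackers[ch].fits(start, start + L):
                trackers[ch].add(start, start + L)
                peaks.append(GenomicInterval(ch, start, start + L))
                placed = True
                break
        if not placed:
            raise CapacityError("could not place peak without overlap")
    peaks.sort(key=lambda p: (p.chrom, p.start))

    # analytic expectation of the fold under the coverage null
    G = genome.total_size
    truth = SimTruth()
    for subfam, frac in sorted(spec.enrichment.items()):
        members = tes.by_subfamily(subfam)
        p_s = min(1.0, sum(len(m.interval) + L - 1 for m in members) / G)
        expected_fold = (frac + (1 - frac) * p_s) / p_s
        truth.enriched_subfamilies[subfam] = frac
        truth.expected_peak_fold[subfam] = float(expected_fold)
    return peaks, truth


def write_peaks_bed(peaks: list[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\tpeak{i:05d}\t0\t.\n")


def simulate_dataset(config: SimConfig, outdir: str | Path) -> None:
    """Run every generator stage and write all outputs as text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, tes, genes = simulate_genome(config)
    genome.write(outdir / "genome.sizes")
    tes.write_bed(outdir / "tes.bed")
    genes.write_gtf(outdir / "genes.gtf")

    control, treatment, bulk_truth = simulate_bulk_counts(genome, tes, genes, config)
    combined = CountMatrix.concat(control, treatment)
    combined.write_tsv(outdir / "bulk_counts.tsv", outdir / "bulk_design.tsv")
    bulk_truth.write_json(outdir / "bulk_truth.json")

    adata, cell_truth = simulate_cells(tes, genes, config)
    mmwrite(str(outdir / "sc_counts.mtx"), sparse.coo_matrix(adata.X))
    adata.obs.to_csv(outdir / "sc_cells.tsv", sep="\t")
    adata.var.to_csv(outdir / "sc_features.tsv", sep="\t")
    cell_truth.write_json(outdir / "sc_truth.json")

    peaks, peak_truth = simulate_peaks(genome, tes, config)
    write_peaks_bed(peaks, outdir / "peaks.bed")
    peak_truth.write_json(outdir / "peak_truth.json")
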