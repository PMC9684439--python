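"""TE-subfamily enrichment in chromatin-accessibility peak sets.

Observed overlap is counted at the peak level: a peak counts once per
subfamily it touches.  Two nulls are provided: (i) chromosome-
preserving non-overlapping random shuffles of the integrants (default
10, mirroring a `bedtools shuffle -chrom -noOverlapping` background),
giving a fold over the mean shuffled overlap and a +1-corrected
empirical p; (ii) an analytic random-genome-coverage null with a
binomial tail p, where a subfamily is called significant at fold > 2
and p < 0.05.  A rectangular-window smoother produces TE density
tracks in bedGraph form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import (
    AnnotationError,
    Genome,
    GenomicInterval,
    TEAnnotation,
    TEIntegrant,
    _NonOverlapTracker,
)

logger = logging.getLogger(__name__)

DEFAULT_K = 10
DENSITY_WINDOW_BP = 10_000


@dataclass
class PeakSet:
    """A set of accessibility intervals, optionally labeled by cell type."""

    intervals: list[GenomicInterval]
    genome: Genome
    cell_type: str | None = None

    def __post_init__(self) -> None:
        for iv in self.intervals:
            if iv.chrom not in self.genome:
                raise AnnotationError(f"unknown chromosome {iv.chrom!r} in peak set")
            if not self.genome.contains_interval(iv):
                raise AnnotationError(
                    f"peak {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome bounds"
                )

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def mean_length(self) -> float:
        return float(np.mean([len(iv) for iv in self.intervals]))

    @classmethod
    def read_bed(cls, path: str | Path, genome: Genome, cell_type: str | None = None):
        intervals = []
        for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise AnnotationError(f"{path}:{i}: need >=3 BED columns")
            intervals.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2])))
        return cls(intervals, genome, cell_type)


def _sorted_spans(tes: TEAnnotation) -> dict[tuple[str, str], tuple[np.ndarray, np.ndarray]]:
    tmp: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for te in tes:
        tmp.setdefault((te.interval.chrom, te.subfamily), []).append(
            (te.interval.start, te.interval.end)
        )
    return {
        k: (
            np.sort(np.array([s for s, _ in v], dtype=np.int64)),
            np.sort(np.array([e for _, e in v], dtype=np.int64)),
        )
        for k, v in tmp.items()
    }


def count_subfamily_overlaps(peaks: PeakSet, tes: TEAnnotation) -> pd.Series:
    """Peaks overlapping >= 1 integrant, counted once per subfamily.

    A peak spanning several integrants of one subfamily still counts
    once for it; a peak touching two subfamilies counts once for each.
    """
    spans = _sorted_spans(tes)
    tmp: dict[str, list[tuple[int, int]]] = {}
    for iv in peaks.intervals:
        tmp.setdefault(iv.chrom, []).append((iv.start, iv.end))
    peak_arrays = {
        ch: (
            np.array([s for s, _ in v], dtype=np.int64),
            np.array([e for _, e in v], dtype=np.int64),
        )
        for ch, v in tmp.items()
    }
    counts = {s: 0 for s in tes.subfamilies}
    for (chrom, s), (starts, ends) in spans.items():
        if chrom not in peak_arrays:
            continue
        ps, pe = peak_arrays[chrom]
        # per peak: #integrants with start < peak_end and end > peak_start
        n = np.searchsorted(starts, pe, side="left") - np.searchsorted(
            ends, ps, side="right"
        )
        counts[s] += int((n > 0).sum())
    return pd.Series(counts, name="observed").sort_index()


@dataclass
class ShuffleSet:
    """K chromosome-preserving non-overlapping shuffles of a TE annotation."""

    shuffles: list[TEAnnotation]
    seed: int
    K: int = DEFAULT_K


def shuffle_integrants(
    tes: TEAnnotation,
    K: int = DEFAULT_K,
    seed: int = 0,
    max_retries: int = 1000,
) -> ShuffleSet:
    """Randomly replace every integrant on its own chromosome.

    Each shuffle keeps per-chromosome integrant counts and lengths,
    placing starts uniformly and rejecting overlaps with integrants
    already placed in that shuffle (bounded rejection sampling).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    rng = np.random.default_rng(seed)
    genome = tes.genome
    shuffles = []
    for _k in range(K):
        trackers = {ch: _NonOverlapTracker() for ch in genome.sizes}
        placed: list[TEIntegrant] = []
        for i, te in enumerate(tes.integrants):
            ch = te.interval.chrom
            L = len(te.interval)
            limit = genome.sizes[ch] - L
            if limit < 0:
                raise ValueError(f"integrant longer than chromosome {ch}")
            ok = False
            for _ in range(max_retries):
                start = int(rng.integers(0, limit + 1))
                if trackers[ch].fits(start, start + L):
                    trackers[ch].add(start, start + L)
                    placed.append(
                        TEIntegrant(
                            GenomicInterval(ch, start, start + L, te.interval.strand),
                            locus_id=te.locus_id,
                            subfamily=te.subfamily,
                            family_class=te.family_class,
                            age_category=te.age_category,
                        )
                    )
                    ok = True
                    break
            if not ok:
                raise RuntimeError(
                    f"shuffle packing failed on chromosome {ch} "
                    f"after {max_retries} retries"
                )
        shuffles.append(TEAnnotation(genome, placed))
    return ShuffleSet(shuffles=shuffles, seed=seed, K=K)


def permutation_enrichment(
    peaks: PeakSet,
    tes: TEAnnotation,
    K: int = DEFAULT_K,
    seed: int = 0,
) -> pd.DataFrame:
    """Fold enrichment of observed peak overlaps over shuffled backgrounds.

    fold = observed / mean(shuffled observed); the empirical p uses the
    +1-corrected estimator (1 + #{shuffles >= observed}) / (K + 1), so
    with K = 10 its floor is 1/11.  A subfamily with observed > 0 but
    zero expected is flagged infinite.  ``observed_per_element`` is the
    integrant-count-normalized variant of the observed overlap.
    """
    observed = count_subfamily_overlaps(peaks, tes)
    shuffled = shuffle_integrants(tes, K=K, seed=seed)
    counts = pd.DataFrame(
        {k: count_subfamily_overlaps(peaks, sh) for k, sh in enumerate(shuffled.shuffles)}
    )
    out = permutation_summary(observed, counts)
    n_elements = pd.Series({s: len(tes.by_subfamily(s)) for s in observed.index})
    out["observed_per_element"] = observed / n_elements
    out["n_elements"] = n_elements
    return out


def permutation_summary(observed: pd.Series, shuffled_counts: pd.DataFrame) -> pd.DataFrame:
    """Fold and empirical p from observed vs per-shuffle overlap counts."""
    K = shuffled_counts.shape[1]
    expected = shuffled_counts.mean(axis=1)
    n_ge = shuffled_counts.ge(observed, axis=0).sum(axis=1)
    emp_p = (1.0 + n_ge) / (K + 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = observed / expected
    fold = fold.where(~((expected == 0) & (observed > 0)), np.inf)
    fold = fold.where(~((expected == 0) & (observed == 0)), np.nan)
    out = pd.DataFrame(
        {
            "observed": observed,
            "expected_mean": expected,
            "fold": fold,
            "fold_infinite": (expected == 0) & (observed > 0),
            "empirical_p": emp_p,
        }
    )
    out.index.name = "subfamily"
    return out


def coverage_enrichment(
    peaks: PeakSet, tes: TEAnnotation, genome: Genome
) -> pd.DataFrame:
    """Analytic random-genome-coverage null with binomial tail p.

    A uniformly placed peak of mean length Lbar hits an integrant of
    length len_i with probability (len_i + Lbar - 1)/G; summing over a
    subfamily's integrants (capped at 1) gives the per-peak hit
    probability p_s.  Expected overlap is n_peaks * p_s; significance
    requires fold > 2 and binomial upper-tail p < 0.05.
    """
    G = genome.total_size
    if G <= 0:
        raise ValueError("zero-length genome")
    n = len(peaks)
    lbar = peaks.mean_length
    observed = count_subfamily_overlaps(peaks, tes)
    rows = []
    for s in observed.index:
        members = tes.by_subfamily(s)
        p_s = min(1.0, sum(len(m.interval) + lbar - 1 for m in members) / G)
        expected = n * p_s
        fold = observed[s] / expected if expected > 0 else np.nan
        binom_p = float(stats.binom.sf(observed[s] - 1, n, p_s))
        rows.append((s, int(observed[s]), expected, fold, binom_p))
    out = pd.DataFrame(
        rows,
        columns=["subfamily", "observed", "analytic_expected", "fold", "binomial_p"],
    ).set_index("subfamily")
    out["significant"] = (out["fold"] > 2) & (out["binomial_p"] < 0.05)
    return out


@dataclass
class DensityTrack:
    """Smoothed TE coverage sampled every ``step`` bp per chromosome."""

    step: int
    window_bp: int
    values: dict[str, np.ndarray] = field(default_factory=dict)

    def total_mass(self) -> float:
        return float(sum(v.sum() * self.step for v in self.values.values()))

    def write_bedgraph(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.values):
                vals = self.values[chrom]
                for i, v in enumerate(vals):
                    if v != 0:
                        fh.write(
                            f"{chrom}\t{i * self.step}\t{(i + 1) * self.step}\t{v:.6g}\n"
                        )


def te_density_track(
    tes: TEAnnotation,
    genome: Genome,
    window_bp: int = DENSITY_WINDOW_BP,
    step: int = 100,
    subfamilies: list[str] | None = None,
    age_category: str | None = None,
) -> DensityTrack:
    """Base-level TE coverage smoothed with a centered rectangular window.

    Coverage depth is convolved with a moving average of width
    ``window_bp`` and emitted every ``step`` bp (value at each bin
    center).  Optional filters restrict to given subfamilies or an
    age category before smoothing.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be > 0")
    if step > window_bp:
        raise ValueError("step must be <= window_bp")
    selected = [
        te
        for te in tes
        if (subfamilies is None or te.subfamily in subfamilies)
        and (age_category is None or te.age_category == age_category)
    ]
    track = DensityTrack(step=step, window_bp=window_bp)
    h1 = window_bp // 2
    h2 = window_bp - h1
    for chrom, size in genome.sizes.items():
        diff = np.zeros(size + 1, dtype=np.int64)
        for te in selected:
            if te.interval.chrom == chrom:
                diff[te.interval.start] += 1
                diff[te.interval.end] -= 1
        depth = np.cumsum(diff[:-1])
        csum = np.concatenate([[0], np.cumsum(depth, dtype=np.float64)])
        centers = np.arange(step // 2, size, step)
        lo = np.clip(centers - h1, 0, size)
        hi = np.clip(centers + h2, 0, size)
        track.values[chrom] = (csum[hi] - csum[lo]) / window_bp
    return track
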