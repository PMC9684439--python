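import numpy as np
import pandas as pd
import pytest

from tecre import peak_enrichment as pe
from tecre.genome_io import Genome, GenomicInterval, TEAnnotation, TEIntegrant

from conftest import random_intervals


@pytest.fixture(scope="module")
def two_chrom_genome():
    return Genome({"chr1": 1_000_000, "chr2": 600_000})


def _ann(genome, spans):
    """spans: list of (chrom, start, end, subfamily)."""
    return TEAnnotation(
        genome,
        [
            TEIntegrant(GenomicInterval(c, s, e), f"te{i}", sub)
            for i, (c, s, e, sub) in enumerate(spans)
        ],
    )


class TestOverlapCounting:
    def test_peak_spanning_two_integrants_counts_once(self, two_chrom_genome):
        tes = _ann(
            two_chrom_genome,
            [("chr1", 1000, 1200, "LTR5Hs"), ("chr1", 1400, 1600, "LTR5Hs")],
        )
        peaks = pe.PeakSet([GenomicInterval("chr1", 900, 1700)], two_chrom_genome)
        obs = pe.count_subfamily_overlaps(peaks, tes)
        assert obs["LTR5Hs"] == 1

    def test_peak_touching_two_subfamilies_counts_for_each(self, two_chrom_genome):
        tes = _ann(
            two_chrom_genome,
            [("chr1", 1000, 1200, "LTR5Hs"), ("chr1", 1300, 1500, "AluY")],
        )
        peaks = pe.PeakSet([GenomicInterval("chr1", 1100, 1400)], two_chrom_genome)
        obs = pe.count_subfamily_overlaps(peaks, tes)
        assert obs["LTR5Hs"] == 1
        assert obs["AluY"] == 1

    def test_matches_brute_force(self, two_chrom_genome):
        rng = np.random.default_rng(7)
        spans = []
        for i, iv in enumerate(random_intervals(rng, 400, two_chrom_genome)):
            spans.append((iv.chrom, iv.start, iv.end, f"SF{i % 6}"))
        tes = _ann(two_chrom_genome, spans)
        peaks = pe.PeakSet(random_intervals(rng, 200, two_chrom_genome), two_chrom_genome)
        fast = pe.count_subfamily_overlaps(peaks, tes)
        brute = {s: 0 for s in tes.subfamilies}
        for iv in peaks.intervals:
            for s in {te.subfamily for te in tes if te.interval.overlaps(iv)}:
                brute[s] += 1
        assert fast.to_dict() == brute

    def test_unknown_chromosome_in_peaks_rejected(self, two_chrom_genome):
        with pytest.raises(Exception, match="chr9"):
            pe.PeakSet([GenomicInterval("chr9", 0, 100)], two_chrom_genome)


class TestShuffle:
    def test_preserves_chromosome_and_length_multisets(self, two_chrom_genome):
        rng = np.random.default_rng(0)
        spans = [
            (iv.chrom, iv.start, iv.end, f"SF{i % 3}")
            for i, iv in enumerate(random_intervals(rng, 150, two_chrom_genome))
        ]
        # the random intervals may overlap; keep a thinned non-overlapping set
        tes = _ann(two_chrom_genome, spans[:100])
        res = pe.shuffle_integrants(tes, K=5, seed=1)
        orig = {}
        for te in tes:
            orig.setdefault(te.interval.chrom, []).append(len(te.interval))
        for sh in res.shuffles:
            got = {}
            for te in sh:
                got.setdefault(te.interval.chrom, []).append(len(te.interval))
            assert {c: sorted(v) for c, v in got.items()} == {
                c: sorted(v) for c, v in orig.items()
            }

    def test_shuffled_integrants_non_overlapping(self, two_chrom_genome):
        rng = np.random.default_rng(1)
        spans = [
            (iv.chrom, iv.start, iv.end, "SFA")
            for iv in random_intervals(rng, 80, two_chrom_genome)
        ]
        tes = _ann(two_chrom_genome, spans)
        for sh in pe.shuffle_integrants(tes, K=3, seed=2).shuffles:
            prev = None
            for te in sh.integrants:
                if prev and prev.interval.chrom == te.interval.chrom:
                    assert prev.interval.end <= te.interval.start
                prev = te

    def test_same_seed_reproduces_shuffles(self, two_chrom_genome):
        tes = _ann(two_chrom_genome, [("chr1", 100, 500, "SFA"), ("chr2", 0, 300, "SFB")])
        a = pe.shuffle_integrants(tes, K=4, seed=9)
        b = pe.shuffle_integrants(tes, K=4, seed=9)
        for sa, sb in zip(a.shuffles, b.shuffles):
            assert [t.interval for t in sa] == [t.interval for t in sb]

    def test_single_integrant_start_is_uniform(self):
        genome = Genome({"chr1": 10_000})
        tes = _ann(genome, [("chr1", 0, 1_000, "SFA")])
        res = pe.shuffle_integrants(tes, K=10_000, seed=3)
        starts = np.array([sh.integrants[0].interval.start for sh in res.shuffles])
        expected_mean = (10_000 - 1_000) / 2
        assert abs(starts.mean() - expected_mean) < 0.01 * 10_000
        assert starts.min() >= 0 and starts.max() <= 9_000

    def test_infeasible_packing_raises(self):
        genome = Genome({"chr1": 1_000})
        tes = _ann(genome, [("chr1", 0, 600, "SFA"), ("chr1", 600, 1_000, "SFA")])
        with pytest.raises(RuntimeError, match="chr1"):
            pe.shuffle_integrants(tes, K=1, seed=0, max_retries=50)


class TestPermutationSummary:
    def test_fold_and_empirical_p_formulas(self):
        observed = pd.Series({"SFA": 10})
        shuffled = pd.DataFrame({k: {"SFA": 5} for k in range(10)})
        out = pe.permutation_summary(observed, shuffled)
        assert out.loc["SFA", "fold"] == 2.0
        assert out.loc["SFA", "empirical_p"] == pytest.approx(1 / 11)

    def test_zero_expected_with_hits_flagged_infinite(self):
        observed = pd.Series({"SFA": 3})
        shuffled = pd.DataFrame({k: {"SFA": 0} for k in range(10)})
        out = pe.permutation_summary(observed, shuffled)
        assert np.isinf(out.loc["SFA", "fold"])
        assert out.loc["SFA", "fold_infinite"]
        assert out.loc["SFA", "empirical_p"] == pytest.approx(1 / 11)

    def test_observed_below_null_has_high_p(self):
        observed = pd.Series({"SFA": 2})
        shuffled = pd.DataFrame({k: {"SFA": 5 + k} for k in range(10)})
        out = pe.permutation_summary(observed, shuffled)
        assert out.loc["SFA", "empirical_p"] == 1.0

    def test_k_below_one_rejected(self, two_chrom_genome):
        tes = _ann(two_chrom_genome, [("chr1", 100, 500, "SFA")])
        peaks = pe.PeakSet([GenomicInterval("chr1", 0, 100)], two_chrom_genome)
        with pytest.raises(ValueError, match="K"):
            pe.permutation_enrichment(peaks, tes, K=0)


class TestCoverageNull:
    def test_half_genome_subfamily_with_point_peaks(self):
        genome = Genome({"chr1": 100_000})
        tes = _ann(genome, [("chr1", 0, 50_000, "SFA")])
        peaks = pe.PeakSet(
            [GenomicInterval("chr1", 60_000 + 10 * i, 60_001 + 10 * i) for i in range(100)],
            genome,
        )
        out = pe.coverage_enrichment(peaks, tes, genome)
        assert out.loc["SFA", "analytic_expected"] == pytest.approx(50, rel=0.01)

    def test_observed_equal_expected_not_significant(self):
        genome = Genome({"chr1": 100_000})
        tes = _ann(genome, [("chr1", 0, 50_000, "SFA")])
        # 100 peaks on a genome-wide grid: exactly 50 fall inside the integrant
        ivs = [GenomicInterval("chr1", 1000 * i, 1000 * i + 50) for i in range(100)]
        peaks = pe.PeakSet(ivs, genome)
        out = pe.coverage_enrichment(peaks, tes, genome)
        assert out.loc["SFA", "fold"] == pytest.approx(1.0, rel=0.05)
        assert not out.loc["SFA", "significant"]

    def test_binomial_p_matches_monte_carlo(self):
        # small genome, one subfamily; compare the analytic tail with the
        # frequency of equally extreme overlaps under uniform peak placement
        genome = Genome({"chr1": 100_000, "chr2": 100_000})
        rng = np.random.default_rng(11)
        spans = []
        pos = 0
        for i in range(40):
            pos += 2_000
            spans.append(("chr1" if i % 2 else "chr2", pos, pos + 800, "SFA"))
        tes = _ann(genome, spans)
        L = 200
        n_peaks = 50
        peaks = pe.PeakSet(
            [GenomicInterval("chr1", 1_900 * i, 1_900 * i + L) for i in range(n_peaks)],
            genome,
        )
        out = pe.coverage_enrichment(peaks, tes, genome)
        observed = out.loc["SFA", "observed"]
        # Monte Carlo: uniform placement of 50 peaks, 10,000 repetitions
        starts_ch1, ends_ch1 = _span_arrays(tes, "chr1")
        starts_ch2, ends_ch2 = _span_arrays(tes, "chr2")
        hits = 0
        n_mc = 10_000
        for _ in range(n_mc):
            chrom_pick = rng.random(n_peaks) < 0.5
            s = rng.integers(0, 100_000 - L, n_peaks)
            k = 0
            for j in range(n_peaks):
                st, en = (starts_ch1, ends_ch1) if chrom_pick[j] else (starts_ch2, ends_ch2)
                if np.searchsorted(st, s[j] + L) - np.searchsorted(en, s[j], side="right") > 0:
                    k += 1
            if k >= observed:
                hits += 1
        mc_p = hits / n_mc
        assert out.loc["SFA", "binomial_p"] == pytest.approx(mc_p, rel=0.10, abs=0.01)


def _span_arrays(tes, chrom):
    spans = [
        (te.interval.start, te.interval.end)
        for te in tes
        if te.interval.chrom == chrom
    ]
    return (
        np.sort(np.array([s for s, _ in spans])),
        np.sort(np.array([e for _, e in spans])),
    )


class TestDensityTrack:
    def test_single_integrant_plateau_height(self):
        genome = Genome({"chr1": 100_000})
        tes = _ann(genome, [("chr1", 50_000, 50_300, "SFA")])
        track = pe.te_density_track(tes, genome, window_bp=10_000, step=100)
        assert track.values["chr1"].max() == pytest.approx(300 / 10_000)

    def test_empty_annotation_gives_zero_track(self):
        genome = Genome({"chr1": 50_000})
        tes = TEAnnotation(genome, [])
        track = pe.te_density_track(tes, genome, window_bp=10_000, step=100)
        assert np.all(track.values["chr1"] == 0)

    def test_mass_conservation(self):
        genome = Genome({"chr1": 200_000})
        tes = _ann(genome, [("chr1", 80_000, 83_000, "SFA"), ("chr1", 120_000, 121_000, "SFB")])
        track = pe.te_density_track(tes, genome, window_bp=10_000, step=100)
        assert track.total_mass() == pytest.approx(4_000, rel=0.01)

    def test_age_filter_restricts_mass(self):
        genome = Genome({"chr1": 200_000})
        tes = TEAnnotation(
            genome,
            [
                TEIntegrant(GenomicInterval("chr1", 10_000, 12_000), "a", "SFA",
                            age_category="hominid"),
                TEIntegrant(GenomicInterval("chr1", 50_000, 51_000), "b", "SFB",
                            age_category="older"),
            ],
        )
        track = pe.te_density_track(tes, genome, age_category="hominid", step=100)
        assert track.total_mass() == pytest.approx(2_000, rel=0.01)

    def test_bedgraph_round_numbers(self, tmp_path):
        genome = Genome({"chr1": 50_000})
        tes = _ann(genome, [("chr1", 20_000, 20_500, "SFA")])
        track = pe.te_density_track(tes, genome, step=100)
        out = tmp_path / "d.bedgraph"
        track.write_bedgraph(out)
        lines = out.read_text().splitlines()
        assert all(len(l.split("\t")) == 4 for l in lines)
        assert lines[0].startswith("chr1\t")
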