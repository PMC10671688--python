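"""Per-SNP ROH occurrence, top-1% islands and gene annotation."""

import numpy as np
import pytest

from rohscan.detect import ROHSegment
from rohscan.islands import (
    annotate_islands,
    build_islands,
    occurrence_plot,
    select_top_percent,
    snp_occurrence,
    write_island_tsv,
    Island,
    OccurrenceProfile,
)
from rohscan.model import GeneInterval, SNPRecord


def make_map(n=100, spacing=50_000, chrom=1, start=1):
    return [SNPRecord(chrom, f"s{chrom}_{i}", 0.0, start + spacing * i)
            for i in range(n)]


def seg(iid, chrom, start, end):
    return ROHSegment("F", iid, chrom, start, end, 20)


class TestSnpOccurrence:
    def test_identical_segment_in_everyone(self):
        snps = make_map(100)
        segs = [seg(f"i{k}", 1, 1_000_001, 2_000_001) for k in range(10)]
        prof = snp_occurrence(segs, snps, 10)
        inside = (np.array([s.position_bp for s in snps]) >= 1_000_001) & \
                 (np.array([s.position_bp for s in snps]) <= 2_000_001)
        assert (prof.percent[inside] == 100.0).all()
        assert (prof.percent[~inside] == 0.0).all()

    def test_zero_segments(self):
        prof = snp_occurrence([], make_map(10), 5)
        assert (prof.counts == 0).all()

    def test_individual_counts_once_despite_overlap(self):
        snps = make_map(40)
        segs = [seg("i0", 1, 1, 500_001), seg("i0", 1, 400_001, 900_001)]
        prof = snp_occurrence(segs, snps, 4)
        assert prof.counts.max() == 1

    def test_unknown_chromosome_errors(self):
        with pytest.raises(ValueError, match="absent from map"):
            snp_occurrence([seg("i0", 9, 1, 10)], make_map(5), 2)

    def test_matches_membership_recount(self, rng):
        snps = make_map(60) + make_map(40, chrom=2)
        segs = []
        for k in range(15):
            chrom = int(rng.integers(1, 3))
            a = int(rng.integers(1, 4_000_000))
            segs.append(seg(f"i{int(rng.integers(0, 6))}", chrom, a,
                            a + int(rng.integers(100_000, 2_000_000))))
        prof = snp_occurrence(segs, snps, 6)
        for j, s in enumerate(snps):
            covering = {
                g.individual_id for g in segs
                if g.chromosome == s.chromosome
                and g.start_bp <= s.position_bp <= g.end_bp}
            assert prof.counts[j] == len(covering)

    def test_double_counting_identity(self, rng):
        # sum of per-SNP counts == sum over (individual, merged coverage)
        # of SNPs inside, which for disjoint per-individual segments is
        # the sum over segments of contained SNPs
        snps = make_map(80)
        segs = []
        for k in range(10):
            a = 1 + 400_000 * k
            segs.append(seg(f"i{k}", 1, a, a + 300_000))
        prof = snp_occurrence(segs, snps, 10)
        positions = np.array([s.position_bp for s in snps])
        per_segment = sum(
            int(((positions >= g.start_bp) & (positions <= g.end_bp)).sum())
            for g in segs)
        assert int(prof.counts.sum()) == per_segment


class TestSelectTopPercent:
    def profile(self, counts):
        counts = np.asarray(counts)
        return OccurrenceProfile(tuple(make_map(len(counts))), counts,
                                 int(counts.max(initial=1)))

    def test_distinct_occurrences_select_exactly_one(self):
        prof = self.profile(np.arange(1, 101))
        selected, cutoff = select_top_percent(prof, 1.0)
        assert selected.sum() == 1 and cutoff == 100

    def test_ties_at_cutoff_all_included(self):
        counts = np.arange(1, 96)
        counts = np.concatenate([counts, [95] * 5])
        prof = self.profile(counts)
        selected, cutoff = select_top_percent(prof, 1.0)
        assert cutoff == 95 and selected.sum() == 6  # 5 ties + original 95

    def test_all_zero_profile_selects_nothing(self):
        selected, cutoff = select_top_percent(self.profile(np.zeros(50, int)))
        assert not selected.any() and cutoff == 0.0

    def test_matches_sort_oracle(self, rng):
        import math
        for _ in range(20):
            counts = rng.integers(0, 50, size=int(rng.integers(20, 300)))
            prof = self.profile(counts)
            selected, cutoff = select_top_percent(prof, 1.0)
            k = max(1, math.ceil(0.01 * counts.size))
            kth = sorted(counts, reverse=True)[k - 1]
            if kth == 0:
                assert (selected == (counts > 0)).all()
            else:
                assert cutoff == kth
                assert (selected == (counts >= kth)).all()
            if selected.any():
                assert counts[selected].min() >= counts[~selected].max(initial=0)
            assert selected.sum() >= min(k, (counts > 0).sum())


class TestBuildIslands:
    def test_adjacent_selected_snps_merge(self):
        snps = make_map(20)
        islands = build_islands(np.ones(20, bool), snps)
        assert len(islands) == 1
        assert islands[0].n_snp == 20

    def test_distant_clusters_split(self):
        snps = make_map(10) + make_map(10, start=6_000_000)
        islands = build_islands(np.ones(20, bool), snps)
        assert len(islands) == 2

    def test_small_islands_dropped(self):
        snps = make_map(10)
        mask = np.zeros(10, bool)
        mask[[0, 1]] = True  # below min_island_snps=3
        assert build_islands(mask, snps) == []

    def test_matches_merge_oracle(self, rng):
        snps = make_map(120) + make_map(80, chrom=2)
        for _ in range(20):
            mask = rng.random(200) < 0.3
            got = build_islands(mask, snps, 1000.0, 3)
            # oracle: walk selected SNPs, close island on chrom change
            # or gap > 1 Mb
            selected = [s for s, m in zip(snps, mask) if m]
            groups, current = [], []
            for s in selected:
                if current and (s.chromosome != current[-1].chromosome
                                or s.position_bp - current[-1].position_bp
                                > 1_000_000):
                    groups.append(current)
                    current = []
                current.append(s)
            if current:
                groups.append(current)
            expected = [
                Island(g[0].chromosome, g[0].position_bp, g[-1].position_bp,
                       len(g))
                for g in groups if len(g) >= 3]
            assert got == expected


class TestAnnotateIslands:
    def test_island_containing_gene(self):
        # chr13 island 50.59-51.89 Mb containing a BMP2-like interval
        island = Island(13, 50_590_000, 51_890_000, 19)
        genes = [GeneInterval(13, 50_910_000, 50_921_000, "BMP2")]
        (out,) = annotate_islands([island], genes)
        assert out.genes == ("BMP2",)
        assert (out.start_mb, out.end_mb) == (50.59, 51.89)

    def test_no_overlap_leaves_empty(self):
        island = Island(13, 50_590_000, 51_890_000, 19)
        genes = [GeneInterval(13, 60_000_000, 60_100_000, "FAR"),
                 GeneInterval(12, 50_600_000, 50_700_000, "WRONG_CHROM")]
        (out,) = annotate_islands([island], genes)
        assert out.genes == ()

    def test_one_bp_overlap_counts(self):
        island = Island(1, 1_000, 2_000, 5)
        genes = [GeneInterval(1, 2_000, 3_000, "EDGE")]
        (out,) = annotate_islands([island], genes)
        assert out.genes == ("EDGE",)

    def test_matches_all_pairs_oracle(self, rng):
        islands = [Island(int(c), int(a), int(a + w), 5)
                   for c, a, w in zip(rng.integers(1, 5, 10),
                                      rng.integers(1, 10**7, 10),
                                      rng.integers(10**4, 10**6, 10))]
        genes = [GeneInterval(int(c), int(a), int(a + w), f"G{i}")
                 for i, (c, a, w) in enumerate(zip(
                     rng.integers(1, 5, 50), rng.integers(1, 10**7, 50),
                     rng.integers(10**3, 10**6, 50)))]
        out = annotate_islands(islands, genes)
        for isl, res in zip(islands, out):
            expected = sorted(
                (g for g in genes if g.chromosome == isl.chromosome
                 and g.start_bp <= isl.end_bp and g.end_bp >= isl.start_bp),
                key=lambda g: (g.start_bp, g.end_bp, g.gene_name))
            assert res.genes == tuple(g.gene_name for g in expected)


class TestOutputs:
    def test_island_tsv_layout(self, tmp_path):
        isl = Island(13, 50_590_000, 51_890_000, 19, ("BMP2",))
        write_island_tsv([isl], tmp_path / "islands.tsv")
        lines = (tmp_path / "islands.tsv").read_text().splitlines()
        assert lines[0] == "CHR\tN_SNP\tSTART_MB\tEND_MB\tGENES"
        assert lines[1] == "13\t19\t50.59\t51.89\tBMP2"

    def test_plot_renders_flat_profile(self, tmp_path):
        prof = OccurrenceProfile(tuple(make_map(30)), np.zeros(30, int), 10)
        out = occurrence_plot(prof, None, tmp_path / "flat.png")
        assert out.exists() and out.stat().st_size > 0

    def test_plot_with_empty_selection(self, tmp_path):
        prof = OccurrenceProfile(tuple(make_map(30)), np.zeros(30, int), 10)
        out = occurrence_plot(prof, np.zeros(30, bool), tmp_path / "e.png", 1.0)
        assert out.exists()

    def test_planted_island_is_the_peak(self, tmp_path):
        from rohscan.detect import detect_roh
        from rohscan.simulate import PlantedIsland, SimConfig, simulate_population
        from rohscan.islands import select_top_percent, snp_occurrence
        cfg = SimConfig(
            n_individuals=40, chromosomes=((50_000_000, 1000),) * 2,
            tracts_per_individual=0.3, missing_rate=0.0, seed=13,
            planted_islands=(PlantedIsland(1, 20_000_000, 23_000_000, 0.7),))
        ds, _ = simulate_population(cfg)
        segs = detect_roh(ds)
        prof = snp_occurrence(segs, ds.snps, ds.n_samples)
        selected, _ = select_top_percent(prof, 1.0)
        out = occurrence_plot(prof, selected, tmp_path / "m.png",
                              100.0 * 0.5)
        assert out.exists()
        peak = np.argmax(prof.counts)
        assert ds.snps[peak].chromosome == 1
        assert 20_000_000 <= ds.snps[peak].position_bp <= 23_000_000
        assert selected[peak]
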