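"""Sliding-window ROH detection against brute-force oracles."""

import numpy as np
import pytest

from rohscan.detect import (
    ROHParams,
    call_segments,
    detect_roh,
    snp_support,
    window_flags,
)
from rohscan.model import (
    GenotypeDataset,
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    SampleRecord,
    SNPRecord,
)
from rohscan.reference import count_windows_direct, enumerate_roh_segments
from rohscan.simulate import SimConfig, simulate_population, target_tract_rate


def random_instance(rng, n_max=200):
    n = int(rng.integers(5, n_max + 1))
    calls = rng.choice([HOM_REF, HET, HOM_ALT, MISSING], size=n,
                       p=[0.45, 0.12, 0.40, 0.03])
    positions = np.sort(rng.choice(20_000_000, size=n, replace=False)) + 1
    params = ROHParams(
        window_snps=int(rng.integers(2, 20)),
        window_max_het=int(rng.integers(0, 3)),
        window_max_missing=int(rng.integers(0, 3)),
        window_threshold=float(rng.uniform(0.01, 0.9)),
        min_snps=int(rng.integers(2, 20)),
        min_length_kb=float(rng.uniform(10, 2000)),
        max_density_kb_per_snp=float(rng.uniform(20, 500)),
        max_gap_kb=float(rng.uniform(50, 1000)),
        het_terminates=bool(rng.integers(0, 2)),
    )
    return calls, positions, params


class TestWindowFlags:
    def test_all_hom_single_window(self):
        flags = window_flags(np.full(15, HOM_REF), ROHParams())
        assert flags.tolist() == [True]

    def test_two_hets_fail_default_allowance(self):
        calls = np.full(15, HOM_REF)
        calls[[3, 9]] = HET
        assert window_flags(calls, ROHParams()).tolist() == [False]

    def test_short_chromosome_has_zero_windows(self):
        assert window_flags(np.full(10, HOM_REF), ROHParams()).size == 0

    def test_matches_direct_recount(self, rng):
        for _ in range(30):
            calls = rng.choice([0, 1, 2, 3], size=60)
            params = ROHParams(window_snps=int(rng.integers(2, 16)),
                               window_max_het=int(rng.integers(0, 3)),
                               window_max_missing=int(rng.integers(0, 3)))
            assert window_flags(calls, params).tolist() == \
                count_windows_direct(calls, params)


class TestSnpSupport:
    def test_all_true_windows(self):
        params = ROHParams(window_snps=5)
        prop, flagged = snp_support(np.ones(6, dtype=bool), 10, params)
        assert (prop == 1.0).all() and flagged.all()

    def test_all_false_windows(self):
        params = ROHParams(window_snps=5)
        prop, flagged = snp_support(np.zeros(6, dtype=bool), 10, params)
        assert (prop == 0.0).all() and not flagged.any()

    def test_zero_windows_unflags_everything(self):
        prop, flagged = snp_support(np.zeros(0, dtype=bool), 8, ROHParams())
        assert prop.shape == (8,) and not flagged.any()

    def test_brute_force_per_snp_recount(self, rng):
        params = ROHParams(window_snps=7, window_threshold=0.4)
        calls = np.full(40, HOM_REF)
        calls[18:24] = HET  # one heterozygous block
        flags = window_flags(calls, params)
        prop, _ = snp_support(flags, 40, params)
        k, n_win = 7, flags.size
        for s in range(40):
            containing = [w for w in range(n_win) if w <= s <= w + k - 1]
            expected = sum(flags[w] for w in containing) / len(containing)
            assert prop[s] == pytest.approx(expected)

    def test_end_snp_denominator_shrinks(self):
        params = ROHParams(window_snps=5, window_threshold=0.5)
        flags = np.array([True, False, False, False, False, False], dtype=bool)
        prop, _ = snp_support(flags, 10, params)
        assert prop[0] == 1.0          # SNP 0 in window 0 only
        assert prop[4] == pytest.approx(0.2)   # in windows 0..4


class TestCallSegments:
    def setup_method(self):
        self.params = ROHParams()

    def test_uniform_hom_run(self):
        n = 100
        positions = 1 + 50_000 * np.arange(n)
        calls = np.full(n, HOM_REF)
        flagged = np.ones(n, dtype=bool)
        (seg,) = call_segments(flagged, calls, positions, self.params)
        assert seg.n_snps == 100
        assert seg.length_bp == positions[-1] - positions[0] + 1
        assert seg.length_bp / seg.n_snps <= 100_000

    def test_large_gap_splits_run(self):
        # 60 SNPs at 50 kb, then a 300 kb gap, then 60 more
        left = 1 + 50_000 * np.arange(60)
        right = left[-1] + 300_001 + 50_000 * np.arange(60)
        positions = np.concatenate([left, right])
        calls = np.full(120, HOM_ALT)
        flagged = np.ones(120, dtype=bool)
        segs = call_segments(flagged, calls, positions, self.params)
        assert len(segs) == 2
        assert all(s.n_snps == 60 for s in segs)

    def test_sub_minimum_pieces_dropped_after_split(self):
        # gap splits 20 SNPs into 10+10: each piece < 15 SNPs, dropped
        left = 1 + 50_000 * np.arange(10)
        right = left[-1] + 300_001 + 50_000 * np.arange(10)
        positions = np.concatenate([left, right])
        calls = np.full(20, HOM_REF)
        segs = call_segments(np.ones(20, bool), calls, positions, self.params)
        assert segs == []

    @pytest.mark.parametrize("het_terminates", [True, False])
    def test_matches_enumeration_oracle(self, rng, het_terminates):
        for _ in range(30):
            calls, positions, params = random_instance(rng)
            params = ROHParams(**{**params.__dict__,
                                  "het_terminates": het_terminates})
            flags = window_flags(calls, params)
            _, flagged = snp_support(flags, calls.size, params)
            assert call_segments(flagged, calls, positions, params) == \
                enumerate_roh_segments(flagged, calls, positions, params)

    def test_every_segment_satisfies_invariants(self, rng):
        for _ in range(50):
            calls, positions, params = random_instance(rng)
            flags = window_flags(calls, params)
            _, flagged = snp_support(flags, calls.size, params)
            segs = call_segments(flagged, calls, positions, params)
            prev_end = -1
            for s in segs:
                assert s.n_snps >= params.min_snps
                assert s.length_bp >= params.min_length_kb * 1000
                assert s.length_bp / s.n_snps <= params.max_density_kb_per_snp * 1000
                assert s.start_bp > prev_end  # disjoint and sorted
                prev_end = s.end_bp
                inside = (positions >= s.start_bp) & (positions <= s.end_bp)
                gaps = np.diff(positions[inside])
                assert (gaps <= params.max_gap_kb * 1000).all()

    def test_monotone_in_thresholds(self, rng):
        for _ in range(20):
            calls, positions, params = random_instance(rng, n_max=120)

            def count(p):
                flags = window_flags(calls, p)
                _, flagged = snp_support(flags, calls.size, p)
                return len(call_segments(flagged, calls, positions, p))

            base = count(params)
            import dataclasses
            stricter_len = dataclasses.replace(
                params, min_length_kb=params.min_length_kb * 2)
            stricter_snps = dataclasses.replace(
                params, min_snps=params.min_snps + 5)
            stricter_het = dataclasses.replace(
                params, window_max_het=max(0, params.window_max_het - 1))
            assert count(stricter_len) <= base
            assert count(stricter_snps) <= base
            assert count(stricter_het) <= base


class TestDetectROH:
    def test_all_het_individual_yields_nothing(self):
        n = 50
        snps = [SNPRecord(1, f"s{j}", 0.0, 1 + 50_000 * j) for j in range(n)]
        ds = GenotypeDataset([SampleRecord("F", "I")], snps,
                             np.full((1, n), HET, dtype=np.int8))
        assert detect_roh(ds) == []

    def test_fully_homozygous_chromosome_is_one_segment(self):
        n = 100  # 5 Mb at 50 kb spacing
        snps = [SNPRecord(1, f"s{j}", 0.0, 1 + 50_000 * j) for j in range(n)]
        ds = GenotypeDataset([SampleRecord("F", "I")], snps,
                             np.full((1, n), HOM_ALT, dtype=np.int8))
        (seg,) = detect_roh(ds)
        assert (seg.start_bp, seg.end_bp) == (1, 1 + 50_000 * (n - 1))

    def test_deterministic(self, rng):
        cfg = SimConfig(n_individuals=20, chromosomes=((20_000_000, 400),) * 2,
                        seed=3)
        ds, _ = simulate_population(cfg)
        assert detect_roh(ds) == detect_roh(ds)

    def test_planted_tracts_recovered(self):
        # dense map (20 kb spacing) and high-MAF background keep run
        # extension past the tract short relative to the >= 3 Mb tracts,
        # so 90% reciprocal overlap is the right yardstick
        base = dict(n_individuals=20, chromosomes=((100_000_000, 5000),) * 2,
                    freq_range=(0.45, 0.5), tract_mean_mb=6.0,
                    tract_min_mb=3.0, missing_rate=0.0, seed=5)
        cfg = SimConfig(**base)
        cfg = SimConfig(**base,
                        tracts_per_individual=target_tract_rate(cfg, 0.04))
        ds, truth = simulate_population(cfg)
        segs = detect_roh(ds)
        by_iid = {}
        for s in segs:
            by_iid.setdefault(s.individual_id, []).append(s)
        for rec in truth.individuals:
            for chrom, a, b in rec.tracts:
                overlaps = [
                    s for s in by_iid.get(rec.individual_id, [])
                    if s.chromosome == chrom
                    and min(s.end_bp, b) - max(s.start_bp, a) + 1
                    >= 0.9 * (b - a + 1)
                    and (b - a + 1)
                    >= 0.9 * s.length_bp
                ]
                assert len(overlaps) == 1, (
                    f"tract {chrom}:{a}-{b} of {rec.individual_id} not "
                    f"recovered 1:1 (got {len(overlaps)} matches)")
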