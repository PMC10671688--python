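"""Validation experiments exercising the pipeline end to end.

Each function runs a self-contained study on synthetic data with known
truth and returns plain numbers, so the same code backs the test suite,
the acceptance script and the analysis drivers.  Problem sizes are the
package's standard desk-scale conditions: 100 individuals on 3
chromosomes of 100 Mb x 2000 SNPs (~50 kb spacing) unless stated
otherwise.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .detect import ROHParams, call_segments, detect_roh, snp_support, window_flags
from .islands import build_islands, select_top_percent, snp_occurrence
from .model import HET, HOM_ALT, HOM_REF, MISSING
from .qc import QCConfig, apply_qc, hwe_exact_pvalue, _het_distribution
from .reference import enumerate_roh_segments, hwe_pvalue_by_enumeration
from .simulate import PlantedIsland, SimConfig, simulate_population, target_tract_rate
from .stats import autosomal_span, froh_table


def froh_recovery(
    true_f: float,
    n_replicates: int = 10,
    seed: int = 0,
    *,
    n_individuals: int = 100,
    with_qc: bool = True,
) -> dict[str, float]:
    """Mean detected F_ROH (>1 Mb) against a known planted fraction.

    Simulates ``n_replicates`` populations with autozygous tracts of
    mean 4 Mb (minimum 2 Mb) totalling ``true_f`` of the genome in
    expectation, zero heterozygote error and 1% missingness, runs
    QC + detection, and averages per-individual F_ROH > 1 Mb.
    """
    detected: list[float] = []
    truths: list[float] = []
    for rep in range(n_replicates):
        base = dict(
            n_individuals=n_individuals,
            chromosomes=((100_000_000, 2000),) * 3,
            het_error_rate=0.0,
            missing_rate=0.01,
            seed=seed * 10_000 + rep,
        )
        cfg = SimConfig(**base)
        cfg = SimConfig(**base, tracts_per_individual=target_tract_rate(cfg, true_f))
        dataset, truth = simulate_population(cfg)
        if with_qc:
            dataset, _report = apply_qc(dataset, QCConfig())
        segments = detect_roh(dataset, ROHParams())
        l_aut = autosomal_span(dataset.snps)
        table = froh_table(segments, dataset.samples, l_aut)
        detected.append(float(table["froh_gt_1mb"].mean()))
        truths.append(float(np.mean([r.true_f for r in truth.individuals])))
    mean_detected = float(np.mean(detected))
    mean_true = float(np.mean(truths))
    return {
        "true_f": true_f,
        "mean_true_f": mean_true,
        "mean_detected_f": mean_detected,
        "abs_error_vs_target": abs(mean_detected - true_f),
        "n_replicates": n_replicates,
    }


def island_recovery(
    n_replicates: int = 20,
    seed: int = 0,
    *,
    carrier_fraction: float = 0.6,
    background_f: float = 0.08,
) -> dict[str, float]:
    """How often a shared 2 Mb tract surfaces as a reported island.

    Each replicate plants a 2 Mb tract at one fixed locus in
    ``carrier_fraction`` of 100 individuals over ``background_f``
    background autozygosity, runs detection and the top-1% island scan,
    and checks that the locus midpoint falls inside a reported island.
    """
    locus = PlantedIsland(2, 40_000_000, 42_000_000, carrier_fraction)
    midpoint = (locus.start_bp + locus.end_bp) // 2
    hits = 0
    for rep in range(n_replicates):
        base = dict(
            n_individuals=100,
            chromosomes=((100_000_000, 2000),) * 3,
            het_error_rate=0.0,
            missing_rate=0.01,
            planted_islands=(locus,),
            seed=seed * 10_000 + 777 + rep,
        )
        cfg = SimConfig(**base)
        cfg = SimConfig(
            **base, tracts_per_individual=target_tract_rate(cfg, background_f)
        )
        dataset, _truth = simulate_population(cfg)
        segments = detect_roh(dataset, ROHParams())
        profile = snp_occurrence(segments, dataset.snps, dataset.n_samples)
        selected, _cutoff = select_top_percent(profile, 1.0)
        islands = build_islands(selected, dataset.snps)
        if any(
            isl.chromosome == locus.chromosome
            and isl.start_bp <= midpoint <= isl.end_bp
            for isl in islands
        ):
            hits += 1
    return {
        "n_replicates": n_replicates,
        "n_recovered": hits,
        "recovery_rate": hits / n_replicates,
    }


def caller_oracle_agreement(
    n_instances: int = 100, seed: int = 0, n_max_snps: int = 200
) -> dict[str, float]:
    """Fraction of randomized instances where the sliding-window caller
    matches the exhaustive sub-interval enumeration oracle exactly.

    Instances mix HOM/HET/MISSING calls and draw every scan parameter
    from a sane range; both heterozygote-termination modes are covered.
    """
    rng = np.random.default_rng(seed)
    agree = 0
    for k in range(n_instances):
        n = int(rng.integers(5, n_max_snps + 1))
        calls = rng.choice(
            [HOM_REF, HET, HOM_ALT, MISSING], size=n, p=[0.45, 0.12, 0.40, 0.03]
        )
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
            het_terminates=bool(k % 2),
        )
        flags = window_flags(calls, params)
        _, flagged = snp_support(flags, n, params)
        if call_segments(flagged, calls, positions, params) == \
                enumerate_roh_segments(flagged, calls, positions, params):
            agree += 1
    return {"n_instances": n_instances, "n_agreeing": agree,
            "agreement_rate": agree / n_instances}


def hwe_exhaustive_sweep(n_max: int = 100) -> dict[str, float]:
    """Worst disagreement between the recurrence-based exact HWE test
    and the direct-summation oracle over every genotype-count triple
    with total at most ``n_max``.

    A triple (n_hom_ref, n_het, n_hom_alt) is determined up to allele
    swap by (n, rare-allele count, n_het), so sweeping every
    heterozygote count of every (n, n_rare) pair covers all triples.
    """
    worst = 0.0
    n_checked = 0
    for n in range(1, n_max + 1):
        for n_rare in range(0, n + 1):
            h_min = n_rare % 2
            for h in range(h_min, n_rare + 1, 2):
                rare_homs = (n_rare - h) // 2
                a = rare_homs
                c = n - h - rare_homs
                fast = hwe_exact_pvalue(a, h, c)
                slow = hwe_pvalue_by_enumeration(a, h, c)
                worst = max(worst, abs(fast - slow))
                n_checked += 1
    return {"n_max": n_max, "n_triples": n_checked, "max_abs_diff": worst}


__all__ = [
    "froh_recovery",
    "island_recovery",
    "caller_oracle_agreement",
    "hwe_exhaustive_sweep",
]
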