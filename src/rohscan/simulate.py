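"""Synthetic diploid SNP-chip populations with known autozygosity truth.

The generator emulates the array data this pipeline consumes: a map of
biallelic SNPs at ~50 kb spacing over a configurable set of autosomes,
genotypes drawn from Hardy-Weinberg proportions in a single panmictic
base population, and — the point of the exercise — per-individual
autozygous tracts forced homozygous at a known location and length, so
that the true inbreeding fraction and island carriers are known exactly
(tracts are identical-by-descent by construction rather than produced by
a pedigree).  Optional knobs add genotyping error inside tracts, random
missingness, shared tracts at fixed loci (recoverable islands) and
planted QC failures of every kind.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import write_ped_map
from .model import (
    GenotypeDataset,
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    SampleRecord,
    SNPRecord,
)

log = logging.getLogger(__name__)

_TRACT_RETRY_CAP = 1000


@dataclass(frozen=True)
class PlantedIsland:
    """A shared autozygous tract at a fixed locus, carried by a fixed
    fraction of individuals — the recoverable island truth."""

    chromosome: int
    start_bp: int
    end_bp: int
    carrier_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.carrier_fraction <= 1.0:
            raise ValueError("carrier_fraction outside [0, 1]")
        if self.start_bp > self.end_bp:
            raise ValueError("island start > end")


@dataclass(frozen=True)
class QCSpike:
    """Planted QC failures (counts), injected after genotype simulation."""

    n_low_call_snps: int = 0
    n_low_maf_snps: int = 0
    n_hwe_snps: int = 0
    n_high_missing_individuals: int = 0
    missing_fraction: float = 0.20  # for spiked SNPs/individuals


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic population.

    Defaults are the desk-scale shape used throughout the test suite:
    100 individuals on 3 chromosomes of 100 Mb x 2000 SNPs (~50 kb
    spacing), tract lengths 2 Mb + Exp(2 Mb) (mean 4 Mb), no genotyping
    error, 1% missingness.  ``tracts_per_individual`` is the Poisson mean
    number of random tracts; :func:`target_tract_rate` converts a target
    F into this rate.
    """

    n_individuals: int = 100
    chromosomes: tuple[tuple[int, int], ...] = ((100_000_000, 2000),) * 3
    freq_range: tuple[float, float] = (0.05, 0.5)
    tracts_per_individual: float = 3.75
    tract_mean_mb: float = 4.0
    tract_min_mb: float = 2.0
    planted_islands: tuple[PlantedIsland, ...] = ()
    het_error_rate: float = 0.0
    missing_rate: float = 0.01
    qc_spike: QCSpike | None = None
    populations: tuple[tuple[str, int], ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("het_error_rate", "missing_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} outside [0, 1]")
        if self.tract_min_mb > self.tract_mean_mb:
            raise ValueError("tract_min_mb exceeds tract_mean_mb")
        if self.populations is not None and sum(
            n for _, n in self.populations
        ) != self.n_individuals:
            raise ValueError("population sizes do not sum to n_individuals")
        for isl in self.planted_islands:
            length, _ = self.chromosomes[isl.chromosome - 1]
            if isl.end_bp > length:
                raise ValueError("planted island outside chromosome bounds")

    @property
    def total_bp(self) -> int:
        return sum(length for length, _ in self.chromosomes)


def target_tract_rate(config: SimConfig, target_f: float) -> float:
    """Poisson tract rate giving an expected autozygous fraction target_f."""
    return target_f * config.total_bp / (config.tract_mean_mb * 1e6)


def chip_scale_config(seed: int = 0) -> SimConfig:
    """A chip-scale preset: 26 autosomes x 1775 SNPs (~46k markers) and
    281 individuals in three cohorts of 95/115/71 — the shape of a real
    ovine 50K study, at ~90 Mb per synthetic chromosome."""
    return SimConfig(
        n_individuals=281,
        chromosomes=((90_000_000, 1775),) * 26,
        populations=(("POP1", 95), ("POP2", 115), ("POP3", 71)),
        seed=seed,
    )


@dataclass
class TruthRecord:
    """Ground truth for one simulated individual."""

    individual_id: str
    tracts: list[tuple[int, int, int]]  # (chromosome, start_bp, end_bp)
    true_f: float


@dataclass
class SimTruth:
    """Ground truth for a whole simulated population."""

    individuals: list[TruthRecord]
    island_carriers: dict[int, list[str]]  # island index -> carrier IDs
    spiked_low_call_snps: list[str] = field(default_factory=list)
    spiked_low_maf_snps: list[str] = field(default_factory=list)
    spiked_hwe_snps: list[str] = field(default_factory=list)
    spiked_high_missing_individuals: list[str] = field(default_factory=list)

    def write_tsv(self, tract_path: str | Path, summary_path: str | Path) -> None:
        with Path(tract_path).open("w") as fh:
            fh.write("IID\tCHR\tTRACT_START_BP\tTRACT_END_BP\n")
            for rec in self.individuals:
                for chrom, a, b in rec.tracts:
                    fh.write(f"{rec.individual_id}\t{chrom}\t{a}\t{b}\n")
        with Path(summary_path).open("w") as fh:
            fh.write("IID\tTRUE_F\n")
            for rec in self.individuals:
                fh.write(f"{rec.individual_id}\t{rec.true_f:.6f}\n")


def simulate_map(config: SimConfig, rng: np.random.Generator) -> list[SNPRecord]:
    """Per chromosome, n_snps unique positions uniform in [1, length_bp]."""
    records: list[SNPRecord] = []
    for c, (length_bp, n_snps) in enumerate(config.chromosomes, start=1):
        if n_snps > length_bp:
            raise ValueError(
                f"chromosome {c}: {n_snps} SNPs do not fit in {length_bp} bp"
            )
        positions = rng.choice(length_bp, size=n_snps, replace=False) + 1
        positions.sort()
        records.extend(
            SNPRecord(c, f"snp{c}_{i}", 0.0, int(p))
            for i, p in enumerate(positions)
        )
    return records


def sample_tracts(
    config: SimConfig,
    individual_index: int,
    rng: np.random.Generator,
    *,
    island_carrier: Sequence[bool] = (),
) -> list[tuple[int, int, int]]:
    """Autozygous tracts for one individual: planted islands first, then
    Poisson-many random tracts, placed uniformly without overlap
    (rejection sampling, capped retries).

    Tract lengths are ``min_mb + Exp(mean_mb - min_mb)``; random tracts
    land on a chromosome with probability proportional to its length.
    """
    tracts: list[tuple[int, int, int]] = []
    for carrier, isl in zip(island_carrier, config.planted_islands):
        if carrier:
            tracts.append((isl.chromosome, isl.start_bp, isl.end_bp))
    n_random = int(rng.poisson(config.tracts_per_individual))
    lengths_bp = np.array([length for length, _ in config.chromosomes], dtype=float)
    chrom_p = lengths_bp / lengths_bp.sum()
    scale_bp = (config.tract_mean_mb - config.tract_min_mb) * 1e6
    min_bp = config.tract_min_mb * 1e6
    for _ in range(n_random):
        placed = False
        for _attempt in range(_TRACT_RETRY_CAP):
            chrom = int(rng.choice(len(lengths_bp), p=chrom_p)) + 1
            tract_len = int(min_bp + (rng.exponential(scale_bp) if scale_bp > 0 else 0))
            chrom_len = int(lengths_bp[chrom - 1])
            if tract_len >= chrom_len:
                continue
            start = int(rng.integers(1, chrom_len - tract_len + 1))
            end = start + tract_len - 1
            if all(
                c != chrom or end < a or start > b for c, a, b in tracts
            ):
                tracts.append((chrom, start, end))
                placed = True
                break
        if not placed:
            raise RuntimeError(
                "could not place a non-overlapping tract after "
                f"{_TRACT_RETRY_CAP} retries; reduce tracts_per_individual "
                "or tract lengths"
            )
    return sorted(tracts)


def simulate_genotypes(
    snps: Sequence[SNPRecord],
    freqs: np.ndarray,
    tracts: Sequence[tuple[int, int, int]],
    config: SimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """One individual's call vector.

    Outside tracts genotypes follow Hardy-Weinberg proportions for the
    SNP's ALT frequency; inside tracts a single allele is drawn by
    frequency and the genotype forced homozygous for it.  Heterozygous
    genotyping error is then applied inside tracts, and missingness
    everywhere.
    """
    freqs = np.asarray(freqs, dtype=float)
    if ((freqs <= 0) | (freqs >= 1)).any():
        raise ValueError("allele frequencies must lie strictly in (0, 1)")
    n = len(snps)
    a1 = rng.random(n) < freqs
    a2 = rng.random(n) < freqs
    calls = (a1.astype(np.int8) + a2.astype(np.int8)).astype(np.int8)

    chroms = np.array([s.chromosome for s in snps])
    positions = np.array([s.position_bp for s in snps], dtype=np.int64)
    in_tract = np.zeros(n, dtype=bool)
    for chrom, start, end in tracts:
        in_tract |= (chroms == chrom) & (positions >= start) & (positions <= end)
    if in_tract.any():
        allele = rng.random(n) < freqs  # one IBD allele per site
        calls[in_tract] = np.where(allele[in_tract], HOM_ALT, HOM_REF)
        if config.het_error_rate > 0:
            err = in_tract & (rng.random(n) < config.het_error_rate)
            calls[err] = HET
    if config.missing_rate > 0:
        calls[rng.random(n) < config.missing_rate] = MISSING
    return calls


def _population_labels(config: SimConfig) -> list[str]:
    if config.populations is None:
        return ["POP1"] * config.n_individuals
    labels: list[str] = []
    for name, count in config.populations:
        labels.extend([name] * count)
    return labels


def simulate_population(
    config: SimConfig,
    out_dir: str | Path | None = None,
) -> tuple[GenotypeDataset, SimTruth]:
    """Simulate a full population; optionally write PED/MAP/truth files.

    Deterministic for a fixed ``config.seed``.  When ``out_dir`` is
    given, writes ``sim.ped``, ``sim.map``, ``truth_tracts.tsv`` and
    ``truth_summary.tsv`` there.
    """
    rng = np.random.default_rng(config.seed)
    snps = simulate_map(config, rng)
    lo, hi = config.freq_range
    freqs = rng.uniform(lo, hi, size=len(snps))

    labels = _population_labels(config)
    samples = [
        SampleRecord(labels[i], f"ind{i:04d}", "0", "0", 1 + i % 2, "-9", labels[i])
        for i in range(config.n_individuals)
    ]

    carriers = np.zeros((config.n_individuals, len(config.planted_islands)), dtype=bool)
    island_carriers: dict[int, list[str]] = {}
    for j, isl in enumerate(config.planted_islands):
        n_carriers = int(round(isl.carrier_fraction * config.n_individuals))
        chosen = rng.choice(config.n_individuals, size=n_carriers, replace=False)
        carriers[chosen, j] = True
        island_carriers[j] = [samples[i].individual_id for i in sorted(chosen)]

    calls = np.zeros((config.n_individuals, len(snps)), dtype=np.int8)
    truth_individuals: list[TruthRecord] = []
    total_bp = config.total_bp
    for i in range(config.n_individuals):
        tracts = sample_tracts(config, i, rng, island_carrier=carriers[i])
        calls[i] = simulate_genotypes(snps, freqs, tracts, config, rng)
        tract_bp = sum(b - a + 1 for _, a, b in tracts)
        truth_individuals.append(
            TruthRecord(samples[i].individual_id, tracts, tract_bp / total_bp)
        )
    truth = SimTruth(truth_individuals, island_carriers)

    if config.qc_spike is not None:
        _inject_qc_spikes(calls, snps, samples, config, truth, rng)

    dataset = GenotypeDataset(samples, snps, calls)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_ped_map(dataset, out_dir / "sim.ped", out_dir / "sim.map")
        truth.write_tsv(out_dir / "truth_tracts.tsv", out_dir / "truth_summary.tsv")
    return dataset, truth


def _inject_qc_spikes(
    calls: np.ndarray,
    snps: Sequence[SNPRecord],
    samples: Sequence[SampleRecord],
    config: SimConfig,
    truth: SimTruth,
    rng: np.random.Generator,
) -> None:
    """Plant one unambiguous failure of each configured kind.

    Spiked SNPs are distinct; spiked individuals are distinct.  Low call
    rate: ``missing_fraction`` of calls blanked.  Low MAF: column forced
    monomorphic HOM_REF.  HWE: column forced all-HET (MAF 0.5, call rate
    1, wildly out of equilibrium for any reasonable n).  High-missing
    individual: ``missing_fraction`` of the row blanked.
    """
    spike = config.qc_spike
    assert spike is not None
    n_ind, n_snps = calls.shape
    n_spiked = spike.n_low_call_snps + spike.n_low_maf_snps + spike.n_hwe_snps
    if n_spiked > n_snps:
        raise ValueError("more spiked SNPs than SNPs in the map")
    if spike.n_high_missing_individuals > n_ind:
        raise ValueError("more spiked individuals than individuals")
    snp_idx = rng.choice(n_snps, size=n_spiked, replace=False)
    cursor = 0

    for j in snp_idx[cursor : cursor + spike.n_low_call_snps]:
        blank = rng.random(n_ind) < spike.missing_fraction
        # guarantee the planted column actually dips below any sane
        # call-rate threshold even after individual-level removals
        blank[: max(1, int(math.ceil(spike.missing_fraction * n_ind)))] = True
        calls[blank, j] = MISSING
        truth.spiked_low_call_snps.append(snps[j].snp_id)
    cursor += spike.n_low_call_snps

    for j in snp_idx[cursor : cursor + spike.n_low_maf_snps]:
        calls[:, j] = HOM_REF
        truth.spiked_low_maf_snps.append(snps[j].snp_id)
    cursor += spike.n_low_maf_snps

    for j in snp_idx[cursor : cursor + spike.n_hwe_snps]:
        calls[:, j] = HET
        truth.spiked_hwe_snps.append(snps[j].snp_id)

    ind_idx = rng.choice(n_ind, size=spike.n_high_missing_individuals, replace=False)
    for i in ind_idx:
        blank = rng.random(n_snps) < spike.missing_fraction
        blank[: max(1, int(math.ceil(spike.missing_fraction * n_snps)))] = True
        calls[i, blank] = MISSING
        truth.spiked_high_missing_individuals.append(samples[i].individual_id)


__all__ = [
    "PlantedIsland",
    "QCSpike",
    "SimConfig",
    "TruthRecord",
    "SimTruth",
    "target_tract_rate",
    "chip_scale_config",
    "simulate_map",
    "sample_tracts",
    "simulate_genotypes",
    "simulate_population",
]
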