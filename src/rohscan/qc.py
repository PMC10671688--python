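"""Marker and sample quality control for SNP-array genotypes.

Filters and their defaults follow standard chip QC practice: restrict to
autosomes, drop individuals with >10% missing genotypes, drop SNPs with
call rate <90%, minor allele frequency <0.05, or an exact
Hardy-Weinberg-equilibrium p-value <1e-4.  Boundary semantics are strict:
values exactly at a threshold are retained.  Filters are applied in a
fixed order (autosomes, individuals, call rate, MAF, HWE), each computed
on the data surviving the previous steps; sample filters run before the
SNP frequency filters because missing individuals distort MAF and HWE.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np

from .model import GenotypeDataset, HET, HOM_ALT, HOM_REF, MISSING

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class QCConfig:
    autosome_max: int = 26
    max_individual_missing: float = 0.10
    min_snp_call_rate: float = 0.90
    min_maf: float = 0.05
    hwe_alpha: float = 0.0001
    hwe_midp: bool = False

    def __post_init__(self) -> None:
        for name in ("max_individual_missing", "min_snp_call_rate", "min_maf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0.0 <= self.hwe_alpha <= 1.0:
            raise ValueError(f"hwe_alpha={self.hwe_alpha} outside [0, 1]")


@dataclass
class QCReport:
    """What each filter removed, in application order."""

    n_input_snps: int = 0
    n_input_individuals: int = 0
    removed_non_autosomal: list[str] = field(default_factory=list)
    removed_high_missing_individuals: list[str] = field(default_factory=list)
    removed_low_call_rate: list[str] = field(default_factory=list)
    removed_low_maf: list[str] = field(default_factory=list)
    removed_hwe: list[str] = field(default_factory=list)
    n_retained_snps: int = 0
    n_retained_individuals: int = 0

    @property
    def n_removed_snps(self) -> int:
        return (
            len(self.removed_non_autosomal)
            + len(self.removed_low_call_rate)
            + len(self.removed_low_maf)
            + len(self.removed_hwe)
        )

    def check_reconciles(self) -> None:
        assert self.n_retained_snps + self.n_removed_snps == self.n_input_snps
        assert (
            self.n_retained_individuals
            + len(self.removed_high_missing_individuals)
            == self.n_input_individuals
        )

    def rows(self) -> list[tuple[str, int, str]]:
        return [
            ("non_autosomal_snps", len(self.removed_non_autosomal),
             ";".join(self.removed_non_autosomal)),
            ("high_missing_individuals", len(self.removed_high_missing_individuals),
             ";".join(self.removed_high_missing_individuals)),
            ("low_call_rate_snps", len(self.removed_low_call_rate),
             ";".join(self.removed_low_call_rate)),
            ("low_maf_snps", len(self.removed_low_maf),
             ";".join(self.removed_low_maf)),
            ("hwe_failing_snps", len(self.removed_hwe),
             ";".join(self.removed_hwe)),
        ]

    def write_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("filter\tn_removed\tids\n")
            for name, n, ids in self.rows():
                fh.write(f"{name}\t{n}\t{ids}\n")
            fh.write(f"retained_snps\t{self.n_retained_snps}\t\n")
            fh.write(f"retained_individuals\t{self.n_retained_individuals}\t\n")


class QCEmptyError(RuntimeError):
    """No SNPs or no individuals survived QC; carries the partial report."""

    def __init__(self, message: str, report: QCReport):
        super().__init__(message)
        self.report = report


# --------------------------------------------------------------------------
# elementary statistics
# --------------------------------------------------------------------------

def snp_call_rate(column: np.ndarray) -> float:
    """Fraction of non-missing calls in one SNP column."""
    column = np.asarray(column)
    if column.size == 0:
        raise ValueError("empty SNP column")
    return float(np.count_nonzero(column != MISSING) / column.size)


def individual_missingness(row: np.ndarray) -> float:
    """Fraction of missing calls in one individual's row."""
    row = np.asarray(row)
    if row.size == 0:
        raise ValueError("empty sample row")
    return float(np.count_nonzero(row == MISSING) / row.size)


def minor_allele_freq(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """MAF from genotype counts (missing calls excluded by the caller)."""
    total = n_hom_ref + n_het + n_hom_alt
    if total < 1:
        raise ValueError("MAF undefined for an all-missing SNP")
    p = (2 * n_hom_ref + n_het) / (2 * total)
    return min(p, 1.0 - p)


# --------------------------------------------------------------------------
# exact Hardy-Weinberg test
# --------------------------------------------------------------------------

# Relative tolerance when comparing outcome probabilities for the two-sided
# tail: outcomes exactly tied in exact arithmetic (symmetric distributions)
# must land on the same side despite float rounding.
_TIE_RTOL = 1e-12


@lru_cache(maxsize=None)
def _het_distribution(n: int, n_rare: int) -> np.ndarray:
    """P(het count) given n diploids and n_rare copies of the rarer allele.

    Support is ``h = n_rare % 2, n_rare % 2 + 2, ..., n_rare``.  Computed
    by the standard stable two-directional recurrence from the modal
    heterozygote count (no large factorials).
    """
    h_min = n_rare % 2
    size = n_rare // 2 + 1
    probs = np.zeros(size)
    # modal het count under the conditional distribution
    mode = int(round(n_rare * (2 * n - n_rare) / (2.0 * n)))
    if (mode - h_min) % 2:
        mode += 1
    mode = min(max(mode, h_min), n_rare - (n_rare - h_min) % 2)
    mi = (mode - h_min) // 2
    probs[mi] = 1.0
    # downward: P(h-2) = P(h) * h(h-1) / (4 (r+1)(c+1)) with r,c at h-2
    for i in range(mi, 0, -1):
        h = h_min + 2 * i
        r = (n_rare - h) // 2
        c = n - h - r
        probs[i - 1] = probs[i] * h * (h - 1) / (4.0 * (r + 1) * (c + 1))
    # upward: P(h+2) = P(h) * 4 r c / ((h+2)(h+1))
    for i in range(mi, size - 1):
        h = h_min + 2 * i
        r = (n_rare - h) // 2
        c = n - h - r
        probs[i + 1] = probs[i] * 4.0 * r * c / ((h + 2.0) * (h + 1.0))
    probs /= probs.sum()
    return probs


def hwe_exact_pvalue(
    n_hom_ref: int, n_het: int, n_hom_alt: int, *, midp: bool = False
) -> float:
    """Two-sided exact Hardy-Weinberg p-value from genotype counts.

    Sums the conditional probabilities (given allele counts and sample
    size) of every heterozygote count at most as probable as the observed
    one.  With ``midp`` only half the observed outcome's probability is
    counted.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("negative genotype count")
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise ValueError("empty genotype counts")
    n_rare = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)
    probs = _het_distribution(n, n_rare)
    idx = (n_het - (n_rare % 2)) // 2
    p_obs = probs[idx]
    tail = float(probs[probs <= p_obs * (1.0 + _TIE_RTOL)].sum())
    if midp:
        tail -= 0.5 * float(p_obs)
    return min(tail, 1.0)


# --------------------------------------------------------------------------
# full QC pass
# --------------------------------------------------------------------------

def filter_autosomes(
    dataset: GenotypeDataset, autosome_max: int = 26
) -> GenotypeDataset:
    """Keep SNPs with 1 <= chromosome <= autosome_max, preserving order."""
    chroms = dataset.chromosomes()
    keep = np.flatnonzero((chroms >= 1) & (chroms <= autosome_max))
    if keep.size == 0:
        log.warning("no autosomal SNPs retained")
    return dataset.subset(snp_idx=keep)


def _genotype_counts(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    return (
        (calls == HOM_REF).sum(axis=0),
        (calls == HET).sum(axis=0),
        (calls == HOM_ALT).sum(axis=0),
    )


def apply_qc(
    dataset: GenotypeDataset, config: QCConfig | None = None
) -> tuple[GenotypeDataset, QCReport]:
    """Run the full QC cascade and report what each step removed.

    Raises :class:`QCEmptyError` (report attached) if nothing survives on
    either axis.
    """
    config = config or QCConfig()
    report = QCReport(
        n_input_snps=dataset.n_snps, n_input_individuals=dataset.n_samples
    )

    # (1) autosome restriction
    chroms = dataset.chromosomes()
    auto = (chroms >= 1) & (chroms <= config.autosome_max)
    report.removed_non_autosomal = [
        s.snp_id for s, a in zip(dataset.snps, auto) if not a
    ]
    ds = dataset.subset(snp_idx=np.flatnonzero(auto))
    if ds.n_snps == 0:
        report.n_retained_individuals = ds.n_samples
        raise QCEmptyError("no autosomal SNPs survive QC", report)

    # (2) individual missingness (strict >)
    miss_frac = (ds.calls == MISSING).mean(axis=1) if ds.n_samples else np.zeros(0)
    keep_ind = miss_frac <= config.max_individual_missing
    report.removed_high_missing_individuals = [
        s.individual_id for s, k in zip(ds.samples, keep_ind) if not k
    ]
    ds = ds.subset(sample_idx=np.flatnonzero(keep_ind))
    if ds.n_samples == 0:
        report.n_retained_snps = ds.n_snps
        raise QCEmptyError("no individuals survive QC", report)

    # (3) SNP call rate (strict <)
    call_rate = (ds.calls != MISSING).mean(axis=0)
    keep = call_rate >= config.min_snp_call_rate
    report.removed_low_call_rate = [
        s.snp_id for s, k in zip(ds.snps, keep) if not k
    ]
    ds = ds.subset(snp_idx=np.flatnonzero(keep))

    # (4) MAF on non-missing calls (strict <)
    if ds.n_snps:
        nrr, nht, naa = _genotype_counts(ds.calls)
        totals = nrr + nht + naa
        if (totals == 0).any():
            raise QCEmptyError(
                "all-missing SNP reached the MAF filter "
                "(set min_snp_call_rate > 0)", report
            )
        p = (2 * nrr + nht) / (2.0 * totals)
        maf = np.minimum(p, 1.0 - p)
        keep = maf >= config.min_maf
        report.removed_low_maf = [s.snp_id for s, k in zip(ds.snps, keep) if not k]
        ds = ds.subset(snp_idx=np.flatnonzero(keep))

    # (5) exact HWE (strict <)
    if ds.n_snps:
        nrr, nht, naa = _genotype_counts(ds.calls)
        pvals = np.array(
            [
                hwe_exact_pvalue(int(a), int(b), int(c), midp=config.hwe_midp)
                for a, b, c in zip(nrr, nht, naa)
            ]
        )
        keep = pvals >= config.hwe_alpha
        report.removed_hwe = [s.snp_id for s, k in zip(ds.snps, keep) if not k]
        ds = ds.subset(snp_idx=np.flatnonzero(keep))

    report.n_retained_snps = ds.n_snps
    report.n_retained_individuals = ds.n_samples
    report.check_reconciles()
    if ds.n_snps == 0:
        raise QCEmptyError("no SNPs survive QC", report)
    log.info(
        "QC: %d/%d SNPs, %d/%d individuals retained",
        ds.n_snps, report.n_input_snps, ds.n_samples, report.n_input_individuals,
    )
    return ds, report


__all__ = [
    "QCConfig",
    "QCReport",
    "QCEmptyError",
    "snp_call_rate",
    "individual_missingness",
    "minor_allele_freq",
    "hwe_exact_pvalue",
    "filter_autosomes",
    "apply_qc",
]
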