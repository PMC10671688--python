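"""Sliding-window detection of runs of homozygosity (ROH).

The scan is the PLINK-style heuristic: fixed-size SNP windows tolerant of
a small number of heterozygous and missing calls slide along each
chromosome; every SNP is scored by the fraction of overlapping windows
that look homozygous; supported stretches of homozygous calls become
candidate segments, which must then clear minimum-SNP, minimum-length,
density and maximum-gap constraints.

Contract details that tools disagree on are pinned down here and exposed
as parameters:

* ``het_terminates=True`` (default): a heterozygous call always ends a
  candidate run, even when window support would bridge it.  With
  ``False`` (the lenient, window-smoothed alternative) heterozygous calls
  may sit inside a run.
* Missing calls may sit inside a run; neither missing nor (in lenient
  mode) heterozygous calls count toward ``n_snps``.
* Runs are split wherever two consecutive in-run SNPs are more than
  ``max_gap_kb`` apart, then trimmed so both endpoints are homozygous
  calls; segment length is last minus first SNP position + 1.
* Density is segment-level: ``length_bp / n_snps <= max_density_kb_per_snp``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .model import GenotypeDataset, HET, HOM_ALT, HOM_REF, MISSING

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ROHParams:
    """Scan parameters (defaults: 15-SNP window, 1 het + 1 missing allowed,
    0.05 support threshold, 1 Mb / 15 SNP minimum, 1 SNP per 100 kb,
    250 kb maximum gap)."""

    window_snps: int = 15
    window_max_missing: int = 1
    window_max_het: int = 1
    window_threshold: float = 0.05
    min_snps: int = 15
    min_length_kb: float = 1000.0
    max_density_kb_per_snp: float = 100.0
    max_gap_kb: float = 250.0
    het_terminates: bool = True

    def __post_init__(self) -> None:
        if self.window_snps < 1:
            raise ValueError("window_snps must be >= 1")
        for name in ("window_threshold", "min_length_kb",
                     "max_density_kb_per_snp", "max_gap_kb"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class ROHSegment:
    """One homozygous run: the pipeline's atomic result.

    ``start_bp``/``end_bp`` are the 1-based positions of the first and
    last homozygous SNP of the run; ``n_snps`` counts homozygous calls.
    """

    family_id: str
    individual_id: str
    chromosome: int
    start_bp: int
    end_bp: int
    n_snps: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    @property
    def length_mb(self) -> float:
        return self.length_bp / 1e6


def window_flags(calls: np.ndarray, params: ROHParams) -> np.ndarray:
    """Boolean per sliding window: homozygous-looking or not.

    A window of ``window_snps`` consecutive calls is TRUE iff it contains
    at most ``window_max_het`` heterozygous and ``window_max_missing``
    missing calls.  A chromosome shorter than one window yields zero
    windows.
    """
    calls = np.asarray(calls)
    n = calls.size
    k = params.window_snps
    if n < k:
        return np.zeros(0, dtype=bool)
    het = np.concatenate([[0], np.cumsum(calls == HET)])
    mis = np.concatenate([[0], np.cumsum(calls == MISSING)])
    n_het = het[k:] - het[:-k]
    n_mis = mis[k:] - mis[:-k]
    return (n_het <= params.window_max_het) & (n_mis <= params.window_max_missing)


def snp_support(
    flags: np.ndarray, n_snps_on_chrom: int, params: ROHParams
) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP window support: (proportion, flagged).

    A SNP's proportion is the fraction of windows physically containing
    it that are TRUE; near chromosome ends fewer windows fit and the
    denominator shrinks.  Flagged iff proportion >= ``window_threshold``.
    """
    k = params.window_snps
    n_win = flags.size
    if n_win == 0:
        log.warning("chromosome shorter than one window: no SNP flagged")
        return np.zeros(n_snps_on_chrom), np.zeros(n_snps_on_chrom, dtype=bool)
    cum = np.concatenate([[0], np.cumsum(flags)])
    idx = np.arange(n_snps_on_chrom)
    lo = np.maximum(0, idx - k + 1)
    hi = np.minimum(n_win - 1, idx)
    denom = hi - lo + 1
    num = cum[hi + 1] - cum[lo]
    prop = num / denom
    return prop, prop >= params.window_threshold


def _true_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, end] index stretches of True."""
    if mask.size == 0:
        return []
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1) - 1
    return list(zip(starts.tolist(), ends.tolist()))


def call_segments(
    flagged: np.ndarray,
    calls: np.ndarray,
    positions: np.ndarray,
    params: ROHParams,
    *,
    family_id: str = "0",
    individual_id: str = "0",
    chromosome: int = 0,
) -> list[ROHSegment]:
    """Turn per-SNP support flags into filtered ROH segments.

    Candidate runs are maximal stretches of consecutive flagged SNPs
    whose own call does not terminate a run (heterozygous calls terminate
    unless ``het_terminates=False``), split at inter-SNP gaps over
    ``max_gap_kb`` and trimmed to homozygous endpoints; survivors must
    meet ``min_snps`` (homozygous calls), ``min_length_kb`` and the
    density ceiling.  Returned sorted by start position.
    """
    flagged = np.asarray(flagged, dtype=bool)
    calls = np.asarray(calls)
    positions = np.asarray(positions, dtype=np.int64)
    in_run = flagged & (calls != HET) if params.het_terminates else flagged.copy()
    hom = (calls == HOM_REF) | (calls == HOM_ALT)
    gap_bp = params.max_gap_kb * 1000.0
    min_len_bp = params.min_length_kb * 1000.0
    max_density_bp = params.max_density_kb_per_snp * 1000.0

    segments: list[ROHSegment] = []
    for run_start, run_end in _true_runs(in_run):
        # split at oversized gaps between consecutive in-run SNPs
        piece_start = run_start
        boundaries: list[tuple[int, int]] = []
        for k in range(run_start, run_end):
            if positions[k + 1] - positions[k] > gap_bp:
                boundaries.append((piece_start, k))
                piece_start = k + 1
        boundaries.append((piece_start, run_end))
        for a, b in boundaries:
            hom_idx = np.flatnonzero(hom[a : b + 1])
            if hom_idx.size == 0:
                continue
            a2 = a + int(hom_idx[0])
            b2 = a + int(hom_idx[-1])
            n_hom = int(hom_idx.size)
            length = int(positions[b2] - positions[a2] + 1)
            if n_hom < params.min_snps:
                continue
            if length < min_len_bp:
                continue
            if length / n_hom > max_density_bp:
                continue
            segments.append(
                ROHSegment(
                    family_id, individual_id, chromosome,
                    int(positions[a2]), int(positions[b2]), n_hom,
                )
            )
    segments.sort(key=lambda s: s.start_bp)
    return segments


def detect_roh(dataset: GenotypeDataset, params: ROHParams | None = None) -> list[ROHSegment]:
    """Scan every (individual, chromosome) of a post-QC dataset.

    Deterministic given its inputs; segments are ordered by individual
    (roster order), then chromosome, then start position.
    """
    params = params or ROHParams()
    slices = dataset.chromosome_slices()
    positions = dataset.positions()
    out: list[ROHSegment] = []
    for i, sample in enumerate(dataset.samples):
        row = dataset.calls[i]
        for chrom, sl in slices.items():
            calls = row[sl]
            flags = window_flags(calls, params)
            _, flagged = snp_support(flags, calls.size, params)
            out.extend(
                call_segments(
                    flagged, calls, positions[sl], params,
                    family_id=sample.family_id,
                    individual_id=sample.individual_id,
                    chromosome=chrom,
                )
            )
    return out


__all__ = ["ROHParams", "ROHSegment", "window_flags", "snp_support",
           "call_segments", "detect_roh"]
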