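"""ROH-island detection: per-SNP occurrence, top-1% selection, annotation.

An ROH island is a region where runs of homozygosity pile up across many
individuals — a candidate selection signature.  The per-SNP statistic is
the percentage of individuals whose ROHs cover the SNP's position; SNPs
in the top 1% of occurrence are selected (ties at the cutoff included)
and merged into islands, which are then annotated against a
user-supplied gene-interval file.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from intervaltree import IntervalTree

from .detect import ROHSegment
from .model import GeneInterval, SNPRecord

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class OccurrenceProfile:
    """Per-SNP ROH coverage, aligned with the (post-QC) SNP map."""

    snps: tuple[SNPRecord, ...]
    counts: np.ndarray  # individuals covering each SNP
    n_individuals: int

    @property
    def percent(self) -> np.ndarray:
        if self.n_individuals == 0:
            return np.zeros(len(self.snps))
        return 100.0 * self.counts / self.n_individuals


@dataclass(frozen=True)
class Island:
    """One merged top-occurrence region (coordinates of the first/last
    selected SNP; Mb values rounded to 2 decimals in reports)."""

    chromosome: int
    start_bp: int
    end_bp: int
    n_snp: int
    genes: tuple[str, ...] = field(default_factory=tuple)

    @property
    def start_mb(self) -> float:
        return round(self.start_bp / 1e6, 2)

    @property
    def end_mb(self) -> float:
        return round(self.end_bp / 1e6, 2)


def snp_occurrence(
    segments: Sequence[ROHSegment],
    snps: Sequence[SNPRecord],
    n_individuals: int,
) -> OccurrenceProfile:
    """Count, per SNP, the individuals with an ROH covering its position.

    An individual contributes at most 1 per SNP however many of its
    segments overlap it.
    """
    snps = tuple(snps)
    chroms = np.array([s.chromosome for s in snps])
    positions = np.array([s.position_bp for s in snps], dtype=np.int64)
    chrom_index: dict[int, tuple[int, np.ndarray]] = {}
    for c in np.unique(chroms):
        idx = np.flatnonzero(chroms == c)
        chrom_index[int(c)] = (int(idx[0]), positions[idx])

    covered_by_iid: dict[str, np.ndarray] = {}
    for seg in segments:
        if seg.chromosome not in chrom_index:
            raise ValueError(
                f"segment chromosome {seg.chromosome} absent from map"
            )
        offset, pos = chrom_index[seg.chromosome]
        lo = int(np.searchsorted(pos, seg.start_bp, side="left"))
        hi = int(np.searchsorted(pos, seg.end_bp, side="right"))
        mask = covered_by_iid.setdefault(
            seg.individual_id, np.zeros(len(snps), dtype=bool)
        )
        mask[offset + lo : offset + hi] = True

    counts = np.zeros(len(snps), dtype=np.int64)
    for mask in covered_by_iid.values():
        counts += mask
    return OccurrenceProfile(snps, counts, n_individuals)


def select_top_percent(
    profile: OccurrenceProfile, pct: float = 1.0
) -> tuple[np.ndarray, float]:
    """Select the top ``pct`` percent of SNPs by occurrence.

    Returns (boolean selection mask, numeric cutoff used).  The cutoff is
    the k-th largest occurrence with ``k = ceil(pct/100 * n_snps)``; all
    SNPs tied at the cutoff are included.  Zero-occurrence SNPs are never
    selected (an all-zero profile yields an empty selection).
    """
    counts = profile.counts
    n = counts.size
    if n == 0:
        raise ValueError("empty occurrence profile")
    if counts.max() == 0:
        log.warning("all-zero occurrence profile: empty selection")
        return np.zeros(n, dtype=bool), 0.0
    k = max(1, math.ceil(pct / 100.0 * n))
    cutoff = float(np.partition(counts, n - k)[n - k])
    if cutoff == 0:
        log.warning(
            "top-%.3g%% cutoff fell on zero occurrence; selecting only "
            "SNPs with positive occurrence", pct,
        )
        selected = counts > 0
    else:
        selected = counts >= cutoff
    return selected, cutoff


def build_islands(
    selected: np.ndarray,
    snps: Sequence[SNPRecord],
    max_island_gap_kb: float = 1000.0,
    min_island_snps: int = 3,
) -> list[Island]:
    """Merge selected SNPs into islands.

    Consecutive selected SNPs on one chromosome join the same island when
    separated by at most ``max_island_gap_kb``; islands carrying fewer
    than ``min_island_snps`` selected SNPs are dropped.
    """
    selected = np.asarray(selected, dtype=bool)
    if selected.size != len(snps):
        raise ValueError("selection mask does not match map length")
    gap_bp = max_island_gap_kb * 1000.0
    islands: list[Island] = []
    current: list[SNPRecord] = []

    def flush() -> None:
        if len(current) >= min_island_snps:
            islands.append(
                Island(
                    current[0].chromosome,
                    current[0].position_bp,
                    current[-1].position_bp,
                    len(current),
                )
            )
        current.clear()

    for snp, sel in zip(snps, selected):
        if not sel:
            continue
        if current and (
            snp.chromosome != current[-1].chromosome
            or snp.position_bp - current[-1].position_bp > gap_bp
        ):
            flush()
        current.append(snp)
    flush()
    return islands


def annotate_islands(
    islands: Sequence[Island], gene_intervals: Sequence[GeneInterval]
) -> list[Island]:
    """Attach every gene whose interval overlaps an island by >= 1 bp.

    Genes are listed in start-position order.
    """
    trees: dict[int, IntervalTree] = {}
    for g in gene_intervals:
        # IntervalTree is half-open; +1 makes the closed end inclusive.
        trees.setdefault(g.chromosome, IntervalTree()).addi(
            g.start_bp, g.end_bp + 1, g
        )
    out: list[Island] = []
    for isl in islands:
        tree = trees.get(isl.chromosome)
        hits: list[GeneInterval] = (
            sorted(
                (iv.data for iv in tree.overlap(isl.start_bp, isl.end_bp + 1)),
                key=lambda g: (g.start_bp, g.end_bp, g.gene_name),
            )
            if tree is not None
            else []
        )
        out.append(replace(isl, genes=tuple(g.gene_name for g in hits)))
    return out


def write_island_tsv(islands: Sequence[Island], path: str | Path) -> None:
    """Island report: CHR, N_SNP, START_MB, END_MB, GENES (semicolon-joined)."""
    with Path(path).open("w") as fh:
        fh.write("CHR\tN_SNP\tSTART_MB\tEND_MB\tGENES\n")
        for isl in islands:
            fh.write(
                f"{isl.chromosome}\t{isl.n_snp}\t{isl.start_mb:.2f}\t"
                f"{isl.end_mb:.2f}\t{';'.join(isl.genes)}\n"
            )


def occurrence_plot(
    profile: OccurrenceProfile,
    selected: np.ndarray | None,
    path: str | Path,
    cutoff_percent: float | None = None,
) -> Path:
    """Manhattan-style plot of occurrence % along the genome.

    Chromosomes are alternately coloured on a cumulative bp axis;
    selected SNPs are highlighted and the cutoff drawn as a horizontal
    line.  Returns the written path.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = np.array([s.chromosome for s in profile.snps])
    positions = np.array([s.position_bp for s in profile.snps], dtype=np.float64)
    x = np.zeros_like(positions)
    offset = 0.0
    ticks, tick_labels = [], []
    fig, ax = plt.subplots(figsize=(10, 3.5))
    palette = ("#4C72B0", "#AAB4C4")
    for i, c in enumerate(np.unique(chroms)):
        m = chroms == c
        x[m] = positions[m] + offset
        ax.scatter(
            x[m] / 1e6, profile.percent[m], s=4,
            color=palette[i % 2], linewidths=0,
        )
        ticks.append((offset + positions[m].mean()) / 1e6)
        tick_labels.append(str(int(c)))
        offset += positions[m].max() if m.any() else 0.0
    if selected is not None and np.asarray(selected).any():
        sel = np.asarray(selected, dtype=bool)
        ax.scatter(x[sel] / 1e6, profile.percent[sel], s=8, color="#C44E52",
                   linewidths=0, label="top SNPs")
        ax.legend(frameon=False, loc="upper right")
    if cutoff_percent is not None:
        ax.axhline(cutoff_percent, color="#C44E52", lw=0.8, ls="--")
    ax.set_xticks(ticks, tick_labels)
    ax.set_xlabel("chromosome")
    ax.set_ylabel("SNP occurrence in ROHs (%)")
    ax.set_ylim(bottom=0)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


__all__ = [
    "OccurrenceProfile",
    "Island",
    "snp_occurrence",
    "select_top_percent",
    "build_islands",
    "annotate_islands",
    "annotate",
    "write_island_tsv",
    "occurrence_plot",
]

# short alias used by the CLI layer
annotate = annotate_islands
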