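"""In-memory data model shared by every pipeline stage.

Genotype calls are stored as a dense ``numpy`` int8 matrix of shape
``(n_samples, n_snps)`` using the call codes below.  Only the
homozygous/heterozygous/missing state matters downstream, so the REF/ALT
orientation is a deterministic convention (lexicographically smaller
observed allele is REF), never a biological statement.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

# Call codes for the genotype matrix.
HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = 3

CALL_CODES = (HOM_REF, HET, HOM_ALT, MISSING)

#: Calls that count as homozygous genotypes.
HOM_CODES = (HOM_REF, HOM_ALT)


@dataclass(frozen=True)
class SNPRecord:
    """One marker of the array map.

    ``chromosome`` is the numeric code from the map file: 1..26 are the
    ovine autosomes; larger codes (sex chromosomes, mtDNA, unmapped
    contigs) are carried through I/O and dropped only by the QC stage.
    ``position_bp`` is 1-based.  ``genetic_distance`` is a pass-through
    (morgans or cM, never interpreted).
    """

    chromosome: int
    snp_id: str
    genetic_distance: float
    position_bp: int

    def __post_init__(self) -> None:
        if self.position_bp < 0:
            raise ValueError(
                f"SNP {self.snp_id!r}: negative position {self.position_bp}"
            )


@dataclass(frozen=True)
class SampleRecord:
    """One individual of the PED roster.

    ``population_label`` groups individuals into cohorts for the
    population-level summaries; it defaults to ``family_id``.
    """

    family_id: str
    individual_id: str
    paternal_id: str = "0"
    maternal_id: str = "0"
    sex: int = 0
    phenotype: str = "-9"
    population_label: str = ""

    def __post_init__(self) -> None:
        if not self.population_label:
            object.__setattr__(self, "population_label", self.family_id)

    @property
    def key(self) -> tuple[str, str]:
        return (self.family_id, self.individual_id)


@dataclass(frozen=True)
class GeneInterval:
    """A named gene interval in 1-based closed bp coordinates."""

    chromosome: int
    start_bp: int
    end_bp: int
    gene_name: str

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError(
                f"gene {self.gene_name!r}: start {self.start_bp} > end {self.end_bp}"
            )


class GenotypeDataset:
    """Sample roster + SNP map + call matrix; the object every stage consumes.

    Parameters
    ----------
    samples
        Ordered roster; ``(family_id, individual_id)`` must be unique.
    snps
        Ordered map, sorted by ``(chromosome, position_bp)``; ``snp_id``
        must be unique.
    calls
        int8 matrix of shape ``(len(samples), len(snps))`` holding
        :data:`CALL_CODES`.
    """

    def __init__(
        self,
        samples: Sequence[SampleRecord],
        snps: Sequence[SNPRecord],
        calls: np.ndarray,
    ) -> None:
        self.samples = list(samples)
        self.snps = list(snps)
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"call matrix shape {calls.shape} does not match roster "
                f"({len(self.samples)} samples x {len(self.snps)} SNPs)"
            )
        if calls.size and ((calls < HOM_REF) | (calls > MISSING)).any():
            raise ValueError("call matrix contains codes outside {0,1,2,3}")
        keys = [s.key for s in self.samples]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (family_id, individual_id) in roster")
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate snp_id in map")
        self.calls = calls

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def positions(self) -> np.ndarray:
        return np.array([s.position_bp for s in self.snps], dtype=np.int64)

    def chromosomes(self) -> np.ndarray:
        return np.array([s.chromosome for s in self.snps], dtype=np.int64)

    def chromosome_slices(self) -> dict[int, slice]:
        """Column slice of each chromosome (map is sorted, so contiguous)."""
        chroms = self.chromosomes()
        out: dict[int, slice] = {}
        if chroms.size == 0:
            return out
        bounds = np.flatnonzero(np.diff(chroms)) + 1
        starts = np.concatenate([[0], bounds])
        ends = np.concatenate([bounds, [chroms.size]])
        for a, b in zip(starts, ends):
            out[int(chroms[a])] = slice(int(a), int(b))
        return out

    # -- subsetting -----------------------------------------------------
    def subset(
        self,
        sample_idx: np.ndarray | Sequence[int] | None = None,
        snp_idx: np.ndarray | Sequence[int] | None = None,
    ) -> "GenotypeDataset":
        s_idx = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        m_idx = np.arange(self.n_snps) if snp_idx is None else np.asarray(snp_idx)
        return GenotypeDataset(
            [self.samples[i] for i in s_idx],
            [self.snps[j] for j in m_idx],
            self.calls[np.ix_(s_idx, m_idx)] if self.calls.size else
            np.zeros((len(s_idx), len(m_idx)), dtype=np.int8),
        )

    # -- equality (used heavily by round-trip tests) --------------------
    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        return (
            self.samples == other.samples
            and self.snps == other.snps
            and np.array_equal(self.calls, other.calls)
        )

    def __repr__(self) -> str:
        return f"GenotypeDataset({self.n_samples} samples x {self.n_snps} SNPs)"


def sorted_snps(snps: Sequence[SNPRecord]) -> list[SNPRecord]:
    """Map order used everywhere: by (chromosome, position_bp)."""
    return sorted(snps, key=lambda s: (s.chromosome, s.position_bp))


def equal_up_to_orientation(a: GenotypeDataset, b: GenotypeDataset) -> bool:
    """Dataset equality tolerating a per-SNP HOM_REF/HOM_ALT relabelling.

    A PED file records zygosity, not orientation: a SNP whose only
    non-missing calls are one homozygote class reads back with that
    class as REF whichever it was on write.  Downstream analysis only
    uses zygosity, so this is the right notion of round-trip equality.
    """
    if a.samples != b.samples or a.snps != b.snps:
        return False
    if a.calls.shape != b.calls.shape:
        return False
    flipped = np.where(
        b.calls == HOM_REF, HOM_ALT,
        np.where(b.calls == HOM_ALT, HOM_REF, b.calls),
    )
    same = (a.calls == b.calls).all(axis=0)
    swapped = (a.calls == flipped).all(axis=0)
    return bool((same | swapped).all())


__all__ = [
    "HOM_REF",
    "HET",
    "HOM_ALT",
    "MISSING",
    "CALL_CODES",
    "HOM_CODES",
    "SNPRecord",
    "SampleRecord",
    "GeneInterval",
    "GenotypeDataset",
    "sorted_snps",
    "replace",
    "field",
]
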