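"""Readers and writers for PLINK-dialect PED/MAP text files and gene intervals.

The PED/MAP text dialect is what GenomeStudio's PLINK export emits: a MAP
file of ``chromosome snp_id genetic_distance position`` lines and a PED
file of ``fid iid pat mat sex phenotype`` followed by two allele symbols
per SNP.  Both the ACGT and the 1/2 allele dialects are accepted; ``0`` is
the missing-allele symbol.  Binary PLINK (BED/BIM/FAM) and VCF are out of
scope here.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .model import (
    GeneInterval,
    GenotypeDataset,
    SampleRecord,
    SNPRecord,
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    sorted_snps,
)

log = logging.getLogger(__name__)

_ALLELE_SYMBOLS = frozenset("ACGT120")


class ParseError(ValueError):
    """Malformed genotype or annotation input."""


def read_map(path: str | Path, *, strict_sorted: bool = False) -> list[SNPRecord]:
    """Read a MAP file into SNP records sorted by (chromosome, position).

    Each non-empty line must carry four whitespace-separated fields:
    chromosome code, SNP id, genetic distance, bp position.  Unsorted
    input is sorted with a warning unless ``strict_sorted`` is set, in
    which case it is rejected.
    """
    path = Path(path)
    records: list[SNPRecord] = []
    seen: set[str] = set()
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            fields = raw.split()
            if not fields:
                continue
            if len(fields) != 4:
                raise ParseError(
                    f"{path}:{lineno}: expected 4 fields, got {len(fields)}"
                )
            chrom_s, snp_id, dist_s, pos_s = fields
            try:
                chrom = int(chrom_s)
                dist = float(dist_s)
                pos = int(pos_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric field: {exc}") from None
            if pos < 0:
                raise ParseError(f"{path}:{lineno}: negative position {pos}")
            if snp_id in seen:
                raise ParseError(f"{path}:{lineno}: duplicate snp_id {snp_id!r}")
            seen.add(snp_id)
            records.append(SNPRecord(chrom, snp_id, dist, pos))
    ordered = sorted_snps(records)
    if ordered != records:
        if strict_sorted:
            raise ParseError(f"{path}: map not sorted by (chromosome, position)")
        log.warning("%s: map not sorted by (chromosome, position); sorting", path)
    return ordered


def read_ped(path: str | Path, snps: Sequence[SNPRecord]) -> GenotypeDataset:
    """Read a PED file against an already-loaded map.

    Genotype coding: two equal non-missing alleles -> homozygous, two
    different non-missing alleles -> heterozygous, any ``0`` allele ->
    missing.  Per SNP the lexicographically smaller observed allele is
    taken as REF (the pipeline only ever uses zygosity, so any
    deterministic orientation works).
    """
    path = Path(path)
    n_snps = len(snps)
    expected = 6 + 2 * n_snps
    samples: list[SampleRecord] = []
    a1_rows: list[list[str]] = []
    a2_rows: list[list[str]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            fields = raw.split()
            if not fields:
                continue
            if len(fields) != expected:
                raise ParseError(
                    f"{path}:{lineno}: expected {expected} fields "
                    f"(6 + 2x{n_snps} SNPs), got {len(fields)}"
                )
            fid, iid, pat, mat, sex_s, pheno = fields[:6]
            try:
                sex = int(sex_s)
            except ValueError:
                sex = 0
            samples.append(SampleRecord(fid, iid, pat, mat, sex, pheno))
            alleles = fields[6:]
            bad = set(alleles) - _ALLELE_SYMBOLS
            if bad:
                raise ParseError(
                    f"{path}:{lineno}: unknown allele symbol(s) {sorted(bad)}"
                )
            a1_rows.append(alleles[0::2])
            a2_rows.append(alleles[1::2])

    if not samples:
        return GenotypeDataset([], list(snps), np.zeros((0, n_snps), dtype=np.int8))

    a1 = np.array(a1_rows, dtype="U1")
    a2 = np.array(a2_rows, dtype="U1")
    miss = (a1 == "0") | (a2 == "0")
    # Compare single-character allele symbols by codepoint ('1'<'2'<'A'<...);
    # '~' sorts after every symbol, so per-column minima skip missing.
    c1 = np.where(miss, "~", a1).view(np.uint32).reshape(a1.shape)
    c2 = np.where(miss, "~", a2).view(np.uint32).reshape(a2.shape)
    ref = np.minimum(c1.min(axis=0), c2.min(axis=0))  # '~' where all-missing
    a1_codes = a1.view(np.uint32).reshape(a1.shape)

    # Triallelic screen: at most two distinct non-missing symbols per SNP.
    for j in range(n_snps):
        observed = set(a1[:, j][~miss[:, j]]) | set(a2[:, j][~miss[:, j]])
        if len(observed) > 2:
            raise ParseError(
                f"{path}: SNP {snps[j].snp_id!r} has >2 alleles: {sorted(observed)}"
            )

    het = (a1 != a2) & ~miss
    calls = np.where(
        miss, MISSING,
        np.where(het, HET, np.where(a1_codes == ref, HOM_REF, HOM_ALT)),
    ).astype(np.int8)
    return GenotypeDataset(samples, list(snps), calls)


def write_ped_map(
    dataset: GenotypeDataset, ped_path: str | Path, map_path: str | Path
) -> None:
    """Write a dataset as PED/MAP in the 1/2 allele dialect.

    ``read_map`` + ``read_ped`` of the output reconstructs an equal
    dataset ('1' < '2' lexicographically, so REF stays REF).
    """
    map_path = Path(map_path)
    ped_path = Path(ped_path)
    with map_path.open("w") as fh:
        for s in dataset.snps:
            dist = f"{s.genetic_distance:g}"
            fh.write(f"{s.chromosome}\t{s.snp_id}\t{dist}\t{s.position_bp}\n")
    geno_strings = {HOM_REF: "1 1", HET: "1 2", HOM_ALT: "2 2", MISSING: "0 0"}
    with ped_path.open("w") as fh:
        for i, sample in enumerate(dataset.samples):
            head = (
                f"{sample.family_id} {sample.individual_id} {sample.paternal_id} "
                f"{sample.maternal_id} {sample.sex} {sample.phenotype}"
            )
            row = dataset.calls[i]
            body = " ".join(geno_strings[int(c)] for c in row)
            fh.write(head + (" " + body if body else "") + "\n")


def read_gene_intervals(
    path: str | Path, dialect: str = "BED", *, gff3_name_attr: str = "Name"
) -> list[GeneInterval]:
    """Read gene intervals from BED (0-based half-open) or GFF3 (1-based closed).

    Everything is normalized to 1-based closed bp coordinates.  For GFF3,
    only ``gene`` features are taken and the name comes from the attribute
    key ``gff3_name_attr`` (falling back to ``ID``).
    """
    path = Path(path)
    dialect = dialect.upper()
    if dialect not in {"BED", "GFF3"}:
        raise ParseError(f"unknown gene-interval dialect {dialect!r}")
    out: list[GeneInterval] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            try:
                if dialect == "BED":
                    if len(fields) < 4:
                        raise ParseError(
                            f"{path}:{lineno}: BED needs >=4 columns"
                        )
                    chrom = _parse_chrom(fields[0])
                    start = int(fields[1]) + 1  # 0-based half-open -> 1-based closed
                    end = int(fields[2])
                    name = fields[3]
                else:
                    if len(fields) < 9:
                        raise ParseError(
                            f"{path}:{lineno}: GFF3 needs 9 columns"
                        )
                    if fields[2].lower() != "gene":
                        continue
                    chrom = _parse_chrom(fields[0])
                    start = int(fields[3])
                    end = int(fields[4])
                    attrs = dict(
                        kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
                    )
                    name = attrs.get(gff3_name_attr) or attrs.get("ID") or ""
            except ParseError:
                raise
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad coordinates: {exc}") from None
            out.append(GeneInterval(chrom, start, end, name))
    return out


def _parse_chrom(token: str) -> int:
    token = token.removeprefix("chr").removeprefix("OAR")
    try:
        return int(token)
    except ValueError:
        raise ParseError(f"non-numeric chromosome {token!r}") from None


def write_segments_tsv(segments: Iterable, path: str | Path) -> None:
    """Write ROH segments in a PLINK ``.hom``-like TSV layout."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("FID\tIID\tCHR\tSTART_BP\tEND_BP\tN_SNPS\tLENGTH_KB\n")
        for seg in segments:
            fh.write(
                f"{seg.family_id}\t{seg.individual_id}\t{seg.chromosome}\t"
                f"{seg.start_bp}\t{seg.end_bp}\t{seg.n_snps}\t"
                f"{seg.length_bp / 1000:.3f}\n"
            )


__all__ = [
    "ParseError",
    "read_map",
    "read_ped",
    "write_ped_map",
    "read_gene_intervals",
    "write_segments_tsv",
]
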