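#!/usr/bin/env python
"""Detect runs of homozygosity in the QC-filtered cohort.

Runs the sliding-window scan (15-SNP windows, 1 Mb / 15 SNP minimum,
250 kb gap cap) on every individual and chromosome, writes the segment
table, and summarizes the haul per chromosome.
"""

from collections import Counter
from pathlib import Path

from rohscan.config import load_config
from rohscan.detect import detect_roh
from rohscan.io import read_map, read_ped, write_segments_tsv

ROOT = Path(__file__).resolve().parent


def main() -> None:
    cfg = load_config(ROOT / "study.yaml")
    out = Path(cfg.io.out_dir)
    data = out / "data"

    snps = read_map(data / "filtered.map")
    dataset = read_ped(data / "filtered.ped", snps)
    segments = detect_roh(dataset, cfg.roh)
    write_segments_tsv(segments, out / "roh_segments.tsv")

    per_chrom = Counter(s.chromosome for s in segments)
    n_with = len({s.individual_id for s in segments})
    print(f"detected {len(segments)} ROH segments in "
          f"{n_with}/{dataset.n_samples} individuals "
          f"-> {out}/roh_segments.tsv")
    for chrom in sorted(per_chrom):
        print(f"  chr{chrom}: {per_chrom[chrom]} segments")
    if segments:
        mean_mb = sum(s.length_bp for s in segments) / len(segments) / 1e6
        print(f"mean segment length: {mean_mb:.2f} Mb")


if __name__ == "__main__":
    main()
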