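#!/usr/bin/env python
"""Quality control: call-rate, MAF, exact-HWE and missingness filters.

Reads the simulated cohort, applies the standard chip QC cascade, writes
the filtered PED/MAP and the per-filter report, and compares what was
removed against the failures the simulator planted.
"""

from pathlib import Path

from rohscan.config import load_config
from rohscan.io import read_map, read_ped, write_ped_map
from rohscan.qc import apply_qc

ROOT = Path(__file__).resolve().parent


def main() -> None:
    cfg = load_config(ROOT / "study.yaml")
    out = Path(cfg.io.out_dir)
    data = out / "data"

    snps = read_map(data / "sim.map")
    dataset = read_ped(data / "sim.ped", snps)
    filtered, report = apply_qc(dataset, cfg.qc)

    write_ped_map(filtered, data / "filtered.ped", data / "filtered.map")
    report.write_tsv(out / "qc_report.tsv")

    print(f"QC on {report.n_input_individuals} individuals x "
          f"{report.n_input_snps} SNPs:")
    for name, n, _ids in report.rows():
        print(f"  {name}: {n} removed")
    print(f"retained {report.n_retained_individuals} individuals, "
          f"{report.n_retained_snps} SNPs -> {data}/filtered.ped")
    spike = cfg.sim.qc_spike
    if spike is not None:
        expected = (spike.n_low_call_snps + spike.n_low_maf_snps
                    + spike.n_hwe_snps)
        print(f"(simulator planted {expected} failing SNPs and "
              f"{spike.n_high_missing_individuals} high-missing individuals)")


if __name__ == "__main__":
    main()
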