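# Study conditions for the worked end-to-end analysis (desk scale).
#
# 90 ewes/rams in three cohorts on 3 chromosomes of 100 Mb x 2000 SNPs
# (~50 kb spacing, the density of a 50K array).  Random autozygous
# tracts total ~5% of the genome per individual; one shared 2 Mb tract
# on chromosome 2 (40-42 Mb) is planted in 30% of individuals as a
# recoverable selection-signature island.  QC failures of every kind
# are spiked in so the QC stage has real work to do.
sim:
  n_individuals: 90
  chromosomes: [[100000000, 2000], [100000000, 2000], [100000000, 2000]]
  populations: [[POP1, 30], [POP2, 30], [POP3, 30]]
  tracts_per_individual: 3.75     # ~0.05 expected autozygous fraction
  tract_mean_mb: 4.0
  tract_min_mb: 2.0
  planted_islands: [[2, 40000000, 42000000, 0.30]]
  het_error_rate: 0.0
  missing_rate: 0.01
  qc_spike:
    n_low_call_snps: 5
    n_low_maf_snps: 5
    n_hwe_snps: 3
    n_high_missing_individuals: 2
  seed: 2023

io:
  out_dir: results
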