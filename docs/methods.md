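# Methods

This note records the models, parameter choices and numerical decisions
behind `rohscan`, and what the validation experiments do and do not
demonstrate.

## Data model

Genotypes are held as an `(n_individuals × n_snps)` int8 matrix with
codes HOM_REF/HET/HOM_ALT/MISSING over a map sorted by (chromosome,
position).  Only zygosity matters anywhere downstream, so REF/ALT
orientation is a convention: the lexicographically smaller observed
allele per SNP is REF.  A consequence worth knowing: a SNP whose only
non-missing calls are one homozygote class reads back from PED with
that class as REF whichever it was on write; round-trip equality is
therefore defined up to this per-SNP relabelling
(`model.equal_up_to_orientation`).  Coordinates are 1-based closed
internally; BED input/output is converted at the boundary.

## Quality control

Filters run in a fixed order — (1) autosomes (codes 1–26 by default;
sex/mt/unmapped codes pass through I/O untouched and are dropped here),
(2) individual missingness > 0.10, (3) SNP call rate < 0.90, (4) MAF
< 0.05 on non-missing calls, (5) exact HWE p < 1e-4 — each computed on
the data surviving the previous step.  Sample filters precede SNP
frequency filters because missing individuals distort MAF and HWE.
Thresholds are strict: values exactly at a boundary are retained.

The Hardy–Weinberg test is the two-sided exact test conditional on
allele counts: the p-value sums the probabilities of all heterozygote
counts no more probable than the observed one.  Probabilities come from
the standard two-directional recurrence started at the modal
heterozygote count (no factorials of large n); a mid-p variant is a
flag.  Outcome-probability comparisons use a 1+1e-12 relative
tolerance so exactly-tied outcomes (symmetric distributions) land on
the same side of the cut despite float rounding; the brute-force
enumeration oracle in `reference.py` applies the same rule, and the two
agree to < 1e-10 over every triple with n ≤ 100 (~90k triples, swept in
the test suite and the acceptance script).

QC is *not* a fixpoint iteration: removing low-call-rate SNPs can in
principle push an individual's missingness over threshold on a second
pass.  The cascade runs once, in the stated order; idempotence holds in
practice (and is tested on randomized data) but is not a theorem.

## ROH detection

The scan follows the sliding-window heuristic used by standard tools,
with every contested mechanical detail pinned down and exposed as a
parameter (`ROHParams`):

* windows of 15 SNPs, at most 1 heterozygous and 1 missing call each;
* per-SNP support = fraction of physically-fitting windows containing
  the SNP that pass (denominators shrink at chromosome ends); flagged
  at support ≥ 0.05 (with a 15-SNP window an interior SNP is flagged
  iff at least one of its 15 windows passes);
* candidate runs are maximal stretches of flagged SNPs whose own call
  does not terminate a run.  By default a heterozygous call always
  terminates (`het_terminates=True`), preventing one window-smoothed
  heterozygote from bridging two runs; the lenient window-smoothed
  alternative is `het_terminates=False`.  Missing calls may sit inside
  a run but never count toward its SNP total; in lenient mode the same
  holds for heterozygous calls;
* runs are split wherever consecutive in-run SNPs are > 250 kb apart,
  then trimmed so both endpoints are homozygous calls (a run cannot
  open or close on a missing call — this makes "boundaries are the
  first/last SNP of the run" and "missing sits inside" consistent);
* survivors must have ≥ 15 homozygous SNPs, span ≥ 1 Mb (last minus
  first SNP position + 1; no extension into flanking inter-SNP space),
  and satisfy the segment-level density cap length/n_snps ≤ 100 kb.

Correctness is established against an independent O(n²) oracle that
enumerates every sub-interval and keeps maximal admissible ones
(`reference.enumerate_roh_segments`); the two agree exactly on
randomized instances in both termination modes.

## F_ROH and length classes

F_ROH(>e) = Σ L_ROH(>e) / L_aut with a *strictly longer* rule per
threshold, matching the ">e Mb" column convention; the cumulative
length-class view "e+" uses ≥ (a segment of exactly 2.0 Mb counts in
2+ and in class [2,4)).  L_aut is recomputed from the post-QC map
(per-chromosome max−min+1, summed) rather than taken as a genome
constant, which keeps simulated and real runs self-consistent; a
chromosome left with one SNP contributes 1 bp.  All thresholds derive
from one segment set, so F_ROH is monotone non-increasing in the
threshold by construction — re-detecting per class can break this and
is deliberately not done.  Population summaries use sample SD (n−1, 0
reported for singleton groups) and include zero-segment individuals as
zeros (dropping them would bias means upward).

## Islands

Occurrence is pooled over all individuals surviving QC (each
contributes at most 1 per SNP).  The top-1% cutoff is the k-th largest
occurrence with k = ⌈0.01·n_snps⌉, ties included.  Zero-occurrence
SNPs are never selected: if the k-th largest occurrence is 0 the
selection falls back to SNPs with positive occurrence (with a warning)
rather than sweeping in the whole genome.  Selected SNPs merge into an
island while consecutive selections are ≤ 1 Mb apart; islands need ≥ 3
selected SNPs.  Both island parameters are declared defaults, not
values inferred from any published analysis.  A gene annotates an
island on ≥ 1 bp overlap (interval tree), listed in position order.

## Synthetic populations

The generator emulates a diploid chip dataset, not a population
history: allele frequencies are drawn once per map (uniform on
[0.05, 0.5] by default — a single panmictic base population),
background genotypes follow Hardy–Weinberg proportions independently
per site, and autozygosity is *planted* — per-individual tracts (count
~ Poisson, length = min + exponential, default 2 + Exp(2) Mb, placed
uniformly without overlap, retry cap 1000) are forced homozygous for a
single frequency-drawn allele.  Planted tracts are IBD by construction,
so the true autozygous fraction per individual is known exactly and
additive.  Shared tracts at fixed loci with a configurable carrier
fraction create recoverable islands; optional knobs add heterozygous
genotyping error inside tracts, uniform missingness, and planted QC
failures of every kind (the latter recorded in the truth object).

What this does **not** emulate: linkage disequilibrium, realistic
allele-frequency spectra, mutation/recombination processes, pedigree
structure, or IBS runs arising by chance in low-recombination regions.
Passing the recovery experiments therefore shows the *pipeline
machinery* is correct and calibrated on known truth — it does not
certify accuracy on real data, where IBS/IBD confusion and array
ascertainment add error sources the simulator omits.

Default desk scale is 100 individuals × 3 chromosomes of 100 Mb ×
2000 SNPs (~50 kb spacing, seconds per run); `chip_scale_config()`
gives a 26-chromosome, ~46k-SNP, 281-individual preset in three cohorts
for slower end-to-end exercises.

## Validation experiments and their design choices

* **F_ROH recovery** (acceptance): planted true F ∈ {0.02, 0.05, 0.10},
  10 replicates each, zero het error, 1% missing; full QC + detection.
  Mean detected F_ROH > 1 Mb lands within ±0.015 of target at every
  level (typically within ±0.006).  Residual bias has three understood
  components: tract edges between SNPs are invisible (−), runs extend a
  few homozygous background SNPs past the tract (+), and chance
  background runs of ≥ 15 homozygous SNPs over ≥ 1 Mb add false
  segments (+, ~1 Mb per individual at this map density).
* **Island recovery**: a 2 Mb tract in 60% of individuals over 8%
  background autozygosity, 20 replicates; the locus midpoint must fall
  inside a reported island.  This experiment runs simulate → detect →
  islands *without* the QC stage: a 60% carrier fraction leaves the
  island's own SNPs with a heterozygote deficit so extreme (per-SNP
  inbreeding ≈ 0.6) that the exact-HWE filter at α = 1e-4 would remove
  precisely the island before detection.  That interaction is a real
  property of HWE filtering ahead of selection-signature scans —
  strongly shared haplotypes look like genotyping artifacts — and is
  worth remembering on real data too (at more realistic carrier
  fractions ≈ 0.3 the test statistic stays well above the cut).
* A known failure mode accounts for the occasional missed replicate
  (~1 in 20): when the random map happens to contain a > 250 kb
  inter-SNP gap near the middle of the planted locus, the gap rule
  splits every carrier's segment into two sub-1 Mb pieces, and the
  locus produces no reportable segments at all.  This is faithful
  behavior of the declared scan contract, not a detection bug.
* **Oracle equivalences** run at reduced problem sizes (≤ 200 SNPs per
  instance; HWE n ≤ 100) because the oracles are O(n²)/enumerative by
  design; the fast paths are size-independent algorithms, so agreement
  at these sizes is the meaningful check.

## Known limitations

* The caller targets array data; genotype-likelihood/sequencing ROH and
  HMM-based callers are out of scope, as are binary PLINK and VCF I/O.
* No LD pruning before detection, no relatedness/sex-check QC.
* The sliding-window contract is *a* precise resolution of details on
  which published tools disagree (window support near chromosome ends,
  heterozygote termination, gap handling); it does not claim
  bit-compatibility with any particular tool, and the divergent choices
  are parameters.
* `apply_qc` idempotence is empirical, not guaranteed (see above).
* Gene annotation trusts the user's interval file; no liftover or
  build checking is performed.
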