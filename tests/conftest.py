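import numpy as np
import pytest

from rohscan.model import GenotypeDataset, SampleRecord, SNPRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20230)


def random_dataset(rng, n_samples=10, n_snps=50, n_chrom=2, missing_p=0.05,
                   chrom_codes=None):
    """Small random dataset with a sorted map, for round-trip/QC tests."""
    if chrom_codes is None:
        chrom_codes = list(range(1, n_chrom + 1))
    per = n_snps // len(chrom_codes)
    snps = []
    k = 0
    for c in chrom_codes:
        count = per if c != chrom_codes[-1] else n_snps - per * (len(chrom_codes) - 1)
        positions = np.sort(rng.choice(10_000_000, size=count, replace=False)) + 1
        for p in positions:
            snps.append(SNPRecord(c, f"s{k}", 0.0, int(p)))
            k += 1
    samples = [SampleRecord("FAM", f"i{j}") for j in range(n_samples)]
    calls = rng.choice(
        [0, 1, 2, 3], size=(n_samples, n_snps),
        p=[(1 - missing_p) * 0.4, (1 - missing_p) * 0.3, (1 - missing_p) * 0.3,
           missing_p],
    ).astype(np.int8)
    return GenotypeDataset(samples, snps, calls)
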