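import numpy as np
import pandas as pd
import pytest

from geno2lnc.datatypes import GenotypeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_genotypes(dosages: np.ndarray, sample_ids=None, snp_ids=None) -> GenotypeMatrix:
    """Wrap a raw dosage array (samples x SNPs) in a GenotypeMatrix."""
    n, m = dosages.shape
    sample_ids = sample_ids or [f"S{i:03d}" for i in range(n)]
    snp_ids = snp_ids or [f"rs{i:04d}" for i in range(m)]
    info = pd.DataFrame(
        {"chrom": "1", "pos": np.arange(1, m + 1) * 1000, "ref": "A", "alt": "G"},
        index=snp_ids,
    )
    return GenotypeMatrix(
        pd.DataFrame(dosages.astype(float), index=sample_ids, columns=snp_ids), info
    )


def hwe_genotypes(rng, n, m, maf=0.3) -> GenotypeMatrix:
    p = np.full(m, maf) if np.isscalar(maf) else np.asarray(maf)
    return make_genotypes(rng.binomial(2, p, size=(n, m)).astype(float))
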