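import numpy as np
import pytest

from snpcombine import (
    GenotypeMatrix,
    PhenotypeVector,
    encode_binary,
)


def random_dataset(rng, n_samples=60, n_snps=10, case_frac=0.5, missing_frac=0.0):
    """Unstructured random genotype data with balanced-ish labels."""
    vals = rng.integers(0, 3, size=(n_samples, n_snps)).astype(np.int8)
    if missing_frac > 0:
        mask = rng.random(vals.shape) < missing_frac
        vals[mask] = -1
    G = GenotypeMatrix(
        [f"s{i:03d}" for i in range(n_samples)],
        [f"snp{j:03d}" for j in range(n_snps)],
        vals,
    )
    n_case = max(1, min(n_samples - 1, int(round(case_frac * n_samples))))
    is_case = np.zeros(n_samples, dtype=bool)
    is_case[rng.choice(n_samples, n_case, replace=False)] = True
    labels = PhenotypeVector(G.sample_ids, is_case)
    return G, labels


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_data(rng):
    G, labels = random_dataset(rng, n_samples=60, n_snps=8)
    return encode_binary(G), labels


def single_column_table(a, b, c, d):
    """Genotype matrix with one SNP whose mm genotype realises the
    contingency table (a, b, c, d): a+c cases, b+d controls."""
    n_case, n_ctrl = a + c, b + d
    vals = np.zeros((n_case + n_ctrl, 1), dtype=np.int8)
    vals[:a, 0] = 2
    vals[n_case : n_case + b, 0] = 2
    G = GenotypeMatrix(
        [f"s{i}" for i in range(n_case + n_ctrl)], ["snpA"], vals
    )
    labels = PhenotypeVector(
        G.sample_ids, np.arange(n_case + n_ctrl) < n_case
    )
    return encode_binary(G), labels
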