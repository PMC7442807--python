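import numpy as np
import pandas as pd
import pytest

from polybench.genotype_io import GenotypeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20200817)


def _make_genotypes(dosages) -> GenotypeMatrix:
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    variants = pd.DataFrame({
        "id": [f"snp{i}" for i in range(m)],
        "chrom": "1",
        "pos": np.arange(m, dtype=np.int64) * 1000 + 1,
        "a1": "A", "a2": "G",
    })
    samples = pd.DataFrame({
        "fid": [f"F{i}" for i in range(n)],
        "iid": [f"I{i}" for i in range(n)],
        "sex": 0,
    })
    return GenotypeMatrix(dosages, variants, samples)


@pytest.fixture
def make_genotypes():
    return _make_genotypes


@pytest.fixture
def random_genotypes(rng, make_genotypes):
    """120 samples x 40 HWE variants with a few missing calls."""
    p = rng.uniform(0.1, 0.5, 40)
    d = rng.binomial(2, p, size=(120, 40)).astype(np.int8)
    d[rng.random(d.shape) < 0.01] = -1
    return make_genotypes(d)
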