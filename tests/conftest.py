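import numpy as np
import pandas as pd
import pytest

from epistakit.datamodel import GenotypeMatrix, PhenotypeTable


def make_genotypes(codes, missing=None, **kw):
    """Build a GenotypeMatrix from a plain array (test helper)."""
    codes = np.asarray(codes, dtype=np.int8)
    n, p = codes.shape
    mask = np.zeros((n, p), bool) if missing is None else np.asarray(missing, bool)
    codes = codes.copy()
    codes[mask] = 0
    defaults = dict(
        sample_ids=[f"S{i}" for i in range(n)],
        snp_ids=[f"rs{j}" for j in range(p)],
        chrom=["1"] * p,
        pos=np.arange(1, p + 1) * 100,
    )
    defaults.update(kw)
    return GenotypeMatrix(codes=codes, missing_mask=mask, **defaults)


def make_phenotypes(**cols):
    n = len(next(iter(cols.values())))
    base = {
        "sample_id": [f"S{i}" for i in range(n)],
        "sex": np.zeros(n),
        "age": np.linspace(20, 70, n),
        "sbp": np.full(n, 120.0),
        "dbp": np.full(n, 80.0),
        "bpmeds": np.zeros(n),
    }
    base.update(cols)
    return PhenotypeTable(pd.DataFrame(base))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
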