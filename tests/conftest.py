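import numpy as np
import pandas as pd
import pytest

from pleioscore.io import SummaryMatrix, _empty_trait_meta, _empty_variant_meta


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_matrix(z: np.ndarray, variant_ids=None, trait_ids=None) -> SummaryMatrix:
    """Build a SummaryMatrix around a raw Z array with stub metadata."""
    n, l = z.shape
    variants = _empty_variant_meta(
        variant_ids if variant_ids is not None else [f"v{i}" for i in range(n)]
    )
    variants["chr"] = "1"
    variants["pos"] = np.arange(1, n + 1)
    traits = _empty_trait_meta(
        trait_ids if trait_ids is not None else [f"t{j}" for j in range(l)]
    )
    return SummaryMatrix(z, variants, traits)


@pytest.fixture
def null_matrix(rng):
    """20,000 x 8 independent standard-normal Z-scores."""
    return make_matrix(rng.normal(size=(20_000, 8)))


def write_sumstats(path, trait_id, rows):
    """Write one LDSC-dialect sumstats file; rows = (snp, a1, a2, z, n)."""
    df = pd.DataFrame(rows, columns=["SNP", "A1", "A2", "Z", "N"])
    df.to_csv(path / f"{trait_id}.sumstats", sep="\t", index=False)
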