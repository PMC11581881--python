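import numpy as np
import pandas as pd
import pytest

from ssnlet.types import OmicsMatrix, SampleMetadata


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


@pytest.fixture
def small_meta():
    """3 GC + 6 SF samples with spread-out LET values."""
    return SampleMetadata(pd.DataFrame({
        "sample_id": ["GC1", "GC2", "GC3", "SF1", "SF2", "SF3", "SF4",
                      "SF5", "SF6"],
        "group": ["GC"] * 3 + ["SF"] * 6,
        "let_value": [np.nan] * 3 + [0.0, 20.0, 60.0, 110.0, 180.0, 250.0],
        "stage": "tillering",
    }))


@pytest.fixture
def expression_matrix(rng, small_meta):
    genes = [f"g{i}" for i in range(12)]
    frame = pd.DataFrame(
        rng.lognormal(2.0, 0.8, size=(12, 9)),
        index=pd.Index(genes, name="gene_id"),
        columns=small_meta.sample_ids)
    return OmicsMatrix(frame, layer="expression")
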