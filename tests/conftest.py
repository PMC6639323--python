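import numpy as np
import pandas as pd
import pytest

from soma import GenomeIndex
from soma.data import load_reference_signatures


@pytest.fixture(scope="session")
def reference_signatures() -> pd.DataFrame:
    return load_reference_signatures()


@pytest.fixture(scope="session")
def separated_signatures(reference_signatures) -> pd.DataFrame:
    """Three reference profiles with pairwise cosine < 0.4 (checked)."""
    sigs = reference_signatures.loc[["SBS2", "SBS13", "SBS17b"]]
    M = sigs.to_numpy()
    U = M / np.linalg.norm(M, axis=1, keepdims=True)
    C = U @ U.T
    assert C[np.triu_indices(3, k=1)].max() < 0.4
    return sigs


@pytest.fixture(scope="session")
def small_genome() -> GenomeIndex:
    return GenomeIndex((("chr1", 50_000_000), ("chr2", 40_000_000), ("chr3", 30_000_000)))
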