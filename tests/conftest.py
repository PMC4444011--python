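import numpy as np
import pytest

from pausewave import CountMatrix, GeneModel


@pytest.fixture
def toy_counts() -> CountMatrix:
    counts = np.array([[10, 20], [0, 5], [100, 80]])
    return CountMatrix(
        gene_ids=["g1", "g2", "g3"],
        sample_ids=["mock", "treated"],
        counts=counts,
        library_sizes=np.array([1_000_000, 1_000_000]),
    )


@pytest.fixture
def toy_genes() -> list[GeneModel]:
    return [
        GeneModel("g1", "chr1", "+", ((0, 1000),)),
        GeneModel("g2", "chr1", "+", ((2000, 2500), (2600, 3100))),
        GeneModel("g3", "chr1", "-", ((5000, 7000),)),
    ]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
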