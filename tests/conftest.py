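import numpy as np
import pytest

from panelkin import GenotypeMatrix, MISSING


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def random_matrix(rng):
    """A 20 x 50 matrix with planted missingness across two populations."""
    calls = rng.integers(0, 3, size=(20, 50)).astype(np.int8)
    miss = rng.random((20, 50)) < 0.15
    calls[miss] = MISSING
    samples = [f"S{i:02d}" for i in range(20)]
    pops = {s: ("A" if i < 10 else "B") for i, s in enumerate(samples)}
    return GenotypeMatrix(samples, [f"L{j}" for j in range(50)], calls, pops)


@pytest.fixture
def tiny_matrix():
    """3 samples x 4 loci, hand-checkable."""
    calls = np.array(
        [
            [0, 1, 2, MISSING],
            [1, 1, 0, 0],
            [2, MISSING, 2, 1],
        ],
        dtype=np.int8,
    )
    return GenotypeMatrix(
        ["a", "b", "c"], ["L1", "L2", "L3", "L4"], calls, {"a": "X", "b": "X", "c": "Y"}
    )
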