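import numpy as np
import pytest

from taxopan import CollectionParams, DistanceMatrix, OrthoMatrix, simulate_collection


@pytest.fixture(scope="session")
def toy_ortho() -> OrthoMatrix:
    """Three genomes with OG sets A={1,2,3}, B={2,3,4}, C={3,5}."""
    counts = np.array(
        [
            [1, 1, 1, 0, 0],
            [0, 1, 1, 1, 0],
            [0, 0, 1, 0, 1],
        ]
    )
    return OrthoMatrix(("A", "B", "C"), ("og1", "og2", "og3", "og4", "og5"), counts)


@pytest.fixture(scope="session")
def small_collection():
    """Default-sized synthetic collection: 10 groups x 2 species x 3 genomes."""
    return simulate_collection(CollectionParams(seed=42))


def block_matrix(rng, sizes, within=(0.0, 0.1), between=(0.3, 0.9)) -> tuple[DistanceMatrix, list[int]]:
    """Random gap-structured matrix: blocks with a clean distance gap."""
    labels, block = [], []
    for b, s in enumerate(sizes):
        for i in range(s):
            labels.append(f"{chr(97 + b)}{i}")
            block.append(b)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            lo, hi = within if block[i] == block[j] else between
            d[i, j] = d[j, i] = rng.uniform(lo, hi)
    return DistanceMatrix(tuple(labels), d), block
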