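import numpy as np
import pytest

from phylokit.matrix import DistanceMatrix
from phylokit.synthdata import SimulationConfig, additive_matrix, random_tree


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def worked_matrix():
    """The classic 4-taxon additive matrix generated by the tree
    ((A:2,B:3):1,C:4,D:5)."""
    taxa = ["A", "B", "C", "D"]
    values = np.array(
        [
            [0.0, 5.0, 7.0, 8.0],
            [5.0, 0.0, 8.0, 9.0],
            [7.0, 8.0, 0.0, 9.0],
            [8.0, 9.0, 9.0, 0.0],
        ]
    )
    return DistanceMatrix(taxa, values)


def make_additive(n_taxa: int, seed: int) -> DistanceMatrix:
    cfg = SimulationConfig(n_taxa=n_taxa, seq_length=10, seed=seed)
    return additive_matrix(random_tree(cfg))


def random_symmetric(n: int, rng: np.random.Generator) -> DistanceMatrix:
    vals = rng.uniform(0.05, 2.0, size=(n, n))
    vals = (vals + vals.T) / 2
    np.fill_diagonal(vals, 0.0)
    return DistanceMatrix([f"t{i}" for i in range(n)], vals)
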