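import numpy as np
import pytest

from araneae_pcm import parse_newick, RateMatrixSpec
from araneae_pcm.synthetic import simulate_yule_tree


@pytest.fixture
def three_tip_tree():
    return parse_newick("((A:0.5,B:0.5):0.5,C:1);")


@pytest.fixture
def star5():
    return parse_newick("(A:1,B:1,C:1,D:1,E:1);")


@pytest.fixture
def sym2():
    return RateMatrixSpec(["s1", "s2"], np.array([[0, 1], [1, 0]]))


@pytest.fixture
def sym3():
    return RateMatrixSpec(
        ["a", "b", "c"],
        np.ones((3, 3), dtype=int) - np.eye(3, dtype=int),
    )


@pytest.fixture
def dollo_spec():
    """Five-state constrained matrix of the study (Loss absorbing)."""
    labels = ["Flagelliform", "Loss", "Modified", "None", "Pseudoflagelliform"]
    allowed = np.array([
        [0, 1, 0, 0, 0],
        [0, 0, 0, 0, 0],
        [1, 1, 0, 1, 1],
        [1, 0, 1, 0, 1],
        [1, 1, 0, 0, 0],
    ])
    return RateMatrixSpec(labels, allowed)


@pytest.fixture
def yule50():
    return simulate_yule_tree(50, 1.0, seed=42)
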