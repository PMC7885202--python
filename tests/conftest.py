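import numpy as np
import pytest

from splicenas.cell_network import CellGenotype


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def sep3_genotype():
    """Hand-written genotype using only separable 3x3 convolutions."""
    node = lambda *preds: [("sep_conv_3x3", j) for j in preds]
    part = [node(0, 1), node(1, 2), node(2, 3), node(3, 4)]
    return CellGenotype(normal=part, reduce=[list(n) for n in part])


@pytest.fixture
def zero_genotype():
    node = lambda *preds: [("zero", j) for j in preds]
    part = [node(0, 1), node(1, 2), node(2, 3), node(3, 4)]
    return CellGenotype(normal=part, reduce=[list(n) for n in part])
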