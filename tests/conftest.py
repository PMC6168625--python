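import numpy as np
import pytest

from arborsplit.morpho import NeuronNode, NeuronTree


def make_y_tree() -> NeuronTree:
    """5-node Y: root → stem → bifurcation with two terminal arms."""
    nodes = [
        NeuronNode(1, 0, (0.0, 0.0, 0.0), 1.0, -1),
        NeuronNode(2, 0, (10.0, 0.0, 0.0), 1.0, 1),
        NeuronNode(3, 0, (20.0, 0.0, 0.0), 1.0, 2),
        NeuronNode(4, 0, (28.0, 6.0, 0.0), 0.8, 3),
        NeuronNode(5, 0, (28.0, -6.0, 0.0), 0.8, 3),
    ]
    return NeuronTree(nodes)


def make_path_tree(n: int = 3, step: float = 1.0) -> NeuronTree:
    nodes = [NeuronNode(1, 0, (0.0, 0.0, 0.0), 0.5, -1)]
    for i in range(2, n + 1):
        nodes.append(NeuronNode(i, 0, ((i - 1) * step, 0.0, 0.0), 0.5, i - 1))
    return NeuronTree(nodes)


@pytest.fixture
def y_tree():
    return make_y_tree()


@pytest.fixture
def path3():
    return make_path_tree(3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
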