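import numpy as np
import pytest

from arborcable.cable_model import PassiveParams
from arborcable.morphology import MorphNode, Morphology
from arborcable.synthetic import (
    make_ball_and_stick,
    make_random_tree,
    make_three_compartment,
)


@pytest.fixture
def params():
    return PassiveParams(Ra=150.0, cm=1.0, gpas=2.64e-4, Epas=-45.0)


@pytest.fixture
def three_comp():
    return make_three_compartment()


@pytest.fixture
def ball_and_stick():
    return make_ball_and_stick(n_nodes=5)


@pytest.fixture
def random_tree():
    return make_random_tree(seed=0)


@pytest.fixture
def single_compartment():
    """One isopotential spherical compartment of area 1000 um^2."""
    r = np.sqrt(1000.0 / (4 * np.pi))
    return Morphology([MorphNode(1, -1, [0.0, 0.0, 0.0], r, 1, "soma")])


def symmetric_y(n_per_branch=6, branch_radius=0.4, branch_length=120.0):
    """Soma with two mirror-identical branches labeled AL and LH."""
    nodes = [MorphNode(1, -1, [0.0, 0.0, 0.0], 2.0, 1, "soma")]
    nid = 2
    for sign, region in ((-1.0, "AL"), (1.0, "LH")):
        parent = 1
        for k in range(1, n_per_branch + 1):
            x = sign * branch_length * k / n_per_branch
            nodes.append(
                MorphNode(nid, parent, [x, 0.0, 0.0], branch_radius, 5, region)
            )
            parent = nid
            nid += 1
    return Morphology(nodes)
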