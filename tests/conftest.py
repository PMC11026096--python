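import numpy as np
import pytest

from somamap import Skeleton, SkeletonNode, TypeSpec, generate_layout


def chain_skeleton(zs, neuron_id="chain", x=0.0, y=0.0):
    """Straight chain along z with one node per entry of ``zs``."""
    nodes = [
        SkeletonNode(node_id=i + 1, x=x, y=y, z=float(z), radius=1.0,
                     parent_id=-1 if i == 0 else i)
        for i, z in enumerate(zs)
    ]
    return Skeleton(neuron_id=neuron_id, nodes=nodes)


@pytest.fixture
def chain10():
    return chain_skeleton(range(10))


@pytest.fixture
def small_layout():
    types = [TypeSpec(f"T{i}", 4, n_partners=6) for i in range(5)]
    return generate_layout(types, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
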