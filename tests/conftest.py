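import random

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("ci")


def random_binary_newick(rng: random.Random, n_tips: int, max_bl: float = 3.0) -> str:
    """Random binary tree with uniform branch lengths, as Newick text.

    Built independently of the package's tree machinery so it can serve as
    raw input for oracle comparisons.
    """
    nodes = [f"t{i}" for i in range(n_tips)]
    subtrees = {n: n for n in nodes}
    active = nodes[:]
    while len(active) > 1:
        a, b = rng.sample(active, 2)
        active.remove(a)
        active.remove(b)
        la = rng.uniform(0.1, max_bl)
        lb = rng.uniform(0.1, max_bl)
        merged = f"({subtrees.pop(a)}:{la:.6f},{subtrees.pop(b)}:{lb:.6f})"
        key = f"{a}+{b}"
        subtrees[key] = merged
        active.append(key)
    return subtrees[active[0]] + ";"


@pytest.fixture
def rng():
    return random.Random(20160621)


@pytest.fixture
def nprng():
    return np.random.default_rng(20160621)
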