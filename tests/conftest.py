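import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import thermogc as tg
from thermogc.synth import gen_tree

settings.register_profile(
    "suite", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def cherry():
    return tg.read_newick("(A:1,B:1);")


@pytest.fixture(scope="session")
def three_tip():
    return tg.read_newick("(A:1,(B:0.5,C:0.5):0.5);")


@pytest.fixture(scope="session")
def balanced4():
    return tg.read_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture(scope="session")
def tree50():
    return gen_tree(n_tips=50, seed=1)


@pytest.fixture(scope="session")
def tree100():
    return gen_tree(n_tips=100, seed=2)


def brute_force_covariance(tree: tg.PhyloTree) -> tuple[list, np.ndarray]:
    """Independent oracle: shared root-to-MRCA path length by explicit
    root-to-tip path enumeration over node ancestries."""
    leaves = list(tree._tree.leaf_node_iter())

    def root_path(nd):
        chain = []
        while nd is not None:
            chain.append(nd)
            nd = nd.parent_node
        return list(reversed(chain))

    paths = [root_path(lf) for lf in leaves]
    n = len(leaves)
    C = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            shared = 0.0
            for a, b in zip(paths[i], paths[j]):
                if a is b:
                    if a.parent_node is not None:
                        shared += a.edge.length
                else:
                    break
            if i == j:
                shared = sum(nd.edge.length for nd in paths[i]
                             if nd.parent_node is not None)
            C[i, j] = shared
    return [lf.taxon.label for lf in leaves], C
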