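import numpy as np
import pytest

import neogfs as ng


@pytest.fixture(scope="session")
def phenotable():
    """The packaged 28-species phenotype table."""
    return ng.load_phenotype_table()


@pytest.fixture(scope="session")
def bundle():
    """One default synthetic study bundle, shared across tests (read-only)."""
    return ng.simulate_bundle(seed=20_240_101)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def naive_pic(node, values):
    """Independent recursive reimplementation of Felsenstein pruning.

    Returns (tip-or-ancestral value, adjusted branch length, contrasts list);
    used as the oracle for the production contrast operator.
    """
    if node.is_leaf():
        return values[node.taxon.label.replace(" ", "_")], float(node.edge.length), []
    left, right = node.child_nodes()
    x1, v1, c1 = naive_pic(left, values)
    x2, v2, c2 = naive_pic(right, values)
    contrast = (x1 - x2) / np.sqrt(v1 + v2)
    anc = (x1 / v1 + x2 / v2) / (1 / v1 + 1 / v2)
    own = float(node.edge.length) if node.parent_node is not None else 0.0
    return anc, own + v1 * v2 / (v1 + v2), c1 + c2 + [contrast]
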