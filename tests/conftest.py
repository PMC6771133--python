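import numpy as np
import pytest

from ldapred.data_io import EntityIndex, assemble_network
from ldapred.synthetic import SyntheticSpec, generate


@pytest.fixture
def toy_net():
    """Hand-built nl=3, nd=4, nm=2 network with known matrix entries."""
    L = np.array([[1.0, 0.5, 0.2], [0.5, 1.0, 0.3], [0.2, 0.3, 1.0]])
    D = np.array([
        [1.0, 0.4, 0.1, 0.0],
        [0.4, 1.0, 0.6, 0.2],
        [0.1, 0.6, 1.0, 0.3],
        [0.0, 0.2, 0.3, 1.0],
    ])
    M = np.array([[1.0, 0.7], [0.7, 1.0]])
    A = np.array([[1.0, 0, 1, 0], [0, 1, 0, 0], [1, 0, 0, 1]])
    B = np.array([[1.0, 0], [0, 1], [1, 1]])
    C = np.array([[1.0, 0, 1, 0], [0, 1, 0, 1]])
    return assemble_network(
        L, D, M, A, B, C,
        EntityIndex(["l1", "l2", "l3"], "lncRNA"),
        EntityIndex(["d1", "d2", "d3", "d4"], "disease"),
        EntityIndex(["m1", "m2"], "miRNA"),
    )


@pytest.fixture(scope="session")
def small_synthetic():
    """Small planted network for fast pipeline tests."""
    spec = SyntheticSpec(nl=20, nd=12, nm=10, n_clusters=2, seed=11)
    net, planted = generate(spec)
    return spec, net, planted


@pytest.fixture(scope="session")
def default_synthetic():
    """The default study-condition network (used by the heavier checks)."""
    spec = SyntheticSpec()
    net, planted = generate(spec)
    return spec, net, planted
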