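import numpy as np
import pytest

from scnkit.network import BinaryNetwork


def net_from_edges(n, edges, labels=None):
    """Build a BinaryNetwork from an explicit undirected edge list."""
    a = np.zeros((n, n), dtype=np.int8)
    for i, j in edges:
        a[i, j] = a[j, i] = 1
    if labels is None:
        labels = [f"n{k}" for k in range(n)]
    return BinaryNetwork(a=a, node_labels=labels)


def random_adjacency(rng, n, p=0.5):
    """Random symmetric hollow 0/1 matrix (Erdos-Renyi G(n, p))."""
    a = (rng.random((n, n)) < p).astype(np.int8)
    a = np.triu(a, 1)
    return a + a.T


@pytest.fixture
def triangle():
    return net_from_edges(3, [(0, 1), (1, 2), (0, 2)], labels=["A", "B", "C"])


@pytest.fixture
def path3():
    return net_from_edges(3, [(0, 1), (1, 2)])


@pytest.fixture
def star5():
    """Hub node 0 with 4 leaves."""
    return net_from_edges(5, [(0, k) for k in range(1, 5)])


@pytest.fixture
def k5():
    return net_from_edges(5, [(i, j) for i in range(5) for j in range(i + 1, 5)])


@pytest.fixture
def cohort_csv(tmp_path):
    """Hand-written 4-subject, 3-region cohort file."""
    path = tmp_path / "cohort.csv"
    path.write_text(
        "subject_id,group,age,sex,tiv,regA,regB,regC\n"
        "s1,a,30,0,1400000,5000,6000,7000\n"
        "s2,a,40,1,1500000,5100,5900,7100\n"
        "s3,b,35,0,1450000,4900,6100,6900\n"
        "s4,b,45,1,1550000,5050,6050,7050\n"
    )
    return path
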