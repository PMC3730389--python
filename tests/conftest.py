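import numpy as np
import pytest

from acunet import AdjacencyMatrix, PrescriptionDataset, lbp_fixture, mi_matrix


@pytest.fixture(scope="session")
def lbp():
    """The shipped synthetic 53x33 low-back-pain incidence fixture."""
    return lbp_fixture()


@pytest.fixture(scope="session")
def lbp_mi(lbp):
    return mi_matrix(lbp)


def random_dataset(rng: np.random.Generator, m: int, p: int) -> PrescriptionDataset:
    inc = (rng.random((m, p)) < rng.uniform(0.2, 0.8)).astype(np.uint8)
    # every column needs at least one use for MI to be defined
    for j in range(p):
        if inc[:, j].sum() == 0:
            inc[rng.integers(m), j] = 1
    return PrescriptionDataset(
        study_ids=tuple(f"S{i}" for i in range(m)),
        acupoint_labels=tuple(f"A{j}" for j in range(p)),
        incidence=inc,
    )


def random_adjacency(rng: np.random.Generator, n: int, p_edge: float = 0.4) -> AdjacencyMatrix:
    upper = rng.random((n, n)) < p_edge
    edges = np.triu(upper, k=1)
    edges = (edges | edges.T).astype(np.uint8)
    return AdjacencyMatrix(labels=tuple(f"N{i}" for i in range(n)), edges=edges)


def adjacency_from_edges(n: int, edges) -> AdjacencyMatrix:
    a = np.zeros((n, n), dtype=np.uint8)
    for i, j in edges:
        a[i, j] = a[j, i] = 1
    return AdjacencyMatrix(labels=tuple(f"N{i}" for i in range(n)), edges=a)
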