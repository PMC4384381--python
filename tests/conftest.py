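import numpy as np
import pytest

from pill import (
    AnnotationMatrix,
    LabelHierarchy,
    generate_annotations,
    generate_hierarchy,
    true_path_closure,
)


@pytest.fixture
def toy_corpus():
    """Ten proteins; label A with 4 members, children A.1 (2) and A.2 (3).

    The member sets are nested (true-path closed): A.1 in {p0, p1},
    A.2 in {p1, p2, p3}, A = union.
    """
    hierarchy = LabelHierarchy({"A": set(), "A.1": {"A"}, "A.2": {"A"}})
    proteins = [f"p{i}" for i in range(10)]
    labels = ["A", "A.1", "A.2"]
    Y = np.zeros((10, 3), dtype=np.int8)
    Y[[0, 1], 1] = 1      # A.1
    Y[[1, 2, 3], 2] = 1   # A.2
    Y[[0, 1, 2, 3], 0] = 1
    return AnnotationMatrix(proteins, labels, Y), hierarchy


def random_closed_corpus(seed, n_proteins=40, depth=4, branching=3):
    """Small random tree + closed annotations, for property tests."""
    hierarchy = generate_hierarchy(depth, branching, seed)
    Y = generate_annotations(hierarchy, n_proteins, 0.6, seed + 1, max_walks=3)
    return Y, hierarchy


@pytest.fixture
def closed_corpus():
    Y, H = random_closed_corpus(7)
    assert np.array_equal(true_path_closure(Y, H).Y, Y.Y)
    return Y, H
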