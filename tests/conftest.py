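import numpy as np
import pytest

from examine.hypergraph import encode, figure2_fixture
from examine.rsom import TrainingSchedule, train

#: Reduced iteration count for tests; the default I = ceil(1e6/|T|) is a
#: production setting, 2000 epochs are plenty for a converged small module.
TEST_ITERATIONS = 2000


@pytest.fixture(scope="session")
def fig2():
    return figure2_fixture()


@pytest.fixture(scope="session")
def fig2_matrix(fig2):
    return encode(fig2)


@pytest.fixture(scope="session")
def fig2_trained(fig2_matrix):
    """One trained six-gene module shared by contour/render tests."""
    schedule = TrainingSchedule(c=0.5, iterations=TEST_ITERATIONS, seed=42)
    layout, grid = train(fig2_matrix, schedule)
    return layout, grid


def random_module(seed: int, n_nodes: int | None = None):
    """A small random annotated module for property tests."""
    from examine.io import generate_module

    rng = np.random.default_rng(seed)
    if n_nodes is None:
        n_nodes = int(rng.integers(5, 41))
    max_edges = n_nodes * (n_nodes - 1) // 2
    n_edges = int(min(max_edges, n_nodes + rng.integers(0, n_nodes)))
    n_sets = int(rng.integers(3, 2 * n_nodes))
    return generate_module(
        n_nodes=n_nodes, n_edges=n_edges, n_sets=n_sets,
        seed=int(rng.integers(2**31 - 1)), overlap=0.5,
        n_active=min(3, n_sets),
    )
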