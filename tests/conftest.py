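import numpy as np
import pytest

from ehc_compose import (
    StateSpace,
    build_four_room,
    build_t_maze,
    build_track_loop,
    random_walk_generator,
)


@pytest.fixture(scope="session")
def four_room():
    return build_four_room(5)


@pytest.fixture(scope="session")
def t_maze():
    return build_t_maze(8, 6)


@pytest.fixture(scope="session")
def ring40():
    # square perimeter of an 11x11 grid: a 40-state ring
    return build_track_loop(11)


def random_connected_space(n: int, seed: int, p: float = 0.3) -> StateSpace:
    """Erdos-Renyi graph resampled until connected; coordinates are (i, 0)."""
    rng = np.random.default_rng(seed)
    for _ in range(200):
        adj = (rng.random((n, n)) < p).astype(np.int8)
        adj = np.triu(adj, 1)
        adj = adj + adj.T
        try:
            return StateSpace(n, [(i, 0) for i in range(n)], adj)
        except ValueError:
            continue
    raise RuntimeError("failed to sample a connected graph")


def random_rate_matrix(n: int, rng: np.random.Generator) -> np.ndarray:
    """Random generator matrix with unit exit rates on a random sparse graph."""
    A = rng.uniform(0, 1, (n, n)) * (rng.random((n, n)) < 0.5)
    A += np.roll(np.eye(n), 1, axis=1)  # cycle backbone: no dead states
    np.fill_diagonal(A, 0)
    A = A / A.sum(axis=1, keepdims=True)
    return A - np.eye(n)


@pytest.fixture(scope="session")
def explore_generator(four_room):
    return random_walk_generator(four_room)
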