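"""Infinitesimal generators of continuous-time Markov dynamics on state spaces.

A generator ``O`` is an ``n x n`` rate matrix: non-negative off-diagonal
transition rates, rows summing to zero (the diagonal carries minus the exit
rate).  The master equation ``rho_dot = rho O`` then evolves a state
probability row vector, and the propagator ``exp(O)`` (built in
:mod:`ehc_compose.spectral`) is its one-step solution.

Constructors here cover the dynamical repertoire of the simulations:

* ``random_walk_generator`` — unit-exit-rate diffusion on the map graph,
* ``avoid_region`` — row scaling ``O_s. <- c O_s.`` that shortens dwell time
  in a named region (room avoidance),
* ``directed_region_generator`` — drift toward preferred successors within a
  region, random walk elsewhere (directed maze arms, track traversal),
* ``lap_generator`` — advancement along an abstract lap chain,
* ``kronecker_sum`` — identity embeddings of a lap and a base generator into
  their product space; the lifted pair commutes exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from .state_spaces import StateSpace, build_lap_space, build_product_space

__all__ = [
    "Generator",
    "GeneratorError",
    "random_walk_generator",
    "avoid_region",
    "directed_region_generator",
    "toward_target_direction_map",
    "cycle_direction_map",
    "lap_generator",
    "kronecker_sum",
    "save_generator",
    "load_generator",
]

ROW_SUM_TOL = 1e-10
OFFDIAG_TOL = 1e-12


class GeneratorError(ValueError):
    pass


@dataclass
class Generator:
    """A rate matrix bound to the state space it acts on."""

    matrix: np.ndarray
    space: StateSpace
    label: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.validate()

    def validate(self) -> None:
        n = self.space.n_states
        if self.matrix.shape != (n, n):
            raise GeneratorError(
                f"matrix shape {self.matrix.shape} does not match space ({n} states)"
            )
        off = self.matrix - np.diag(np.diag(self.matrix))
        if off.min() < -OFFDIAG_TOL:
            i, j = np.unravel_index(np.argmin(off), off.shape)
            raise GeneratorError(
                f"negative off-diagonal rate O[{i},{j}]={self.matrix[i, j]:.3e}"
            )
        row_sums = self.matrix.sum(axis=1)
        worst = np.abs(row_sums).max()
        if worst > ROW_SUM_TOL:
            raise GeneratorError(f"rows must sum to 0; worst deviation {worst:.3e}")

    @property
    def n_states(self) -> int:
        return self.space.n_states


# ----------------------------------------------------------------------
# Constructors
# ----------------------------------------------------------------------

def random_walk_generator(space: StateSpace, label: str = "explore") -> Generator:
    """O = T - I with T the degree-normalised adjacency.

    Every state has unit exit rate split equally among its neighbours, so all
    explore-type generators share a spectrum inside ``[-2, 0]`` regardless of
    graph size.
    """
    deg = space.adjacency.sum(axis=1).astype(float)
    if np.any(deg == 0):
        isolated = np.flatnonzero(deg == 0).tolist()
        raise GeneratorError(f"cannot normalise: isolated states {isolated}")
    T = space.adjacency / deg[:, None]
    O = T - np.eye(space.n_states)
    return Generator(O, space, label)


def avoid_region(gen: Generator, region: str, c: float) -> Generator:
    """Scale the rows of ``gen`` belonging to ``region`` by ``c``.

    Scaling a zero-sum row keeps it zero-sum; rates out of the region's
    states grow with ``c``, shortening the dwell time there, so sampled
    sequences increasingly avoid the region.  ``c = 1`` returns an identical
    generator.
    """
    if c <= 0:
        raise GeneratorError(f"scale c must be > 0, got {c}")
    states = gen.space.region(region)  # KeyError for unknown region
    O = gen.matrix.copy()
    O[states, :] *= c
    return Generator(O, gen.space, label=f"{gen.label}_avoid[{region}]x{c:g}")


def toward_target_direction_map(
    space: StateSpace, region: str, target: int
) -> dict[int, int]:
    """Preferred-successor map pointing each region state toward ``target``.

    Each state's preferred successor is its lowest-index neighbour lying one
    BFS level closer to the target.  The target itself (if inside the region)
    is omitted — it has nowhere closer to go.
    """
    from .state_spaces import shortest_path_states

    dmap: dict[int, int] = {}
    for s in space.region(region):
        if s == target:
            continue
        path = shortest_path_states(space, s, target)
        dmap[s] = path[1]
    return dmap


def cycle_direction_map(order: list[int]) -> dict[int, int]:
    """Successor map following a closed traversal order (e.g. a track loop)."""
    return {s: order[(i + 1) % len(order)] for i, s in enumerate(order)}


def directed_region_generator(
    space: StateSpace,
    region: str,
    direction_map: Mapping[int, int],
    drift: float,
    label: str = "directed",
) -> Generator:
    """Drift toward preferred successors inside a region; random walk outside.

    Within the region, a state with a preferred successor allocates rate
    ``drift`` to it and splits ``1 - drift`` equally among its remaining
    neighbours (a degree-1 state sends its full unit rate to the successor).
    Region states without an entry in ``direction_map`` and all states
    outside the region keep random-walk rows.  Exit rates are 1 everywhere.
    """
    if not 0 < drift < 1:
        raise GeneratorError(f"drift must be in (0, 1), got {drift}")
    base = random_walk_generator(space)
    O = base.matrix.copy()
    region_states = set(space.region(region))
    for s, succ in direction_map.items():
        if s not in region_states:
            raise GeneratorError(f"direction map state {s} outside region {region!r}")
        nbrs = space.neighbors(s)
        if succ not in nbrs:
            raise GeneratorError(
                f"preferred successor {succ} is not adjacent to state {s}"
            )
        row = np.zeros(space.n_states)
        if len(nbrs) == 1:
            row[succ] = 1.0
        else:
            row[succ] = drift
            for v in nbrs:
                if v != succ:
                    row[v] = (1.0 - drift) / (len(nbrs) - 1)
        row[s] = -1.0
        O[s, :] = row
    return Generator(O, space, label)


def lap_generator(
    n_laps: int,
    advance_rate: float = 1.0,
    cyclic: bool = False,
    space: StateSpace | None = None,
) -> Generator:
    """Lap-advancement generator on an ``n_laps``-state chain.

    Each lap flows to the next at ``advance_rate``.  With ``cyclic=True`` the
    last lap loops back to the first; otherwise it is absorbing (a row of
    zeros), matching a single trial that ends after the final lap.
    """
    if n_laps < 2:
        raise GeneratorError("n_laps must be >= 2")
    if advance_rate <= 0:
        raise GeneratorError("advance_rate must be > 0")
    if space is None:
        space = build_lap_space(n_laps, cyclic=cyclic)
    O = np.zeros((n_laps, n_laps))
    for i in range(n_laps - 1):
        O[i, i] = -advance_rate
        O[i, i + 1] = advance_rate
    if cyclic:
        O[n_laps - 1, n_laps - 1] = -advance_rate
        O[n_laps - 1, 0] = advance_rate
    return Generator(O, space, label="lap")


def kronecker_sum(
    gen_a: Generator,
    gen_b: Generator,
    product_space: StateSpace | None = None,
) -> tuple[Generator, Generator]:
    """Lift an (outer, inner) generator pair onto their product space.

    With lap-major ordering (outer index varies slowest), the outer
    generator ``A`` lifts to ``A (x) I`` and the inner ``B`` to ``I (x) B``.
    Because the two lifts act on disjoint index factors their commutator is
    exactly zero — not merely within tolerance — which is what makes the
    conjunctive composition of lap and track dynamics order-free.
    """
    na, nb = gen_a.n_states, gen_b.n_states
    if product_space is None:
        product_space = build_product_space(gen_b.space, n_laps=na)
    if product_space.n_states != na * nb:
        raise GeneratorError(
            f"product space has {product_space.n_states} states, "
            f"expected {na} x {nb} = {na * nb}"
        )
    lifted_a = Generator(
        np.kron(gen_a.matrix, np.eye(nb)), product_space,
        label=f"{gen_a.label or 'outer'}_lifted",
    )
    lifted_b = Generator(
        np.kron(np.eye(na), gen_b.matrix), product_space,
        label=f"{gen_b.label or 'inner'}_lifted",
    )
    return lifted_a, lifted_b


# ----------------------------------------------------------------------
# Serialization: CSV matrix + JSON sidecar
# ----------------------------------------------------------------------

def save_generator(gen: Generator, basepath: str | Path) -> None:
    base = Path(basepath)
    np.savetxt(base.with_suffix(".csv"), gen.matrix, delimiter=",", fmt="%.17g")
    sidecar = {"label": gen.label, "space": json.loads(gen.space.to_json())}
    base.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_generator(basepath: str | Path) -> Generator:
    base = Path(basepath)
    matrix = np.loadtxt(base.with_suffix(".csv"), delimiter=",", ndmin=2)
    sidecar = json.loads(base.with_suffix(".json").read_text())
    space = StateSpace.from_json(json.dumps(sidecar["space"]))
    return Generator(matrix, space, label=sidecar.get("label", ""))
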