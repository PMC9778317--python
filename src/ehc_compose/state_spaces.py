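"""Discrete state spaces (cognitive maps) for generator-based sequence models.

A :class:`StateSpace` is a finite graph of states with integer coordinates and
named regions (rooms, maze arms, laps).  All dynamical structure — transition
rates, drift, lap advancement — lives in the generators that act on a space,
never in the space itself.  Three families of environments are provided:

* an open or walled grid world, including a four-room map with single-cell
  doorways,
* a T-maze (central corridor, junction, two lateral arms),
* lap-by-track product spaces for conjunctive (position, lap) codes.

State ordering is deterministic and documented per builder so that every
matrix built downstream is reproducible bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from collections import deque
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "StateSpace",
    "build_grid_world",
    "build_four_room",
    "build_t_maze",
    "build_track_loop",
    "build_lap_space",
    "build_product_space",
    "shortest_path_states",
    "perimeter_cycle",
]

Coord = tuple[int, int]
Edge = tuple[Coord, Coord]


class StateSpaceError(ValueError):
    """Raised when a construction yields an invalid state space."""


@dataclass
class StateSpace:
    """A discrete cognitive map: states, 0/1 adjacency, named regions.

    Parameters
    ----------
    n_states:
        Number of states.
    coordinates:
        Per-state integer pair: ``(row, col)`` grid position for planar maps,
        ``(lap, base_index)`` for product spaces.  Unique across states.
    adjacency:
        ``(n, n)`` symmetric 0/1 matrix with zero diagonal; 1 marks a
        single-step neighbour.
    regions:
        Mapping from region name (``"room_top_left"``, ``"central_arm"``,
        ``"lap_2"``, ...) to a frozen set of state indices.
    kind:
        One of ``grid_world``, ``t_maze``, ``product_space``, ``custom``.
    start_state:
        Optional designated start (e.g. the base of a T-maze corridor).
    """

    n_states: int
    coordinates: list[Coord]
    adjacency: np.ndarray
    regions: dict[str, frozenset[int]] = field(default_factory=dict)
    kind: str = "custom"
    start_state: int | None = None

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=np.int8)
        self.coordinates = [tuple(int(v) for v in c) for c in self.coordinates]
        self.regions = {k: frozenset(int(i) for i in v) for k, v in self.regions.items()}
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        n = self.n_states
        if n < 1:
            raise StateSpaceError("state space must have at least one state")
        if self.adjacency.shape != (n, n):
            raise StateSpaceError(
                f"adjacency shape {self.adjacency.shape} does not match n_states={n}"
            )
        if not np.array_equal(self.adjacency, self.adjacency.T):
            raise StateSpaceError("adjacency must be symmetric")
        if np.any(np.diag(self.adjacency) != 0):
            raise StateSpaceError("adjacency diagonal must be zero")
        if not np.isin(self.adjacency, (0, 1)).all():
            raise StateSpaceError("adjacency entries must be 0 or 1")
        if len(self.coordinates) != n:
            raise StateSpaceError("one coordinate pair required per state")
        if len(set(self.coordinates)) != n:
            raise StateSpaceError("coordinates must be unique across states")
        for name, states in self.regions.items():
            if not states:
                raise StateSpaceError(f"region {name!r} is empty")
            bad = [i for i in states if not 0 <= i < n]
            if bad:
                raise StateSpaceError(f"region {name!r} has invalid states {bad}")
        # Product spaces are intentionally lap-disconnected: lap transitions
        # belong to the lap generator, not the map.
        if self.kind != "product_space":
            self._check_connected()

    def _check_connected(self) -> None:
        comp = _bfs_component(self.adjacency, 0)
        if len(comp) != self.n_states:
            unreachable = sorted(set(range(self.n_states)) - comp)
            raise StateSpaceError(
                f"state space is disconnected; unreachable component {unreachable}"
            )

    # ------------------------------------------------------------------
    def neighbors(self, i: int) -> list[int]:
        return list(np.flatnonzero(self.adjacency[i]))

    def degree(self, i: int) -> int:
        return int(self.adjacency[i].sum())

    def region(self, name: str) -> list[int]:
        """Sorted state indices of a named region."""
        if name not in self.regions:
            raise KeyError(f"unknown region {name!r}; have {sorted(self.regions)}")
        return sorted(self.regions[name])

    def graph(self) -> nx.Graph:
        g = nx.from_numpy_array(self.adjacency)
        nx.set_node_attributes(g, dict(enumerate(self.coordinates)), "coordinate")
        return g

    def state_at(self, coord: Coord) -> int:
        try:
            return self.coordinates.index(tuple(coord))
        except ValueError:
            raise KeyError(f"no state at coordinate {coord}") from None

    # -- serialization --------------------------------------------------
    def to_json(self) -> str:
        edges = [
            [int(i), int(j)]
            for i, j in zip(*np.nonzero(np.triu(self.adjacency)))
        ]
        payload = {
            "n_states": self.n_states,
            "coordinates": [list(c) for c in self.coordinates],
            "adjacency": edges,
            "regions": {k: sorted(v) for k, v in self.regions.items()},
            "kind": self.kind,
            "start_state": self.start_state,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "StateSpace":
        payload = json.loads(text)
        n = payload["n_states"]
        adj = np.zeros((n, n), dtype=np.int8)
        for i, j in payload["adjacency"]:
            adj[i, j] = adj[j, i] = 1
        return cls(
            n_states=n,
            coordinates=[tuple(c) for c in payload["coordinates"]],
            adjacency=adj,
            regions={k: frozenset(v) for k, v in payload["regions"].items()},
            kind=payload.get("kind", "custom"),
            start_state=payload.get("start_state"),
        )


def _bfs_component(adjacency: np.ndarray, root: int) -> set[int]:
    seen = {root}
    queue = deque([root])
    while queue:
        u = queue.popleft()
        for v in np.flatnonzero(adjacency[u]):
            v = int(v)
            if v not in seen:
                seen.add(v)
                queue.append(v)
    return seen


# ----------------------------------------------------------------------
# Builders
# ----------------------------------------------------------------------

def build_grid_world(
    width: int,
    height: int,
    walls: Iterable[Edge] = (),
    blocked: Iterable[Coord] = (),
    regions: Mapping[str, Iterable[Coord]] | None = None,
    kind: str = "grid_world",
) -> StateSpace:
    """Rectangular grid world with 4-neighbourhood adjacency.

    States are the unblocked cells in row-major ``(row, col)`` order.
    ``walls`` removes adjacency between the given neighbouring cell pairs;
    ``blocked`` removes whole cells.  Raises if the result is disconnected,
    naming the unreachable component.
    """
    if width < 1 or height < 1:
        raise StateSpaceError("width and height must be >= 1")
    blocked_set = {tuple(c) for c in blocked}
    wall_set = set()
    for a, b in walls:
        a, b = tuple(a), tuple(b)
        if abs(a[0] - b[0]) + abs(a[1] - b[1]) != 1:
            raise StateSpaceError(f"wall {a}-{b} is not between neighbouring cells")
        wall_set.add(frozenset((a, b)))
    cells = [
        (r, c)
        for r in range(height)
        for c in range(width)
        if (r, c) not in blocked_set
    ]
    index = {cell: i for i, cell in enumerate(cells)}
    n = len(cells)
    adj = np.zeros((n, n), dtype=np.int8)
    for (r, c), i in index.items():
        for dr, dc in ((0, 1), (1, 0)):
            nb = (r + dr, c + dc)
            if nb in index and frozenset(((r, c), nb)) not in wall_set:
                j = index[nb]
                adj[i, j] = adj[j, i] = 1
    region_map: dict[str, frozenset[int]] = {}
    if regions:
        for name, coords in regions.items():
            region_map[name] = frozenset(index[tuple(c)] for c in coords)
    return StateSpace(n, cells, adj, region_map, kind=kind)


def build_four_room(room_size: int = 5) -> StateSpace:
    """Four square rooms joined by single-cell doorways at wall midpoints.

    The map is a ``(2r+1) x (2r+1)`` grid with wall lines along the central
    row and column.  Doorway cells sit on the wall lines and are their own
    states, belonging to no room region, so that room-targeted generator
    modifications (avoidance scaling) leave transit past the room intact.
    """
    r = room_size
    if r < 2:
        raise StateSpaceError("room_size must be >= 2")
    side = 2 * r + 1
    mid = r
    o = r // 2  # doorway offset: (near-)midpoint of each wall segment
    doorways = {(mid, o), (mid, r + 1 + o), (o, mid), (r + 1 + o, mid)}
    blocked = {
        (mid, c) for c in range(side)
    } | {(rr, mid) for rr in range(side)}
    blocked -= doorways
    rooms = {
        "room_top_left": [(a, b) for a in range(r) for b in range(r)],
        "room_top_right": [(a, b) for a in range(r) for b in range(r + 1, side)],
        "room_bottom_left": [(a, b) for a in range(r + 1, side) for b in range(r)],
        "room_bottom_right": [
            (a, b) for a in range(r + 1, side) for b in range(r + 1, side)
        ],
    }
    return build_grid_world(side, side, blocked=blocked, regions=rooms)


def build_t_maze(central_len: int = 8, arm_len: int = 6) -> StateSpace:
    """T-maze: vertical central corridor ending at a junction with two arms.

    State ordering is corridor-then-arms: indices ``0..central_len-1`` run
    from the corridor base (the designated start state) up to the junction,
    followed by the left arm (junction outward) then the right arm.  Regions:
    ``central_arm`` (corridor including the junction), ``left_arm``,
    ``right_arm``, plus the singleton ``junction`` convenience region.
    """
    c, a = central_len, arm_len
    if c < 2:
        raise StateSpaceError("central_len must be >= 2")
    if a < 1:
        raise StateSpaceError("arm_len must be >= 1")
    coords: list[Coord] = []
    # corridor: base at the bottom, junction at the top
    for i in range(c):
        coords.append((c - 1 - i, a))
    for j in range(a):  # left arm, junction outward
        coords.append((0, a - 1 - j))
    for j in range(a):  # right arm, junction outward
        coords.append((0, a + 1 + j))
    n = c + 2 * a
    adj = np.zeros((n, n), dtype=np.int8)

    def link(i: int, j: int) -> None:
        adj[i, j] = adj[j, i] = 1

    for i in range(c - 1):
        link(i, i + 1)
    junction = c - 1
    link(junction, c)  # first left-arm state
    for j in range(a - 1):
        link(c + j, c + j + 1)
    link(junction, c + a)  # first right-arm state
    for j in range(a - 1):
        link(c + a + j, c + a + j + 1)
    regions = {
        "central_arm": frozenset(range(c)),
        "left_arm": frozenset(range(c, c + a)),
        "right_arm": frozenset(range(c + a, n)),
        "junction": frozenset({junction}),
    }
    return StateSpace(n, coords, adj, regions, kind="t_maze", start_state=0)


def perimeter_cycle(side: int) -> list[Coord]:
    """Coordinates of a square perimeter in counterclockwise traversal order.

    Starts at the bottom-left corner; with rows increasing downward,
    counterclockwise means: right along the bottom, up the right edge,
    left along the top, down the left edge.
    """
    if side < 2:
        raise StateSpaceError("side must be >= 2")
    bottom = [(side - 1, c) for c in range(side)]
    right = [(r, side - 1) for r in range(side - 2, 0, -1)]
    top = [(0, c) for c in range(side - 1, -1, -1)]
    left = [(r, 0) for r in range(1, side - 1)]
    return bottom + right + top + left


def build_track_loop(side: int = 10) -> StateSpace:
    """Square-perimeter running track (a cycle of ``4*side - 4`` states).

    Built as a grid world whose interior cells are blocked, so each perimeter
    cell has exactly two neighbours.  The full perimeter forms the region
    ``"track"``; the bottom-left corner is the designated start (the reward
    site in the four-lap task).
    """
    interior = {(r, c) for r in range(1, side - 1) for c in range(1, side - 1)}
    space = build_grid_world(side, side, blocked=interior, kind="grid_world")
    space.regions["track"] = frozenset(range(space.n_states))
    space.start_state = space.state_at((side - 1, 0))
    return space


def build_lap_space(n_laps: int, cyclic: bool = False) -> StateSpace:
    """Chain (or cycle) of lap states used by the lap-advancement generator."""
    if n_laps < 2:
        raise StateSpaceError("n_laps must be >= 2")
    adj = np.zeros((n_laps, n_laps), dtype=np.int8)
    for i in range(n_laps - 1):
        adj[i, i + 1] = adj[i + 1, i] = 1
    if cyclic and n_laps > 2:
        adj[0, n_laps - 1] = adj[n_laps - 1, 0] = 1
    coords = [(i, 0) for i in range(n_laps)]
    regions = {f"lap_{i + 1}": frozenset({i}) for i in range(n_laps)}
    return StateSpace(n_laps, coords, adj, regions, kind="custom")


def build_product_space(base: StateSpace, n_laps: int) -> StateSpace:
    """Lap-by-base product space with lap-major state ordering.

    State ``(lap l, base state b)`` has index ``l * base.n_states + b`` and
    coordinate ``(l, b)``.  Adjacency within each lap copies the base
    adjacency; no cross-lap adjacency is added — lap transitions are the lap
    generator's job.  Regions: ``lap_1..lap_{n_laps}`` (1-based) plus lifted
    copies of every base region (union over laps, same names).
    """
    if n_laps < 1:
        raise StateSpaceError("n_laps must be >= 1")
    nb = base.n_states
    n = n_laps * nb
    adj = np.kron(np.eye(n_laps, dtype=np.int8), base.adjacency)
    coords = [(l, b) for l in range(n_laps) for b in range(nb)]
    regions: dict[str, frozenset[int]] = {}
    for l in range(n_laps):
        regions[f"lap_{l + 1}"] = frozenset(range(l * nb, (l + 1) * nb))
    for name, states in base.regions.items():
        regions[name] = frozenset(
            l * nb + b for l in range(n_laps) for b in states
        )
    kind = base.kind if n_laps == 1 else "product_space"
    if n_laps == 1:
        # singleton product is isomorphic to the base; keep base structure
        return StateSpace(
            nb, list(base.coordinates), base.adjacency.copy(),
            dict(base.regions) | {"lap_1": frozenset(range(nb))},
            kind=base.kind, start_state=base.start_state,
        )
    start = None if base.start_state is None else base.start_state
    return StateSpace(n, coords, adj, regions, kind=kind, start_state=start)


# ----------------------------------------------------------------------
# Geodesics
# ----------------------------------------------------------------------

def shortest_path_states(space: StateSpace, a: int, b: int) -> list[int]:
    """One geodesic from ``a`` to ``b`` as an ordered list of states.

    Breadth-first search with deterministic tie-breaking: each state keeps
    the lowest-index predecessor that first reaches it, so repeated runs
    return the identical path.  ``a == b`` returns ``[a]``.
    """
    n = space.n_states
    for s in (a, b):
        if not 0 <= s < n:
            raise IndexError(f"state {s} out of range 0..{n - 1}")
    if a == b:
        return [a]
    dist = np.full(n, -1, dtype=int)
    dist[a] = 0
    queue = deque([a])
    while queue:
        u = queue.popleft()
        for v in np.flatnonzero(space.adjacency[u]):
            v = int(v)
            if dist[v] == -1:
                dist[v] = dist[u] + 1
                queue.append(v)
    # backtrack from b, always taking the lowest-index neighbour one BFS
    # level closer to a
    path = [b]
    while path[-1] != a:
        u = path[-1]
        nbrs = [int(v) for v in np.flatnonzero(space.adjacency[u])]
        path.append(min(v for v in nbrs if dist[v] == dist[u] - 1))
    return path[::-1]
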