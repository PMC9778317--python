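"""Generator constructors: rate-matrix invariants and dynamical structure."""

import numpy as np
import pytest

from ehc_compose import (
    Generator,
    avoid_region,
    build_grid_world,
    build_t_maze,
    build_track_loop,
    cycle_direction_map,
    directed_region_generator,
    kronecker_sum,
    lap_generator,
    load_generator,
    perimeter_cycle,
    random_walk_generator,
    save_generator,
    series_propagator,
    toward_target_direction_map,
)
from ehc_compose.generators import GeneratorError
from ehc_compose.state_spaces import StateSpace

from conftest import random_connected_space


class TestRandomWalk:
    def test_two_state_path(self):
        s = build_grid_world(2, 1)
        O = random_walk_generator(s).matrix
        assert np.array_equal(O, [[-1.0, 1.0], [1.0, -1.0]])

    def test_three_cycle_rows(self):
        adj = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=np.int8)
        s = StateSpace(3, [(0, 0), (0, 1), (1, 0)], adj)
        O = random_walk_generator(s).matrix
        for row in O:
            assert sorted(row) == [-1.0, 0.5, 0.5]

    @pytest.mark.parametrize("seed", range(3))
    def test_rows_sum_exactly_zero(self, seed):
        s = random_connected_space(12, seed)
        O = random_walk_generator(s).matrix
        assert np.abs(O.sum(axis=1)).max() < 1e-12

    def test_isolated_state_raises(self):
        adj = np.zeros((1, 1), dtype=np.int8)
        s = StateSpace(1, [(0, 0)], adj)
        with pytest.raises(GeneratorError, match="isolated"):
            random_walk_generator(s)


class TestAvoidRegion:
    def test_c_equal_one_is_identity(self, explore_generator):
        out = avoid_region(explore_generator, "room_bottom_left", 1.0)
        assert np.array_equal(out.matrix, explore_generator.matrix)

    def test_elementwise_row_scaling(self):
        adj = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=np.int8)
        s = StateSpace(3, [(0, 0), (0, 1), (1, 0)], adj,
                       regions={"target": frozenset({0})})
        g = random_walk_generator(s)
        out = avoid_region(g, "target", 2.0)
        assert np.allclose(out.matrix[0], [-2.0, 1.0, 1.0])
        assert np.array_equal(out.matrix[1:], g.matrix[1:])

    def test_composition_multiplies_scales(self, explore_generator):
        twice = avoid_region(
            avoid_region(explore_generator, "room_bottom_left", 2.0),
            "room_bottom_left", 3.0,
        )
        once = avoid_region(explore_generator, "room_bottom_left", 6.0)
        assert np.allclose(twice.matrix, once.matrix, atol=1e-14)

    def test_rows_outside_region_bit_identical(self, explore_generator):
        out = avoid_region(explore_generator, "room_bottom_left", 10.0)
        outside = sorted(
            set(range(explore_generator.n_states))
            - explore_generator.space.regions["room_bottom_left"]
        )
        assert np.array_equal(out.matrix[outside], explore_generator.matrix[outside])

    def test_propagated_mass_reduced_from_opposite_room(self, explore_generator):
        """With c=10, 20-step mass in the avoided room drops below c=1.

        Oracle: the truncated-series exponential; propagation by repeated
        one-step application from the room diagonally opposite.
        """
        space = explore_generator.space
        room = space.region("room_bottom_left")
        start = space.state_at((2, 8))  # top-right room centre
        avoided = avoid_region(explore_generator, "room_bottom_left", 10.0)
        P1 = series_propagator(explore_generator, 1.0, 60).matrix
        P10 = series_propagator(avoided, 1.0, 60).matrix
        e = np.zeros(space.n_states)
        e[start] = 1.0
        m1 = (e @ np.linalg.matrix_power(P1, 20))[room].sum()
        m10 = (e @ np.linalg.matrix_power(P10, 20))[room].sum()
        assert m10 < m1

    def test_error_paths(self, explore_generator):
        with pytest.raises(GeneratorError):
            avoid_region(explore_generator, "room_bottom_left", 0.0)
        with pytest.raises(KeyError):
            avoid_region(explore_generator, "no_such_room", 2.0)


class TestDirected:
    def test_equal_split_limit_recovers_random_walk(self, t_maze):
        # drift = 1/degree makes every allocation equal to the random walk
        junction = t_maze.region("junction")[0]
        dmap = toward_target_direction_map(t_maze, "central_arm", junction)
        corridor_only = {s: v for s, v in dmap.items() if t_maze.degree(s) == 2}
        g = directed_region_generator(t_maze, "central_arm", corridor_only, 0.5)
        rw = random_walk_generator(t_maze)
        rows = sorted(corridor_only)
        assert np.allclose(g.matrix[rows], rw.matrix[rows])

    def test_corridor_allocation(self, t_maze):
        junction = t_maze.region("junction")[0]
        dmap = toward_target_direction_map(t_maze, "central_arm", junction)
        g = directed_region_generator(t_maze, "central_arm", dmap, 0.8)
        s = 3  # mid-corridor, degree 2
        row = g.matrix[s]
        assert row[dmap[s]] == pytest.approx(0.8)
        assert row[s] == pytest.approx(-1.0)
        others = [v for v in t_maze.neighbors(s) if v != dmap[s]]
        assert row[others[0]] == pytest.approx(0.2)

    def test_positive_drift_toward_junction(self, t_maze):
        """Rate-weighted displacement along the corridor points junction-ward."""
        junction = t_maze.region("junction")[0]
        dmap = toward_target_direction_map(t_maze, "central_arm", junction)
        g = directed_region_generator(t_maze, "central_arm", dmap, 0.8)
        from ehc_compose import shortest_path_states

        dist = {s: len(shortest_path_states(t_maze, s, junction)) - 1
                for s in range(t_maze.n_states)}
        for s in t_maze.region("central_arm"):
            if s == junction:
                continue
            drift_rate = sum(
                g.matrix[s, v] * (dist[s] - dist[v])
                for v in t_maze.neighbors(s)
            )
            assert drift_rate > 0

    def test_non_adjacent_successor_raises(self, t_maze):
        with pytest.raises(GeneratorError, match="not adjacent"):
            directed_region_generator(t_maze, "central_arm", {0: 5}, 0.8)


class TestLap:
    def test_two_lap_cycle(self):
        g = lap_generator(2, 1.0, cyclic=True)
        assert np.array_equal(g.matrix, [[-1.0, 1.0], [1.0, -1.0]])

    def test_absorbing_final_lap(self):
        g = lap_generator(4, 0.5, cyclic=False)
        assert np.array_equal(g.matrix[-1], np.zeros(4))
        assert np.abs(g.matrix.sum(axis=1)).max() == 0.0


class TestKroneckerSum:
    def test_lifted_pair_commutes_exactly(self):
        box = random_walk_generator(build_track_loop(6))
        lap = lap_generator(3, 0.1)
        la, lb = kronecker_sum(lap, box)
        comm = la.matrix @ lb.matrix - lb.matrix @ la.matrix
        assert np.abs(comm).max() == 0.0  # exact, not approximate

    def test_block_structure_and_row_sums(self):
        lap = lap_generator(2, 1.0, cyclic=True)
        box = random_walk_generator(random_connected_space(3, 0))
        la, lb = kronecker_sum(lap, box)
        assert la.matrix.shape == (6, 6)
        # lifted outer restricted to a fixed inner index reproduces it
        for b in range(3):
            sub = la.matrix[np.ix_([b, 3 + b], [b, 3 + b])]
            assert np.array_equal(sub, lap.matrix)
        # lifted inner restricted to a lap block reproduces it
        assert np.array_equal(lb.matrix[:3, :3], box.matrix)
        assert np.abs(la.matrix.sum(axis=1)).max() < 1e-12
        assert np.abs(lb.matrix.sum(axis=1)).max() < 1e-12

    def test_dimension_mismatch_raises(self):
        lap = lap_generator(2, 1.0, cyclic=True)
        box = random_walk_generator(random_connected_space(3, 0))
        wrong = random_connected_space(5, 1)
        with pytest.raises(GeneratorError, match="product space"):
            kronecker_sum(lap, box, product_space=wrong)


class TestValidationAndIO:
    def test_negative_offdiagonal_rejected(self):
        s = build_grid_world(2, 1)
        with pytest.raises(GeneratorError, match="negative off-diagonal"):
            Generator(np.array([[1.0, -1.0], [1.0, -1.0]]), s)

    def test_nonzero_row_sum_rejected(self):
        s = build_grid_world(2, 1)
        with pytest.raises(GeneratorError, match="sum to 0"):
            Generator(np.array([[-1.0, 0.5], [1.0, -1.0]]), s)

    def test_csv_round_trip(self, tmp_path, t_maze):
        track = build_track_loop(6)
        order = [track.state_at(c) for c in perimeter_cycle(6)]
        g = directed_region_generator(
            track, "track", cycle_direction_map(order), 0.7, label="box"
        )
        save_generator(g, tmp_path / "box")
        back = load_generator(tmp_path / "box")
        assert np.array_equal(back.matrix, g.matrix)
        assert back.label == "box"
        assert back.space.n_states == track.n_states
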