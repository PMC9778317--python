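"""End-to-end experiments: avoidance, extended replay, lap coding, CLI."""

import json

import numpy as np
import pytest
from click.testing import CliRunner

from ehc_compose import (
    EsrConfig,
    ExploreAvoidConfig,
    ReplayConfig,
    SampledSequence,
    build_t_maze,
    choose_goal,
    coverage,
    rank_test_greater,
    run_esr,
    run_explore_avoid,
    run_extended_replay,
    shortest_path_states,
)
from ehc_compose.cli import main as cli_main


@pytest.fixture(scope="module")
def maze():
    return build_t_maze(8, 6)


class TestCoverage:
    def test_full_geodesic_traversal_scores_100(self, maze):
        left_end = max(maze.regions["left_arm"])
        path = shortest_path_states(maze, maze.start_state, left_end)
        seq = SampledSequence(states=path, seed=0)
        assert coverage(seq, maze, maze.start_state, left_end) == pytest.approx(100.0)

    def test_constant_sequence_scores_one_over_length(self, maze):
        left_end = max(maze.regions["left_arm"])
        L = len(shortest_path_states(maze, maze.start_state, left_end))
        seq = SampledSequence(states=[maze.start_state] * 5, seed=0)
        assert coverage(seq, maze, maze.start_state, left_end) == pytest.approx(100.0 / L)

    def test_central_confined_sequence_is_bounded(self, maze):
        left_end = max(maze.regions["left_arm"])
        geo = shortest_path_states(maze, maze.start_state, left_end)
        central = sorted(maze.regions["central_arm"])
        seq = SampledSequence(states=central, seed=0)
        bound = 100.0 * len(set(geo) & set(central)) / len(geo)
        assert coverage(seq, maze, maze.start_state, left_end) <= bound + 1e-12

    def test_goal_choice_follows_overlap_with_left_tie(self, maze):
        left_end = max(maze.regions["left_arm"])
        right_end = max(maze.regions["right_arm"])
        right_seq = SampledSequence(states=sorted(maze.regions["right_arm"]), seed=0)
        assert choose_goal(right_seq, maze, maze.start_state,
                           (left_end, right_end)) == right_end
        # a purely central sequence overlaps both geodesics equally -> left
        central_seq = SampledSequence(states=[maze.start_state], seed=0)
        assert choose_goal(central_seq, maze, maze.start_state,
                           (left_end, right_end)) == left_end


class TestRankTest:
    def test_exact_small_sample_p(self):
        # all four composed values above all segmented: p = 1/6 by
        # enumeration of the six equally likely orderings
        u, p = rank_test_greater(np.array([3.0, 4.0]), np.array([1.0, 2.0]))
        assert p == pytest.approx(1 / 6, abs=1e-12)

    def test_tied_samples_use_midrank_normal_approximation(self):
        x = np.array([2.0, 2.0, 3.0])
        y = np.array([1.0, 2.0, 2.0])
        u, p = rank_test_greater(x, y)
        assert 0.0 < p < 1.0


class TestExploreAvoid:
    def test_no_avoidance_yields_identical_densities(self):
        res = run_explore_avoid(ExploreAvoidConfig(room_size=3, c=1.0, horizon=10))
        assert np.abs(res.density_difference).max() < 1e-12
        assert res.room_mass_stack == pytest.approx(res.room_mass_explore)

    def test_avoidance_reduces_room_mass(self):
        res = run_explore_avoid(ExploreAvoidConfig())
        assert res.room_mass_stack < res.room_mass_explore
        assert res.density_explore.sum() == pytest.approx(1.0, abs=1e-9)
        assert res.density_stack.sum() == pytest.approx(1.0, abs=1e-9)

    def test_one_step_samples_reproducible(self):
        a = run_explore_avoid(ExploreAvoidConfig(room_size=3, seed=5, horizon=5))
        b = run_explore_avoid(ExploreAvoidConfig(room_size=3, seed=5, horizon=5))
        assert a.step_samples_explore == b.step_samples_explore
        assert a.step_samples_stack == b.step_samples_stack


class TestExtendedReplay:
    def test_composed_coverage_exceeds_segmented(self):
        res = run_extended_replay(ReplayConfig(n_sequences=16, seed=1))
        assert res.composed.mean() > res.segmented.mean()
        assert res.truncated_composed == 0
        assert np.all((res.composed >= 0) & (res.composed <= 100))

    def test_bit_reproducible(self):
        cfg = ReplayConfig(n_sequences=10, seed=3)
        a = run_extended_replay(cfg)
        b = run_extended_replay(cfg)
        assert np.array_equal(a.composed, b.composed)
        assert np.array_equal(a.segmented, b.segmented)
        assert a.p_value == b.p_value

    def test_null_mode_is_not_systematically_significant(self):
        ps = [
            run_extended_replay(
                ReplayConfig(n_sequences=20, seed=s, null_mode=True)
            ).p_value
            for s in range(10)
        ]
        assert min(ps) > 1e-4  # identical conditions: no extreme evidence
        assert max(ps) > 0.2


class TestEsr:
    def test_every_unit_prefers_its_own_lap(self):
        res = run_esr(EsrConfig(side=6, n_laps=3))
        assert res.own_lap_fraction == 1.0
        assert res.commutator_max == 0.0
        for m in res.rate_maps:
            assert m.rates.min() >= 0.0
            assert 1 <= m.preferred_lap <= 3

    def test_rate_maps_redistribute_one_probability_vector(self):
        res = run_esr(EsrConfig(side=6, n_laps=3))
        # for any fixed initialisation the rates across units sum to 1
        stacked = np.stack([m.rates for m in res.rate_maps])  # (units, lap, pos)
        per_init = stacked.sum(axis=0)
        assert np.abs(per_init - 1.0).max() < 1e-9

    def test_lap_weight_zero_removes_lap_preference(self):
        res = run_esr(EsrConfig(side=6, n_laps=3, tau_lap=0.0))
        assert res.n_lap_preferring == 0
        # each unit is active on its own lap only
        for m in res.rate_maps:
            active = m.lap_peaks > 1e-9 * m.lap_peaks.max()
            assert active.sum() == 1

    def test_units_late_laps_accumulate_upstream_activation(self):
        res = run_esr(EsrConfig(side=6, n_laps=3))
        lap2 = [m for m in res.rate_maps if m.unit_lap == 2]
        assert all(m.lap_preferring for m in lap2)


class TestCli:
    def test_init_config_and_run_explore_avoid(self, tmp_path):
        runner = CliRunner()
        cfg_path = tmp_path / "cfg.yaml"
        out = runner.invoke(cli_main, ["init-config", "explore-avoid",
                                       "-o", str(cfg_path)])
        assert out.exit_code == 0, out.output
        cfg_path.write_text(
            cfg_path.read_text().replace("room_size: 5", "room_size: 3")
        )
        run_dir = tmp_path / "run"
        out = runner.invoke(cli_main, [
            "run", "explore-avoid", "--config", str(cfg_path),
            "--seed", "1", "--out", str(run_dir),
        ])
        assert out.exit_code == 0, out.output
        summary = json.loads((run_dir / "summary.json").read_text())
        assert summary["room_mass_stack"] < summary["room_mass_explore"]
        assert (run_dir / "density_difference.csv").exists()

    def test_run_esr_writes_unit_table(self, tmp_path):
        runner = CliRunner()
        cfg = tmp_path / "esr.yaml"
        runner.invoke(cli_main, ["init-config", "esr", "-o", str(cfg)])
        cfg.write_text(cfg.read_text().replace("side: 10", "side: 6")
                       .replace("n_laps: 4", "n_laps: 3"))
        run_dir = tmp_path / "esr_run"
        out = runner.invoke(cli_main, [
            "run", "esr", "--config", str(cfg), "--out", str(run_dir),
        ])
        assert out.exit_code == 0, out.output
        summary = json.loads((run_dir / "summary.json").read_text())
        assert summary["own_lap_fraction"] == 1.0
        assert (run_dir / "units.tsv").exists()

    def test_adhoc_sample_and_propagate(self, tmp_path):
        from ehc_compose import build_track_loop, random_walk_generator, save_generator

        g = random_walk_generator(build_track_loop(6), label="ring")
        save_generator(g, tmp_path / "ring")
        runner = CliRunner()
        seq_path = tmp_path / "seq.tsv"
        out = runner.invoke(cli_main, [
            "sample", "--generator", str(tmp_path / "ring"), "--start", "0",
            "--length", "10", "--seed", "2", "--out", str(seq_path),
        ])
        assert out.exit_code == 0, out.output
        assert len(seq_path.read_text().strip().splitlines()) == 11
        dens_path = tmp_path / "dens.csv"
        out = runner.invoke(cli_main, [
            "propagate", "--generator", str(tmp_path / "ring"), "--start", "0",
            "--steps", "5", "--out", str(dens_path),
        ])
        assert out.exit_code == 0, out.output
        dens = np.loadtxt(dens_path, delimiter=",")
        assert dens.shape == (6, g.n_states)
        assert np.abs(dens.sum(axis=1) - 1.0).max() < 1e-9
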