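"""End-to-end simulations: directed exploration, extended replay, lap coding.

Three experiments exercise the full pipeline (state space -> generators ->
spectral propagators -> composition -> sampling):

* **explore + avoid** — a four-room grid world where stacking a random
  exploration propagator with an "avoid room" propagator steers sequence
  generation away from a room known not to contain the goal.
* **extended replay** — a T-maze where sequencing a central-arm-directed and
  a lateral-arm-directed propagator in time concatenates two replay
  segments into one spatially contiguous extended trajectory; spatial
  coverage of composed vs segmented sequences is compared with a one-sided
  Mann-Whitney U test.
* **event-specific rate remapping (ESR)** — a square track crossed with an
  abstract lap variable; commuting lifted track and lap generators compose
  conjunctively, and each unit of the resulting lap-by-track population
  attains its maximal firing rate on its own lap.

Every experiment is a pure function of (config, seed) and bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .composition import CompositionPlan, commutator, compose_generators, stack_propagators
from .generators import (
    Generator,
    avoid_region,
    cycle_direction_map,
    directed_region_generator,
    kronecker_sum,
    lap_generator,
    random_walk_generator,
    toward_target_direction_map,
)
from .sampling import SampledSequence, propagate, sample_sequence, sequence_stream, sequencing_sample
from .spectral import Propagator, decompose, build_propagator, propagator_for
from .state_spaces import (
    StateSpace,
    build_four_room,
    build_product_space,
    build_t_maze,
    build_track_loop,
    perimeter_cycle,
    shortest_path_states,
)

__all__ = [
    "ExploreAvoidConfig",
    "ReplayConfig",
    "EsrConfig",
    "ExploreAvoidResult",
    "CoverageResult",
    "RateMap",
    "EsrResult",
    "coverage",
    "choose_goal",
    "rank_test_greater",
    "run_explore_avoid",
    "run_extended_replay",
    "run_esr",
    "write_explore_avoid",
    "write_replay",
    "write_esr",
    "default_config",
    "load_config",
]


# ----------------------------------------------------------------------
# Configs
# ----------------------------------------------------------------------

@dataclass
class ExploreAvoidConfig:
    """Four-room exploration with room avoidance."""

    room_size: int = 5
    avoid_room: str = "room_bottom_left"
    c: float = 10.0  # avoidance scale; 1 disables avoidance
    tau: float = 1.0
    alpha: float = 1.0
    dt: float = 1.0
    n_step_samples: int = 20  # one-step samples drawn per condition
    horizon: int = 20  # propagation steps for the density maps
    n_components: int = 4  # spectral-component maps exported per generator
    seed: int = 0


@dataclass
class ReplayConfig:
    """T-maze extended replay: composed vs segmented sequences."""

    central_len: int = 8
    arm_len: int = 6
    drift: float = 0.8
    tau: float = 1.0
    alpha: float = 1.0
    dt: float = 1.0
    length: int = 20  # states per sequence
    n_sequences: int = 50  # per condition
    seed: int = 0
    null_mode: bool = False  # both conditions identical (calibration)


@dataclass
class EsrConfig:
    """Lap-by-track event-specific rate remapping."""

    side: int = 10  # square track side; perimeter has 4*side-4 states
    n_laps: int = 4
    drift: float = 0.8  # counterclockwise bias of the track generator
    advance_rate: float = 1.0 / 60.0  # lap rate ~ one advance per circuit
    cyclic_laps: bool = False  # absorbing final lap by default (single trial)
    tau_box: float = 1.0  # conjunctive weight of the track generator
    tau_lap: float = 1.0  # conjunctive weight of the lap generator
    k: int = 3  # propagation horizon for the firing maps
    seed: int = 0


_CONFIGS = {
    "explore-avoid": ExploreAvoidConfig,
    "extended-replay": ReplayConfig,
    "esr": EsrConfig,
}


def default_config(experiment: str):
    try:
        return _CONFIGS[experiment]()
    except KeyError:
        raise KeyError(
            f"unknown experiment {experiment!r}; choose from {sorted(_CONFIGS)}"
        ) from None


def load_config(experiment: str, mapping: dict):
    cls = type(default_config(experiment))
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - names
    if unknown:
        raise KeyError(f"unknown config keys for {experiment!r}: {sorted(unknown)}")
    return cls(**mapping)


# ----------------------------------------------------------------------
# Results
# ----------------------------------------------------------------------

@dataclass
class ExploreAvoidResult:
    space: StateSpace
    start: int
    step_samples_explore: list[int]
    step_samples_stack: list[int]
    density_explore: np.ndarray  # over states, after `horizon` steps
    density_stack: np.ndarray
    room_mass_explore: float  # mass in the avoided room
    room_mass_stack: float
    spectral_components: dict[str, np.ndarray]  # label -> (n_components, n)
    config: ExploreAvoidConfig

    @property
    def density_difference(self) -> np.ndarray:
        """Explore minus composed: positive where avoidance removed mass."""
        return self.density_explore - self.density_stack

    def grid(self, values: np.ndarray) -> np.ndarray:
        """Reshape per-state values onto the (row, col) grid; NaN off-map."""
        side = 2 * self.config.room_size + 1
        g = np.full((side, side), np.nan)
        for i, (r, c) in enumerate(self.space.coordinates):
            g[r, c] = values[i]
        return g


@dataclass
class CoverageResult:
    composed: np.ndarray  # coverage percentages
    segmented: np.ndarray
    u_statistic: float
    p_value: float  # one-sided, composed > segmented
    n_composed: int
    n_segmented: int
    truncated_composed: int
    composed_sequences: list[SampledSequence] = field(repr=False, default_factory=list)
    segmented_sequences: list[SampledSequence] = field(repr=False, default_factory=list)
    config: ReplayConfig | None = field(repr=False, default=None)
    space: StateSpace | None = field(repr=False, default=None)

    def __post_init__(self) -> None:
        for arr in (self.composed, self.segmented):
            if len(arr) and (min(arr) < 0 or max(arr) > 100):
                raise ValueError("coverages must lie in [0, 100]")


@dataclass
class RateMap:
    """Firing map of one lap-by-track unit over initialisation states."""

    unit: int
    unit_lap: int  # 1-based
    unit_pos: int
    rates: np.ndarray  # (n_laps, n_track)
    lap_peaks: np.ndarray  # (n_laps,)
    preferred_lap: int  # 1-based, argmax of lap_peaks, ties -> lowest
    lap_preferring: bool  # active on >= 2 laps with a strict peak maximum

    def __post_init__(self) -> None:
        if self.rates.min() < 0:
            raise ValueError("rate maps must be non-negative")


@dataclass
class EsrResult:
    space: StateSpace
    rate_maps: list[RateMap]
    own_lap_fraction: float  # units whose max sits on their own lap
    n_lap_preferring: int
    commutator_max: float  # max |[lifted lap, lifted track]| (must be 0)
    config: EsrConfig


# ----------------------------------------------------------------------
# Coverage statistic and rank test
# ----------------------------------------------------------------------

def coverage(
    seq: SampledSequence, space: StateSpace, start: int, goal: int
) -> float:
    """Percent of the start->goal geodesic visited by the sequence.

    ``100 * |distinct geodesic states visited| / geodesic length``, with the
    geodesic from :func:`shortest_path_states`.  A sequence that never
    leaves ``start`` scores ``100 / L``.
    """
    geodesic = shortest_path_states(space, start, goal)
    visited = set(seq.states)
    return 100.0 * len(visited.intersection(geodesic)) / len(geodesic)


def choose_goal(
    seq: SampledSequence, space: StateSpace, start: int, candidates: Sequence[int]
) -> int:
    """Pick the candidate goal whose geodesic the sequence overlaps most.

    Ties resolve to the earliest-listed candidate (the left arm end when
    candidates are listed left-first).
    """
    best, best_overlap = candidates[0], -1
    for cand in candidates:
        geo = set(shortest_path_states(space, start, cand))
        overlap = len(geo.intersection(seq.states))
        if overlap > best_overlap:
            best, best_overlap = cand, overlap
    return best


def rank_test_greater(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """One-sided Mann-Whitney U test of ``x`` stochastically greater than ``y``.

    Exact null distribution for tie-free samples below 8 per group;
    otherwise the normal approximation with mid-ranks and tie-corrected
    variance.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    small = len(x) < 8 and len(y) < 8
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = scipy.stats.mannwhitneyu(x, y, alternative="greater", method=method)
    return float(res.statistic), float(res.pvalue)


# ----------------------------------------------------------------------
# Experiment 1: explore + avoid
# ----------------------------------------------------------------------

def run_explore_avoid(config: ExploreAvoidConfig | None = None) -> ExploreAvoidResult:
    """Four-room exploration with the avoid-room propagator stacked in.

    Both conditions run the same two-layer stacked network so that network
    depth (total integrated time per pass) is matched: the avoidance
    condition stacks the exploration propagator with the avoid-room
    propagator, while the control stacks it with the degenerate ``c = 1``
    avoid layer (which equals the exploration propagator).  Any difference
    between the two propagation densities is therefore attributable to the
    avoidance content alone, and at ``c = 1`` the difference map is
    identically zero.
    """
    cfg = config or ExploreAvoidConfig()
    space = build_four_room(cfg.room_size)
    explore = random_walk_generator(space, label="explore")
    avoid = avoid_region(explore, cfg.avoid_room, cfg.c)

    basis_explore = decompose(explore)
    basis_avoid = decompose(avoid)
    p_explore_layer = build_propagator(basis_explore, cfg.tau, cfg.alpha, cfg.dt)
    p_avoid = build_propagator(basis_avoid, cfg.tau, cfg.alpha, cfg.dt)
    p_explore = stack_propagators([p_explore_layer, p_explore_layer])  # control
    p_stack = stack_propagators([p_explore_layer, p_avoid])

    # start at the centre of the top-left room
    r = cfg.room_size
    start = space.state_at((r // 2, r // 2))

    rng = sequence_stream(cfg.seed)
    samples_explore = [
        sample_sequence(start, p_explore, 2, cfg.seed, _rng=rng).states[1]
        for _ in range(cfg.n_step_samples)
    ]
    samples_stack = [
        sample_sequence(start, p_stack, 2, cfg.seed, _rng=rng).states[1]
        for _ in range(cfg.n_step_samples)
    ]

    rho0 = np.zeros(space.n_states)
    rho0[start] = 1.0
    dens_explore = propagate(rho0, p_explore, cfg.horizon).densities[-1]
    dens_stack = propagate(rho0, p_stack, cfg.horizon).densities[-1]

    room = space.region(cfg.avoid_room)
    components = {
        "explore": np.stack(
            [basis_explore.component(k) for k in range(cfg.n_components)]
        ),
        "avoid": np.stack(
            [basis_avoid.component(k) for k in range(cfg.n_components)]
        ),
    }
    return ExploreAvoidResult(
        space=space,
        start=start,
        step_samples_explore=samples_explore,
        step_samples_stack=samples_stack,
        density_explore=dens_explore,
        density_stack=dens_stack,
        room_mass_explore=float(dens_explore[room].sum()),
        room_mass_stack=float(dens_stack[room].sum()),
        spectral_components=components,
        config=cfg,
    )


# ----------------------------------------------------------------------
# Experiment 2: extended replay
# ----------------------------------------------------------------------

def _replay_machinery(cfg: ReplayConfig):
    space = build_t_maze(cfg.central_len, cfg.arm_len)
    junction = space.region("junction")[0]
    left_end = max(space.region("left_arm"))
    right_end = max(space.region("right_arm"))
    central = directed_region_generator(
        space, "central_arm",
        toward_target_direction_map(space, "central_arm", junction),
        cfg.drift, label="central",
    )
    # the lateral behavioural component encodes the turn: its directed
    # region is the left arm plus the junction, so sequences handed off at
    # the junction flow into the arm instead of dithering there
    space.regions["left_arm_ext"] = space.regions["left_arm"] | space.regions["junction"]
    lateral = directed_region_generator(
        space, "left_arm_ext",
        toward_target_direction_map(space, "left_arm_ext", left_end),
        cfg.drift, label="lateral",
    )
    p_central = propagator_for(central, cfg.tau, cfg.alpha, cfg.dt)
    p_lateral = propagator_for(lateral, cfg.tau, cfg.alpha, cfg.dt)
    return space, junction, left_end, right_end, p_central, p_lateral


def run_extended_replay(config: ReplayConfig | None = None) -> CoverageResult:
    """Composed (sequenced) vs segmented replay on the T-maze.

    Segmented condition (per event): independent fixed-initialisation
    samples of ``length`` states — half start at the corridor base under the
    central-directed propagator, half at the junction under the
    lateral-directed propagator — each scored on its own spatial coverage of
    the base-to-arm-end geodesic.  Composed condition (per burst): the
    sequencing sampler concatenates two events — the central propagator
    runs until the junction is reached (or its ``length`` budget runs out),
    then hands off to the lateral propagator for a second segment of up to
    ``length`` states — so a composed trajectory may extend up to twice an
    individual event, exactly because it is a concatenation.  Coverage is
    compared with a one-sided Mann-Whitney U test (composed greater).

    With ``null_mode=True`` both groups are composed sequences from disjoint
    seeds — the calibration configuration in which the test should be null.
    """
    cfg = config or ReplayConfig()
    space, junction, left_end, right_end, p_central, p_lateral = _replay_machinery(cfg)
    start = space.start_state
    goals = (left_end, right_end)  # left listed first: ties go left
    n = cfg.n_sequences

    # each stage is one replay event of up to `length` states: hand off on
    # junction entry or when the event budget runs out, whichever first
    def composed_seq(idx: int) -> SampledSequence:
        return sequencing_sample(
            [(p_central, ("junction", cfg.length)), (p_lateral, cfg.length)],
            x0=start, seed=cfg.seed, max_steps=2 * cfg.length, space=space,
            _rng=sequence_stream(cfg.seed, idx),
        )

    composed = [composed_seq(i) for i in range(n)]
    if cfg.null_mode:
        segmented = [composed_seq(n + i) for i in range(n)]
    else:
        segmented = []
        for i in range(n):
            if i % 2 == 0:
                segmented.append(
                    sample_sequence(start, p_central, cfg.length, cfg.seed,
                                    _rng=sequence_stream(cfg.seed, n + i))
                )
            else:
                segmented.append(
                    sample_sequence(junction, p_lateral, cfg.length, cfg.seed,
                                    _rng=sequence_stream(cfg.seed, n + i))
                )

    def score(seq: SampledSequence) -> float:
        goal = choose_goal(seq, space, start, goals)
        return coverage(seq, space, start, goal)

    cov_composed = np.array([score(s) for s in composed])
    cov_segmented = np.array([score(s) for s in segmented])
    n_trunc = sum(s.truncated for s in composed)
    if n_trunc > 0.2 * len(composed):
        raise RuntimeError(
            f"{n_trunc}/{len(composed)} composed sequences truncated before "
            "hand-off; increase the length budget or the drift"
        )
    u, p = rank_test_greater(cov_composed, cov_segmented)
    return CoverageResult(
        composed=cov_composed, segmented=cov_segmented,
        u_statistic=u, p_value=p,
        n_composed=len(composed), n_segmented=len(segmented),
        truncated_composed=n_trunc,
        composed_sequences=composed, segmented_sequences=segmented,
        config=cfg, space=space,
    )


# ----------------------------------------------------------------------
# Experiment 3: event-specific rate remapping
# ----------------------------------------------------------------------

ACTIVE_REL_TOL = 1e-9  # a lap counts as active above this fraction of the peak


def run_esr(config: EsrConfig | None = None) -> EsrResult:
    """Lap-by-track rate maps from the conjunctive lap + track composition.

    The track generator drives a counterclockwise traversal of a square
    perimeter; the lap generator advances an abstract lap variable.  Both
    are lifted to the lap-by-track product space via identity embeddings
    (their commutator is exactly zero — verified, any nonzero entry raises)
    and composed conjunctively with weights ``(tau_box, tau_lap)``.  Each
    unit's firing map over initialisation states is the k-step propagated
    density evaluated at that unit; the preferred lap is the argmax over
    laps of the unit's peak rate (ties to the lowest lap).  A unit *shows
    lap preference* (rate remapping) only if it is active on at least two
    laps with a strict peak maximum — a unit confined to a single lap has
    nothing to remap across.
    """
    cfg = config or EsrConfig()
    track = build_track_loop(cfg.side)
    n_track = track.n_states
    order = [track.state_at(c) for c in perimeter_cycle(cfg.side)]
    box = directed_region_generator(
        track, "track", cycle_direction_map(order), cfg.drift, label="box",
    )
    lap = lap_generator(cfg.n_laps, cfg.advance_rate, cyclic=cfg.cyclic_laps)
    product = build_product_space(track, cfg.n_laps)
    lifted_lap, lifted_box = kronecker_sum(lap, box, product)

    comm = commutator(lifted_lap, lifted_box)
    comm_max = float(np.abs(comm).max())
    if comm_max != 0.0:
        raise RuntimeError(
            f"lifted lap/track generators do not commute (max |[.,.]| = "
            f"{comm_max:.3e}); the identity embedding is broken"
        )

    plan = CompositionPlan(
        components=[(lifted_box, cfg.tau_box), (lifted_lap, cfg.tau_lap)],
        mode="conjunctive",
    )
    prop = compose_generators(plan)
    Pk = np.linalg.matrix_power(prop.matrix, cfg.k)

    maps: list[RateMap] = []
    own_lap_hits = 0
    for u in range(product.n_states):
        lap_u, pos_u = product.coordinates[u]
        rates = Pk[:, u].reshape(cfg.n_laps, n_track)
        peaks = rates.max(axis=1)
        preferred = int(np.argmax(peaks)) + 1  # argmax returns lowest on ties
        active = peaks > ACTIVE_REL_TOL * peaks.max()
        strict = active.sum() >= 2 and np.sum(peaks == peaks.max()) == 1
        maps.append(RateMap(
            unit=u, unit_lap=lap_u + 1, unit_pos=pos_u,
            rates=rates, lap_peaks=peaks,
            preferred_lap=preferred, lap_preferring=bool(strict),
        ))
        own_lap_hits += preferred == lap_u + 1
    return EsrResult(
        space=product,
        rate_maps=maps,
        own_lap_fraction=own_lap_hits / product.n_states,
        n_lap_preferring=sum(m.lap_preferring for m in maps),
        commutator_max=comm_max,
        config=cfg,
    )


# ----------------------------------------------------------------------
# Output writers (TSV sequences, CSV grids, JSON summaries)
# ----------------------------------------------------------------------

def _sequence_frame(seqs: list[SampledSequence], space: StateSpace, condition: str) -> pd.DataFrame:
    rows = []
    for si, seq in enumerate(seqs):
        seg = 0
        for step, state in enumerate(seq.states):
            if step in seq.segment_boundaries:
                seg += 1
            r, c = space.coordinates[state]
            region = next(
                (name for name, states in sorted(space.regions.items())
                 if state in states), "",
            )
            rows.append({
                "condition": condition, "sequence": si, "step": step,
                "state_index": state, "row": r, "col": c, "region": region,
                "propagator_label": seq.propagator_labels[step] if seq.propagator_labels else "",
                "segment_id": seg, "truncated": seq.truncated,
            })
    return pd.DataFrame(rows)


def write_explore_avoid(result: ExploreAvoidResult, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    np.savetxt(out / "density_explore.csv", result.grid(result.density_explore), delimiter=",")
    np.savetxt(out / "density_stack.csv", result.grid(result.density_stack), delimiter=",")
    np.savetxt(out / "density_difference.csv", result.grid(result.density_difference), delimiter=",")
    for label, comps in result.spectral_components.items():
        for k, comp in enumerate(comps):
            np.savetxt(out / f"component_{label}_{k}.csv", result.grid(comp), delimiter=",")
    summary = {
        "experiment": "explore-avoid",
        "config": dataclasses.asdict(result.config),
        "start_state": result.start,
        "step_samples_explore": result.step_samples_explore,
        "step_samples_stack": result.step_samples_stack,
        "room_mass_explore": result.room_mass_explore,
        "room_mass_stack": result.room_mass_stack,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1))


def write_replay(result: CoverageResult, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    frames = [
        _sequence_frame(result.composed_sequences, result.space, "composed"),
        _sequence_frame(result.segmented_sequences, result.space, "segmented"),
    ]
    pd.concat(frames).to_csv(out / "sequences.tsv", sep="\t", index=False)
    summary = {
        "experiment": "extended-replay",
        "config": dataclasses.asdict(result.config),
        "coverage_composed_mean": float(result.composed.mean()),
        "coverage_segmented_mean": float(result.segmented.mean()),
        "coverage_composed": result.composed.tolist(),
        "coverage_segmented": result.segmented.tolist(),
        "u_statistic": result.u_statistic,
        "p_value": result.p_value,
        "n_composed": result.n_composed,
        "n_segmented": result.n_segmented,
        "truncated_composed": result.truncated_composed,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1))


def write_esr(result: EsrResult, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    table = pd.DataFrame({
        "unit": [m.unit for m in result.rate_maps],
        "unit_lap": [m.unit_lap for m in result.rate_maps],
        "unit_pos": [m.unit_pos for m in result.rate_maps],
        "preferred_lap": [m.preferred_lap for m in result.rate_maps],
        "lap_preferring": [m.lap_preferring for m in result.rate_maps],
    })
    table.to_csv(out / "units.tsv", sep="\t", index=False)
    # full per-unit maps are bulky; store the stacked array once
    stacked = np.stack([m.rates for m in result.rate_maps])
    np.savetxt(
        out / "rate_maps.csv",
        stacked.reshape(len(result.rate_maps), -1),
        delimiter=",",
    )
    summary = {
        "experiment": "esr",
        "config": dataclasses.asdict(result.config),
        "own_lap_fraction": result.own_lap_fraction,
        "n_units": len(result.rate_maps),
        "n_lap_preferring": result.n_lap_preferring,
        "commutator_max": result.commutator_max,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
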