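"""Density propagation and state-sequence sampling.

Densities evolve by iterated propagator application, ``rho_{t+1} = rho_t P``;
sequences are realised by recursively sampling ``x_t ~ e_{x_{t-1}} P`` from
one-hot initialisations.  The sequencing sampler concatenates segments from
different propagators in time — only one dynamical system is active at any
moment — which is the mechanism behind extended (multi-segment) replay.

Randomness comes from one counter-based Philox stream per sequence, keyed by
``(seed, sequence_index)``, so batches are bit-reproducible and independent
of execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .spectral import Propagator, SpectralError
from .state_spaces import StateSpace

__all__ = [
    "DensityTrajectory",
    "SampledSequence",
    "propagate",
    "sample_sequence",
    "sequencing_sample",
    "sequence_stream",
]

DENSITY_TOL = 1e-9
DRIFT_TOL = 1e-12


@dataclass
class DensityTrajectory:
    """Ordered probability row vectors ``rho_t`` with their step indices."""

    densities: np.ndarray  # (steps+1, n)
    times: np.ndarray  # (steps+1,)

    def __post_init__(self) -> None:
        self.densities = np.asarray(self.densities, dtype=float)
        if self.densities.min() < 0:
            raise ValueError("densities must be non-negative")
        err = np.abs(self.densities.sum(axis=1) - 1.0).max()
        if err > DENSITY_TOL:
            raise ValueError(f"densities must sum to 1; worst deviation {err:.3e}")

    def __len__(self) -> int:
        return self.densities.shape[0]


@dataclass
class SampledSequence:
    """A realised state sequence plus the provenance of each transition."""

    states: list[int]
    seed: int
    propagator_labels: list[str] = field(default_factory=list)
    segment_boundaries: list[int] = field(default_factory=list)
    truncated: bool = False

    def __post_init__(self) -> None:
        if len(self.states) < 1:
            raise ValueError("sequence must contain at least one state")
        if self.propagator_labels and len(self.propagator_labels) != len(self.states):
            raise ValueError("one propagator label required per state")
        if self.segment_boundaries != sorted(set(self.segment_boundaries)):
            raise ValueError("segment boundaries must be strictly increasing")
        for b in self.segment_boundaries:
            if not 0 < b < len(self.states):
                raise ValueError(f"segment boundary {b} out of range")

    def __len__(self) -> int:
        return len(self.states)


def sequence_stream(seed: int, index: int = 0) -> np.random.Generator:
    """Counter-based random stream for sequence ``index`` of batch ``seed``."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(int(index),))
    return np.random.Generator(np.random.Philox(ss))


def propagate(rho0: np.ndarray, prop: Propagator, steps: int) -> DensityTrajectory:
    """Trajectory ``[rho0, rho0 P, rho0 P^2, ...]`` of length ``steps + 1``.

    Each vector is renormalised when round-off drift exceeds 1e-12, so total
    probability is conserved exactly along arbitrarily long horizons.
    """
    rho = np.asarray(rho0, dtype=float)
    if rho.shape != (prop.n_states,):
        raise ValueError(
            f"density has {rho.shape} entries, propagator expects {prop.n_states}"
        )
    if rho.min() < 0 or abs(rho.sum() - 1.0) > DENSITY_TOL:
        raise ValueError("rho0 must be a probability vector")
    if steps < 0:
        raise ValueError("steps must be >= 0")
    out = np.empty((steps + 1, prop.n_states))
    out[0] = rho
    for t in range(1, steps + 1):
        rho = rho @ prop.matrix
        s = rho.sum()
        if abs(s - 1.0) > DRIFT_TOL:
            rho = rho / s
        out[t] = rho
    return DensityTrajectory(out, np.arange(steps + 1))


def _draw(row: np.ndarray, rng: np.random.Generator) -> int:
    """Inverse-CDF categorical draw (bit-stable across platforms)."""
    s = row.sum()
    if abs(s - 1.0) > DENSITY_TOL:
        raise SpectralError(f"propagator row sums to {s!r}, not 1")
    cdf = np.cumsum(row / s)
    return int(np.searchsorted(cdf, rng.random(), side="right"))


def sample_sequence(
    x0: int,
    prop: Propagator,
    length: int,
    seed: int,
    _rng: np.random.Generator | None = None,
) -> SampledSequence:
    """Sample ``length`` states starting from ``x0`` under one propagator.

    Bit-reproducible for a given ``(propagator, x0, length, seed)``.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0 <= x0 < prop.n_states:
        raise IndexError(f"start state {x0} out of range")
    rng = _rng if _rng is not None else sequence_stream(seed)
    states = [int(x0)]
    for _ in range(length - 1):
        states.append(_draw(prop.matrix[states[-1]], rng))
    return SampledSequence(
        states=states, seed=seed,
        propagator_labels=[prop.label] * length,
    )


StageSpec = tuple[Propagator, "str | int | tuple[str, int]"]


def sequencing_sample(
    stages: Sequence[StageSpec],
    x0: int,
    seed: int,
    max_steps: int,
    space: StateSpace | None = None,
    _rng: np.random.Generator | None = None,
) -> SampledSequence:
    """Temporal concatenation: sample each stage's propagator in turn.

    Each stage is ``(propagator, hand_off)`` where ``hand_off`` is a region
    name — leave the stage as soon as the sampled state enters that region
    (typically the next stage's operating region) — an integer budget of
    states the stage may emit (the first stage's budget includes ``x0``),
    or a ``(region, budget)`` pair that fires on whichever condition is met
    first.  A region hand-off requires ``space``.  If a region hand-off
    never fires within ``max_steps`` the sequence is returned with
    ``truncated=True`` rather than raising; the final stage simply runs out
    the remaining budget.

    A single-stage call with budget ``b`` consumes the random stream exactly
    like ``sample_sequence(x0, prop, b, seed)`` and returns the identical
    sequence.
    """
    if not stages:
        raise ValueError("need at least one stage")
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    rng = _rng if _rng is not None else sequence_stream(seed)
    states = [int(x0)]
    labels: list[str] = [stages[0][0].label]
    boundaries: list[int] = []
    truncated = False

    def in_region(state: int, name: str) -> bool:
        if space is None:
            raise ValueError("region hand-offs require the state space")
        return state in space.regions[name]

    stage_idx = 0
    emitted_in_stage = 1  # x0 counts against the first stage's budget
    while len(states) < max_steps:
        prop, hand_off = stages[stage_idx]
        if isinstance(hand_off, str):
            fired = in_region(states[-1], hand_off)
        elif isinstance(hand_off, tuple):
            region, budget = hand_off
            fired = in_region(states[-1], region) or emitted_in_stage >= int(budget)
        else:
            fired = emitted_in_stage >= int(hand_off)
        if fired:
            if stage_idx + 1 < len(stages):
                stage_idx += 1
                emitted_in_stage = 0
                boundaries.append(len(states))
                continue
            break  # final stage exhausted its budget
        prop = stages[stage_idx][0]
        states.append(_draw(prop.matrix[states[-1]], rng))
        labels.append(prop.label)
        emitted_in_stage += 1
    else:
        # ran into max_steps; truncated only if a later stage never started
        if stage_idx + 1 < len(stages):
            truncated = True
    # a boundary recorded at len(states) (hand-off fired on the final state)
    # would be out of range; drop it
    boundaries = [b for b in boundaries if b < len(states)]
    return SampledSequence(
        states=states, seed=seed, propagator_labels=labels,
        segment_boundaries=boundaries, truncated=truncated,
    )
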