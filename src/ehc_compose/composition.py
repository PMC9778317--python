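"""Composing dynamical systems: stacking, conjunction, and interfaces.

Three mechanisms combine generators / propagators:

* **Stacking** — the ordered matrix product ``P1 P2 ... Pn`` of propagators,
  a logical AND across dynamics.  Order matters whenever the propagators do
  not commute.
* **Conjunctive composition** — exponentiate a single weighted sum
  ``sum_i w_i O_i`` (any non-negative combination of generators is again a
  generator).  Exact, but requires building a dedicated combined generator.
* **Interfacing composition** — approximate ``exp(t(A+B))`` by the product
  ``exp(tA) exp(tB) exp(t^2 C2) exp(t^3 C3) ...`` of the component
  exponentials and exponentiated correction terms built from nested
  commutators (a truncated Zassenhaus expansion).  The corrections form a
  distinct "interface" dynamical system encoding the interactions between
  noncommuting components; for commuting components every correction
  vanishes and the interface reduces to plain stacking.

Correction matrices are generally not valid generators (they can carry
negative off-diagonal entries); they are exponentiated by plain series and
only the final product is required to be row-stochastic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .generators import Generator, GeneratorError
from .spectral import (
    Propagator,
    SpectralError,
    _sanitize,
    propagator_for,
)

__all__ = [
    "CompositionPlan",
    "ZassenhausSeries",
    "commutator",
    "stack_propagators",
    "compose_generators",
    "zassenhaus_terms",
    "interface_propagator",
]


@dataclass
class CompositionPlan:
    """An ordered list of weighted generators plus how to combine them.

    ``mode`` is one of ``stack``, ``conjunctive``, ``interface``;
    ``interface_order`` (1..4) is the number of Zassenhaus factors retained
    (1 = the two leading exponentials only, i.e. naive stacking).  ``tau``,
    ``alpha`` and ``dt`` are forwarded to the propagator construction.
    """

    components: list[tuple[Generator, float]]
    mode: str = "conjunctive"
    interface_order: int = 2
    tau: float = 1.0
    alpha: float = 1.0
    dt: float = 1.0

    def __post_init__(self) -> None:
        if not self.components:
            raise GeneratorError("composition plan needs at least one component")
        weights = [w for _, w in self.components]
        if any(w < 0 for w in weights):
            raise GeneratorError("component weights must be >= 0")
        if not any(w > 0 for w in weights):
            raise GeneratorError("at least one component weight must be > 0")
        spaces = {id(g.space) for g, _ in self.components}
        if len(spaces) > 1:
            dims = {g.n_states for g, _ in self.components}
            if len(dims) > 1:
                raise GeneratorError(
                    f"components act on different state spaces (sizes {sorted(dims)})"
                )
        if self.mode not in ("stack", "conjunctive", "interface"):
            raise GeneratorError(f"unknown composition mode {self.mode!r}")

    @property
    def space(self):
        return self.components[0][0].space


@dataclass
class ZassenhausSeries:
    """Leading factors and nested-commutator corrections for one pair.

    ``corrections`` is a list of ``(time_power, matrix)`` pairs: the factor
    contributed at evaluation time t is ``exp(t**time_power * matrix)``.
    """

    leading_factors: tuple[np.ndarray, np.ndarray]
    corrections: list[tuple[int, np.ndarray]]
    order: int


def _as_matrix(x: Generator | np.ndarray) -> np.ndarray:
    return x.matrix if isinstance(x, Generator) else np.asarray(x, dtype=float)


def commutator(a: Generator | np.ndarray, b: Generator | np.ndarray) -> np.ndarray:
    """Matrix commutator ``[a, b] = ab - ba`` (row-vector convention: a first)."""
    A, B = _as_matrix(a), _as_matrix(b)
    if A.shape != B.shape:
        raise GeneratorError(f"dimension mismatch {A.shape} vs {B.shape}")
    if isinstance(a, Generator) and isinstance(b, Generator):
        if a.space is not b.space and a.n_states != b.n_states:
            raise GeneratorError("generators act on different state spaces")
    return A @ B - B @ A


def stack_propagators(props: Sequence[Propagator]) -> Propagator:
    """Ordered product ``P1 P2 ... Pn`` — the AND composition ``P1 ^ ... ^ Pn``.

    The caller's order is respected (row-vector convention: the first
    propagator acts first).  The product of row-stochastic matrices is
    row-stochastic up to round-off; the result is re-sanitised.
    """
    if not props:
        raise SpectralError("need at least one propagator to stack")
    n = props[0].n_states
    M = props[0].matrix.copy()
    for p in props[1:]:
        if p.n_states != n:
            raise SpectralError("stacked propagators must share one state space")
        M = M @ p.matrix
    P, clip = _sanitize(M, "stacked propagator")
    first = props[0]
    return Propagator(
        matrix=P, tau=first.tau, alpha=first.alpha, dt=first.dt,
        clip_magnitude=clip,
        label="^".join(p.label or "?" for p in props),
    )


def _weighted_sum(plan: CompositionPlan) -> Generator:
    S = sum(w * g.matrix for g, w in plan.components)
    label = "+".join(
        f"{w:g}*{g.label or '?'}" for g, w in plan.components if w > 0
    )
    return Generator(S, plan.space, label=label)


def compose_generators(plan: CompositionPlan) -> Propagator:
    """Conjunctive composition: propagator of the summed generator.

    ``P = exp(dt/tau * sum_i w_i O_i)`` built spectrally when the sum is
    diagonalisable, by series fallback otherwise.  An invalid weighted sum
    (e.g. a weight that breaks the generator invariants) raises.
    """
    if plan.mode != "conjunctive":
        raise GeneratorError(f"compose_generators requires mode='conjunctive', got {plan.mode!r}")
    combined = _weighted_sum(plan)
    prop = propagator_for(combined, tau=plan.tau, alpha=plan.alpha, dt=plan.dt)
    prop.meta["mode"] = "conjunctive"
    return prop


# ----------------------------------------------------------------------
# Zassenhaus expansion
# ----------------------------------------------------------------------

def zassenhaus_terms(
    a: Generator | np.ndarray,
    b: Generator | np.ndarray,
    order: int,
) -> ZassenhausSeries:
    """Correction terms of ``exp(t(A+B)) ~= exp(tA) exp(tB) prod exp(t^n Cn)``.

    Supported orders 1..4.  With the leading factors in the written order,

        C2 = -[A,B]/2
        C3 =  [B,[A,B]]/3 + [A,[A,B]]/6
        C4 = -[A,[A,[A,B]]]/24 - [B,[A,[A,B]]]/8 - [B,[B,[A,B]]]/8

    The convention was pinned by requiring the truncated product to converge
    to the direct exponential with increasing order (the residual scales as
    ``t^(order+1)``); commuting inputs give identically zero corrections.
    """
    if order not in (1, 2, 3, 4):
        raise GeneratorError(f"order must be in 1..4, got {order}")
    A, B = _as_matrix(a), _as_matrix(b)
    if A.shape != B.shape:
        raise GeneratorError(f"dimension mismatch {A.shape} vs {B.shape}")
    corrections: list[tuple[int, np.ndarray]] = []
    if order >= 2:
        c = A @ B - B @ A
        corrections.append((2, -0.5 * c))
        if order >= 3:
            Ac = A @ c - c @ A
            Bc = B @ c - c @ B
            corrections.append((3, Bc / 3.0 + Ac / 6.0))
            if order >= 4:
                AAc = A @ Ac - Ac @ A
                BAc = B @ Ac - Ac @ B
                BBc = B @ Bc - Bc @ B
                corrections.append((4, -AAc / 24.0 - BAc / 8.0 - BBc / 8.0))
    return ZassenhausSeries(leading_factors=(A, B), corrections=corrections, order=order)


def _expm_taylor(M: np.ndarray, n_terms: int = 40) -> np.ndarray:
    """Series exponential with scaling-and-squaring for numerical safety."""
    norm = np.abs(M).sum(axis=1).max()
    s = max(0, int(np.ceil(np.log2(norm))) if norm > 1 else 0)
    X = M / (2 ** s)
    n = M.shape[0]
    term = np.eye(n)
    acc = np.eye(n)
    for k in range(1, n_terms + 1):
        term = term @ X / k
        acc = acc + term
    for _ in range(s):
        acc = acc @ acc
    return acc


def _zassenhaus_bound(A: np.ndarray, B: np.ndarray, t: float, order: int) -> float:
    """Generous order-implied residual bound used as a sign/order bug detector."""
    c = np.abs(A).sum(axis=1).max() + np.abs(B).sum(axis=1).max()
    return (c * t) ** (order + 1) * float(np.exp(c * t))


def interface_propagator(plan: CompositionPlan) -> Propagator:
    """Interfacing composition via the truncated Zassenhaus product.

    For two components the result is
    ``exp(tA) exp(tB) exp(t^2 C2) ... `` at ``t = dt/tau`` with
    ``A = w1 O1``, ``B = w2 O2``; additional components are folded in
    left-to-right (pairwise interfaces).  ``meta`` records the truncation
    order and the max-entry residual against the exact conjunctive
    propagator; a residual above 10x the order-implied bound raises, which
    catches sign/order convention bugs.  Requires ``alpha = 1``.
    """
    if plan.mode != "interface":
        raise GeneratorError(
            f"interface_propagator requires mode='interface', got {plan.mode!r}"
        )
    if plan.alpha != 1:
        raise GeneratorError("interfacing composition is defined for alpha = 1")
    if len(plan.components) < 2:
        raise GeneratorError("interfacing composition needs >= 2 components")
    t = plan.dt / plan.tau
    order = plan.interface_order
    mats = [w * g.matrix for g, w in plan.components]
    # left fold of pairwise interfaces: the accumulated product stands in
    # for exp(t * A_acc) and each new component contributes its leading
    # exponential plus the corrections between A_acc and itself
    A = mats[0]
    M = _expm_taylor(t * A)
    for B in mats[1:]:
        M = M @ _expm_taylor(t * B)
        for power, C in zassenhaus_terms(A, B, order).corrections:
            M = M @ _expm_taylor((t ** power) * C)
        A = A + B
    total = sum(mats)
    exact = _expm_taylor(t * total)
    residual = float(np.abs(M - exact).max())
    bound = _zassenhaus_bound(mats[0], total - mats[0], t, order)
    if residual > 10 * max(bound, 1e-12):
        raise SpectralError(
            f"interface residual {residual:.3e} exceeds 10x the order-{order} "
            f"bound {bound:.3e}: sign or factor-order bug"
        )
    # negatives up to the truncation error are expected: M = exact + E with
    # exact >= 0, so min(M) >= -||E||; anything beyond that still raises
    P, clip = _sanitize(
        M, "interface propagator", tol=max(1e-6, 2.0 * residual)
    )
    prop = Propagator(
        matrix=P, tau=plan.tau, alpha=plan.alpha, dt=plan.dt,
        clip_magnitude=clip,
        label="|".join(g.label or "?" for g, _ in plan.components),
    )
    prop.meta.update(
        mode="interface", interface_order=order,
        residual_vs_conjunctive=residual,
    )
    return prop
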