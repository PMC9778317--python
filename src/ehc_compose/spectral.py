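"""Spectral propagators: eigendecomposition, power spectrum, matrix exponential.

The one-step propagator of a generator ``O`` is ``P = exp(dt/tau * O)``.
Diagonalising ``O = G L W`` (``W = G^-1``) turns exponentiation into a
per-eigenvalue gain — the *power spectrum* ``s(lambda)`` — applied between
two synaptic layers: the columns of ``G`` play the role of grid-cell firing
maps (spectral components), ``W`` maps the spectral code back to place
space, and modulating the gain changes the sequence statistics without
touching the weights:

* tempo ``tau`` rescales time: ``s(lambda) = exp(dt/tau * lambda)``,
* stability ``alpha < 1`` produces superdiffusive, jumpy sequences via
  ``s(lambda) = exp(-dt/tau * (-lambda)^alpha)`` (principal branch; equal to
  ``exp(-dt/tau * |lambda|^alpha)`` on the real non-positive axis).

A truncated power-series exponential doubles as the package's internal
oracle and as the fallback for non-diagonalisable generators (absorbing lap
chains are the canonical example).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .generators import Generator

__all__ = [
    "SpectralBasis",
    "Propagator",
    "SpectralError",
    "decompose",
    "power_spectrum",
    "build_propagator",
    "series_propagator",
    "propagator_for",
]

RECON_TOL = 1e-8
SPECTRUM_TOL = 1e-10
CLIP_TOL = 1e-6
ROW_TOL = 1e-9
COND_LIMIT = 1e12


class SpectralError(ValueError):
    pass


@dataclass
class SpectralBasis:
    """Eigendecomposition ``O = G diag(eigenvalues) W`` of a generator.

    Columns of ``G`` are the spectral components (the model's grid-cell
    maps); ``W = G^-1``.  Eigenvalues are sorted by descending real part,
    ties by ascending imaginary part, so bases are reproducible.
    """

    G: np.ndarray
    eigenvalues: np.ndarray
    W: np.ndarray
    source: Generator

    def __post_init__(self) -> None:
        n = self.source.n_states
        recon = self.G @ np.diag(self.eigenvalues) @ self.W
        err = np.abs(recon - self.source.matrix).max()
        if err > RECON_TOL:
            raise SpectralError(f"G L W reconstruction error {err:.3e} > {RECON_TOL}")
        ident = np.abs(self.G @ self.W - np.eye(n)).max()
        if ident > RECON_TOL:
            raise SpectralError(f"G W deviates from identity by {ident:.3e}")
        worst = self.eigenvalues.real.max()
        if worst > SPECTRUM_TOL:
            raise SpectralError(
                f"generator spectrum leaks into the right half-plane: "
                f"max Re(lambda) = {worst:.3e}"
            )

    def component(self, k: int) -> np.ndarray:
        """Real part of the k-th spectral component (eigenvector)."""
        return self.G[:, k].real.copy()


@dataclass
class Propagator:
    """Row-stochastic one-step transition matrix built from a generator.

    ``clip_magnitude`` records the largest negative raw entry removed during
    sanitisation (round-off diagnostics — genuine violations raise instead).
    """

    matrix: np.ndarray
    tau: float = 1.0
    alpha: float = 1.0
    dt: float = 1.0
    basis: SpectralBasis | None = None
    clip_magnitude: float = 0.0
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        P = self.matrix
        if P.min() < 0:
            raise SpectralError(f"negative propagator entry {P.min():.3e}")
        err = np.abs(P.sum(axis=1) - 1.0).max()
        if err > ROW_TOL:
            raise SpectralError(f"rows must sum to 1; worst deviation {err:.3e}")

    @property
    def n_states(self) -> int:
        return self.matrix.shape[0]


# ----------------------------------------------------------------------

def decompose(gen: Generator) -> SpectralBasis:
    """Diagonalise a generator into a :class:`SpectralBasis`.

    Raises :class:`SpectralError` when the eigenvector matrix is numerically
    singular (condition estimate above 1e12), e.g. for defective generators
    such as an absorbing lap chain; callers should fall back to
    :func:`series_propagator`.
    """
    lam, G = scipy.linalg.eig(gen.matrix)
    order = np.lexsort((lam.imag, -lam.real))
    lam, G = lam[order], G[:, order]
    cond = np.linalg.cond(G)
    if not np.isfinite(cond) or cond > COND_LIMIT:
        raise SpectralError(
            f"eigenvector matrix condition {cond:.3e} exceeds {COND_LIMIT:.0e}; "
            "generator is (near-)defective — use series_propagator instead"
        )
    W = np.linalg.inv(G)
    return SpectralBasis(G=G, eigenvalues=lam, W=W, source=gen)


def power_spectrum(
    lam: complex | np.ndarray,
    tau: float,
    alpha: float = 1.0,
    dt: float = 1.0,
) -> complex | np.ndarray:
    """Per-eigenvalue gain ``s_{tau,alpha}(lambda)`` over time increment dt.

    ``alpha = 1``: ``exp(dt/tau * lambda)`` (diffusive; decay comes from
    ``Re(lambda) <= 0``).  ``alpha < 1``: ``exp(-dt/tau * (-lambda)^alpha)``
    with the principal branch, the unique continuous extension of
    ``exp(-dt/tau * |lambda|^alpha)`` off the real axis.  ``s(0) = 1`` for
    every parameter setting, so stationary mass is always preserved.
    """
    if tau <= 0:
        raise SpectralError(f"tau must be > 0, got {tau}")
    if dt <= 0:
        raise SpectralError(f"dt must be > 0, got {dt}")
    if not 0 < alpha <= 1:
        raise SpectralError(f"alpha must be in (0, 1], got {alpha}")
    lam = np.asarray(lam, dtype=complex)
    scale = dt / tau
    if alpha == 1:
        out = np.exp(scale * lam)
    else:
        out = np.exp(-scale * (-lam) ** alpha)
    return out if out.shape else complex(out)


def _sanitize(
    raw: np.ndarray, context: str, tol: float = CLIP_TOL
) -> tuple[np.ndarray, float]:
    """Clip small negatives (<= tol) and renormalise rows.

    Entries more negative than ``-tol`` signal a genuinely invalid
    construction and raise instead of being repaired silently.  ``tol``
    defaults to round-off scale; truncated-expansion products pass their
    measured truncation residual instead.
    """
    low = raw.min()
    if low < -tol:
        raise SpectralError(
            f"{context}: entry {low:.3e} below -{tol:g}; "
            "not a valid stochastic operator"
        )
    clip = max(0.0, float(-low))
    P = np.clip(raw, 0.0, None)
    sums = P.sum(axis=1)
    if np.any(sums <= 0):
        raise SpectralError(f"{context}: a row lost all its mass")
    return P / sums[:, None], clip


def build_propagator(
    basis: SpectralBasis,
    tau: float = 1.0,
    alpha: float = 1.0,
    dt: float = 1.0,
) -> Propagator:
    """Spectral propagator ``P = G diag(s(lambda)) W`` (real part), sanitised.

    Complex eigenvalues of non-symmetric (directed) generators come in
    conjugate pairs, so the product is real up to round-off; an imaginary
    residual above 1e-6 raises rather than being discarded.
    """
    s = power_spectrum(basis.eigenvalues, tau, alpha, dt)
    raw = basis.G @ np.diag(s) @ basis.W
    imag = np.abs(raw.imag).max()
    if imag > CLIP_TOL:
        raise SpectralError(
            f"imaginary residual {imag:.3e} > {CLIP_TOL:g}: "
            "invalid basis or unsupported generator"
        )
    P, clip = _sanitize(raw.real, "spectral propagator")
    return Propagator(
        matrix=P, tau=tau, alpha=alpha, dt=dt, basis=basis,
        clip_magnitude=clip, label=basis.source.label,
    )


def series_propagator(
    gen: Generator,
    t: float = 1.0,
    n_terms: int = 60,
) -> Propagator:
    """Truncated power-series exponential ``sum_{n<=n_terms} (tO)^n / n!``.

    The package's internal oracle and the fallback for non-diagonalisable
    generators.  Sanitisation contract matches :func:`build_propagator`;
    note a too-short truncation of a fast generator can legitimately fail
    sanitisation (the partial sum is not a stochastic matrix).
    """
    if n_terms < 1:
        raise SpectralError("n_terms must be >= 1")
    if t < 0:
        raise SpectralError("t must be >= 0")
    O = gen.matrix
    n = O.shape[0]
    term = np.eye(n)
    acc = np.eye(n)
    for k in range(1, n_terms + 1):
        term = term @ (t * O) / k
        acc = acc + term
    P, clip = _sanitize(acc, "series propagator")
    return Propagator(
        matrix=P, tau=1.0, alpha=1.0, dt=t, basis=None,
        clip_magnitude=clip, label=gen.label,
    )


def propagator_for(
    gen: Generator,
    tau: float = 1.0,
    alpha: float = 1.0,
    dt: float = 1.0,
    n_terms: int = 80,
) -> Propagator:
    """Spectral propagator with automatic series fallback.

    The fallback only exists for ``alpha = 1`` (the series computes
    ``exp(dt/tau * O)``); a defective generator combined with ``alpha < 1``
    raises.
    """
    try:
        return build_propagator(decompose(gen), tau=tau, alpha=alpha, dt=dt)
    except SpectralError:
        if alpha != 1:
            raise
        prop = series_propagator(gen, t=dt / tau, n_terms=n_terms)
        prop.tau, prop.dt = tau, dt
        return prop
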