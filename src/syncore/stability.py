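"""Stability of the synchronization manifold: spectra and Lyapunov exponents.

Two complementary levels of analysis:

* **Linear, global**: the obstruction matrix ``w-`` is the linearization of
  the transversal dynamics at the origin.  If every entry satisfies
  ``|w-_ij| < 1/n`` the origin is a global fixed point of the transversal
  dynamics (a contraction bound), and if every eigenvalue has modulus
  below 1 the synchronization manifold is asymptotically stable.

* **Nonlinear, orbit-wise**: along a synchronized orbit ``xi(t)`` the
  tangent dynamics splits into a block parallel to the manifold with
  one-step matrices ``w+ @ diag(tanh'(xi))`` (synchronization exponents)
  and a transversal block with ``w- @ diag(tanh'(xi))`` (transversal
  exponents).  The manifold is asymptotically stable when the largest
  transversal exponent is negative on every orbit it carries.

Since ``0 < tanh'(x) <= 1``, each transversal exponent is bounded above by
the log of the largest eigen-modulus of ``w-``, which is why the matrix
criteria above control stability without simulating anything.

Exponents are estimated with the standard QR method: iterate an
orthonormal tangent frame, re-orthonormalize every step, average the log
diagonal of R.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coupling import (
    DEFAULT_SYNC_TOL,
    CoupledPair,
    obstruction_matrix,
    synchronized_module,
)
from .network import Neuromodule, _as_matrix, _as_vector, step

__all__ = [
    "EigenReport",
    "LyapunovSpectrum",
    "obstruction_eigen",
    "contraction_check",
    "lyapunov_spectrum",
    "split_spectrum",
    "tangent_matrix",
]


@dataclass(frozen=True)
class EigenReport:
    """Eigenvalues sorted by decreasing modulus, with the stability verdict.

    ``stable`` is the spectral criterion ``max_i |eps_i| < 1``.  Ties in
    modulus are broken by descending real then imaginary part, so reports
    are deterministic; conjugate pairs appear adjacently.
    """

    eigenvalues: tuple[complex, ...]

    @property
    def max_modulus(self) -> float:
        return abs(self.eigenvalues[0]) if self.eigenvalues else 0.0

    @property
    def stable(self) -> bool:
        return self.max_modulus < 1.0


@dataclass(frozen=True)
class LyapunovSpectrum:
    """Estimated Lyapunov exponents, sorted descending.

    Deterministic given the initial state and the step counts; ``n_steps``
    is the averaging length after ``n_transient`` discarded steps.
    """

    exponents: np.ndarray
    n_steps: int
    n_transient: int
    initial_state: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "exponents", np.asarray(self.exponents, dtype=float))
        object.__setattr__(
            self, "initial_state", np.asarray(self.initial_state, dtype=float)
        )

    @property
    def largest(self) -> float:
        return float(self.exponents[0])


def obstruction_eigen(w_minus) -> EigenReport:
    """Eigenvalues of the obstruction matrix, sorted by decreasing modulus.

    Real eigenvalues are reported with exactly zero imaginary part.
    """
    w = _as_matrix(w_minus, name="w_minus")
    eig = np.linalg.eigvals(w)
    # collapse rounding noise on the imaginary part of real eigenvalues
    if np.allclose(eig.imag, 0.0, atol=1e-12 * max(1.0, np.abs(eig).max(initial=0.0))):
        eig = eig.real.astype(complex)
    order = sorted(
        range(len(eig)),
        key=lambda k: (-abs(eig[k]), -eig[k].real, -eig[k].imag),
    )
    return EigenReport(eigenvalues=tuple(complex(eig[k]) for k in order))


def contraction_check(w_minus) -> bool:
    """Entry-wise contraction bound: ``max_ij |w-_ij| < 1/n``.

    Sufficient (not necessary) for the origin of the transversal dynamics
    to be a *global* fixed point attractor, hence for globally stable
    synchronization.  The bound is applied to magnitudes: a contraction
    estimate concerns norms, and a signed reading would certify any
    strongly negative matrix, contradicting the spectral criterion.
    """
    w = _as_matrix(w_minus, name="w_minus")
    n = w.shape[0]
    return bool(np.max(np.abs(w)) < 1.0 / n)


def tangent_matrix(module: Neuromodule, a: np.ndarray) -> np.ndarray:
    """Jacobian of the module map at state ``a``: ``w @ diag(tanh'(a))``."""
    d = 1.0 / np.cosh(np.asarray(a, dtype=float)) ** 2
    return module.weights * d[np.newaxis, :]


def _qr_exponents(
    matrices_at,
    states,
    dim: int,
) -> np.ndarray:
    """Average log-diagonal of R over a QR-iterated tangent frame."""
    q = np.eye(dim)
    acc = np.zeros(dim)
    n_steps = len(states)
    for a in states:
        j = matrices_at(a)
        q, r = np.linalg.qr(j @ q)
        diag = np.abs(np.diag(r))
        if np.any(diag == 0.0):
            raise FloatingPointError(
                "tangent frame collapsed during QR iteration; the orbit reaches a "
                "point with a singular Jacobian — use a shorter averaging window "
                "or perturb the initial state"
            )
        acc += np.log(diag)
    return np.sort(acc / n_steps)[::-1]


def lyapunov_spectrum(
    module: Neuromodule,
    a0,
    n_transient: int = 10_000,
    n_steps: int = 100_000,
) -> LyapunovSpectrum:
    """All Lyapunov exponents of the module along the orbit through ``a0``.

    QR re-orthonormalization every step; exponents are averages over
    ``n_steps`` after discarding ``n_transient``.  The defaults resolve
    exponents of low-dimensional maps to a few times 1e-3 in seconds; for
    rough scans much shorter windows suffice.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    a = _as_vector(a0, module.n, "a0")
    for _ in range(n_transient):
        a = step(module, a)
    states = np.empty((n_steps, module.n))
    for t in range(n_steps):
        states[t] = a
        a = step(module, a)
    exponents = _qr_exponents(lambda s: tangent_matrix(module, s), states, module.n)
    return LyapunovSpectrum(
        exponents=exponents,
        n_steps=n_steps,
        n_transient=n_transient,
        initial_state=np.asarray(a0, dtype=float),
    )


def split_spectrum(
    pair: CoupledPair,
    xi0,
    n_transient: int = 10_000,
    n_steps: int = 100_000,
    tol: float = DEFAULT_SYNC_TOL,
) -> tuple[LyapunovSpectrum, LyapunovSpectrum]:
    """Synchronization and transversal Lyapunov spectra along one orbit.

    The orbit is generated *on* the synchronization manifold by iterating
    the synchronized ``w+``-module from ``xi0``.  Both returned spectra
    have length ``n``: the first from tangent matrices
    ``w+ @ diag(tanh'(xi))``, the second from ``w- @ diag(tanh'(xi))``.
    The manifold is asymptotically stable if the largest transversal
    exponent is negative for every attractor it carries; this function
    evaluates one orbit, so global statements need a census over
    attractors.
    """
    sync_mod = synchronized_module(pair, tol)
    w_minus = obstruction_matrix(pair, tol)
    xi = _as_vector(xi0, pair.n, "xi0")
    for _ in range(n_transient):
        xi = step(sync_mod, xi)
    states = np.empty((n_steps, pair.n))
    for t in range(n_steps):
        states[t] = xi
        xi = step(sync_mod, xi)

    def d(a):
        return 1.0 / np.cosh(a) ** 2

    sync_exp = _qr_exponents(lambda s: sync_mod.weights * d(s)[None, :], states, pair.n)
    trans_exp = _qr_exponents(lambda s: w_minus * d(s)[None, :], states, pair.n)
    common = dict(n_steps=n_steps, n_transient=n_transient, initial_state=xi0)
    return (
        LyapunovSpectrum(exponents=sync_exp, **common),
        LyapunovSpectrum(exponents=trans_exp, **common),
    )
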