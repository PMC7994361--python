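"""Coupled pairs of neuromodules and their synchronization structure.

Two ``n``-neuron modules A and B with coupling blocks ``wAB`` (B -> A) and
``wBA`` (A -> B) form a ``2n``-neuron system with block weight matrix

    [[wA,  wAB],
     [wBA, wB ]].

When the *synchronization condition*

    thetaA == thetaB,   wA - wBA == wB - wAB,   wAB != 0,   wBA != 0

holds, the diagonal subspace ``a == b`` (the synchronization manifold) is
invariant, and the dynamics splits in the coordinates
``xi = (a + b) / 2``, ``eta = (a - b) / 2`` into

* the *synchronized dynamics*: an ``n``-module with the synchronization
  matrix ``w+ = wA + wAB`` (= ``wB + wBA``) and bias ``theta``;
* the *obstruction dynamics* transversal to the manifold, governed by the
  obstruction matrix ``w- = wA - wBA`` (= ``wB - wAB``), independent of the
  bias.

The sign pattern of ``w+`` is the *synchronization core*.  A coupling is
*generative* when the core contains a connection present in neither module
alone; generative couplings can make the synchronized dynamics richer than
the dynamics of the isolated parts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import (
    Neuromodule,
    SignedStructure,
    _as_matrix,
    _as_vector,
    step,
)

__all__ = [
    "CoupledPair",
    "XiEtaState",
    "SyncCore",
    "CouplingClass",
    "SyncConditionError",
    "DEFAULT_SYNC_TOL",
    "assemble",
    "disassemble",
    "check_sync_condition",
    "sync_residual",
    "sync_matrix",
    "obstruction_matrix",
    "identical_module_split",
    "to_xi_eta",
    "from_xi_eta",
    "xi_eta_step",
    "synchronized_module",
    "obstruction_map",
    "sync_core_structure",
    "classify_coupling",
    "sync_equivalent",
    "coupled_step",
]

#: Default absolute, entry-wise tolerance for the synchronization condition.
#: Weights are user-specified constants, so deviations beyond rounding noise
#: mean the condition genuinely fails; a looser default would silently break
#: the invariance of the synchronization manifold.
DEFAULT_SYNC_TOL = 1e-9


class SyncConditionError(ValueError):
    """Raised when an operation requires the synchronization condition."""


@dataclass(frozen=True)
class CoupledPair:
    """Two same-dimension modules plus the two coupling blocks.

    ``wAB`` carries connections from module B into module A, ``wBA`` the
    reverse.  Unequal module dimensions are rejected: partial
    synchronization of unequal modules is outside this package's scope.
    """

    thetaA: np.ndarray
    thetaB: np.ndarray
    wA: np.ndarray
    wB: np.ndarray
    wAB: np.ndarray
    wBA: np.ndarray
    name: str | None = None

    def __post_init__(self):
        thetaA = _as_vector(self.thetaA, name="thetaA")
        n = thetaA.shape[0]
        object.__setattr__(self, "thetaA", thetaA)
        object.__setattr__(self, "thetaB", _as_vector(self.thetaB, n, "thetaB"))
        for attr in ("wA", "wB", "wAB", "wBA"):
            object.__setattr__(self, attr, _as_matrix(getattr(self, attr), n, attr))

    @property
    def n(self) -> int:
        return self.thetaA.shape[0]

    def is_recurrent(self) -> bool:
        """Whether both coupling blocks contain at least one nonzero entry."""
        return bool(np.any(self.wAB != 0.0) and np.any(self.wBA != 0.0))


@dataclass(frozen=True)
class XiEtaState:
    """Coordinates parallel (``xi``) and transversal (``eta``) to the diagonal.

    ``eta == 0`` identifies the synchronization manifold, ``xi == 0`` the
    obstruction manifold.
    """

    xi: np.ndarray
    eta: np.ndarray

    def __post_init__(self):
        xi = _as_vector(self.xi, name="xi")
        eta = _as_vector(self.eta, xi.shape[0], "eta")
        object.__setattr__(self, "xi", xi)
        object.__setattr__(self, "eta", eta)


@dataclass(frozen=True)
class SyncCore:
    """The synchronization matrix ``w+`` with its bias and sign pattern."""

    w_plus: np.ndarray
    theta: np.ndarray
    structure: SignedStructure

    def __post_init__(self):
        w = _as_matrix(self.w_plus, name="w_plus")
        theta = _as_vector(self.theta, w.shape[0], "theta")
        object.__setattr__(self, "w_plus", w)
        object.__setattr__(self, "theta", theta)
        if self.structure != SignedStructure(np.sign(w)):
            raise ValueError("structure does not match the sign pattern of w_plus")


@dataclass(frozen=True)
class CouplingClass:
    """Generative/conservative verdict with the witnessing index pairs.

    ``witnesses`` lists the positions ``(i, j)`` where the synchronization
    matrix has a connection absent from both modules; non-empty exactly for
    generative couplings.
    """

    label: str
    witnesses: tuple[tuple[int, int], ...]

    @property
    def is_generative(self) -> bool:
        return self.label == "generative"


def assemble(pair: CoupledPair) -> Neuromodule:
    """The ``2n``-neuron module with block matrix [[wA, wAB], [wBA, wB]].

    Iterating the assembled module reproduces the coupled dynamics of the
    pair exactly: neurons ``0..n-1`` are module A, ``n..2n-1`` module B.
    """
    w = np.block([[pair.wA, pair.wAB], [pair.wBA, pair.wB]])
    theta = np.concatenate([pair.thetaA, pair.thetaB])
    return Neuromodule(theta=theta, weights=w, name=pair.name)


def disassemble(module: Neuromodule, name: str | None = None) -> CoupledPair:
    """Split an even-dimensional module into blocks; inverse of :func:`assemble`."""
    if module.n % 2:
        raise ValueError("only even-dimensional modules can be split into two blocks")
    n = module.n // 2
    w = module.weights
    return CoupledPair(
        thetaA=module.theta[:n],
        thetaB=module.theta[n:],
        wA=w[:n, :n],
        wB=w[n:, n:],
        wAB=w[:n, n:],
        wBA=w[n:, :n],
        name=name if name is not None else module.name,
    )


def sync_residual(pair: CoupledPair) -> float:
    """Largest entry-wise violation of the synchronization condition equations.

    ``max(|thetaA - thetaB|, |(wA - wBA) - (wB - wAB)|)``; zero when the
    matrix part of the condition holds exactly.  The recurrence requirement
    (nonzero coupling blocks) is checked separately.
    """
    r_theta = float(np.max(np.abs(pair.thetaA - pair.thetaB))) if pair.n else 0.0
    r_w = float(np.max(np.abs((pair.wA - pair.wBA) - (pair.wB - pair.wAB))))
    return max(r_theta, r_w)


def check_sync_condition(pair: CoupledPair, tol: float = DEFAULT_SYNC_TOL) -> bool:
    """Whether the pair satisfies the synchronization condition within ``tol``.

    Requires equal biases, ``wA - wBA == wB - wAB`` entry-wise within
    ``tol``, and a recurrent coupling (both blocks nonzero).
    """
    if tol < 0:
        raise ValueError("tol must be >= 0")
    return pair.is_recurrent() and sync_residual(pair) <= tol


def _require_sync(pair: CoupledPair, tol: float) -> None:
    if not pair.is_recurrent():
        raise SyncConditionError(
            "coupling is not recurrent: both wAB and wBA must have a nonzero entry"
        )
    res = sync_residual(pair)
    if res > tol:
        d = np.abs((pair.wA - pair.wBA) - (pair.wB - pair.wAB))
        dt = np.abs(pair.thetaA - pair.thetaB)
        if dt.max(initial=0.0) >= d.max():
            i = int(np.argmax(dt))
            where = f"theta[{i}]"
        else:
            i, j = np.unravel_index(np.argmax(d), d.shape)
            where = f"weight entry ({i}, {j})"
        raise SyncConditionError(
            f"synchronization condition violated by {res:.3g} at {where} (tol {tol:.3g})"
        )


def sync_matrix(pair: CoupledPair, tol: float = DEFAULT_SYNC_TOL) -> SyncCore:
    """The synchronization matrix ``w+ = wA + wAB`` with bias ``thetaA``.

    Under the synchronization condition ``wA + wAB`` and ``wB + wBA`` agree
    within ``tol``; the first form is returned for bit-reproducibility.
    """
    _require_sync(pair, tol)
    w_plus = pair.wA + pair.wAB
    other = pair.wB + pair.wBA
    assert np.max(np.abs(w_plus - other)) <= tol, "inconsistent synchronization matrix"
    return SyncCore(
        w_plus=w_plus,
        theta=pair.thetaA.copy(),
        structure=SignedStructure(np.sign(w_plus)),
    )


def obstruction_matrix(pair: CoupledPair, tol: float = DEFAULT_SYNC_TOL) -> np.ndarray:
    """The obstruction matrix ``w- = wA - wBA`` (= ``wB - wAB`` within ``tol``).

    ``w-`` is the linearization of the transversal dynamics at the
    synchronization manifold; its eigen-moduli decide whether the manifold
    is stable.
    """
    _require_sync(pair, tol)
    return pair.wA - pair.wBA


def identical_module_split(w_plus, w_minus) -> tuple[np.ndarray, np.ndarray]:
    """Module and coupling weights realizing given ``w+``/``w-`` with identical modules.

    For identical modules (``wA == wB == w``) and a symmetric coupling
    (``wAB == wBA == w_coup``), the synchronization and obstruction
    matrices are ``w + w_coup`` and ``w - w_coup``; inverting gives

        w = (w+ + w-) / 2,    w_coup = (w+ - w-) / 2.

    If ``w+ == w-`` the coupling is zero, hence not recurrent; the returned
    pair is then degenerate and rejected by the synchronization check.
    """
    w_plus = _as_matrix(w_plus, name="w_plus")
    w_minus = _as_matrix(w_minus, w_plus.shape[0], "w_minus")
    w = (w_plus + w_minus) / 2.0
    w_coup = (w_plus - w_minus) / 2.0
    return w, w_coup


def to_xi_eta(a, b) -> XiEtaState:
    """Parallel/transversal coordinates ``xi = (a+b)/2``, ``eta = (a-b)/2``."""
    a = _as_vector(a, name="a")
    b = _as_vector(b, a.shape[0], "b")
    return XiEtaState(xi=(a + b) / 2.0, eta=(a - b) / 2.0)


def from_xi_eta(s: XiEtaState) -> tuple[np.ndarray, np.ndarray]:
    """Inverse transform: ``a = xi + eta``, ``b = xi - eta``."""
    return s.xi + s.eta, s.xi - s.eta


def xi_eta_step(pair: CoupledPair, s: XiEtaState) -> XiEtaState:
    """One step of the coupled dynamics expressed in (xi, eta) coordinates.

    Valid for *any* pair (the synchronization condition is not required):
    this is the full dynamics rewritten with the helper functions
    ``G+-(x, y) = tanh(x +- y)``,

        xi'  = (thetaA + thetaB)/2 + (wA + wBA)/2 @ G+ + (wB + wAB)/2 @ G-,
        eta' = (thetaA - thetaB)/2 + (wA - wBA)/2 @ G+ - (wB - wAB)/2 @ G-.

    It commutes with the coordinate transform: transforming ``(a, b)``,
    stepping here, and transforming back matches stepping the assembled
    ``2n``-module directly (up to rounding).
    """
    if s.xi.shape[0] != pair.n:
        raise ValueError(f"state has dimension {s.xi.shape[0]}, pair expects {pair.n}")
    g_plus = np.tanh(s.xi + s.eta)  # = tanh(a)
    g_minus = np.tanh(s.xi - s.eta)  # = tanh(b)
    xi_next = (
        (pair.thetaA + pair.thetaB) / 2.0
        + ((pair.wA + pair.wBA) @ g_plus) / 2.0
        + ((pair.wB + pair.wAB) @ g_minus) / 2.0
    )
    eta_next = (
        (pair.thetaA - pair.thetaB) / 2.0
        + ((pair.wA - pair.wBA) @ g_plus) / 2.0
        - ((pair.wB - pair.wAB) @ g_minus) / 2.0
    )
    return XiEtaState(xi=xi_next, eta=eta_next)


def synchronized_module(pair: CoupledPair, tol: float = DEFAULT_SYNC_TOL) -> Neuromodule:
    """The ``n``-module governing the dynamics on the synchronization manifold.

    Its weight matrix is ``w+`` and its bias ``theta``; iterating it from
    ``xi0`` reproduces the xi-component of the coupled system started at
    ``a0 = b0 = xi0``.
    """
    core = sync_matrix(pair, tol)
    name = f"{pair.name}/synchronized" if pair.name else None
    return Neuromodule(theta=core.theta, weights=core.w_plus, name=name)


def obstruction_map(pair: CoupledPair, eta, tol: float = DEFAULT_SYNC_TOL) -> np.ndarray:
    """One step of the transversal dynamics: ``eta' = w- @ tanh(eta)``.

    Bias-free by construction, so the origin is always a fixed point; its
    stability controls whether synchronized orbits attract nearby states.
    """
    w_minus = obstruction_matrix(pair, tol)
    eta = _as_vector(eta, pair.n, "eta")
    return w_minus @ np.tanh(eta)


def sync_core_structure(pair: CoupledPair, tol: float = DEFAULT_SYNC_TOL) -> SignedStructure:
    """The synchronization core: sign pattern of ``w+``."""
    return sync_matrix(pair, tol).structure


def classify_coupling(pair: CoupledPair, tol: float = DEFAULT_SYNC_TOL) -> CouplingClass:
    """Decide whether the coupling is generative or conservative.

    Generative iff some entry of ``w+`` is nonzero where *both* module
    matrices are zero — i.e. the coupling creates a connection in the
    synchronized dynamics that neither module had.  The verdict is
    invariant under positive rescaling of all weights.
    """
    core = sync_matrix(pair, tol)
    new = (core.w_plus != 0.0) & (pair.wA == 0.0) & (pair.wB == 0.0)
    witnesses = tuple((int(i), int(j)) for i, j in zip(*np.nonzero(new)))
    label = "generative" if witnesses else "conservative"
    return CouplingClass(label=label, witnesses=witnesses)


def sync_equivalent(
    pairX: CoupledPair,
    pairY: CoupledPair,
    up_to_permutation: bool = False,
    tol: float = DEFAULT_SYNC_TOL,
) -> bool:
    """Whether two coupled systems share the same synchronization core.

    By default cores are compared entry-wise as labelled sign matrices.
    With ``up_to_permutation`` the comparison allows a simultaneous
    relabelling of neurons (same permutation applied to rows and columns);
    this mode is an explicit opt-in since core equality is defined on
    matrices.
    """
    cx = sync_core_structure(pairX, tol).entries
    cy = sync_core_structure(pairY, tol).entries
    if cx.shape != cy.shape:
        return False
    if np.array_equal(cx, cy):
        return True
    if not up_to_permutation:
        return False
    from itertools import permutations

    n = cx.shape[0]
    for perm in permutations(range(n)):
        p = list(perm)
        if np.array_equal(cx[np.ix_(p, p)], cy):
            return True
    return False


def coupled_step(pair: CoupledPair, a, b) -> tuple[np.ndarray, np.ndarray]:
    """One step of the coupled dynamics in the original (a, b) coordinates."""
    joint = step(assemble(pair), np.concatenate([np.atleast_1d(a), np.atleast_1d(b)]))
    return joint[: pair.n], joint[pair.n :]
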