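"""Catalog of reference systems and a generator of random synchronizable pairs.

The catalog ships the small networks used throughout the documentation and
tests: the isolated inhibitory 2-cycle, the strongly coupled pair built
from it whose synchronization core gains a negative self-connection (a
*generative* coupling with a transversally unstable manifold), and the
*conservative* rewiring of the same core whose obstruction matrix is
spectrally stable, so the manifold attracts globally.  An approximate
Freeman KII structure (two excitatory and two inhibitory populations) is
included as a sign pattern only.

:func:`random_sync_pair` manufactures coupled pairs that satisfy the
synchronization condition with *exactly zero* residual: weights are drawn
on a dyadic grid (multiples of 1/64), for which the defining sums and
differences are exact in double precision.
"""

from __future__ import annotations

import numpy as np

from .coupling import CoupledPair
from .network import Neuromodule, is_strongly_connected

__all__ = ["FIXTURE_NAMES", "load_fixture", "random_sync_pair"]


def _odd2cycle() -> Neuromodule:
    """Inhibitory 2-cycle, |w| = 1.6: a global period-4 attractor at zero bias."""
    return Neuromodule(
        theta=[0.0, 0.0],
        weights=[[0.0, 1.6], [-1.6, 0.0]],
        name="odd2cycle_w16",
    )


def _chaotic_core() -> Neuromodule:
    """2-neuron core with a negative self-connection; chaotic for biases near -4.

    This is the synchronization matrix shared by the generative and the
    conservative catalog pairs.
    """
    return Neuromodule(
        theta=[-4.0, 0.0],
        weights=[[-4.0, 1.6], [-1.6, 0.0]],
        name="chaotic_core",
    )


def _pair_generative() -> CoupledPair:
    """Two identical inhibitory 2-cycles, strongly coupled through neuron 1.

    The single coupling entry (-4) creates a self-connection in the core
    that neither module has: the coupling is generative.  The obstruction
    matrix has an eigenvalue of modulus > 1, so asynchronous attractors
    coexist with the synchronized ones.
    """
    w = np.array([[0.0, 1.6], [-1.6, 0.0]])
    w_coup = np.array([[-4.0, 0.0], [0.0, 0.0]])
    theta = np.array([-4.0, 0.0])
    return CoupledPair(
        thetaA=theta, thetaB=theta, wA=w, wB=w, wAB=w_coup, wBA=w_coup,
        name="pair_generative",
    )


def _pair_conservative() -> CoupledPair:
    """Conservative rewiring with the same synchronization core.

    Module and coupling weights are chosen so that the synchronization
    matrix is identical to the generative pair's, while the obstruction
    matrix has spectral radius below one — the synchronization manifold is
    globally stable and only synchronized attractors exist.
    """
    w = np.array([[-2.675, 1.1], [-1.1, 0.0]])
    w_coup = np.array([[-1.325, 0.5], [-0.5, 0.0]])
    theta = np.array([-4.0, 0.0])
    return CoupledPair(
        thetaA=theta, thetaB=theta, wA=w, wB=w, wAB=w_coup, wBA=w_coup,
        name="pair_conservative",
    )


def _obstruction_unstable() -> Neuromodule:
    """Obstruction matrix of the generative pair (spectral radius 3.2)."""
    return Neuromodule(
        theta=[0.0, 0.0],
        weights=[[4.0, 1.6], [-1.6, 0.0]],
        name="obstruction_unstable",
    )


def _obstruction_stable() -> Neuromodule:
    """Obstruction matrix of the conservative pair (eigenvalues -0.984, -0.366)."""
    return Neuromodule(
        theta=[0.0, 0.0],
        weights=[[-1.35, 0.6], [-0.6, 0.0]],
        name="obstruction_stable",
    )


def _odd3cycle() -> Neuromodule:
    """Directed 3-ring with one inhibitory edge (odd cycle), unit magnitudes."""
    return Neuromodule(
        theta=[0.0, 0.0, 0.0],
        weights=[[0.0, 0.0, 1.0], [1.0, 0.0, 0.0], [0.0, -1.0, 0.0]],
        name="odd3cycle",
    )


def _kii_structure_approx() -> Neuromodule:
    """Synthetic stand-in for a Freeman KII set: sign structure only.

    Encodes the textual description — two excitatory populations (0, 1)
    and two inhibitory populations (2, 3) with mutual excitation between
    the excitatory units, excitatory drive onto the inhibitory units,
    inhibitory feedback, and mutual inhibition — with unit magnitudes.
    The exact published connectivity is figure-only, so this entry is
    approximate and excluded from any quantitative comparison.
    """
    w = np.array(
        [
            [0.0, 1.0, -1.0, 0.0],
            [1.0, 0.0, 0.0, -1.0],
            [1.0, 0.0, 0.0, -1.0],
            [0.0, 1.0, -1.0, 0.0],
        ]
    )
    return Neuromodule(theta=np.zeros(4), weights=w, name="kii_structure_approx")


_CATALOG = {
    "odd2cycle_w16": _odd2cycle,
    "chaotic_core": _chaotic_core,
    "obstruction_unstable": _obstruction_unstable,
    "obstruction_stable": _obstruction_stable,
    "pair_generative": _pair_generative,
    "pair_conservative": _pair_conservative,
    "kii_structure_approx": _kii_structure_approx,
    "odd3cycle": _odd3cycle,
}

FIXTURE_NAMES = tuple(sorted(_CATALOG))


def load_fixture(name: str) -> Neuromodule | CoupledPair:
    """Return a validated catalog system by name.

    Unknown names raise with the full catalog listing.
    """
    try:
        builder = _CATALOG[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        ) from None
    return builder()


def _dyadic(rng: np.random.Generator, size, scale: float) -> np.ndarray:
    """Random magnitudes on the grid {1/64, 2/64, ...} * sign, within +-scale."""
    steps = max(1, int(round(scale * 64)))
    mags = rng.integers(8, steps + 1, size=size) / 64.0
    signs = rng.choice([-1.0, 1.0], size=size)
    return mags * signs


def random_sync_pair(
    n: int,
    density: float = 0.5,
    weight_scale: float = 1.5,
    seed: int | None = None,
    generative: bool = False,
    stable_manifold: bool = False,
    max_tries: int = 100,
) -> CoupledPair:
    """A random coupled pair satisfying the synchronization condition exactly.

    Construction: draw a strongly connected module matrix ``wA`` (a random
    Hamiltonian cycle plus density-controlled extra edges), random coupling
    blocks with at least one entry each, and set
    ``wB = wA + wAB - wBA`` and ``thetaB = thetaA`` — then
    ``wA - wBA == wB - wAB`` identically.  All weights live on a dyadic
    grid so the identity holds with zero floating-point residual.

    With ``generative`` the coupling is forced to create a connection at a
    position where both module matrices vanish, so the resulting core has
    a connection neither module has.

    With ``stable_manifold`` the blocks are arranged so the obstruction
    matrix ``wA - wBA`` is dense with every magnitude below ``1/n``; its
    spectral radius is then below 1 (row-sum bound), the synchronization
    manifold attracts transversally, and — important for numerical work —
    rounding noise off the diagonal is damped instead of amplified, so
    iterated orbits started at ``a0 == b0`` stay synchronized to machine
    precision even when the synchronized dynamics itself is chaotic.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        w_a = np.zeros((n, n))
        perm = rng.permutation(n)
        for k in range(n):  # Hamiltonian cycle guarantees strong connectivity
            src, dst = perm[k], perm[(k + 1) % n]
            w_a[dst, src] = _dyadic(rng, (), weight_scale)
        extra = (rng.random((n, n)) < density) & (w_a == 0.0)
        w_a[extra] = _dyadic(rng, int(extra.sum()), weight_scale)

        def block():
            b = np.where(
                rng.random((n, n)) < density / 2.0,
                _dyadic(rng, (n, n), weight_scale),
                0.0,
            )
            if not b.any():
                b[rng.integers(n), rng.integers(n)] = _dyadic(rng, (), weight_scale)
            return b

        if stable_manifold:
            # dense dyadic obstruction matrix with |entries| < 1/n
            q = max(1, 64 // n - 1)
            mags = rng.integers(1, q + 1, size=(n, n)) / 64.0
            w_minus = mags * rng.choice([-1.0, 1.0], size=(n, n))
            w_ba = w_a - w_minus
            w_ab = block()
            if generative:
                zeros = np.argwhere(w_a == 0.0)
                if zeros.size == 0:
                    continue
                i, j = zeros[rng.integers(len(zeros))]
                # wB = wAB + w_minus there; cancel it while keeping w+ nonzero
                w_ab[i, j] = -w_minus[i, j]
        else:
            w_ab = block()
            w_ba = block()
            if generative:
                zeros = np.argwhere(w_a == 0.0)
                if zeros.size == 0:
                    continue
                i, j = zeros[rng.integers(len(zeros))]
                v = _dyadic(rng, (), weight_scale)
                # same entry in both blocks keeps wB zero there while w+ is not
                w_ab[i, j] = v
                w_ba[i, j] = v
        w_b = w_a + w_ab - w_ba
        if generative:
            cls_new = (w_a + w_ab != 0.0) & (w_a == 0.0) & (w_b == 0.0)
            if not cls_new.any():
                continue
        theta = _dyadic(rng, n, 1.0)
        pair = CoupledPair(
            thetaA=theta, thetaB=theta.copy(),
            wA=w_a, wB=w_b, wAB=w_ab, wBA=w_ba,
        )
        if not pair.is_recurrent():
            continue
        if not (
            is_strongly_connected(Neuromodule(theta=theta, weights=w_a))
            and is_strongly_connected(Neuromodule(theta=theta, weights=w_b))
        ):
            continue
        return pair
    raise RuntimeError(
        f"could not draw a valid synchronizable pair in {max_tries} attempts "
        f"(n={n}, density={density})"
    )
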