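"""Decomposition of even-dimensional networks into synchronizable submodules.

A ``2m``-neuron network is *s-decomposable* when its neurons can be split
into two ordered groups A and B of size ``m`` — position ``k`` of A paired
with position ``k`` of B — such that the induced blocks

    [[wA,  wAB],
     [wBA, wB ]]

form a recurrent coupling of two strongly connected submodules satisfying
the synchronization condition (equal paired biases and
``wA - wBA == wB - wAB``).  A network admitting no such split is *basic*.

The search is exhaustive: every balanced bipartition (with neuron 0 fixed
in A, which removes the A/B exchange symmetry) and every one of the ``m!``
pairings of B against A.  For structure-level questions — can *any* weight
configuration with a given sign pattern be decomposed? — each paired entry
position imposes one linear relation ``x_A - x_BA = x_B - x_AB`` on
magnitudes with prescribed signs, whose feasibility reduces to a sign
count (see :func:`_signs_feasible`).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations

import numpy as np

from .coupling import (
    DEFAULT_SYNC_TOL,
    CoupledPair,
    CouplingClass,
    SyncCore,
    classify_coupling,
    sync_matrix,
)
from .network import Neuromodule, SignedStructure, is_strongly_connected

__all__ = [
    "SDecomposition",
    "s_decompose",
    "is_basic",
    "structure_s_feasible",
    "DEFAULT_SIZE_CAP",
]

#: Largest dimension searched without an explicit override; a 12-neuron
#: search visits C(11,5) * 6! = 332,640 candidate splits.
DEFAULT_SIZE_CAP = 12


@dataclass(frozen=True)
class SDecomposition:
    """One balanced split of a network into a synchronizable coupled pair.

    ``partition_a[k]`` is paired with ``partition_b[k]`` (0-based neuron
    indices of the original network).  ``pair`` holds the induced blocks,
    ``core`` the synchronization matrix, ``coupling_class`` the
    generative/conservative verdict with witnesses.
    """

    partition_a: tuple[int, ...]
    partition_b: tuple[int, ...]
    pair: CoupledPair
    core: SyncCore
    coupling_class: CouplingClass

    @property
    def label(self) -> str:
        return self.coupling_class.label


def _balanced_splits(n: int):
    """All (A, B-set) bipartitions with 0 in A, and all orderings of B."""
    m = n // 2
    rest = range(1, n)
    for a_tail in combinations(rest, m - 1):
        part_a = (0,) + a_tail
        part_b_set = tuple(sorted(set(rest) - set(a_tail)))
        for part_b in permutations(part_b_set):
            yield part_a, part_b


def _extract_pair(module: Neuromodule, part_a, part_b) -> CoupledPair:
    w = module.weights
    ia = np.asarray(part_a)
    ib = np.asarray(part_b)
    return CoupledPair(
        thetaA=module.theta[ia],
        thetaB=module.theta[ib],
        wA=w[np.ix_(ia, ia)],
        wB=w[np.ix_(ib, ib)],
        wAB=w[np.ix_(ia, ib)],
        wBA=w[np.ix_(ib, ia)],
    )


def _submodule(theta: np.ndarray, w: np.ndarray) -> Neuromodule:
    return Neuromodule(theta=theta, weights=w)


def s_decompose(
    module: Neuromodule,
    tol: float = DEFAULT_SYNC_TOL,
    require_connected: bool = True,
    ignore_theta: bool = False,
    size_cap: int = DEFAULT_SIZE_CAP,
) -> list[SDecomposition]:
    """All decompositions of a network into synchronizable submodule pairs.

    Empty result means the network is basic (at this tolerance).  Flags:

    * ``require_connected`` — demand each submodule be strongly connected
      on its own (the module definition); relax to allow e.g. feedforward
      parts that still share a synchronization core.
    * ``ignore_theta`` — decompose the weight matrix only, treating biases
      as free parameters of the family.
    * ``size_cap`` — refuse larger networks (the search is factorial);
      raise it explicitly for bigger inputs.

    The A/B exchange symmetry is quotiented out: exactly one
    representative per equivalence class is returned (neuron 0 is always
    in partition A).
    """
    if module.n % 2:
        raise ValueError(
            f"s-decomposition requires an even number of neurons, got {module.n}"
        )
    if module.n > size_cap:
        raise ValueError(
            f"refusing exhaustive search for n={module.n} > cap {size_cap}: "
            f"C(n-1, n/2-1) * (n/2)! candidates; pass size_cap explicitly to override"
        )
    found = []
    for part_a, part_b in _balanced_splits(module.n):
        pair = _extract_pair(module, part_a, part_b)
        if not pair.is_recurrent():
            continue
        if not ignore_theta and np.max(np.abs(pair.thetaA - pair.thetaB)) > tol:
            continue
        if np.max(np.abs((pair.wA - pair.wBA) - (pair.wB - pair.wAB))) > tol:
            continue
        if require_connected and not (
            is_strongly_connected(_submodule(pair.thetaA, pair.wA))
            and is_strongly_connected(_submodule(pair.thetaB, pair.wB))
        ):
            continue
        if ignore_theta:
            pair = CoupledPair(
                thetaA=pair.thetaA,
                thetaB=pair.thetaA,  # thetas differ; report the A side
                wA=pair.wA,
                wB=pair.wB,
                wAB=pair.wAB,
                wBA=pair.wBA,
            )
        core = sync_matrix(pair, tol)
        found.append(
            SDecomposition(
                partition_a=tuple(int(i) for i in part_a),
                partition_b=tuple(int(i) for i in part_b),
                pair=pair,
                core=core,
                coupling_class=classify_coupling(pair, tol),
            )
        )
    return found


def is_basic(module: Neuromodule, tol: float = DEFAULT_SYNC_TOL, **kwargs) -> bool:
    """Whether the network admits no decomposition into synchronizable submodules."""
    return not s_decompose(module, tol=tol, **kwargs)


def _signs_feasible(s_a: int, s_ba: int, s_b: int, s_ab: int) -> bool:
    """Can magnitudes with these signs satisfy ``x_A - x_BA = x_B - x_AB``?

    Substituting ``x = s * y`` with ``y > 0`` for each nonzero entry turns
    the relation into ``s_A y_A - s_BA y_BA - s_B y_B + s_AB y_AB = 0``.
    A sum of strictly positive multiples of the coefficients
    ``(s_A, -s_BA, -s_B, s_AB)`` (zeros dropped) vanishes iff the nonzero
    coefficients are not all of the same sign — or there are none at all.
    """
    coeffs = [c for c in (s_a, -s_ba, -s_b, s_ab) if c != 0]
    if not coeffs:
        return True
    return min(coeffs) < 0 < max(coeffs)


def _sign_block_connected(entries: np.ndarray) -> bool:
    mod = Neuromodule(theta=np.zeros(entries.shape[0]), weights=entries.astype(float))
    return is_strongly_connected(mod)


def structure_s_feasible(
    structure: SignedStructure,
    require_connected: bool = True,
    size_cap: int = DEFAULT_SIZE_CAP,
) -> tuple[bool, list[tuple[tuple[int, ...], tuple[int, ...]]]]:
    """Whether *some* configuration with this sign pattern is s-decomposable.

    Works at the structure level: for each candidate split, every paired
    entry position must be sign-feasible for the linear relation of the
    synchronization condition, the coupling sign blocks must be nonzero,
    and (with ``require_connected``) both submodule sign blocks strongly
    connected.  Returns the verdict and the witnessing
    ``(partition_a, partition_b)`` splits.
    """
    n = structure.n
    if n % 2:
        raise ValueError(f"s-decomposition requires an even dimension, got {n}")
    if n > size_cap:
        raise ValueError(
            f"refusing exhaustive search for n={n} > cap {size_cap}; "
            f"pass size_cap explicitly to override"
        )
    c = structure.entries
    witnesses = []
    for part_a, part_b in _balanced_splits(n):
        ia = np.asarray(part_a)
        ib = np.asarray(part_b)
        s_a = c[np.ix_(ia, ia)]
        s_b = c[np.ix_(ib, ib)]
        s_ab = c[np.ix_(ia, ib)]
        s_ba = c[np.ix_(ib, ia)]
        if not (np.any(s_ab != 0) and np.any(s_ba != 0)):
            continue
        m = n // 2
        ok = all(
            _signs_feasible(
                int(s_a[i, j]), int(s_ba[i, j]), int(s_b[i, j]), int(s_ab[i, j])
            )
            for i in range(m)
            for j in range(m)
        )
        if not ok:
            continue
        if require_connected and not (
            _sign_block_connected(s_a) and _sign_block_connected(s_b)
        ):
            continue
        witnesses.append((tuple(int(i) for i in part_a), tuple(int(i) for i in part_b)))
    return bool(witnesses), witnesses
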