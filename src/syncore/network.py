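"""Single neuromodules: discrete-time tanh dynamics and graph structure.

A neuromodule is an ``n``-neuron recurrent network with bias vector
``theta`` and weight matrix ``w`` (``w[i, j]`` is the synapse from neuron
``j`` to neuron ``i``).  Its state is the activation vector ``a`` and the
dynamics is the map

    a_i(t+1) = theta_i + sum_j w[i, j] * tanh(a_j(t)).

The output of neuron ``i`` is ``tanh(a_i)``, so after one step every
activation is confined to ``|a_i| <= |theta_i| + sum_j |w[i, j]|``.

The transfer function is fixed to ``tanh``; the bias houses both the
intrinsic bias term and any stationary external input, merged into one
effective parameter per neuron.

Indices are 0-based throughout the Python API.  The plain-text spec files
and the command line use 1-based neuron numbering (see :mod:`syncore.specio`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np

__all__ = [
    "Neuromodule",
    "SignedStructure",
    "Trajectory",
    "CycleRecord",
    "step",
    "iterate",
    "adjacency_matrix",
    "structure_matrix",
    "is_strongly_connected",
    "to_digraph",
    "cycle_census",
    "activation_bound",
]


def _as_vector(x, n: int | None = None, name: str = "vector") -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.ndim != 1:
        raise ValueError(f"{name} must be 1-dimensional, got shape {v.shape}")
    if n is not None and v.shape[0] != n:
        raise ValueError(f"{name} has length {v.shape[0]}, expected {n}")
    if not np.all(np.isfinite(v)):
        raise ValueError(f"{name} contains non-finite entries")
    return v


def _as_matrix(x, n: int | None = None, name: str = "matrix") -> np.ndarray:
    m = np.asarray(x, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"{name} must be square, got shape {m.shape}")
    if n is not None and m.shape[0] != n:
        raise ValueError(f"{name} is {m.shape[0]}x{m.shape[1]}, expected {n}x{n}")
    if not np.all(np.isfinite(m)):
        raise ValueError(f"{name} contains non-finite entries")
    return m


@dataclass(frozen=True)
class Neuromodule:
    """An ``n``-neuron tanh network: bias vector ``theta``, weight matrix ``weights``."""

    theta: np.ndarray
    weights: np.ndarray
    name: str | None = None

    def __post_init__(self):
        theta = _as_vector(self.theta, name="theta")
        weights = _as_matrix(self.weights, n=theta.shape[0], name="weights")
        object.__setattr__(self, "theta", theta)
        object.__setattr__(self, "weights", weights)

    @property
    def n(self) -> int:
        return self.theta.shape[0]

    def __repr__(self) -> str:  # compact; arrays can be large
        label = f" {self.name!r}" if self.name else ""
        return f"<Neuromodule{label} n={self.n}>"


@dataclass(frozen=True)
class SignedStructure:
    """A matrix over {-1, 0, +1}: the sign pattern of a weight matrix.

    With the diagonal kept it is the *structure* of a network (polarity of
    all connections, self-connections included); with the diagonal zeroed
    and signs collapsed to {0, 1} it is the adjacency pattern.
    """

    entries: np.ndarray

    def __post_init__(self):
        e = np.asarray(self.entries)
        if e.ndim != 2 or e.shape[0] != e.shape[1]:
            raise ValueError(f"structure must be square, got shape {e.shape}")
        if not np.isin(e, (-1, 0, 1)).all():
            raise ValueError("structure entries must be -1, 0 or +1")
        object.__setattr__(self, "entries", e.astype(np.int8))

    @property
    def n(self) -> int:
        return self.entries.shape[0]

    def __eq__(self, other) -> bool:
        if isinstance(other, SignedStructure):
            other = other.entries
        return self.entries.shape == np.shape(other) and bool(
            np.array_equal(self.entries, other)
        )

    def __hash__(self):
        return hash(self.entries.tobytes())


@dataclass(frozen=True)
class Trajectory:
    """A recorded orbit segment: ``states[t]`` is the activation at ``start_time + t``."""

    states: np.ndarray
    start_time: int = 0

    def __post_init__(self):
        s = np.asarray(self.states, dtype=float)
        if s.ndim != 2 or s.shape[0] < 1:
            raise ValueError("states must be a non-empty (T, n) array")
        object.__setattr__(self, "states", s)

    @property
    def n_steps(self) -> int:
        return self.states.shape[0]

    def outputs(self) -> np.ndarray:
        """Orbit mapped through tanh into the open cube (-1, 1)^n."""
        return np.tanh(self.states)


@dataclass(frozen=True)
class CycleRecord:
    """An elementary directed cycle with its inhibitory-edge parity.

    A cycle is *even* (*odd*) when it carries an even (odd) number of
    inhibitory, i.e. negative-weight, connections.  A self-connection is a
    cycle of length 1.
    """

    node_sequence: tuple[int, ...]
    n_inhibitory: int

    def __post_init__(self):
        if len(self.node_sequence) < 1:
            raise ValueError("cycle must contain at least one node")
        if len(set(self.node_sequence)) != len(self.node_sequence):
            raise ValueError("cycle nodes must be distinct")

    @property
    def length(self) -> int:
        return len(self.node_sequence)

    @property
    def parity(self) -> str:
        return "even" if self.n_inhibitory % 2 == 0 else "odd"


def step(module: Neuromodule, a) -> np.ndarray:
    """One step of the dynamics: ``a' = theta + w @ tanh(a)``.

    ``a`` may be a single activation vector of length ``n`` or a batch of
    shape ``(..., n)``; the map is applied to each row.  Pure: inputs are
    not mutated and the result is deterministic.
    """
    a = np.asarray(a, dtype=float)
    if a.shape[-1] != module.n:
        raise ValueError(
            f"activation has dimension {a.shape[-1]}, module expects {module.n}"
        )
    return module.theta + np.tanh(a) @ module.weights.T


def activation_bound(module: Neuromodule) -> np.ndarray:
    """Per-neuron bound ``|theta_i| + sum_j |w_ij|`` holding after one step."""
    return np.abs(module.theta) + np.abs(module.weights).sum(axis=1)


def iterate(
    module: Neuromodule,
    a0,
    n_transient: int = 0,
    n_record: int = 1,
) -> Trajectory:
    """Iterate the map, discard ``n_transient`` steps, record ``n_record`` more.

    The first recorded state is ``a0`` itself when ``n_transient == 0``,
    i.e. the record covers times ``n_transient .. n_transient + n_record - 1``.
    """
    if n_transient < 0:
        raise ValueError("n_transient must be >= 0")
    if n_record < 1:
        raise ValueError("n_record must be >= 1")
    a = _as_vector(a0, n=module.n, name="a0")
    for _ in range(n_transient):
        a = step(module, a)
    states = np.empty((n_record, module.n))
    states[0] = a
    for t in range(1, n_record):
        a = step(module, a)
        states[t] = a
    if not np.all(np.isfinite(states)):
        raise FloatingPointError("non-finite state encountered during iteration")
    return Trajectory(states=states, start_time=n_transient)


def adjacency_matrix(module: Neuromodule, tol: float = 0.0) -> SignedStructure:
    """Connectivity pattern: 1 where ``w[i, j] != 0`` and ``i != j``, else 0.

    Self-connections are ignored by convention.  ``tol`` treats entries with
    ``|w| <= tol`` as absent (useful for numerically derived matrices).
    """
    entries = (np.abs(module.weights) > tol).astype(np.int8)
    np.fill_diagonal(entries, 0)
    return SignedStructure(entries)


def structure_matrix(module: Neuromodule, tol: float = 0.0) -> SignedStructure:
    """Sign pattern of the weight matrix, self-connections included."""
    w = module.weights
    entries = np.sign(w).astype(np.int8)
    if tol > 0.0:
        entries[np.abs(w) <= tol] = 0
    return SignedStructure(entries)


def to_digraph(module: Neuromodule, tol: float = 0.0) -> nx.DiGraph:
    """Directed graph of nonzero weights; edge ``j -> i`` iff ``w[i, j] != 0``.

    Edges carry ``weight`` and ``sign`` attributes.  Self-loops included.
    """
    g = nx.DiGraph()
    g.add_nodes_from(range(module.n))
    w = module.weights
    for i in range(module.n):
        for j in range(module.n):
            if abs(w[i, j]) > tol:
                g.add_edge(j, i, weight=w[i, j], sign=int(np.sign(w[i, j])))
    return g


def is_strongly_connected(module: Neuromodule) -> bool:
    """Whether every neuron is reachable from every other along nonzero weights.

    Self-connections are irrelevant for reachability.  A single neuron
    counts as strongly connected (the weight matrix is then trivially
    irreducible).
    """
    if module.n == 1:
        return True
    g = to_digraph(module)
    g.remove_edges_from(nx.selfloop_edges(g))
    return nx.is_strongly_connected(g)


def _canonical_rotation(nodes: Sequence[int]) -> tuple[int, ...]:
    k = int(np.argmin(nodes))
    return tuple(nodes[k:]) + tuple(nodes[:k])


def cycle_census(module: Neuromodule, max_length: int | None = None) -> list[CycleRecord]:
    """Enumerate elementary directed cycles of length <= ``max_length``.

    Every cycle is annotated with the number of inhibitory (negative)
    connections it traverses and hence its parity.  Cycles are rotated to
    start at their smallest node and the list is sorted by
    ``(length, node_sequence)``, so the output is deterministic.  Default
    ``max_length`` is the module dimension (all elementary cycles).
    """
    if max_length is None:
        max_length = module.n
    if max_length < 1:
        raise ValueError("max_length must be >= 1")
    g = to_digraph(module)
    w = module.weights
    records = []
    for nodes in nx.simple_cycles(g, length_bound=max_length):
        seq = _canonical_rotation(nodes)
        n_inh = sum(
            1
            for u, v in zip(seq, seq[1:] + seq[:1])
            if w[v, u] < 0  # edge u -> v has weight w[v, u]
        )
        records.append(CycleRecord(node_sequence=seq, n_inhibitory=n_inh))
    records.sort(key=lambda r: (r.length, r.node_sequence))
    return records
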