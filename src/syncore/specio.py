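"""Plain-text (YAML) spec files for networks and coupled pairs.

Human-editable schema, 1-based neuron numbering (the Python API is
0-based).  A network spec:

.. code-block:: yaml

    name: odd2cycle
    n: 2
    theta: [0.0, 0.0]
    weights:            # dense, row-major: weights[i][j] is j -> i
      - [0.0, 1.6]
      - [-1.6, 0.0]

or, equivalently, with an edge list where each entry ``[i, j, value]``
declares a synapse from neuron ``j`` to neuron ``i`` (1-based):

.. code-block:: yaml

    name: odd2cycle
    n: 2
    theta: [0.0, 0.0]
    edges:
      - [1, 2, 1.6]
      - [2, 1, -1.6]

A coupled-pair spec carries ``thetaA``/``thetaB`` and the four blocks
``wA``, ``wB``, ``wAB``, ``wBA`` in the same dense-or-edges dialect.
Weights are written back as decimal text that round-trips exactly
(shortest repr of the double).
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .coupling import CoupledPair, sync_residual
from .network import Neuromodule, SignedStructure

__all__ = [
    "read_network",
    "write_network",
    "read_pair",
    "write_pair",
    "load_system",
    "structure_edge_list",
    "structure_to_dot",
    "SpecError",
]


class SpecError(ValueError):
    """Malformed spec file."""


def _float_representer(dumper, value):
    return dumper.represent_scalar("tag:yaml.org,2002:float", repr(float(value)))


class _Dumper(yaml.SafeDumper):
    pass


_Dumper.add_representer(float, _float_representer)


def _parse_matrix(doc: dict, key: str, n: int, where: str) -> np.ndarray:
    dense = doc.get(key)
    edges = doc.get(f"{key}_edges") if key != "weights" else doc.get("edges")
    if dense is not None and edges is not None:
        raise SpecError(f"{where}: give either dense '{key}' or its edge list, not both")
    if dense is not None:
        m = np.asarray(dense, dtype=float)
        if m.shape != (n, n):
            raise SpecError(f"{where}: '{key}' must be {n}x{n}, got {m.shape}")
        return m
    if edges is not None:
        m = np.zeros((n, n))
        for k, entry in enumerate(edges):
            if len(entry) != 3:
                raise SpecError(f"{where}: edge {k} must be [i, j, value] (1-based, j -> i)")
            i, j, value = entry
            if not (1 <= int(i) <= n and 1 <= int(j) <= n):
                raise SpecError(f"{where}: edge {k} index out of range 1..{n}")
            m[int(i) - 1, int(j) - 1] = float(value)
        return m
    raise SpecError(f"{where}: missing '{key}' (dense rows) or its edge list")


def _parse_vector(doc: dict, key: str, n: int, where: str) -> np.ndarray:
    if key not in doc:
        raise SpecError(f"{where}: missing '{key}'")
    v = np.asarray(doc[key], dtype=float)
    if v.shape != (n,):
        raise SpecError(f"{where}: '{key}' must have length {n}")
    return v


def _load_doc(path) -> dict:
    text = Path(path).read_text()
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise SpecError(f"{path}: top level must be a mapping")
    return doc


def read_network(path) -> Neuromodule:
    """Read and validate a network spec file."""
    doc = _load_doc(path)
    where = str(path)
    try:
        n = int(doc["n"])
    except KeyError:
        raise SpecError(f"{where}: missing 'n'") from None
    if n < 1:
        raise SpecError(f"{where}: n must be positive")
    theta = _parse_vector(doc, "theta", n, where)
    weights = _parse_matrix(doc, "weights", n, where)
    return Neuromodule(theta=theta, weights=weights, name=doc.get("name"))


def write_network(module: Neuromodule, path) -> None:
    """Write a dense network spec; reading it back reproduces the module exactly."""
    doc: dict[str, Any] = {}
    if module.name:
        doc["name"] = module.name
    doc["n"] = module.n
    doc["theta"] = [float(x) for x in module.theta]
    doc["weights"] = [[float(x) for x in row] for row in module.weights]
    Path(path).write_text(
        yaml.dump(doc, Dumper=_Dumper, sort_keys=False, default_flow_style=None)
    )


_PAIR_KEYS = ("wA", "wB", "wAB", "wBA")


def read_pair(path) -> CoupledPair:
    """Read and validate a coupled-pair spec file."""
    doc = _load_doc(path)
    where = str(path)
    try:
        n = int(doc["n"])
    except KeyError:
        raise SpecError(f"{where}: missing 'n'") from None
    if n < 1:
        raise SpecError(f"{where}: n must be positive")
    blocks = {key: _parse_matrix(doc, key, n, where) for key in _PAIR_KEYS}
    return CoupledPair(
        thetaA=_parse_vector(doc, "thetaA", n, where),
        thetaB=_parse_vector(doc, "thetaB", n, where),
        name=doc.get("name"),
        **blocks,
    )


def write_pair(pair: CoupledPair, path) -> None:
    """Write a dense coupled-pair spec (exact round trip)."""
    doc: dict[str, Any] = {}
    if pair.name:
        doc["name"] = pair.name
    doc["n"] = pair.n
    doc["thetaA"] = [float(x) for x in pair.thetaA]
    doc["thetaB"] = [float(x) for x in pair.thetaB]
    for key in _PAIR_KEYS:
        doc[key] = [[float(x) for x in row] for row in getattr(pair, key)]
    Path(path).write_text(
        yaml.dump(doc, Dumper=_Dumper, sort_keys=False, default_flow_style=None)
    )


def load_system(path) -> Neuromodule | CoupledPair:
    """Read either kind of spec file, deciding by the fields present."""
    doc = _load_doc(path)
    if any(k in doc for k in _PAIR_KEYS):
        return read_pair(path)
    return read_network(path)


def pair_report_fields(pair: CoupledPair) -> dict:
    """Validation summary used by loaders and the CLI."""
    return {
        "n": pair.n,
        "recurrent": pair.is_recurrent(),
        "sync_residual": sync_residual(pair),
    }


def structure_edge_list(structure: SignedStructure) -> list[tuple[int, int, int]]:
    """Signed edges ``(source, target, sign)``, 1-based, sorted."""
    e = structure.entries
    return [
        (j + 1, i + 1, int(e[i, j]))
        for j in range(structure.n)
        for i in range(structure.n)
        if e[i, j] != 0
    ]


def structure_to_dot(structure: SignedStructure, name: str = "structure") -> str:
    """DOT digraph with a ``sign`` attribute per edge, for external viewers."""
    lines = [f"digraph {name} {{"]
    for src, dst, sign in structure_edge_list(structure):
        style = "" if sign > 0 else " style=dashed"
        lines.append(f'  {src} -> {dst} [sign={sign:+d}{style}];')
    lines.append("}")
    return "\n".join(lines)
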