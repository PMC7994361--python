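"""Attractor detection, classification, censuses and bifurcation scans.

The basic procedure mirrors how attractor landscapes of small recurrent
networks are mapped numerically: draw random initial conditions in the
output cube ``(-1, 1)^n`` (mapped to activations through arctanh), iterate
past a transient, record a block of states, then

* detect a minimal period ``p <= max_period`` by whole-block recurrence
  within ``point_tol`` (the smallest shift under which the recorded block
  repeats; checking shifts in ascending order enforces minimality);
* otherwise estimate the largest Lyapunov exponent along the orbit and
  label the motion chaotic (``lambda1 > chaos_tol``) or quasiperiodic.

Distinct initial conditions reaching the same limit set are merged by the
symmetric Hausdorff distance between their recorded point clouds in output
space; basin hits accumulate on the surviving representative.

For coupled pairs, attractors inside the synchronization manifold whose
transversal exponent is positive are invisible to off-manifold sampling:
they attract nothing in the full state space (they are relative attractors
of the invariant diagonal).  :func:`coupled_census` therefore devotes a
fraction of the initial conditions to the manifold itself, where the exact
synchronized dynamics is the n-dimensional ``w+``-module; those orbits are
embedded back as ``(xi, xi)`` and deduplicated jointly with the
off-manifold sample.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import numpy as np
from scipy.spatial.distance import cdist

from .coupling import DEFAULT_SYNC_TOL, CoupledPair, assemble, synchronized_module
from .network import Neuromodule, step
from .stability import tangent_matrix

__all__ = [
    "CensusSettings",
    "Attractor",
    "AttractorSet",
    "BifurcationData",
    "find_attractor",
    "census",
    "coupled_census",
    "is_synchronized",
    "swap_image",
    "bifurcation_scan",
]

_CLIP = 1.0 - 1e-9  # outputs are clipped to +-(1 - 1e-9) before arctanh


@dataclass(frozen=True)
class CensusSettings:
    """Lengths and tolerances for attractor detection.

    Defaults are sized for few-neuron systems whose coexisting attractors
    are separated by order 0.1 in output space: the transient settles onto
    an attractor to well below ``point_tol``, the recorded block is long
    enough that two samples of the same chaotic set lie within ~0.1 of
    each other in Hausdorff distance, and the merge thresholds sit between
    sampling noise and true attractor separation.

    * ``n_transient`` / ``n_record``: discarded and recorded steps.
    * ``max_period``: largest minimal period searched for.
    * ``point_tol``: recurrence tolerance for period detection.
    * ``chaos_tol``: |lambda1| above this means chaotic.
    * ``sync_tol``: per-neuron |a_i - b_i| below this on every recorded
      state means synchronized (coupled systems only).
    * ``dedup_tol``: Hausdorff merge threshold for fixed points and
      periodic orbits (resolved to point_tol, so separation dominates).
    * ``cloud_tol``: Hausdorff merge threshold for chaotic/quasiperiodic
      sample clouds, looser because two finite samples of one chaotic
      attractor differ by the sampling gaps of the cloud itself.
    * ``lyap_steps``: averaging length for the largest-exponent estimate.
    """

    n_transient: int = 10_000
    n_record: int = 2_000
    max_period: int = 64
    point_tol: float = 1e-6
    chaos_tol: float = 5e-3
    sync_tol: float = 1e-6
    dedup_tol: float = 1e-2
    cloud_tol: float = 0.2
    lyap_steps: int = 20_000


@dataclass(frozen=True)
class Attractor:
    """A classified limit set.

    ``kind`` is one of ``fixed_point``, ``periodic``, ``quasiperiodic``,
    ``chaotic``; ``period`` is the minimal period (1 for fixed points,
    None otherwise).  ``sample_points`` are post-transient activation
    states on the attractor — the full periodic orbit for periodic kinds,
    a recorded cloud otherwise.  ``synchronized`` is set for coupled
    systems when every sample has ``max_i |a_i - b_i| < sync_tol``.
    ``low_confidence`` marks aperiodic orbits whose exponent estimate does
    not clearly resolve chaotic vs quasiperiodic (or that may still be in
    a transient).
    """

    kind: str
    period: int | None
    sample_points: np.ndarray
    lyapunov1: float
    synchronized: bool | None = None
    basin_hits: int = 1
    low_confidence: bool = False

    def __post_init__(self):
        object.__setattr__(
            self, "sample_points", np.asarray(self.sample_points, dtype=float)
        )

    def outputs(self) -> np.ndarray:
        """Samples mapped to output space; always strictly inside (-1, 1)."""
        return np.tanh(self.sample_points)


@dataclass(frozen=True)
class AttractorSet:
    """Census result: deduplicated attractors with their basin hit counts."""

    attractors: tuple[Attractor, ...]
    n_inits: int
    seed: int | None
    settings: CensusSettings

    def __len__(self) -> int:
        return len(self.attractors)

    def __iter__(self):
        return iter(self.attractors)

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for a in self.attractors:
            out[a.kind] = out.get(a.kind, 0) + 1
        return out

    def summary(self) -> str:
        lines = []
        for k, a in enumerate(self.attractors):
            sync = (
                ""
                if a.synchronized is None
                else (" synchronized" if a.synchronized else " asynchronous")
            )
            per = f" period={a.period}" if a.period else ""
            flag = " (low confidence)" if a.low_confidence else ""
            lines.append(
                f"attractor {k}:{sync} {a.kind}{per} "
                f"lambda1={a.lyapunov1:+.4f} basin_hits={a.basin_hits}{flag}"
            )
        return "\n".join(lines)


@dataclass(frozen=True)
class BifurcationData:
    """Asymptotic mean-output samples over a parameter grid.

    ``samples[k]`` holds, for grid point ``param_values[k]``, the recorded
    values of the mean output ``(o_1 + ... + o_n) / n`` collected from all
    initial conditions at that parameter.
    """

    param_name: str
    param_values: np.ndarray
    samples: tuple[np.ndarray, ...]

    def to_frame(self):
        import pandas as pd

        rows = [
            (v, s)
            for v, block in zip(self.param_values, self.samples)
            for s in block
        ]
        return pd.DataFrame(rows, columns=[self.param_name, "mean_output"])


# ---------------------------------------------------------------------------
# recording and classification


def _batch_record(
    module: Neuromodule, a0: np.ndarray, n_transient: int, n_record: int
) -> np.ndarray:
    """Iterate a batch of initial states; return (n_record, N, n) block."""
    a = np.array(a0, dtype=float)
    for _ in range(n_transient):
        a = step(module, a)
    rec = np.empty((n_record,) + a.shape)
    for t in range(n_record):
        rec[t] = a
        a = step(module, a)
    if not np.all(np.isfinite(rec)):
        raise FloatingPointError("non-finite state during census recording")
    return rec


def _detect_periods(rec: np.ndarray, max_period: int, point_tol: float) -> np.ndarray:
    """Minimal period per column of a (T, N, n) block; 0 when none found.

    Period ``p`` requires the whole block to repeat under a shift of ``p``
    within ``point_tol`` — far stronger than a single near-return, so
    chaotic near-recurrences do not masquerade as periods.
    """
    T, N, _ = rec.shape
    periods = np.zeros(N, dtype=int)
    for p in range(1, min(max_period, T - 1) + 1):
        undecided = periods == 0
        if not undecided.any():
            break
        diff = np.abs(rec[p:, undecided, :] - rec[:-p, undecided, :]).max(axis=(0, 2))
        hit = diff < point_tol
        idx = np.nonzero(undecided)[0][hit]
        periods[idx] = p
    return periods


def _lyap1_along(module: Neuromodule, a0: np.ndarray, n_steps: int) -> float:
    """Largest Lyapunov exponent by tangent-vector power iteration."""
    a = np.array(a0, dtype=float)
    v = np.full(module.n, 1.0 / np.sqrt(module.n))
    acc = 0.0
    for _ in range(n_steps):
        v = tangent_matrix(module, a) @ v
        norm = float(np.linalg.norm(v))
        if norm == 0.0:
            return -np.inf
        acc += np.log(norm)
        v /= norm
        a = step(module, a)
    return acc / n_steps


def _lyap1_periodic(module: Neuromodule, orbit: np.ndarray) -> float:
    """Exact largest exponent of a periodic orbit from one Jacobian product."""
    j = np.eye(module.n)
    for a in orbit:
        j = tangent_matrix(module, a) @ j
    moduli = np.abs(np.linalg.eigvals(j))
    top = moduli.max()
    if top == 0.0:
        return -np.inf
    return float(np.log(top)) / orbit.shape[0]


def _classify_kind(period: int, lyap1: float, chaos_tol: float) -> tuple[str, bool]:
    if period == 1:
        return "fixed_point", False
    if period >= 2:
        return "periodic", False
    if lyap1 > chaos_tol:
        return "chaotic", False
    # no period found and exponent not clearly positive: quasiperiodic,
    # flagged when the estimate is not clearly ~0 either
    return "quasiperiodic", not (-chaos_tol <= lyap1 <= chaos_tol)


def _sync_flags(rec: np.ndarray, sync_tol: float) -> np.ndarray:
    """Per-column synchronization flag for a (T, N, 2m) block."""
    m = rec.shape[2] // 2
    return np.abs(rec[:, :, :m] - rec[:, :, m:]).max(axis=(0, 2)) < sync_tol


def _hausdorff(x: np.ndarray, y: np.ndarray) -> float:
    d = cdist(x, y, "chebyshev")
    return max(d.min(axis=1).max(), d.min(axis=0).max())


def is_synchronized(samples, sync_tol: float = 1e-6) -> bool:
    """Whether every sample of a coupled-system orbit has ``a == b`` within tol.

    ``samples`` is an (T, 2m) array (or an :class:`Attractor`); the first
    half of each state is module A, the second module B.
    """
    if isinstance(samples, Attractor):
        samples = samples.sample_points
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if samples.shape[1] % 2:
        raise ValueError("synchronization is defined for even-dimensional states")
    m = samples.shape[1] // 2
    return bool(np.abs(samples[:, :m] - samples[:, m:]).max() < sync_tol)


def swap_image(attractor: Attractor) -> Attractor:
    """The attractor with the two module blocks of every sample exchanged.

    For a coupled pair of identical modules the dynamics commutes with the
    block swap, so the census must be closed under this image: either an
    attractor is its own swap image (e.g. anything synchronized) or its
    partner appears in the census too.
    """
    s = np.atleast_2d(attractor.sample_points)
    if s.shape[1] % 2:
        raise ValueError("swap image requires an even-dimensional state")
    m = s.shape[1] // 2
    swapped = np.concatenate([s[:, m:], s[:, :m]], axis=1)
    return replace(attractor, sample_points=swapped)


# ---------------------------------------------------------------------------
# censuses


def _dedup_key_cloud(
    rec_i: np.ndarray, period: int
) -> np.ndarray:
    """Output-space cloud used for Hausdorff comparison."""
    if period > 0:
        return np.tanh(rec_i[:period])
    # full cloud, never a strided subsample: chaotic attractors born from
    # periodic windows cycle through bands, and a stride resonant with the
    # band period would alias one attractor into disjoint clouds; slowly
    # mixing attractors also need the whole record for stable coverage
    return np.tanh(rec_i)


def _merge_into(
    reps: list[dict],
    cloud: np.ndarray,
    period: int,
    synchronized: bool | None,
    settings: CensusSettings,
) -> int | None:
    """Index of the matching representative, or None."""
    thr = settings.dedup_tol if period > 0 else settings.cloud_tol
    for k, rep in enumerate(reps):
        if rep["period"] != period or rep["synchronized"] != synchronized:
            continue
        if _hausdorff(cloud, rep["cloud"]) < thr:
            return k
    return None


def _census_from_records(
    module: Neuromodule,
    rec: np.ndarray,
    settings: CensusSettings,
    sync_flags: np.ndarray | None,
    lyap_module: Neuromodule | None = None,
    lyap_project=None,
) -> list[dict]:
    """Group recorded orbits into attractor representatives.

    ``lyap_module``/``lyap_project`` override where the largest-exponent
    estimate is computed (used for on-manifold orbits, whose exponent must
    come from the exact synchronized dynamics rather than the full system).
    """
    periods = _detect_periods(rec, settings.max_period, settings.point_tol)
    reps: list[dict] = []
    for i in range(rec.shape[1]):
        p = int(periods[i])
        sync = bool(sync_flags[i]) if sync_flags is not None else None
        cloud = _dedup_key_cloud(rec[:, i, :], p)
        k = _merge_into(reps, cloud, p, sync, settings)
        if k is not None:
            reps[k]["hits"] += 1
            continue
        reps.append(
            {
                "period": p,
                "synchronized": sync,
                "cloud": cloud,
                "samples": rec[:p, i, :] if p > 0 else rec[:, i, :],
                "hits": 1,
                "last_state": rec[-1, i, :],
            }
        )
    # largest exponent once per representative
    for rep in reps:
        mod = lyap_module if lyap_module is not None else module
        proj = lyap_project if lyap_project is not None else (lambda s: s)
        if rep["period"] > 0:
            rep["lyap1"] = _lyap1_periodic(mod, proj(rep["samples"]))
        else:
            rep["lyap1"] = _lyap1_along(mod, proj(rep["last_state"]), settings.lyap_steps)
    return reps


def _reps_to_attractors(reps: list[dict], settings: CensusSettings) -> list[Attractor]:
    out = []
    for rep in reps:
        kind, low_conf = _classify_kind(rep["period"], rep["lyap1"], settings.chaos_tol)
        out.append(
            Attractor(
                kind=kind,
                period=rep["period"] if rep["period"] > 0 else None,
                sample_points=rep["samples"],
                lyapunov1=float(rep["lyap1"]),
                synchronized=rep["synchronized"],
                basin_hits=rep["hits"],
                low_confidence=low_conf,
            )
        )
    # deterministic presentation: synchronized first, then by period, kind
    out.sort(
        key=lambda a: (
            a.synchronized is not True,
            a.period is None,
            a.period or 0,
            a.kind,
            -a.basin_hits,
        )
    )
    return out


def _random_activations(rng: np.random.Generator, count: int, dim: int) -> np.ndarray:
    """Initial activations sampled uniformly in output space (-1, 1)^dim."""
    o = rng.uniform(-1.0, 1.0, size=(count, dim))
    return np.arctanh(np.clip(o, -_CLIP, _CLIP))


def find_attractor(
    module: Neuromodule,
    a0,
    settings: CensusSettings = CensusSettings(),
    coupled: bool = False,
) -> Attractor:
    """Classify the attractor reached from a single initial condition.

    With ``coupled`` the state is treated as the ``(a, b)`` pair of a
    coupled system and the synchronized flag is reported.
    """
    a0 = np.atleast_2d(np.asarray(a0, dtype=float))
    rec = _batch_record(module, a0, settings.n_transient, settings.n_record)
    flags = _sync_flags(rec, settings.sync_tol) if coupled else None
    reps = _census_from_records(module, rec, settings, flags)
    return _reps_to_attractors(reps, settings)[0]


def census(
    module: Neuromodule,
    n_inits: int,
    seed: int | None = None,
    settings: CensusSettings = CensusSettings(),
    coupled: bool = False,
) -> AttractorSet:
    """Attractor census from random initial conditions in the output cube.

    Deterministic given ``seed``.  Counts of chaotic attractors are only as
    good as the sample: the result reports the ``n_inits`` and settings it
    was computed with, and should be read as "at least these attractors".
    """
    if n_inits < 1:
        raise ValueError("n_inits must be >= 1")
    rng = np.random.default_rng(seed)
    a0 = _random_activations(rng, n_inits, module.n)
    rec = _batch_record(module, a0, settings.n_transient, settings.n_record)
    flags = _sync_flags(rec, settings.sync_tol) if coupled else None
    reps = _census_from_records(module, rec, settings, flags)
    return AttractorSet(
        attractors=tuple(_reps_to_attractors(reps, settings)),
        n_inits=n_inits,
        seed=seed,
        settings=settings,
    )


def coupled_census(
    pair: CoupledPair,
    n_inits: int,
    seed: int | None = None,
    settings: CensusSettings = CensusSettings(),
    manifold_fraction: float = 0.2,
    tol: float = DEFAULT_SYNC_TOL,
) -> AttractorSet:
    """Census of a synchronizable coupled pair, including on-manifold attractors.

    ``n_inits`` initial conditions are drawn in total: a fraction
    ``manifold_fraction`` on the synchronization manifold (iterated under
    the exact synchronized ``w+``-module and embedded as ``(xi, xi)``), the
    rest in the full output cube.  Off-manifold inits find asynchronous
    attractors and transversally stable synchronized ones; on-manifold
    inits additionally expose synchronized attractors whose transversal
    exponent is positive, which no off-manifold sample can reach.  All
    orbits are deduplicated jointly.
    """
    if not 0.0 <= manifold_fraction <= 1.0:
        raise ValueError("manifold_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_manifold = int(round(manifold_fraction * n_inits))
    n_full = n_inits - n_manifold
    module = assemble(pair)
    sync_mod = synchronized_module(pair, tol)
    n = pair.n

    reps: list[dict] = []
    if n_full > 0:
        a0 = _random_activations(rng, n_full, 2 * n)
        rec = _batch_record(module, a0, settings.n_transient, settings.n_record)
        flags = _sync_flags(rec, settings.sync_tol)
        reps = _census_from_records(module, rec, settings, flags)
        # a full-space orbit that has collapsed onto the manifold carries
        # the synchronized dynamics: estimate its exponent there
        for rep in reps:
            if rep["synchronized"] and rep["period"] == 0:
                rep["lyap1"] = _lyap1_along(
                    sync_mod, rep["last_state"][:n], settings.lyap_steps
                )

    if n_manifold > 0:
        xi0 = _random_activations(rng, n_manifold, n)
        rec_xi = _batch_record(sync_mod, xi0, settings.n_transient, settings.n_record)
        rec_emb = np.concatenate([rec_xi, rec_xi], axis=2)
        flags = np.ones(n_manifold, dtype=bool)
        man_reps = _census_from_records(
            sync_mod,
            rec_emb,
            settings,
            flags,
            lyap_module=sync_mod,
            lyap_project=lambda s: np.asarray(s)[..., :n],
        )
        for rep in man_reps:
            k = _merge_into(reps, rep["cloud"], rep["period"], True, settings)
            if k is None:
                reps.append(rep)
            else:
                reps[k]["hits"] += rep["hits"]

    return AttractorSet(
        attractors=tuple(_reps_to_attractors(reps, settings)),
        n_inits=n_inits,
        seed=seed,
        settings=settings,
    )


def bifurcation_scan(
    module: Neuromodule,
    neuron_index: int,
    grid,
    settings: CensusSettings = CensusSettings(),
    n_inits: int = 8,
    n_transient: int = 2_000,
    n_record: int = 200,
    seed: int | None = None,
    sweep: bool = True,
) -> BifurcationData:
    """Scan the bias of one neuron over a grid, recording mean outputs.

    At each grid value the network runs from ``n_inits`` fresh random
    initial conditions (exposing coexisting branches) and — with ``sweep``
    — additionally from the final states of the previous grid point
    (following branches through bifurcations).  Recorded are the values of
    the mean output ``(o_1 + ... + o_n)/n`` over ``n_record`` steps after
    the transient.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 1:
        raise ValueError("grid must be a non-empty 1-D array")
    d = np.diff(grid)
    if grid.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
        raise ValueError("grid must be strictly monotone")
    if not 0 <= neuron_index < module.n:
        raise ValueError("neuron_index out of range")
    rng = np.random.default_rng(seed)
    carried: np.ndarray | None = None
    blocks = []
    for value in grid:
        theta = module.theta.copy()
        theta[neuron_index] = value
        mod = Neuromodule(theta=theta, weights=module.weights, name=module.name)
        a0 = _random_activations(rng, n_inits, module.n)
        if sweep and carried is not None:
            a0 = np.vstack([a0, carried])
        rec = _batch_record(mod, a0, n_transient, n_record)
        carried = rec[-1] if sweep else None
        blocks.append(np.tanh(rec).mean(axis=2).ravel().copy())
    return BifurcationData(
        param_name=f"theta[{neuron_index}]",
        param_values=grid,
        samples=tuple(blocks),
    )
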