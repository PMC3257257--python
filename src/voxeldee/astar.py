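"""A* enumeration of conformations in nondecreasing bound order.

Conformations (one rotamer per design position) are generated best-first
under an admissible completion heuristic, so the stream of fully assigned
conformations arrives in nondecreasing order of

    bound(A) = E_template + sum_i E(i_r) + sum_{i<j} E(i_r, j_s)

evaluated either on rigid energies or on voxel lower bounds (the
sum-of-lower-bounds E_lb(A) that underpins MinDEE/A* and iMinDEE).
Pruned rotamers and flagged pairs never appear in emitted conformations.

``enumerate_and_minimize`` couples the stream to continuous minimization
with the minimization-aware stopping rule: enumeration stops at the first
conformation whose bound exceeds the best minimized energy seen so far
(optionally slackened by the GEM interval during a first-phase search),
at which point no unseen conformation can minimize below the best.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .energy import DesignInstance
from .matrix import EnergyMatrix, minimize_conformation
from .pruning import PruningState

__all__ = [
    "astar_enumerate",
    "EnumeratedConformation",
    "EnumerationResult",
    "enumerate_and_minimize",
]


def _accessors(matrix: EnergyMatrix, energy_kind: str):
    if energy_kind == "rigid":
        return (lambda i, r: matrix.single_rigid[i][r]), matrix.pair_rigid_entry
    if energy_kind == "lower_bound":
        return (lambda i, r: matrix.single_lo[i][r]), matrix.pair_lo_entry
    raise ValueError(f"energy_kind must be 'rigid' or 'lower_bound', got {energy_kind!r}")


def astar_enumerate(
    matrix: EnergyMatrix,
    state: PruningState,
    energy_kind: str = "lower_bound",
    max_queue: int = 2_000_000,
) -> Iterator[tuple[tuple[int, ...], float]]:
    """Yield (conformation, bound) pairs in nondecreasing bound order.

    Positions expand in a static order (fewest unpruned rotamers first,
    ties by index); equal-bound ties break lexicographically on the
    assignment for reproducibility.  An infeasible state yields nothing.
    """
    single, pair = _accessors(matrix, energy_kind)
    n = matrix.n_positions
    if state.infeasible or n == 0:
        return
    order = sorted(range(n), key=lambda i: (len(state.unpruned(i)), i))
    live = {i: state.unpruned(i) for i in range(n)}

    def h_and_feasible(assigned: dict[int, int]) -> float | None:
        """Admissible completion estimate; None when no valid completion."""
        unassigned = [j for j in range(n) if j not in assigned]
        # candidate sets respecting flags against the assigned part
        cand: dict[int, list[int]] = {}
        for j in unassigned:
            ok = [
                s for s in live[j]
                if all(not state.is_flagged(i, r, j, s) for i, r in assigned.items())
            ]
            if not ok:
                return None
            cand[j] = ok
        total = 0.0
        for a, j in enumerate(unassigned):
            best = None
            for s in cand[j]:
                v = single(j, s) + sum(
                    pair(i, r, j, s) for i, r in assigned.items()
                )
                for k in unassigned[a + 1:]:
                    v += min(pair(j, s, k, u) for u in cand[k])
                if best is None or v < best:
                    best = v
            total += best
        return total

    g0 = matrix.template
    h0 = h_and_feasible({})
    if h0 is None:
        return
    heap: list[tuple[float, tuple[int, ...]]] = [(g0 + h0, ())]
    while heap:
        if len(heap) > max_queue:
            raise MemoryError(
                f"A* queue exceeded {max_queue} nodes; raise max_queue or "
                "prune harder"
            )
        f, prefix = heapq.heappop(heap)
        depth = len(prefix)
        if depth == n:
            conf = [0] * n
            for d, i in enumerate(order):
                conf[i] = prefix[d]
            yield tuple(conf), f
            continue
        i = order[depth]
        assigned = {order[d]: prefix[d] for d in range(depth)}
        for r in live[i]:
            if any(state.is_flagged(ip, rp, i, r) for ip, rp in assigned.items()):
                continue
            child = assigned | {i: r}
            g = g0 + sum(single(p, q) for p, q in child.items())
            items = list(child.items())
            for a in range(len(items)):
                for b in range(a + 1, len(items)):
                    (pi, pr), (qj, qs) = items[a], items[b]
                    g += pair(pi, pr, qj, qs)
            h = h_and_feasible(child)
            if h is None:
                continue
            heapq.heappush(heap, (g + h, prefix + (r,)))


@dataclass
class EnumeratedConformation:
    conformation: tuple[int, ...]
    lower_bound: float
    minimized_energy: float | None = None
    deltas: list[np.ndarray] | None = None


@dataclass
class EnumerationResult:
    """Outcome of minimization-aware enumeration."""

    best: EnumeratedConformation | None
    first_bound: float  # E_lb(c_b): bound of the first emitted conformation
    n_enumerated: int
    exhausted: bool
    log: list[EnumeratedConformation] = field(default_factory=list)

    @property
    def best_energy(self) -> float:
        if self.best is None or self.best.minimized_energy is None:
            return math.inf
        return self.best.minimized_energy


def enumerate_and_minimize(
    instance: DesignInstance,
    matrix: EnergyMatrix,
    state: PruningState,
    energy_kind: str = "lower_bound",
    stop_slack: float | None = None,
    max_enumerate: int | None = None,
    minimize_kwargs: dict | None = None,
) -> EnumerationResult:
    """Minimize conformations in bound order until the stop rule fires.

    Standard rule: stop at the first emitted conformation whose bound
    strictly exceeds the lowest minimized energy found so far.  With
    ``stop_slack`` (GEM phase 1), the threshold is
    ``min(best_minimized, first_bound + stop_slack)`` so enumeration also
    covers every conformation within the initial interval of the lowest
    bound.  The triggering conformation is not minimized.
    """
    minimize_kwargs = minimize_kwargs or {}
    best: EnumeratedConformation | None = None
    first_bound = math.inf
    n_seen = 0
    exhausted = True
    log: list[EnumeratedConformation] = []
    for conf, bound in astar_enumerate(matrix, state, energy_kind):
        if n_seen == 0:
            first_bound = bound
        threshold = best.minimized_energy if best is not None else math.inf
        if stop_slack is not None:
            threshold = min(threshold, first_bound + stop_slack)
        if bound > threshold:
            exhausted = False
            break
        n_seen += 1
        e_min, deltas = minimize_conformation(instance, conf, **minimize_kwargs)
        rec = EnumeratedConformation(conf, bound, e_min, deltas)
        log.append(rec)
        if best is None or e_min < best.minimized_energy:
            best = rec
        if max_enumerate is not None and n_seen >= max_enumerate:
            exhausted = False
            break
    return EnumerationResult(
        best=best,
        first_bound=first_bound,
        n_enumerated=n_seen,
        exhausted=exhausted,
        log=log,
    )
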