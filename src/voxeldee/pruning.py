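"""Provable pruning of the conformation space: DEE, MinDEE, iMinDEE.

Three Goldstein-style criteria share one engine and differ only in which
matrix fields they compare:

* ``rigid``   — classic dead-end elimination on rigid (modal) energies: a
  rotamer is pruned when a competitor at the same position beats it in
  every context, so it cannot appear in the rigid GMEC.
* ``mindee``  — minimization-aware DEE.  Candidate terms use voxel lower
  bounds, competitor terms upper bounds, and maximum-range terms subtract
  the bound spread of every other position (and pair) to absorb the domino
  effect of minimization.  Never prunes the minGMEC.
* ``imindee`` — interval DEE.  Lower bounds only; the criterion must clear
  an interval I that bounds how far a true minimized energy can fall below
  its sum-of-lower-bounds.  With a valid I (>= E_T(minGMEC) - E_lb(c_b)),
  never prunes the minGMEC — and prunes far more than MinDEE because the
  loose maximum terms are gone.

On top of singles pruning: an initial steric filter, Goldstein pairs
flagging, single-split split flags, and (Min)Bounds pruning against a known
conformation energy, iterated to fixpoint.  Ties never prune (strict
inequalities); within one pass, decisions are evaluated against the state
at pass start and applied synchronously at pass end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

from .matrix import EnergyMatrix

__all__ = [
    "PruningState",
    "PruneConfig",
    "steric_filter",
    "goldstein_rigid",
    "goldstein_mindee",
    "goldstein_imindee",
    "pairs_flag",
    "split_flags",
    "bounds_prune",
    "prune_to_fixpoint",
]

_MODES = ("rigid", "mindee", "imindee")


@dataclass
class PruningState:
    """Pruned singles, flagged pairs, and the per-iteration log."""

    n_rotamers: list[int]
    pruned: list[set[int]] = field(default_factory=list)
    flagged: set[tuple[tuple[int, int], tuple[int, int]]] = field(default_factory=set)
    log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.pruned:
            self.pruned = [set() for _ in self.n_rotamers]

    @classmethod
    def fresh(cls, matrix: EnergyMatrix) -> "PruningState":
        return cls(n_rotamers=[matrix.n_rotamers(i) for i in range(matrix.n_positions)])

    @property
    def n_positions(self) -> int:
        return len(self.n_rotamers)

    def unpruned(self, pos: int) -> list[int]:
        return [r for r in range(self.n_rotamers[pos]) if r not in self.pruned[pos]]

    def is_pruned(self, pos: int, rot: int) -> bool:
        return rot in self.pruned[pos]

    def prune(self, pos: int, rot: int) -> None:
        self.pruned[pos].add(rot)

    @staticmethod
    def _key(i, r, j, s):
        return ((i, r), (j, s)) if i < j else ((j, s), (i, r))

    def flag(self, i: int, r: int, j: int, s: int) -> None:
        self.flagged.add(self._key(i, r, j, s))

    def is_flagged(self, i: int, r: int, j: int, s: int) -> bool:
        return self._key(i, r, j, s) in self.flagged

    @property
    def infeasible(self) -> bool:
        return any(len(self.pruned[i]) == self.n_rotamers[i]
                   for i in range(self.n_positions))

    def surviving_conformations(self) -> int:
        out = 1
        for i in range(self.n_positions):
            out *= self.n_rotamers[i] - len(self.pruned[i])
        return out

    def pruned_fraction(self) -> float:
        total = sum(self.n_rotamers)
        return sum(len(p) for p in self.pruned) / total if total else 0.0

    def copy(self) -> "PruningState":
        return PruningState(
            n_rotamers=list(self.n_rotamers),
            pruned=[set(p) for p in self.pruned],
            flagged=set(self.flagged),
            log=[dict(e) for e in self.log],
        )

    def report(self) -> dict:
        return {
            "iterations": self.log,
            "pruned_per_position": [sorted(p) for p in self.pruned],
            "n_flagged_pairs": len(self.flagged),
            "pruned_fraction": self.pruned_fraction(),
            "surviving_conformations": str(self.surviving_conformations()),
            "infeasible": self.infeasible,
        }


def _require_upper(matrix: EnergyMatrix) -> None:
    if not matrix.has_upper:
        raise ValueError(
            "MinDEE needs voxel upper bounds; run compute_bounds(..., "
            "with_upper=True) first"
        )


# ---------------------------------------------------------------------------
# Shared range terms for the MinDEE criterion
# ---------------------------------------------------------------------------

def _single_range_max(matrix, state, j) -> float:
    vals = [
        matrix.single_up[j][s] - matrix.single_lo[j][s]
        for s in state.unpruned(j)
    ]
    return max(vals) if vals else 0.0


def _pair_range_max(matrix, state, j, k) -> float:
    best = None
    for s in state.unpruned(j):
        for u in state.unpruned(k):
            if state.is_flagged(j, s, k, u):
                continue
            v = matrix.pair_up_entry(j, s, k, u) - matrix.pair_lo_entry(j, s, k, u)
            if best is None or v > best:
                best = v
    return best if best is not None else 0.0


def _mindee_range_terms(matrix, state, skip: tuple[int, ...]) -> float:
    """Sum of maximum-range terms over positions (and pairs) not in ``skip``."""
    n = matrix.n_positions
    others = [j for j in range(n) if j not in skip]
    total = sum(_single_range_max(matrix, state, j) for j in others)
    for a in range(len(others)):
        for b in range(a + 1, len(others)):
            total += _pair_range_max(matrix, state, others[a], others[b])
    return total


# ---------------------------------------------------------------------------
# Initial steric filter
# ---------------------------------------------------------------------------

def steric_filter(matrix: EnergyMatrix, threshold: float,
                  state: PruningState | None = None) -> PruningState:
    """Prune rotamers whose voxel-minimum template clash exceeds threshold.

    Uses the *lower* bound of the single energy, so a rotamer that clashes
    rigidly but can minimize away from the clash survives.
    """
    state = state or PruningState.fresh(matrix)
    count = 0
    for i in range(matrix.n_positions):
        for r in state.unpruned(i):
            if matrix.single_lo[i][r] > threshold:
                state.prune(i, r)
                count += 1
    state.log.append({"criterion": "steric", "pruned": count})
    return state


# ---------------------------------------------------------------------------
# Goldstein singles criteria
# ---------------------------------------------------------------------------

def _candidate_min_terms(matrix, state, mode, i, r, t) -> float | None:
    """Sum over j != i of the per-position minimum comparison term.

    Returns None when the candidate has no usable rotamer at some other
    position (it then belongs to no valid conformation at all).
    """
    n = matrix.n_positions
    total = 0.0
    for j in range(n):
        if j == i:
            continue
        best = None
        for s in state.unpruned(j):
            if state.is_flagged(i, r, j, s):
                continue
            if mode == "rigid":
                d = matrix.pair_rigid_entry(i, r, j, s) - \
                    matrix.pair_rigid_entry(i, t, j, s)
            elif mode == "mindee":
                # same witness s on both sides: candidate lower bound vs
                # competitor upper bound, so zero-width voxels collapse the
                # decision onto the rigid criterion exactly
                d = matrix.pair_lo_entry(i, r, j, s) - \
                    matrix.pair_up_entry(i, t, j, s)
            else:  # imindee
                d = matrix.pair_lo_entry(i, r, j, s) - \
                    matrix.pair_lo_entry(i, t, j, s)
            if best is None or d < best:
                best = d
        if best is None:
            return None
        total += best
    return total


def _goldstein_singles_pass(matrix, state, position, mode, interval) -> list[int]:
    i = position
    to_prune: list[int] = []
    live = state.unpruned(i)
    range_thresh = (
        _mindee_range_terms(matrix, state, skip=(i,)) if mode == "mindee" else 0.0
    )
    for r in live:
        doomed = False
        for t in live:
            if t == r:
                continue
            if mode == "rigid":
                lead = matrix.single_rigid[i][r] - matrix.single_rigid[i][t]
                thresh = 0.0
            elif mode == "mindee":
                lead = matrix.single_lo[i][r] - matrix.single_up[i][t]
                thresh = range_thresh
            else:
                lead = matrix.single_lo[i][r] - matrix.single_lo[i][t]
                thresh = interval
            terms = _candidate_min_terms(matrix, state, mode, i, r, t)
            if terms is None:
                doomed = True  # candidate cannot complete a valid conformation
                break
            if lead + terms > thresh:
                doomed = True
                break
        if doomed:
            to_prune.append(r)
    return to_prune


def goldstein_rigid(matrix: EnergyMatrix, state: PruningState, position: int) -> PruningState:
    """Rigid Goldstein DEE at one position: prune i_r when some competitor
    i_t satisfies E(i_r) - E(i_t) + sum_j min_s [E(i_r,j_s) - E(i_t,j_s)] > 0."""
    for r in _goldstein_singles_pass(matrix, state, position, "rigid", 0.0):
        state.prune(position, r)
    return state


def goldstein_mindee(matrix: EnergyMatrix, state: PruningState, position: int) -> PruningState:
    """MinDEE singles criterion with maximum-range terms (voxel bounds)."""
    _require_upper(matrix)
    for r in _goldstein_singles_pass(matrix, state, position, "mindee", 0.0):
        state.prune(position, r)
    return state


def goldstein_imindee(
    matrix: EnergyMatrix, state: PruningState, position: int, interval_I: float
) -> PruningState:
    """Interval criterion: lower-bound Goldstein comparison must clear I."""
    if interval_I < 0:
        raise ValueError("interval_I must be nonnegative")
    for r in _goldstein_singles_pass(matrix, state, position, "imindee", interval_I):
        state.prune(position, r)
    return state


def _singles(matrix, state, mode, interval) -> int:
    before = sum(len(p) for p in state.pruned)
    for i in range(matrix.n_positions):
        if mode == "rigid":
            goldstein_rigid(matrix, state, i)
        elif mode == "mindee":
            goldstein_mindee(matrix, state, i)
        else:
            goldstein_imindee(matrix, state, i, interval)
    return sum(len(p) for p in state.pruned) - before


# ---------------------------------------------------------------------------
# Goldstein pairs flagging
# ---------------------------------------------------------------------------

def pairs_flag(
    matrix: EnergyMatrix,
    state: PruningState,
    mode: str,
    interval_I: float = 0.0,
) -> PruningState:
    """Flag dominated rotamer pairs; flagged pairs are excluded from the
    singles minima and from A* expansion (no valid conformation uses them)."""
    if mode not in _MODES:
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "mindee":
        _require_upper(matrix)
    n = matrix.n_positions
    new_flags: list[tuple[int, int, int, int]] = []
    for i in range(n):
        for j in range(i + 1, n):
            range_thresh = (
                _mindee_range_terms(matrix, state, skip=(i, j))
                if mode == "mindee" else 0.0
            )
            live_i = state.unpruned(i)
            live_j = state.unpruned(j)
            cand_pairs = [
                (r, s)
                for r in live_i
                for s in live_j
                if not state.is_flagged(i, r, j, s)
            ]
            comp_pairs = cand_pairs
            for (r, s) in cand_pairs:
                if mode == "rigid":
                    cand_base = (
                        matrix.single_rigid[i][r] + matrix.single_rigid[j][s]
                        + matrix.pair_rigid_entry(i, r, j, s)
                    )
                elif mode == "mindee":
                    cand_base = (
                        matrix.single_lo[i][r] + matrix.single_lo[j][s]
                        + matrix.pair_lo_entry(i, r, j, s)
                    )
                else:
                    cand_base = (
                        matrix.single_lo[i][r] + matrix.single_lo[j][s]
                        + matrix.pair_lo_entry(i, r, j, s)
                    )
                flagged_now = False
                for (t, u) in comp_pairs:
                    if (t, u) == (r, s):
                        continue
                    if mode == "rigid":
                        comp_base = (
                            matrix.single_rigid[i][t] + matrix.single_rigid[j][u]
                            + matrix.pair_rigid_entry(i, t, j, u)
                        )
                        thresh = 0.0
                    elif mode == "mindee":
                        comp_base = (
                            matrix.single_up[i][t] + matrix.single_up[j][u]
                            + matrix.pair_up_entry(i, t, j, u)
                        )
                        thresh = range_thresh
                    else:
                        comp_base = (
                            matrix.single_lo[i][t] + matrix.single_lo[j][u]
                            + matrix.pair_lo_entry(i, t, j, u)
                        )
                        thresh = interval_I
                    total = cand_base - comp_base
                    ok = True
                    for k in range(n):
                        if k in (i, j):
                            continue
                        best = None
                        for v in state.unpruned(k):
                            if state.is_flagged(i, r, k, v) or state.is_flagged(j, s, k, v):
                                continue
                            if mode == "rigid":
                                d = (
                                    matrix.pair_rigid_entry(i, r, k, v)
                                    + matrix.pair_rigid_entry(j, s, k, v)
                                    - matrix.pair_rigid_entry(i, t, k, v)
                                    - matrix.pair_rigid_entry(j, u, k, v)
                                )
                            elif mode == "mindee":
                                d = (
                                    matrix.pair_lo_entry(i, r, k, v)
                                    + matrix.pair_lo_entry(j, s, k, v)
                                    - matrix.pair_up_entry(i, t, k, v)
                                    - matrix.pair_up_entry(j, u, k, v)
                                )
                            else:
                                d = (
                                    matrix.pair_lo_entry(i, r, k, v)
                                    + matrix.pair_lo_entry(j, s, k, v)
                                    - matrix.pair_lo_entry(i, t, k, v)
                                    - matrix.pair_lo_entry(j, u, k, v)
                                )
                            if best is None or d < best:
                                best = d
                        if best is None:
                            ok = False  # (r, s) has no usable partner at k
                            break
                        total += best
                    if not ok:
                        flagged_now = True  # unusable pair: flag it outright
                        break
                    if total > thresh:
                        flagged_now = True
                        break
                if flagged_now:
                    new_flags.append((i, r, j, s))
    for i, r, j, s in new_flags:
        state.flag(i, r, j, s)
    state.log.append({"criterion": f"pairs_{mode}", "flagged": len(new_flags)})
    return state


# ---------------------------------------------------------------------------
# Split flags (single splitting position)
# ---------------------------------------------------------------------------

def split_flags(
    matrix: EnergyMatrix,
    state: PruningState,
    mode: str,
    interval_I: float = 0.0,
) -> PruningState:
    """Single-split Goldstein: prune i_r when, for some split position j,
    every usable j_s admits a competitor i_t that dominates i_r given j_s."""
    if mode not in _MODES:
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "mindee":
        _require_upper(matrix)
    n = matrix.n_positions
    to_prune: list[tuple[int, int]] = []
    for i in range(n):
        live = state.unpruned(i)
        range_thresh = (
            _mindee_range_terms(matrix, state, skip=(i,)) if mode == "mindee" else 0.0
        )
        for r in live:
            pruned_here = False
            for j in range(n):
                if j == i or pruned_here:
                    continue
                usable_s = [
                    s for s in state.unpruned(j) if not state.is_flagged(i, r, j, s)
                ]
                if not usable_s:
                    pruned_here = True  # no valid conformation contains i_r
                    break
                all_dominated = True
                for s in usable_s:
                    dominated = False
                    for t in live:
                        if t == r:
                            continue
                        if mode == "rigid":
                            lead = (
                                matrix.single_rigid[i][r] - matrix.single_rigid[i][t]
                                + matrix.pair_rigid_entry(i, r, j, s)
                                - matrix.pair_rigid_entry(i, t, j, s)
                            )
                            thresh = 0.0
                        elif mode == "mindee":
                            lead = (
                                matrix.single_lo[i][r] - matrix.single_up[i][t]
                                + matrix.pair_lo_entry(i, r, j, s)
                                - matrix.pair_up_entry(i, t, j, s)
                            )
                            thresh = range_thresh
                        else:
                            lead = (
                                matrix.single_lo[i][r] - matrix.single_lo[i][t]
                                + matrix.pair_lo_entry(i, r, j, s)
                                - matrix.pair_lo_entry(i, t, j, s)
                            )
                            thresh = interval_I
                        rest = 0.0
                        feasible = True
                        for k in range(n):
                            if k in (i, j):
                                continue
                            best = None
                            for v in state.unpruned(k):
                                if state.is_flagged(i, r, k, v):
                                    continue
                                if mode == "rigid":
                                    d = (
                                        matrix.pair_rigid_entry(i, r, k, v)
                                        - matrix.pair_rigid_entry(i, t, k, v)
                                    )
                                elif mode == "mindee":
                                    d = (
                                        matrix.pair_lo_entry(i, r, k, v)
                                        - matrix.pair_up_entry(i, t, k, v)
                                    )
                                else:
                                    d = (
                                        matrix.pair_lo_entry(i, r, k, v)
                                        - matrix.pair_lo_entry(i, t, k, v)
                                    )
                                if best is None or d < best:
                                    best = d
                            if best is None:
                                feasible = False
                                break
                            rest += best
                        if not feasible:
                            dominated = True  # i_r unusable with this j_s context
                            break
                        if lead + rest > thresh:
                            dominated = True
                            break
                    if not dominated:
                        all_dominated = False
                        break
                if all_dominated:
                    pruned_here = True
            if pruned_here:
                to_prune.append((i, r))
    for i, r in to_prune:
        state.prune(i, r)
    state.log.append({"criterion": f"split_{mode}", "pruned": len(to_prune)})
    return state


# ---------------------------------------------------------------------------
# (Min)Bounds pruning
# ---------------------------------------------------------------------------

def _completion_bound(matrix, state, mode, i, r) -> float:
    """Admissible lower bound on the best conformation containing i_r."""
    if mode == "rigid":
        single = lambda j, s: matrix.single_rigid[j][s]
        pair = matrix.pair_rigid_entry
        e = matrix.template + matrix.single_rigid[i][r]
    else:
        single = lambda j, s: matrix.single_lo[j][s]
        pair = matrix.pair_lo_entry
        e = matrix.template + matrix.single_lo[i][r]
    n = matrix.n_positions
    others = [j for j in range(n) if j != i]
    for a, j in enumerate(others):
        best = None
        for s in state.unpruned(j):
            if state.is_flagged(i, r, j, s):
                continue
            v = single(j, s) + pair(i, r, j, s)
            for k in others[a + 1:]:
                inner = None
                for u in state.unpruned(k):
                    if state.is_flagged(i, r, k, u) or state.is_flagged(j, s, k, u):
                        continue
                    w = pair(j, s, k, u)
                    if inner is None or w < inner:
                        inner = w
                if inner is None:
                    v = None
                    break
                v += inner
            if v is not None and (best is None or v < best):
                best = v
        if best is None:
            return math.inf  # i_r belongs to no valid conformation
        e += best
    return e


def bounds_prune(
    matrix: EnergyMatrix,
    state: PruningState,
    mode: str,
    best_known_energy: float,
    interval_I: float = 0.0,
) -> PruningState:
    """Prune rotamers whose optimistic completion bound exceeds a known
    conformation energy (rigid) or minimized energy plus interval (min modes).

    A small absolute guard keeps float summation-order noise from turning
    an exact tie (the bound of the best-known conformation's own rotamers)
    into a prune; ties must never prune.
    """
    if mode not in _MODES:
        raise ValueError(f"unknown mode {mode!r}")
    slack = interval_I if mode == "imindee" else 0.0
    tie_guard = 1e-9
    count = 0
    if math.isfinite(best_known_energy):
        for i in range(matrix.n_positions):
            for r in state.unpruned(i):
                if _completion_bound(matrix, state, mode, i, r) > (
                    best_known_energy + slack + tie_guard
                ):
                    state.prune(i, r)
                    count += 1
    state.log.append({"criterion": f"bounds_{mode}", "pruned": count})
    return state


# ---------------------------------------------------------------------------
# Fixpoint driver
# ---------------------------------------------------------------------------

@dataclass
class PruneConfig:
    steric_threshold: float = 100.0
    use_pairs: bool = True
    use_split: bool = True
    use_bounds: bool = True
    best_known_energy: float = math.inf
    max_cycles: int = 60


def prune_to_fixpoint(
    matrix: EnergyMatrix,
    mode: str,
    interval_I: float = 0.0,
    config: PruneConfig | None = None,
) -> PruningState:
    """Iterate steric (once), singles, pairs, split and bounds criteria until
    a full cycle changes nothing; pruning at one position in one cycle can
    enable pruning at another in the next."""
    if mode not in _MODES:
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "mindee":
        _require_upper(matrix)
    config = config or PruneConfig()
    state = steric_filter(matrix, config.steric_threshold)
    for cycle in range(config.max_cycles):
        before = (sum(len(p) for p in state.pruned), len(state.flagged))
        n_singles = _singles(matrix, state, mode, interval_I)
        state.log.append(
            {"criterion": f"singles_{mode}", "pruned": n_singles, "cycle": cycle}
        )
        if config.use_pairs and matrix.n_positions >= 3:
            pairs_flag(matrix, state, mode, interval_I)
        if config.use_split and matrix.n_positions >= 2:
            split_flags(matrix, state, mode, interval_I)
        if config.use_bounds:
            bounds_prune(matrix, state, mode, config.best_known_energy, interval_I)
        if state.infeasible:
            break
        after = (sum(len(p) for p in state.pruned), len(state.flagged))
        if after == before:
            break
    return state
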