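"""End-to-end design searches and comparison metrics.

Three searches share the precomputed energy matrix machinery:

* ``find_rigid_gmec``      — rigid DEE + A* on modal energies; the winner is
  the rigid GMEC, which is then post hoc minimized ("rigidMin") so rigid
  and continuous results compare fairly.
* ``find_mingmec_mindee``  — MinDEE pruning (lower *and* upper voxel
  bounds with maximum-range terms) + A* over lower bounds with the
  minimization-aware stop rule; provably returns the minGMEC.
* ``find_mingmec_imindee`` — the two-phase GEM procedure: prune with the
  interval criterion at a guessed I0, search, measure the realized gap
  I1 = E_T(c') - E_lb(c_b); if I1 <= I0 the answer is proven, otherwise
  one rerun with I1 (never more) recovers the minGMEC.

Also here: sequence distance, side-chain volume difference, and native
sequence recovery broken down by dihedral count and residue mass class.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .astar import EnumerationResult, astar_enumerate, enumerate_and_minimize
from .energy import DesignInstance, total_rigid_energy
from .matrix import (
    BoundsConfig,
    EnergyMatrix,
    compute_bounds,
    compute_rigid_matrix,
    minimize_conformation,
)
from .pruning import PruneConfig, PruningState, prune_to_fixpoint

__all__ = [
    "GemState",
    "DesignResult",
    "DriverConfig",
    "prepare_matrix",
    "find_rigid_gmec",
    "find_mingmec_mindee",
    "find_mingmec_imindee",
    "sequence_distance",
    "volume_difference",
    "recovery_report",
    "MASS_CLASS",
    "MULTI_DIHEDRAL",
    "result_to_dict",
    "write_result_bundle",
    "compare_results",
]


@dataclass
class GemState:
    """Bookkeeping of the two-phase interval search."""

    I0: float
    E_lower_cb: float = math.nan   # first emitted bound E_lb(c_b)
    E_best: float = math.nan       # E_T(c'), best minimized energy
    I1: float = math.nan           # E_T(c') - E_lb(c_b)
    phase: int = 1
    rerun_triggered: bool = False


@dataclass
class DesignResult:
    algorithm: str
    conformation: tuple[int, ...] | None
    sequence: tuple[str, ...] | None
    rigid_energy: float
    minimized_energy: float
    pruning_report: dict
    n_enumerated: int
    exhausted: bool = True
    infeasible: bool = False
    gem: GemState | None = None
    rotamer_ids: tuple[str, ...] | None = None
    enumeration_log: list = field(default_factory=list)


@dataclass
class DriverConfig:
    """Shared knobs for the three searches."""

    I0: float = 0.5
    steric_threshold: float = 100.0
    bounds: BoundsConfig = field(default_factory=BoundsConfig)
    minimize_tol: float = 1e-6
    minimize_starts: int = 3
    minimize_seed: int = 0
    use_pairs: bool = True
    use_split: bool = True
    use_bounds: bool = True

    def minimize_kwargs(self) -> dict:
        return {
            "tol": self.minimize_tol,
            "n_starts": self.minimize_starts,
            "seed": self.minimize_seed,
        }

    def prune_config(self, best_known: float = math.inf) -> PruneConfig:
        return PruneConfig(
            steric_threshold=self.steric_threshold,
            use_pairs=self.use_pairs,
            use_split=self.use_split,
            use_bounds=self.use_bounds,
            best_known_energy=best_known,
        )


def prepare_matrix(
    instance: DesignInstance,
    config: DriverConfig | None = None,
    with_upper: bool = False,
) -> EnergyMatrix:
    """Rigid matrix plus voxel bounds (upper bounds only when requested)."""
    config = config or DriverConfig()
    matrix = compute_rigid_matrix(instance)
    return compute_bounds(matrix, instance, config.bounds, with_upper=with_upper)


def _greedy_conformation(matrix: EnergyMatrix, use_lower: bool) -> tuple[int, ...]:
    vals = matrix.single_lo if use_lower else matrix.single_rigid
    return tuple(int(np.argmin(v)) for v in vals)


def _result_common(instance, matrix, conf):
    return {
        "sequence": instance.sequence_of(conf),
        "rotamer_ids": tuple(
            matrix.rotamer_ids[i][r] for i, r in enumerate(conf)
        ),
    }


def find_rigid_gmec(
    instance: DesignInstance,
    config: DriverConfig | None = None,
    matrix: EnergyMatrix | None = None,
) -> DesignResult:
    """Rigid DEE/A*: the first A* emission over rigid energies is the rigid
    GMEC; it is then continuously minimized to give the rigidMin energy."""
    config = config or DriverConfig()
    if matrix is None:
        matrix = compute_rigid_matrix(instance)
    greedy = _greedy_conformation(matrix, use_lower=False)
    best_known = total_rigid_energy(greedy, matrix)
    state = prune_to_fixpoint(
        matrix, "rigid", 0.0, config.prune_config(best_known)
    )
    stream = astar_enumerate(matrix, state, "rigid")
    first = next(stream, None)
    if first is None:
        return DesignResult(
            algorithm="rigid", conformation=None, sequence=None,
            rigid_energy=math.inf, minimized_energy=math.inf,
            pruning_report=state.report(), n_enumerated=0, infeasible=True,
        )
    conf, rigid_e = first
    min_e, _ = minimize_conformation(instance, conf, **config.minimize_kwargs())
    return DesignResult(
        algorithm="rigid",
        conformation=conf,
        rigid_energy=rigid_e,
        minimized_energy=min_e,
        pruning_report=state.report(),
        n_enumerated=1,
        **_result_common(instance, matrix, conf),
    )


def _finish_min_result(
    algorithm, instance, matrix, state, res: EnumerationResult, gem=None
) -> DesignResult:
    if res.best is None:
        return DesignResult(
            algorithm=algorithm, conformation=None, sequence=None,
            rigid_energy=math.inf, minimized_energy=math.inf,
            pruning_report=state.report(), n_enumerated=res.n_enumerated,
            infeasible=True, gem=gem,
        )
    conf = res.best.conformation
    return DesignResult(
        algorithm=algorithm,
        conformation=conf,
        rigid_energy=total_rigid_energy(conf, matrix),
        minimized_energy=res.best.minimized_energy,
        pruning_report=state.report(),
        n_enumerated=res.n_enumerated,
        exhausted=res.exhausted,
        gem=gem,
        enumeration_log=[
            (r.conformation, r.lower_bound, r.minimized_energy) for r in res.log
        ],
        **_result_common(instance, matrix, conf),
    )


def find_mingmec_mindee(
    instance: DesignInstance,
    config: DriverConfig | None = None,
    matrix: EnergyMatrix | None = None,
) -> DesignResult:
    """MinDEE/A*: prune with the minimization-aware criterion (upper and
    lower voxel bounds), then enumerate-and-minimize until the stop rule."""
    config = config or DriverConfig()
    if matrix is None:
        matrix = prepare_matrix(instance, config, with_upper=True)
    greedy = _greedy_conformation(matrix, use_lower=True)
    best_known, _ = minimize_conformation(instance, greedy, **config.minimize_kwargs())
    state = prune_to_fixpoint(
        matrix, "mindee", 0.0, config.prune_config(best_known)
    )
    res = enumerate_and_minimize(
        instance, matrix, state, "lower_bound",
        minimize_kwargs=config.minimize_kwargs(),
    )
    return _finish_min_result("mindee", instance, matrix, state, res)


def find_mingmec_imindee(
    instance: DesignInstance,
    I0: float | None = None,
    config: DriverConfig | None = None,
    matrix: EnergyMatrix | None = None,
) -> DesignResult:
    """iMinDEE with GEM: interval pruning at I0, search, validate the
    interval, and rerun once with I1 if (and only if) I0 was too small."""
    config = config or DriverConfig()
    if I0 is None:
        I0 = config.I0
    if I0 < 0:
        raise ValueError("I0 must be nonnegative")
    if matrix is None:
        matrix = prepare_matrix(instance, config, with_upper=False)
    greedy = _greedy_conformation(matrix, use_lower=True)
    best_known, _ = minimize_conformation(instance, greedy, **config.minimize_kwargs())

    gem = GemState(I0=I0)
    state1 = prune_to_fixpoint(
        matrix, "imindee", I0, config.prune_config(best_known)
    )
    res1 = enumerate_and_minimize(
        instance, matrix, state1, "lower_bound", stop_slack=I0,
        minimize_kwargs=config.minimize_kwargs(),
    )
    if res1.best is None:
        return _finish_min_result("imindee", instance, matrix, state1, res1, gem)
    gem.E_lower_cb = res1.first_bound
    gem.E_best = res1.best.minimized_energy
    gem.I1 = gem.E_best - gem.E_lower_cb
    if gem.I1 <= I0:
        return _finish_min_result("imindee", instance, matrix, state1, res1, gem)

    # the initial interval was too small: one provably sufficient rerun
    gem.phase = 2
    gem.rerun_triggered = True
    state2 = prune_to_fixpoint(
        matrix, "imindee", gem.I1, config.prune_config(gem.E_best)
    )
    res2 = enumerate_and_minimize(
        instance, matrix, state2, "lower_bound",
        minimize_kwargs=config.minimize_kwargs(),
    )
    result = _finish_min_result("imindee", instance, matrix, state2, res2, gem)
    result.n_enumerated += res1.n_enumerated
    return result


# ---------------------------------------------------------------------------
# Comparison metrics
# ---------------------------------------------------------------------------

#: residue volumes [A^3] (standard crystallographic table)
RESIDUE_VOLUME = {
    "ALA": 88.6, "ARG": 173.4, "ASN": 114.1, "ASP": 111.1, "CYS": 108.5,
    "GLN": 143.8, "GLU": 138.4, "GLY": 60.1, "HIS": 153.2, "ILE": 166.7,
    "LEU": 166.7, "LYS": 168.6, "MET": 162.9, "PHE": 189.9, "PRO": 112.7,
    "SER": 89.0, "THR": 116.1, "TRP": 227.8, "TYR": 193.6, "VAL": 140.0,
}

#: residue-mass classes: small < 100 Da, medium 100-130 Da, large > 130 Da
MASS_CLASS = {
    "VAL": "small", "ALA": "small", "GLY": "small", "SER": "small",
    "PRO": "small",
    "ASP": "medium", "LYS": "medium", "ILE": "medium", "GLN": "medium",
    "ASN": "medium", "LEU": "medium", "GLU": "medium", "THR": "medium",
    "CYS": "medium",
    "TRP": "large", "PHE": "large", "TYR": "large", "ARG": "large",
    "MET": "large", "HIS": "large",
}

#: amino acids with more than one flexible dihedral
MULTI_DIHEDRAL = {
    "ASP", "LYS", "ILE", "TRP", "PHE", "GLN", "ASN", "LEU", "TYR", "GLU",
    "ARG", "MET", "HIS",
}


def sequence_distance(seq_a: Sequence[str], seq_b: Sequence[str]) -> float:
    """Fraction of design positions whose amino-acid type differs."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must cover the same design positions")
    if not seq_a:
        return 0.0
    diff = sum(1 for a, b in zip(seq_a, seq_b) if a.upper() != b.upper())
    return diff / len(seq_a)


def volume_difference(seq_a: Sequence[str], seq_b: Sequence[str]) -> float:
    """Signed total side-chain volume difference (A^3) over differing positions."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must cover the same design positions")
    total = 0.0
    for a, b in zip(seq_a, seq_b):
        a, b = a.upper(), b.upper()
        if a == b:
            continue
        try:
            total += RESIDUE_VOLUME[a] - RESIDUE_VOLUME[b]
        except KeyError as exc:
            raise ValueError(f"unknown residue type {exc}") from None
    return total


def recovery_report(
    designed: Sequence[str], native: Sequence[str]
) -> dict:
    """Native sequence recovery, overall and by dihedral count / mass class."""
    if len(designed) != len(native):
        raise ValueError("designed and native position lists must align")

    def tally(pairs):
        n = len(pairs)
        rec = sum(1 for d, w in pairs if d == w)
        return {"n": n, "recovered": rec,
                "percent": (100.0 * rec / n) if n else math.nan}

    pairs = []
    for d, w in zip(designed, native):
        d, w = d.upper(), w.upper()
        if d not in MASS_CLASS or w not in MASS_CLASS:
            raise ValueError(f"unknown residue type in {d!r}/{w!r}")
        pairs.append((d, w))
    report = {"overall": tally(pairs)}
    report["multi_dihedral"] = tally(
        [(d, w) for d, w in pairs if w in MULTI_DIHEDRAL]
    )
    for cls in ("small", "medium", "large"):
        report[cls] = tally([(d, w) for d, w in pairs if MASS_CLASS[w] == cls])
    per_aa = {}
    for aa in sorted({w for _, w in pairs}):
        per_aa[aa] = tally([(d, w) for d, w in pairs if w == aa])
    report["per_amino_acid"] = per_aa
    return report


# ---------------------------------------------------------------------------
# Result bundles
# ---------------------------------------------------------------------------

def result_to_dict(result: DesignResult) -> dict:
    out = {
        "algorithm": result.algorithm,
        "conformation": list(result.conformation) if result.conformation else None,
        "sequence": list(result.sequence) if result.sequence else None,
        "rotamer_ids": list(result.rotamer_ids) if result.rotamer_ids else None,
        "rigid_energy": result.rigid_energy,
        "minimized_energy": result.minimized_energy,
        "n_enumerated": result.n_enumerated,
        "exhausted": result.exhausted,
        "infeasible": result.infeasible,
        "pruning": result.pruning_report,
    }
    if result.gem is not None:
        g = result.gem
        out["gem"] = {
            "I0": g.I0, "E_lower_cb": g.E_lower_cb, "E_best": g.E_best,
            "I1": g.I1, "phase": g.phase, "rerun_triggered": g.rerun_triggered,
        }
    return out


def write_result_bundle(result: DesignResult, out_dir) -> None:
    """Write result.json plus an enumeration log TSV into a directory."""
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    name = f"{result.algorithm}_result.json"
    (out / name).write_text(json.dumps(result_to_dict(result), indent=1))
    rows = ["index\tbound\tminimized_energy\tconformation"]
    for k, (conf, bound, emin) in enumerate(result.enumeration_log):
        rows.append(f"{k}\t{bound:.6f}\t{emin:.6f}\t{','.join(map(str, conf))}")
    (out / f"{result.algorithm}_enumeration.tsv").write_text("\n".join(rows) + "\n")


def compare_results(a: DesignResult, b: DesignResult) -> dict:
    cmp = {
        "algorithms": [a.algorithm, b.algorithm],
        "minimized_energies": [a.minimized_energy, b.minimized_energy],
        "rigid_energies": [a.rigid_energy, b.rigid_energy],
        "energy_difference": a.minimized_energy - b.minimized_energy,
        "pruned_fractions": [
            a.pruning_report.get("pruned_fraction"),
            b.pruning_report.get("pruned_fraction"),
        ],
    }
    if a.sequence and b.sequence and len(a.sequence) == len(b.sequence):
        known = all(s in RESIDUE_VOLUME for s in a.sequence + b.sequence)
        cmp["sequence_distance"] = sequence_distance(a.sequence, b.sequence)
        if known:
            cmp["volume_difference"] = volume_difference(a.sequence, b.sequence)
    return cmp
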