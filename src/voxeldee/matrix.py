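"""Precomputed rigid energies and voxel bounds for singles and pairs.

The search layers never call the energy model during pruning or A*; they
consume an :class:`EnergyMatrix` holding, for every rotamer i_r and every
rotamer pair (i_r, j_s):

* the rigid energy (evaluated at the modal chi point),
* a voxel lower bound  ``lo <= E`` (bounded minimization over the voxel),
* optionally a voxel upper bound ``up >= E`` (MinDEE only; the interval
  criterion removes the need for maxima).

Pair bounds are joint minimizations over both rotamers' chi voxels — the
lowest (highest) energy the pair can reach when no other side chain is
present.  ``minimize_conformation`` performs the full-conformation
continuous minimization (cyclic coordinate descent plus a joint polish)
that defines the minimized energy E_T(A) of a rotamer vector.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .energy import DesignInstance
from .minimize import MinimizerConfig, maximize_box, minimize_box

__all__ = [
    "EnergyMatrix",
    "BoundsConfig",
    "compute_rigid_matrix",
    "compute_bounds",
    "minimize_conformation",
    "save_matrix",
    "load_matrix",
]


@dataclass
class BoundsConfig:
    """Controls the multi-start voxel minimizations behind the bounds."""

    n_random_starts: int = 4
    presample: int = 13
    seed: int = 0
    tol: float = 1e-9

    def minimizer(self) -> MinimizerConfig:
        return MinimizerConfig(
            n_random=self.n_random_starts, presample=self.presample, tol=self.tol
        )


@dataclass
class EnergyMatrix:
    """Template energy, per-rotamer and per-pair rigid energies and bounds."""

    template: float
    position_labels: list[str]
    rotamer_ids: list[list[str]]
    single_rigid: list[np.ndarray]
    single_lo: list[np.ndarray]
    single_up: list[np.ndarray] | None
    pair_rigid: dict[tuple[int, int], np.ndarray]
    pair_lo: dict[tuple[int, int], np.ndarray]
    pair_up: dict[tuple[int, int], np.ndarray] | None
    metadata: dict = field(default_factory=dict)

    @property
    def n_positions(self) -> int:
        return len(self.single_rigid)

    def n_rotamers(self, pos: int) -> int:
        return int(self.single_rigid[pos].size)

    @property
    def has_upper(self) -> bool:
        return self.single_up is not None and self.pair_up is not None

    def _pair_block(self, store, i: int, j: int) -> np.ndarray:
        if i < j:
            return store[(i, j)]
        return store[(j, i)].T

    def pair_rigid_entry(self, i: int, r: int, j: int, s: int) -> float:
        return float(self._pair_block(self.pair_rigid, i, j)[r, s])

    def pair_lo_entry(self, i: int, r: int, j: int, s: int) -> float:
        return float(self._pair_block(self.pair_lo, i, j)[r, s])

    def pair_up_entry(self, i: int, r: int, j: int, s: int) -> float:
        if self.pair_up is None:
            raise ValueError("upper bounds not computed (run compute_bounds "
                             "with with_upper=True)")
        return float(self._pair_block(self.pair_up, i, j)[r, s])

    def zero_width(self) -> "EnergyMatrix":
        """A copy whose bounds collapse onto the rigid energies."""
        return EnergyMatrix(
            template=self.template,
            position_labels=list(self.position_labels),
            rotamer_ids=[list(r) for r in self.rotamer_ids],
            single_rigid=[a.copy() for a in self.single_rigid],
            single_lo=[a.copy() for a in self.single_rigid],
            single_up=[a.copy() for a in self.single_rigid],
            pair_rigid={k: v.copy() for k, v in self.pair_rigid.items()},
            pair_lo={k: v.copy() for k, v in self.pair_rigid.items()},
            pair_up={k: v.copy() for k, v in self.pair_rigid.items()},
            metadata=dict(self.metadata, zero_width=True),
        )


def _voxel_box(rot):
    hw = np.asarray(rot.half_width, dtype=float)
    return -hw, hw


def compute_rigid_matrix(instance: DesignInstance) -> EnergyMatrix:
    """Evaluate template, singles and pairs at the modal chi points.

    Bounds fields are initialized equal to the rigid values; upper bounds
    are absent until :func:`compute_bounds` runs.
    """
    model = instance.model
    n = instance.n_positions
    single = []
    for i in range(n):
        e = np.empty(instance.n_rotamers(i))
        for r, rot in enumerate(instance.rotamers[i]):
            zero = np.zeros(rot.n_chi)
            if model.vectorized:
                e[r] = float(model.intra(i, r, zero[None, :])[0])
            else:
                e[r] = float(model.intra(i, r, zero))
        single.append(e)
    pairs: dict[tuple[int, int], np.ndarray] = {}
    for i in range(n):
        for j in range(i + 1, n):
            blk = np.empty((instance.n_rotamers(i), instance.n_rotamers(j)))
            for r, ri in enumerate(instance.rotamers[i]):
                zi = np.zeros(ri.n_chi)
                for s, rj in enumerate(instance.rotamers[j]):
                    zj = np.zeros(rj.n_chi)
                    if model.vectorized:
                        blk[r, s] = float(
                            model.pair(i, r, zi[None, :], j, s, zj[None, :])[0]
                        )
                    else:
                        blk[r, s] = float(model.pair(i, r, zi, j, s, zj))
            pairs[(i, j)] = blk
    return EnergyMatrix(
        template=float(
            model.template_energy()
        ),
        position_labels=list(instance.position_labels),
        rotamer_ids=[[rot.rotamer_id for rot in rs] for rs in instance.rotamers],
        single_rigid=single,
        single_lo=[e.copy() for e in single],
        single_up=None,
        pair_rigid=pairs,
        pair_lo={k: v.copy() for k, v in pairs.items()},
        pair_up=None,
        metadata={},
    )


def compute_bounds(
    matrix: EnergyMatrix,
    instance: DesignInstance,
    config: BoundsConfig | None = None,
    with_upper: bool = False,
) -> EnergyMatrix:
    """Fill voxel lower (and optionally upper) bounds by box minimization.

    The modal point is always a start, so ``lo <= rigid`` (and
    ``up >= rigid``) holds entry-by-entry by construction.  Pair bounds
    minimize jointly over both rotamers' chi.
    """
    config = config or BoundsConfig()
    model = instance.model
    rng = np.random.default_rng(config.seed)
    mcfg = config.minimizer()
    vec = model.vectorized
    n = instance.n_positions

    lo_s, up_s = [], []
    for i in range(n):
        lo = np.empty(instance.n_rotamers(i))
        up = np.empty(instance.n_rotamers(i))
        for r, rot in enumerate(instance.rotamers[i]):
            lb, ub = _voxel_box(rot)
            f = (lambda d, i=i, r=r: model.intra(i, r, d))
            _, v = minimize_box(
                f, lb, ub, starts=[np.zeros(lb.size)], rng=rng,
                config=mcfg, vectorized=vec,
            )
            lo[r] = min(v, matrix.single_rigid[i][r])
            if with_upper:
                _, vmax = maximize_box(
                    f, lb, ub, starts=[np.zeros(lb.size)], rng=rng,
                    config=mcfg, vectorized=vec,
                )
                up[r] = max(vmax, matrix.single_rigid[i][r])
        lo_s.append(lo)
        up_s.append(up if with_upper else None)

    lo_p: dict[tuple[int, int], np.ndarray] = {}
    up_p: dict[tuple[int, int], np.ndarray] = {}
    for (i, j), blk in matrix.pair_rigid.items():
        lo = np.empty_like(blk)
        up = np.empty_like(blk)
        for r, ri in enumerate(instance.rotamers[i]):
            for s, rj in enumerate(instance.rotamers[j]):
                di, dj = ri.n_chi, rj.n_chi
                lb = np.concatenate([_voxel_box(ri)[0], _voxel_box(rj)[0]])
                ub = np.concatenate([_voxel_box(ri)[1], _voxel_box(rj)[1]])

                if vec:
                    def f(d, i=i, j=j, r=r, s=s, di=di):
                        d = np.atleast_2d(d)
                        return model.pair(i, r, d[:, :di], j, s, d[:, di:])
                else:
                    def f(d, i=i, j=j, r=r, s=s, di=di):
                        return model.pair(i, r, d[:di], j, s, d[di:])

                _, v = minimize_box(
                    f, lb, ub, starts=[np.zeros(lb.size)], rng=rng,
                    config=mcfg, vectorized=vec,
                )
                lo[r, s] = min(v, blk[r, s])
                if with_upper:
                    _, vmax = maximize_box(
                        f, lb, ub, starts=[np.zeros(lb.size)], rng=rng,
                        config=mcfg, vectorized=vec,
                    )
                    up[r, s] = max(vmax, blk[r, s])
        lo_p[(i, j)] = lo
        if with_upper:
            up_p[(i, j)] = up

    matrix.single_lo = lo_s
    matrix.pair_lo = lo_p
    if with_upper:
        matrix.single_up = up_s
        matrix.pair_up = up_p
    matrix.metadata.update(
        {
            "bounds_seed": config.seed,
            "n_random_starts": config.n_random_starts,
            "with_upper": bool(with_upper),
        }
    )
    return matrix


# ---------------------------------------------------------------------------
# Conformation minimization
# ---------------------------------------------------------------------------

def _conformation_energy(instance: DesignInstance, conformation, deltas) -> float:
    model = instance.model
    n = instance.n_positions
    e = model.template_energy()
    for i, r in enumerate(conformation):
        d = deltas[i]
        e += float(model.intra(i, r, d[None, :])[0]) if model.vectorized else float(
            model.intra(i, r, d)
        )
    for i in range(n):
        for j in range(i + 1, n):
            if model.vectorized:
                e += float(
                    model.pair(
                        i, conformation[i], deltas[i][None, :],
                        j, conformation[j], deltas[j][None, :],
                    )[0]
                )
            else:
                e += float(
                    model.pair(i, conformation[i], deltas[i],
                               j, conformation[j], deltas[j])
                )
    return float(e)


def minimize_conformation(
    instance: DesignInstance,
    conformation: Sequence[int],
    tol: float = 1e-6,
    max_sweeps: int = 60,
    n_starts: int = 3,
    seed: int = 0,
    grid: int = 17,
) -> tuple[float, list[np.ndarray]]:
    """Jointly minimize a fully assigned conformation within its voxels.

    Cyclic coordinate descent: each sweep re-minimizes one side chain's chi
    against the current neighbours (dense 1D/2D grid plus local polish),
    iterated until the energy improves by less than ``tol``; a final joint
    L-BFGS-B polish over all chi follows.  Multi-start (modal point plus
    seeded random interior starts) guards against coordinate-descent stalls.

    Returns ``(E_T, deltas)``; the energy never exceeds the rigid energy
    because the modal start is always included.
    """
    model = instance.model
    rng = np.random.default_rng(seed)
    n = instance.n_positions
    conformation = list(conformation)
    boxes = [_voxel_box(instance.rotamers[i][conformation[i]]) for i in range(n)]
    mcfg = MinimizerConfig(n_random=0, presample=grid, polish_top=1)

    starts: list[list[np.ndarray]] = [[np.zeros(b[0].size) for b in boxes]]
    for _ in range(max(n_starts - 1, 0)):
        starts.append([rng.uniform(b[0], b[1]) for b in boxes])

    best_e = np.inf
    best_d: list[np.ndarray] | None = None
    for init in starts:
        deltas = [d.copy() for d in init]
        e = _conformation_energy(instance, conformation, deltas)
        for _ in range(max_sweeps):
            prev = e
            for i in range(n):
                lb, ub = boxes[i]
                if lb.size == 0:
                    continue

                def f_i(d, i=i):
                    if model.vectorized:
                        d2 = np.atleast_2d(d)
                        val = model.intra(i, conformation[i], d2)
                        for j in range(n):
                            if j == i:
                                continue
                            dj = np.broadcast_to(
                                deltas[j], (d2.shape[0], deltas[j].size)
                            )
                            if i < j:
                                val = val + model.pair(
                                    i, conformation[i], d2, j, conformation[j], dj
                                )
                            else:
                                val = val + model.pair(
                                    j, conformation[j], dj, i, conformation[i], d2
                                )
                        return val
                    val = model.intra(i, conformation[i], d)
                    for j in range(n):
                        if j == i:
                            continue
                        if i < j:
                            val += model.pair(
                                i, conformation[i], d, j, conformation[j], deltas[j]
                            )
                        else:
                            val += model.pair(
                                j, conformation[j], deltas[j], i, conformation[i], d
                            )
                    return val

                if model.vectorized and lb.size == 1:
                    # dense 1D sweep: argmin over the axis, current point kept
                    axis = np.linspace(lb[0], ub[0], grid)
                    cand = np.append(axis, deltas[i][0])[:, None]
                    vals = np.asarray(f_i(cand), dtype=float)
                    deltas[i] = cand[int(np.argmin(vals))]
                else:
                    d_best, _ = minimize_box(
                        f_i, lb, ub, starts=[deltas[i]], config=mcfg,
                        vectorized=model.vectorized,
                    )
                    deltas[i] = d_best
            e = _conformation_energy(instance, conformation, deltas)
            if prev - e < tol:
                break
        # joint polish over the concatenated chi vector
        sizes = [b[0].size for b in boxes]
        if sum(sizes) > 0:
            from scipy.optimize import minimize as _sp_min

            lb = np.concatenate([b[0] for b in boxes])
            ub = np.concatenate([b[1] for b in boxes])

            def f_all(x):
                ds, off = [], 0
                for sz in sizes:
                    ds.append(x[off:off + sz])
                    off += sz
                return _conformation_energy(instance, conformation, ds)

            x0 = np.concatenate(deltas) if sum(sizes) else np.empty(0)
            res = _sp_min(
                f_all, x0, method="L-BFGS-B", bounds=list(zip(lb, ub)),
                options={"maxiter": 200, "ftol": 1e-12},
            )
            x = np.clip(res.x, lb, ub)
            v = f_all(x)
            if v < e:
                e = float(v)
                off = 0
                for i, sz in enumerate(sizes):
                    deltas[i] = x[off:off + sz]
                    off += sz
        if e < best_e:
            best_e, best_d = float(e), [d.copy() for d in deltas]
    assert best_d is not None
    return best_e, best_d


# ---------------------------------------------------------------------------
# Serialization: zip archive with a JSON header and raw float64 blocks
# ---------------------------------------------------------------------------

def save_matrix(matrix: EnergyMatrix, path) -> None:
    header = {
        "template": matrix.template,
        "position_labels": matrix.position_labels,
        "rotamer_ids": matrix.rotamer_ids,
        "has_upper": matrix.has_upper,
        "pair_keys": sorted(matrix.pair_rigid),
        "metadata": matrix.metadata,
    }
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("header.json", json.dumps(header, indent=1))

        def put(name, arr):
            buf = io.BytesIO()
            np.save(buf, np.asarray(arr, dtype=np.float64))
            zf.writestr(name, buf.getvalue())

        for i in range(matrix.n_positions):
            put(f"single_rigid_{i}.npy", matrix.single_rigid[i])
            put(f"single_lo_{i}.npy", matrix.single_lo[i])
            if matrix.has_upper:
                put(f"single_up_{i}.npy", matrix.single_up[i])
        for (i, j) in matrix.pair_rigid:
            put(f"pair_rigid_{i}_{j}.npy", matrix.pair_rigid[(i, j)])
            put(f"pair_lo_{i}_{j}.npy", matrix.pair_lo[(i, j)])
            if matrix.has_upper:
                put(f"pair_up_{i}_{j}.npy", matrix.pair_up[(i, j)])


def load_matrix(path) -> EnergyMatrix:
    with zipfile.ZipFile(path) as zf:
        header = json.loads(zf.read("header.json"))

        def get(name):
            return np.load(io.BytesIO(zf.read(name)))

        n = len(header["position_labels"])
        has_up = header["has_upper"]
        single_rigid = [get(f"single_rigid_{i}.npy") for i in range(n)]
        single_lo = [get(f"single_lo_{i}.npy") for i in range(n)]
        single_up = [get(f"single_up_{i}.npy") for i in range(n)] if has_up else None
        pair_rigid, pair_lo, pair_up = {}, {}, ({} if has_up else None)
        for i, j in (tuple(k) for k in header["pair_keys"]):
            pair_rigid[(i, j)] = get(f"pair_rigid_{i}_{j}.npy")
            pair_lo[(i, j)] = get(f"pair_lo_{i}_{j}.npy")
            if has_up:
                pair_up[(i, j)] = get(f"pair_up_{i}_{j}.npy")
    return EnergyMatrix(
        template=float(header["template"]),
        position_labels=header["position_labels"],
        rotamer_ids=header["rotamer_ids"],
        single_rigid=single_rigid,
        single_lo=single_lo,
        single_up=single_up,
        pair_rigid=pair_rigid,
        pair_lo=pair_lo,
        pair_up=pair_up,
        metadata=header["metadata"],
    )
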