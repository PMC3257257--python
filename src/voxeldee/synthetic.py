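"""Seeded synthetic design instances with brute-force ground truth.

The molecular energy model cannot certify the package's provable-pruning
claims, because no oracle knows the true voxel minima of a molecular
landscape.  This module replaces the chemistry with analytic energies —
per-rotamer and per-pair sums of long-wavelength cosines with bounded
coupling, one chi dihedral per rotamer — for which an exhaustive
conformation x chi-grid search *is* ground truth.  Every guarantee
(no criterion prunes the optimum, MinDEE and iMinDEE agree, the GEM
procedure reruns at most once) is validated against this oracle.

Instances are fully reproducible from a seed.  A *trouble-spot* motif can
be injected: one hub position whose pairwise interactions with two
partners each minimize well in isolation but are mutually incompatible
jointly, which inflates the gap between sum-of-lower-bounds and true
minimized energy (the gap the GEM interval must cover).
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize as _sp_min

from .energy import DesignInstance, DesignRotamer, EnergyModel

__all__ = [
    "SyntheticEnergyModel",
    "OracleResult",
    "BruteForceBudgetError",
    "generate_instance",
    "brute_force",
    "oracle_conformation_min",
    "instance_to_json",
    "instance_from_json",
    "frozen_suite",
    "suite_instance",
]

# angular frequency of the cosine terms: 72-degree wavelength, so a voxel
# (half-width 9 degrees) sees at most one well of any term
_W = 2.0 * math.pi / 72.0


class BruteForceBudgetError(RuntimeError):
    pass


class SyntheticEnergyModel(EnergyModel):
    """Analytic intra/pair energies as functions of chi offsets (degrees).

    intra_{i,r}(d)    = a + b * (1 - cos(W (d - mu)))
    pair_{ij,rs}(x,y) = c0 + coupling * [ p (1 - cos(W (x - y - theta)))
                         + qx (1 - cos(W (x - tx))) + qy (1 - cos(W (y - ty)))
                         + C (1 - cos(W (x - y - theta_c))) ]
                         (+ trouble-spot hub terms)

    The C term is a *modal clash*: present on a seeded subset of rotamer
    pairs with |theta_c| just inside the reachable chi range, it makes the
    pair expensive at the modal points yet relaxable inside the voxel —
    the mechanism that makes rigid (modal-point) energies a misleading
    guide to the continuously minimized optimum.
    """

    vectorized = True

    def __init__(self, template: float, intra_params, pair_params, coupling: float):
        self._template = float(template)
        # intra_params[i]: array (R_i, 3) of (a, b, mu)
        self._intra = [np.asarray(p, dtype=float) for p in intra_params]
        # pair_params[(i, j)]: dict with "coef" (R_i, R_j, 6) of
        # (c0, p, theta, qx, tx, qy, ty) minus one -> stored as 7 columns,
        # and "trouble" (s, g, axis) or None
        self._pair = pair_params
        self.coupling = float(coupling)

    def template_energy(self) -> float:
        return self._template

    def intra(self, pos: int, rot: int, delta):
        a, b, mu = self._intra[pos][rot]
        x = np.asarray(delta, dtype=float)[..., 0]
        return a + b * (1.0 - np.cos(_W * (x - mu)))

    def pair(self, pos_i, rot_i, delta_i, pos_j, rot_j, delta_j):
        if pos_i > pos_j:
            pos_i, rot_i, delta_i, pos_j, rot_j, delta_j = (
                pos_j, rot_j, delta_j, pos_i, rot_i, delta_i
            )
        entry = self._pair[(pos_i, pos_j)]
        c0, p, theta, qx, tx, qy, ty, cc, theta_c = entry["coef"][rot_i, rot_j]
        x = np.asarray(delta_i, dtype=float)[..., 0]
        y = np.asarray(delta_j, dtype=float)[..., 0]
        e = c0 + self.coupling * (
            p * (1.0 - np.cos(_W * (x - y - theta)))
            + qx * (1.0 - np.cos(_W * (x - tx)))
            + qy * (1.0 - np.cos(_W * (y - ty)))
            + cc * (1.0 - np.cos(_W * (x - y - theta_c)))
        )
        trouble = entry.get("trouble")
        if trouble is not None:
            s, g, axis = trouble
            hub = x if axis == 0 else y
            e = e + s * (1.0 - np.cos(_W * (hub - g)))
        return e


def generate_instance(
    seed: int,
    n_positions: int = 3,
    rotamers_per_position: int = 3,
    coupling_strength: float = 0.5,
    trouble_spot: bool | None = None,
    half_width: float = 9.0,
    trouble_probability: float = 0.25,
) -> DesignInstance:
    """Deterministically generate a synthetic design instance from a seed.

    ``coupling_strength`` 0 yields separable instances (constant pair
    functions).  ``trouble_spot=None`` draws the motif with the seeded
    probability; the motif needs at least three positions and coupling,
    so it is disabled otherwise.
    """
    if not (2 <= n_positions <= 6):
        raise ValueError("n_positions must be in 2..6")
    if not (2 <= rotamers_per_position <= 8):
        raise ValueError("rotamers_per_position must be in 2..8")
    if coupling_strength < 0:
        raise ValueError("coupling_strength must be nonnegative")
    rng = np.random.default_rng(seed)
    template = float(rng.uniform(-5.0, 5.0))

    rotamers: list[list[DesignRotamer]] = []
    intra_params = []
    for i in range(n_positions):
        rots = []
        params = np.empty((rotamers_per_position, 3))
        for r in range(rotamers_per_position):
            modal = float(rng.uniform(-180.0, 180.0))
            rots.append(
                DesignRotamer(
                    amino_acid="XXX",
                    rotamer_id=f"p{i}r{r}",
                    chi_modal=(modal,),
                    half_width=(half_width,),
                )
            )
            params[r] = (rng.uniform(0.0, 2.0), rng.uniform(0.5, 1.5),
                         rng.uniform(-6.0, 6.0))
        rotamers.append(rots)
        intra_params.append(params)

    draw_trouble = bool(rng.random() < trouble_probability)
    if trouble_spot is None:
        trouble_spot = draw_trouble
    if n_positions < 3 or coupling_strength == 0.0:
        trouble_spot = False
    trouble_s = (float(rng.uniform(2.5, 4.0)), float(rng.uniform(2.5, 4.0)))

    pair_params = {}
    for i in range(n_positions):
        for j in range(i + 1, n_positions):
            ri, rj = rotamers_per_position, rotamers_per_position
            coef = np.empty((ri, rj, 9))
            coef[..., 0] = rng.uniform(-1.0, 1.0, size=(ri, rj))      # c0
            coef[..., 1] = rng.uniform(0.2, 0.8, size=(ri, rj))       # p
            coef[..., 2] = rng.uniform(-8.0, 8.0, size=(ri, rj))      # theta
            coef[..., 3] = rng.uniform(0.2, 0.8, size=(ri, rj))       # qx
            coef[..., 4] = rng.uniform(-8.0, 8.0, size=(ri, rj))      # tx
            coef[..., 5] = rng.uniform(0.2, 0.8, size=(ri, rj))       # qy
            coef[..., 6] = rng.uniform(-8.0, 8.0, size=(ri, rj))      # ty
            # modal clash on ~half the rotamer pairs: expensive at the modal
            # points, relaxable inside the voxel (|theta_c| < 2*half_width)
            clash = rng.random(size=(ri, rj)) < 0.5
            coef[..., 7] = np.where(clash, rng.uniform(4.0, 10.0, size=(ri, rj)), 0.0)
            coef[..., 8] = (
                rng.choice([-1.0, 1.0], size=(ri, rj))
                * rng.uniform(11.0, 17.0, size=(ri, rj))
            )
            if coupling_strength == 0.0:
                coef[..., 1:] = 0.0
            trouble = None
            if trouble_spot and i == 0 and j in (1, 2):
                # hub at position 0: pair (0,1) pulls the hub chi up,
                # pair (0,2) pulls it down; jointly irreconcilable
                s = trouble_s[j - 1]
                g = 7.5 if j == 1 else -7.5
                trouble = (s, g, 0)
            pair_params[(i, j)] = {"coef": coef, "trouble": trouble}

    model = SyntheticEnergyModel(template, intra_params, pair_params, coupling_strength)
    inst = DesignInstance(
        position_labels=[f"P{i}" for i in range(n_positions)],
        rotamers=rotamers,
        model=model,
    )
    inst.metadata = {
        "seed": int(seed),
        "n_positions": n_positions,
        "rotamers_per_position": rotamers_per_position,
        "coupling_strength": coupling_strength,
        "trouble_spot": bool(trouble_spot),
        "half_width": half_width,
    }
    return inst


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

@dataclass
class OracleResult:
    rigid_gmec: tuple[int, ...]
    rigid_gmec_energy: float
    mingmec: tuple[int, ...]
    mingmec_energy: float
    grid_step: float


def _grids(instance: DesignInstance, grid_step: float):
    model = instance.model
    axes, intra_grids, pair_grids = [], [], {}
    n = instance.n_positions
    for i in range(n):
        h = instance.rotamers[i][0].half_width[0]
        npts = int(round(2 * h / grid_step)) + 1
        axes.append(np.linspace(-h, h, npts))
    for i in range(n):
        g = []
        for r in range(instance.n_rotamers(i)):
            g.append(np.asarray(model.intra(i, r, axes[i][:, None]), dtype=float))
        intra_grids.append(g)
    for i in range(n):
        for j in range(i + 1, n):
            xi = axes[i][:, None, None]
            yj = axes[j][None, :, None]
            blocks = {}
            for r in range(instance.n_rotamers(i)):
                for s in range(instance.n_rotamers(j)):
                    blocks[(r, s)] = np.asarray(
                        model.pair(i, r, xi, j, s, yj), dtype=float
                    )
            pair_grids[(i, j)] = blocks
    return axes, intra_grids, pair_grids


def _polish_joint(instance: DesignInstance, conf, x0, bounds) -> tuple[float, np.ndarray]:
    model = instance.model
    n = instance.n_positions

    def f(x):
        e = model.template_energy()
        for i in range(n):
            e += float(model.intra(i, conf[i], np.array([x[i]])[None, :])[0])
        for i in range(n):
            for j in range(i + 1, n):
                e += float(
                    model.pair(
                        i, conf[i], np.array([x[i]])[None, :],
                        j, conf[j], np.array([x[j]])[None, :],
                    )[0]
                )
        return e

    res = _sp_min(f, x0, method="L-BFGS-B", bounds=bounds,
                  options={"maxiter": 200, "ftol": 1e-12})
    x = np.clip(res.x, [b[0] for b in bounds], [b[1] for b in bounds])
    return float(f(x)), x


def oracle_conformation_min(
    instance: DesignInstance, conformation, grid_step: float = 1.0
) -> float:
    """Exhaustive joint grid minimum of one conformation, locally polished."""
    axes, intra_grids, pair_grids = _grids(instance, grid_step)
    n = instance.n_positions
    shape = tuple(len(a) for a in axes)
    total = np.full(shape, instance.model.template_energy(), dtype=float)
    for i in range(n):
        sh = [1] * n
        sh[i] = shape[i]
        total += intra_grids[i][conformation[i]].reshape(sh)
    for (i, j), blocks in pair_grids.items():
        sh = [1] * n
        sh[i], sh[j] = shape[i], shape[j]
        total += blocks[(conformation[i], conformation[j])].reshape(sh)
    k = np.unravel_index(int(np.argmin(total)), shape)
    x0 = np.array([axes[i][k[i]] for i in range(n)])
    bounds = [(axes[i][0], axes[i][-1]) for i in range(n)]
    v, _ = _polish_joint(instance, conformation, x0, bounds)
    return min(v, float(total[k]))


def brute_force(
    instance: DesignInstance,
    grid_step: float = 1.0,
    budget: float = 4e9,
) -> OracleResult:
    """Exhaustive ground truth: rigid GMEC over modal points; minGMEC by a
    per-conformation joint chi-grid search refined by local descent.

    Conformations are scanned in order of an exact sum-of-grid-minima lower
    bound (with a small smoothness slack) so provably non-optimal ones are
    skipped; the result equals the full scan.  Refuses instances whose
    conformations x grid points exceed ``budget``.
    """
    n = instance.n_positions
    counts = [instance.n_rotamers(i) for i in range(n)]
    n_conf = int(np.prod(counts))
    axes, intra_grids, pair_grids = _grids(instance, grid_step)
    pts_per_conf = int(np.prod([len(a) for a in axes]))
    if n_conf * pts_per_conf > budget:
        raise BruteForceBudgetError(
            f"{n_conf} conformations x {pts_per_conf} grid points exceeds "
            f"budget {budget:g}"
        )
    model = instance.model
    template = model.template_energy()

    # rigid GMEC: evaluate every conformation at the modal points
    zero = np.zeros((1, 1))
    rigid_single = [
        np.array([float(model.intra(i, r, zero)[0]) for r in range(counts[i])])
        for i in range(n)
    ]
    rigid_pair = {
        (i, j): np.array(
            [
                [float(model.pair(i, r, zero, j, s, zero)[0]) for s in range(counts[j])]
                for r in range(counts[i])
            ]
        )
        for i in range(n)
        for j in range(i + 1, n)
    }
    best_rigid, best_rigid_conf = math.inf, None
    for conf in itertools.product(*(range(c) for c in counts)):
        e = template + sum(rigid_single[i][conf[i]] for i in range(n))
        for (i, j), blk in rigid_pair.items():
            e += blk[conf[i], conf[j]]
        if e < best_rigid:
            best_rigid, best_rigid_conf = float(e), conf

    # minGMEC: scan conformations by sum-of-grid-minima bound
    intra_min = [np.array([g.min() for g in gs]) for gs in intra_grids]
    pair_min = {
        key: {rs: blk.min() for rs, blk in blocks.items()}
        for key, blocks in pair_grids.items()
    }
    slack = 0.05 + 0.01 * (n + len(pair_grids))  # covers grid-vs-continuum error

    def lb(conf):
        e = template + sum(intra_min[i][conf[i]] for i in range(n))
        for (i, j), mins in pair_min.items():
            e += mins[(conf[i], conf[j])]
        return e

    order = sorted(
        itertools.product(*(range(c) for c in counts)), key=lb
    )
    shape = tuple(len(a) for a in axes)
    bounds = [(axes[i][0], axes[i][-1]) for i in range(n)]
    use32 = pts_per_conf > 8_000_000
    best_min, best_min_conf = math.inf, None
    for conf in order:
        if lb(conf) - slack > best_min:
            break
        total = np.full(shape, template, dtype=np.float32 if use32 else np.float64)
        for i in range(n):
            sh = [1] * n
            sh[i] = shape[i]
            total += intra_grids[i][conf[i]].reshape(sh).astype(total.dtype)
        for (i, j), blocks in pair_grids.items():
            sh = [1] * n
            sh[i], sh[j] = shape[i], shape[j]
            total += blocks[(conf[i], conf[j])].reshape(sh).astype(total.dtype)
        k = np.unravel_index(int(np.argmin(total)), shape)
        x0 = np.array([axes[i][k[i]] for i in range(n)])
        v, _ = _polish_joint(instance, conf, x0, bounds)
        v = min(v, float(total[k]))
        if v < best_min:
            best_min, best_min_conf = v, conf
    return OracleResult(
        rigid_gmec=tuple(best_rigid_conf),
        rigid_gmec_energy=best_rigid,
        mingmec=tuple(best_min_conf),
        mingmec_energy=best_min,
        grid_step=grid_step,
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def instance_to_json(instance: DesignInstance) -> str:
    model = instance.model
    if not isinstance(model, SyntheticEnergyModel):
        raise TypeError("only synthetic instances serialize to JSON")
    data = {
        "metadata": getattr(instance, "metadata", {}),
        "template": model.template_energy(),
        "coupling": model.coupling,
        "positions": [
            {
                "label": instance.position_labels[i],
                "rotamers": [
                    {
                        "id": rot.rotamer_id,
                        "chi_modal": list(rot.chi_modal),
                        "half_width": list(rot.half_width),
                    }
                    for rot in instance.rotamers[i]
                ],
                "intra": model._intra[i].tolist(),
            }
            for i in range(instance.n_positions)
        ],
        "pairs": [
            {
                "i": i,
                "j": j,
                "coef": entry["coef"].tolist(),
                "trouble": list(entry["trouble"]) if entry["trouble"] else None,
            }
            for (i, j), entry in model._pair.items()
        ],
    }
    return json.dumps(data)


def instance_from_json(text: str) -> DesignInstance:
    data = json.loads(text)
    rotamers = [
        [
            DesignRotamer(
                amino_acid="XXX",
                rotamer_id=r["id"],
                chi_modal=tuple(r["chi_modal"]),
                half_width=tuple(r["half_width"]),
            )
            for r in p["rotamers"]
        ]
        for p in data["positions"]
    ]
    pair_params = {
        (e["i"], e["j"]): {
            "coef": np.asarray(e["coef"], dtype=float),
            "trouble": tuple(e["trouble"]) if e["trouble"] else None,
        }
        for e in data["pairs"]
    }
    model = SyntheticEnergyModel(
        data["template"],
        [np.asarray(p["intra"], dtype=float) for p in data["positions"]],
        pair_params,
        data["coupling"],
    )
    inst = DesignInstance(
        position_labels=[p["label"] for p in data["positions"]],
        rotamers=rotamers,
        model=model,
    )
    inst.metadata = data.get("metadata", {})
    return inst


# ---------------------------------------------------------------------------
# The frozen validation suite: 100 seeded instances in three size classes
# ---------------------------------------------------------------------------

def frozen_suite() -> list[dict]:
    """Descriptors of the 100-instance validation suite.

    40 small (2-3 positions, 2-4 rotamers), 40 medium (4 positions, 3-4
    rotamers), 20 large (5 positions with 2-3 rotamers, plus four 6-position
    instances with 2 rotamers).  Every seventh instance is separable
    (coupling 0); a quarter of the coupled ones carry the trouble-spot motif.
    Sizes are bounded by the brute-force oracle's exhaustive-grid cost.
    """
    suite = []
    for idx in range(100):
        if idx < 40:
            n = 2 + idx % 2
            r = 2 + idx % 3
        elif idx < 80:
            n = 4
            r = 3 + idx % 2
        elif idx < 96:
            n = 5
            r = 2 + idx % 2
        else:
            n = 6
            r = 2
        separable = idx % 7 == 0
        coupling = 0.0 if separable else round(0.3 + 0.5 * ((idx * 37) % 10) / 10.0, 2)
        trouble = (not separable) and n >= 3 and idx % 4 == 2
        suite.append(
            {
                "id": idx,
                "seed": 1000 + idx,
                "n_positions": n,
                "rotamers_per_position": r,
                "coupling_strength": coupling,
                "trouble_spot": trouble,
            }
        )
    return suite


def suite_instance(desc: dict) -> DesignInstance:
    return generate_instance(
        seed=desc["seed"],
        n_positions=desc["n_positions"],
        rotamers_per_position=desc["rotamers_per_position"],
        coupling_strength=desc["coupling_strength"],
        trouble_spot=desc["trouble_spot"],
    )
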