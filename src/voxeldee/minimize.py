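"""Bounded multi-start minimization over a chi-angle voxel.

Every continuous-rotamer quantity in the package (per-rotamer bounds,
pair bounds, conformation minimization) reduces to minimizing a smooth
function over an axis-aligned box in *delta* space — offsets from the modal
chi point, so periodic wrap never enters the box arithmetic.  The search is
multi-start local descent: explicit starts (modal point, voxel corners),
an optional dense pre-sample for vectorized objectives, seeded random
starts, and an L-BFGS-B polish of the best candidates.

Local search cannot certify a global box minimum in general; the synthetic
suite uses landscapes where the pre-sample density makes the result exact,
and that is where the provable-pruning tests live.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

__all__ = ["MinimizerConfig", "minimize_box", "maximize_box"]


@dataclass(frozen=True)
class MinimizerConfig:
    """Knobs for the box minimizer.

    n_random: seeded random starts added to the explicit ones.
    presample: points per dimension for the dense pre-sample (vectorized
        objectives, dimension <= 3 only).
    polish_top: how many candidates receive an L-BFGS-B polish.
    tol: function-value convergence tolerance passed to L-BFGS-B.
    max_corner_dim: voxel corners are enumerated only up to this dimension.
    """

    n_random: int = 4
    presample: int = 13
    polish_top: int = 2
    tol: float = 1e-9
    maxiter: int = 100
    max_corner_dim: int = 4


def minimize_box(
    f: Callable[[np.ndarray], float],
    lower: Sequence[float],
    upper: Sequence[float],
    *,
    starts: Sequence[Sequence[float]] = (),
    rng: np.random.Generator | None = None,
    config: MinimizerConfig = MinimizerConfig(),
    vectorized: bool = False,
) -> tuple[np.ndarray, float]:
    """Minimize ``f`` over the box ``[lower, upper]``; returns (argmin, value).

    The returned value never exceeds ``f`` at any explicit start (each start
    is evaluated directly), so passing the modal point guarantees the bound
    lies at or below the rigid energy.
    """
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    d = lower.size
    if d == 0:
        x = np.empty(0)
        return x, float(f(x[None, :])[0] if vectorized else f(x))

    candidates: list[np.ndarray] = [
        np.clip(np.asarray(s, dtype=float), lower, upper) for s in starts
    ]
    if d <= config.max_corner_dim:
        candidates.extend(np.array(c) for c in product(*zip(lower, upper)))
    if rng is not None and config.n_random > 0:
        candidates.extend(rng.uniform(lower, upper) for _ in range(config.n_random))
    if not candidates:
        candidates.append((lower + upper) / 2.0)

    pts = np.array(candidates)
    if vectorized and d <= 3:
        axes = [np.linspace(lower[k], upper[k], config.presample) for k in range(d)]
        mesh = np.stack([m.ravel() for m in np.meshgrid(*axes, indexing="ij")], axis=-1)
        pts = np.vstack([pts, mesh])

    if vectorized:
        vals = np.asarray(f(pts), dtype=float)
        f_scalar = lambda x: float(f(np.asarray(x, dtype=float)[None, :])[0])
    else:
        vals = np.array([float(f(p)) for p in pts])
        f_scalar = f

    k = int(np.argmin(vals))
    best_x, best_v = pts[k], float(vals[k])

    for idx in np.argsort(vals)[: max(config.polish_top, 1)]:
        res = _scipy_minimize(
            f_scalar,
            pts[idx],
            method="L-BFGS-B",
            bounds=list(zip(lower, upper)),
            options={"maxiter": config.maxiter, "ftol": config.tol, "gtol": 1e-10},
        )
        x = np.clip(res.x, lower, upper)
        v = float(f_scalar(x))
        if v < best_v:
            best_x, best_v = x, v
    return np.asarray(best_x, dtype=float), best_v


def maximize_box(f, lower, upper, **kwargs) -> tuple[np.ndarray, float]:
    """Maximize ``f`` over the box (used for MinDEE upper bounds)."""
    if kwargs.get("vectorized", False):
        neg = lambda x: -np.asarray(f(x))
    else:
        neg = lambda x: -f(x)
    x, v = minimize_box(neg, lower, upper, **kwargs)
    return x, -v
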