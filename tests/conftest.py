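"""Shared fixtures: hand-built matrices, toy models, tiny structures."""

from __future__ import annotations

import numpy as np
import pytest

from voxeldee import DesignInstance, DesignRotamer, load_bundled_library
from voxeldee.energy import EnergyModel
from voxeldee.matrix import EnergyMatrix


def make_matrix(
    singles: list[list[float]],
    pairs: dict[tuple[int, int], list[list[float]]],
    template: float = 0.0,
    lo_singles=None,
    up_singles=None,
    lo_pairs=None,
    up_pairs=None,
) -> EnergyMatrix:
    """Assemble an EnergyMatrix directly from hand numbers."""
    n = len(singles)
    single_rigid = [np.asarray(s, dtype=float) for s in singles]
    pair_rigid = {k: np.asarray(v, dtype=float) for k, v in pairs.items()}
    lo_s = (
        [np.asarray(s, dtype=float) for s in lo_singles]
        if lo_singles is not None else [s.copy() for s in single_rigid]
    )
    up_s = (
        [np.asarray(s, dtype=float) for s in up_singles]
        if up_singles is not None else [s.copy() for s in single_rigid]
    )
    lo_p = (
        {k: np.asarray(v, dtype=float) for k, v in lo_pairs.items()}
        if lo_pairs is not None else {k: v.copy() for k, v in pair_rigid.items()}
    )
    up_p = (
        {k: np.asarray(v, dtype=float) for k, v in up_pairs.items()}
        if up_pairs is not None else {k: v.copy() for k, v in pair_rigid.items()}
    )
    return EnergyMatrix(
        template=template,
        position_labels=[f"P{i}" for i in range(n)],
        rotamer_ids=[[f"p{i}r{r}" for r in range(len(singles[i]))] for i in range(n)],
        single_rigid=single_rigid,
        single_lo=lo_s,
        single_up=up_s,
        pair_rigid=pair_rigid,
        pair_lo=lo_p,
        pair_up=up_p,
    )


class BoxFunctionModel(EnergyModel):
    """Analytic test model: explicit vectorized intra/pair callables."""

    vectorized = True

    def __init__(self, template, intra_fns, pair_fns):
        self._template = float(template)
        self._intra = intra_fns  # {(pos, rot): f(x)}
        self._pair = pair_fns    # {(i, r, j, s): f(x, y)} with i < j

    def template_energy(self):
        return self._template

    def intra(self, pos, rot, delta):
        x = np.asarray(delta, dtype=float)[..., 0]
        return self._intra[(pos, rot)](x)

    def pair(self, pos_i, rot_i, delta_i, pos_j, rot_j, delta_j):
        if pos_i > pos_j:
            pos_i, rot_i, delta_i, pos_j, rot_j, delta_j = (
                pos_j, rot_j, delta_j, pos_i, rot_i, delta_i
            )
        x = np.asarray(delta_i, dtype=float)[..., 0]
        y = np.asarray(delta_j, dtype=float)[..., 0]
        return self._pair[(pos_i, rot_i, pos_j, rot_j)](x, y)


def box_instance(n_positions, n_rotamers, intra_fns, pair_fns,
                 template=0.0, half_width=9.0) -> DesignInstance:
    rotamers = [
        [
            DesignRotamer("XXX", f"p{i}r{r}", (0.0,), (half_width,))
            for r in range(n_rotamers)
        ]
        for i in range(n_positions)
    ]
    return DesignInstance(
        position_labels=[f"P{i}" for i in range(n_positions)],
        rotamers=rotamers,
        model=BoxFunctionModel(template, intra_fns, pair_fns),
    )


@pytest.fixture(scope="session")
def bundled_library():
    return load_bundled_library()


@pytest.fixture(scope="session")
def tripeptide():
    """Ideal-geometry Ser-Leu-Val peptide built without any external file."""
    from voxeldee import ideal_backbone

    return ideal_backbone(["SER", "LEU", "VAL"])


@pytest.fixture(scope="session")
def tripeptide_pdb_text(tripeptide):
    from voxeldee import to_pdb_text

    return to_pdb_text(tripeptide)
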