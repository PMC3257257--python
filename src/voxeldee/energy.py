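"""Energy contract consumed by all search layers, plus molecular energy terms.

The design search never looks inside an energy function: it sees a
:class:`DesignInstance` (positions, candidate rotamers with voxels) and an
:class:`EnergyModel` exposing a pairwise decomposition

    E(conformation) = E_template + sum_i E(i_r) + sum_{i<j} E(i_r, j_s)

evaluated at arbitrary chi points inside each rotamer's voxel.  Two
implementations exist: the molecular model (van der Waals + screened
Coulomb + EEF1 implicit solvation over atoms placed from chi angles,
built in :mod:`voxeldee.structure`) and analytic synthetic landscapes
(:mod:`voxeldee.synthetic`) with brute-force-checkable ground truth.

Units are kcal/mol and degrees throughout.
"""

from __future__ import annotations

import abc
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "COULOMB_CONSTANT",
    "EnergyWeights",
    "EnergyModel",
    "DesignRotamer",
    "DesignInstance",
    "vdw_pair",
    "coulomb_pair",
    "solvation_pair",
    "solvation_reference",
    "total_rigid_energy",
]

#: Conversion constant for Coulomb energies in kcal/mol with e-charges and Angstroms.
COULOMB_CONSTANT = 332.0636


@dataclass
class EnergyWeights:
    """Linear-combination weights of the molecular energy function.

    The dielectric enters as a distance-dependent screening eps(r) = D * r.
    The trained values used in published design runs are not part of this
    package; these defaults are configuration, not assertions.
    """

    vdw_weight: float = 1.0
    dielectric: float = 6.0
    solvation_weight: float = 0.5
    radius_scale: float = 0.95
    reference_energies: dict[str, float] = field(default_factory=dict)
    entropy_penalties: dict[str, float] = field(default_factory=dict)
    clash_cap: float = 1e6

    def __post_init__(self) -> None:
        if self.dielectric <= 0:
            raise ValueError("dielectric must be positive")
        if not (0.0 < self.radius_scale <= 1.0):
            raise ValueError("radius_scale must lie in (0, 1]")


# ---------------------------------------------------------------------------
# Pairwise molecular terms.  Atoms are duck-typed: they carry ``coord``
# (Angstrom ndarray), ``charge`` (e), ``rmin``/``eps`` (vdW), and EEF1
# parameters ``dg_free``, ``dg_ref``, ``lam``, ``volume``.
# ---------------------------------------------------------------------------

def _distance(atom_a, atom_b) -> float:
    return float(np.linalg.norm(np.asarray(atom_a.coord) - np.asarray(atom_b.coord)))


def vdw_pair(atom_a, atom_b, radius_scale: float = 1.0, clash_cap: float = 1e6) -> float:
    """6-12 Lennard-Jones energy with combined radii scaled by ``radius_scale``.

    The well depth is -sqrt(eps_a * eps_b), reached exactly at the scaled
    r_min sum.  Zero or near-zero separation returns the clash cap.
    """
    r = _distance(atom_a, atom_b)
    eps = float(np.sqrt(atom_a.eps * atom_b.eps))
    rmin = radius_scale * (atom_a.rmin + atom_b.rmin)
    if r < 1e-8:
        return clash_cap
    q = (rmin / r) ** 6
    return min(eps * (q * q - 2.0 * q), clash_cap)


def coulomb_pair(atom_a, atom_b, dielectric: float, clash_cap: float = 1e6) -> float:
    """Coulomb energy with distance-dependent dielectric eps(r) = D * r:
    332.0636 * q_a * q_b / (D * r^2)."""
    r = _distance(atom_a, atom_b)
    if r < 1e-8:
        return clash_cap if atom_a.charge * atom_b.charge > 0 else -clash_cap
    e = COULOMB_CONSTANT * atom_a.charge * atom_b.charge / (dielectric * r * r)
    return float(np.clip(e, -clash_cap, clash_cap))


def _eef1_exclusion(atom_a, atom_b, r: float) -> float:
    """Desolvation of atom_a by the volume of atom_b (one direction)."""
    if atom_a.dg_free == 0.0 or atom_b.volume == 0.0:
        return 0.0
    lam = atom_a.lam
    x = (r - atom_a.rmin) / lam
    pref = 2.0 * atom_a.dg_free / (4.0 * np.pi * np.sqrt(np.pi) * lam * r * r)
    return float(pref * np.exp(-x * x) * atom_b.volume)


def solvation_pair(atom_a, atom_b, solvation_weight: float = 1.0) -> float:
    """EEF1 Gaussian-exclusion pairwise desolvation (both directions).

    Each atom loses part of its solvation free energy to the excluded
    volume of the other; an isolated atom therefore contributes zero here.
    Missing EEF1 parameters must be resolved before calling (atoms carry
    them after typing).
    """
    r = _distance(atom_a, atom_b)
    if r < 1e-8:
        r = 1e-8
    return -solvation_weight * (
        _eef1_exclusion(atom_a, atom_b, r) + _eef1_exclusion(atom_b, atom_a, r)
    )


def solvation_reference(atoms: Sequence, solvation_weight: float = 1.0) -> float:
    """Per-atom EEF1 reference solvation free energy, summed."""
    return solvation_weight * float(sum(a.dg_ref for a in atoms))


# ---------------------------------------------------------------------------
# The contract
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DesignRotamer:
    """A candidate rotamer at a design position: identity, modal chi, voxel."""

    amino_acid: str
    rotamer_id: str
    chi_modal: tuple[float, ...]
    half_width: tuple[float, ...]

    @property
    def n_chi(self) -> int:
        return len(self.chi_modal)


class EnergyModel(abc.ABC):
    """Pairwise-decomposed energy of a design system as a function of chi.

    ``intra``/``pair`` take *delta* vectors — offsets from the rotamer's
    modal chi, which live in the box ``[-half_width, +half_width]`` — so
    callers never deal with periodic wrap.  ``vectorized`` models accept
    stacked delta arrays with a leading batch axis and return a batch of
    energies; the box minimizer exploits this with dense pre-samples.
    """

    #: whether intra/pair accept batched delta arrays
    vectorized: bool = False

    @abc.abstractmethod
    def template_energy(self) -> float:
        """Energy of the fixed template (backbone + non-design side chains)."""

    @abc.abstractmethod
    def intra(self, pos: int, rot: int, delta) -> float:
        """Rotamer-vs-template plus internal energy at modal chi + delta."""

    @abc.abstractmethod
    def pair(self, pos_i: int, rot_i: int, delta_i, pos_j: int, rot_j: int, delta_j) -> float:
        """Interaction energy of two side chains; symmetric in its arguments."""


@dataclass
class DesignInstance:
    """A design problem: labelled positions, candidate rotamers, energy model."""

    position_labels: list[str]
    rotamers: list[list[DesignRotamer]]
    model: EnergyModel

    def __post_init__(self) -> None:
        if len(self.position_labels) != len(self.rotamers):
            raise ValueError("one rotamer list per position required")
        if any(len(r) == 0 for r in self.rotamers):
            raise ValueError("every position needs at least one rotamer")

    @property
    def n_positions(self) -> int:
        return len(self.rotamers)

    def n_rotamers(self, pos: int) -> int:
        return len(self.rotamers[pos])

    def n_conformations(self) -> int:
        out = 1
        for r in self.rotamers:
            out *= len(r)
        return out

    def sequence_of(self, conformation: Sequence[int]) -> tuple[str, ...]:
        return tuple(
            self.rotamers[i][r].amino_acid for i, r in enumerate(conformation)
        )


def total_rigid_energy(conformation: Sequence[int], matrix) -> float:
    """Rigid energy of a fully assigned conformation from a precomputed matrix:
    E_template + sum_i E(i_r) + sum_{i<j} E(i_r, j_s)."""
    n = matrix.n_positions
    if len(conformation) != n:
        raise ValueError("conformation length must equal the number of positions")
    e = matrix.template
    for i, r in enumerate(conformation):
        if not (0 <= r < matrix.n_rotamers(i)):
            raise KeyError(f"unknown rotamer index {r} at position {i}")
        e += matrix.single_rigid[i][r]
    for i in range(n):
        for j in range(i + 1, n):
            e += matrix.pair_rigid_entry(i, conformation[i], j, conformation[j])
    return float(e)
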