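"""Protein structures, side-chain geometry, core-site selection.

Provides the molecular half of the design stack:

* PDB reading (via Biopython) into light typed containers,
* side-chain placement from chi angles using ideal-geometry templates
  (NeRF construction; every chi is set exactly by rotation about its bond),
* an internal Shrake-Rupley solvent-accessible-surface-area routine used to
  pick buried "core" design positions,
* BLOSUM62-based substitution sets for mutable positions,
* a molecular :class:`~voxeldee.energy.EnergyModel` (van der Waals,
  distance-dependent-dielectric Coulomb, EEF1 implicit solvation).

Parameter tables here (vdW, charges, EEF1 constants, reference areas) are a
minimal self-consistent set sufficient for the 20 amino acids; they are
configuration, not a reproduction of any trained force field.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np

from .energy import (
    DesignInstance,
    DesignRotamer,
    EnergyModel,
    EnergyWeights,
    coulomb_pair,
    solvation_pair,
    vdw_pair,
)
from .rotamers import CHI_COUNT, RotamerLibrary, normalize_angle

__all__ = [
    "Atom",
    "Residue",
    "ProteinStructure",
    "DesignSpec",
    "PdbParseError",
    "StructureValidationError",
    "read_pdb",
    "to_pdb_text",
    "ideal_backbone",
    "place_side_chain",
    "build_side_chain",
    "measure_chi",
    "measure_dihedral",
    "shrake_rupley",
    "relative_sidechain_sasa",
    "select_core_positions",
    "blosum_substitutions",
    "MolecularEnergyModel",
    "build_molecular_instance",
    "THREE_TO_ONE",
    "ONE_TO_THREE",
]


class PdbParseError(ValueError):
    pass


class StructureValidationError(ValueError):
    pass


THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

_BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT", "H", "HA", "H1", "H2", "H3"}
_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}
_ION_NAMES = {"NA", "K", "CL", "MG", "CA", "ZN", "MN", "FE", "CU", "NI", "CO", "SO4", "PO4"}

# --- vdW parameters by element: (r_min/2 [A], epsilon [kcal/mol]) -----------
_VDW = {
    "C": (1.908, 0.086),
    "N": (1.824, 0.170),
    "O": (1.661, 0.210),
    "S": (2.000, 0.250),
    "H": (0.600, 0.016),
}

# --- EEF1-style solvation classes: (dg_ref, dg_free, volume, lambda) --------
_EEF1 = {
    "C_ali": (0.52, 0.74, 23.7, 3.5),
    "C_aro": (0.08, 0.08, 18.4, 3.5),
    "C_pol": (0.00, 0.00, 14.7, 3.5),
    "N_pol": (-5.95, -8.90, 4.4, 3.5),
    "N_chg": (-20.00, -25.00, 11.2, 6.0),
    "O_pol": (-5.92, -6.70, 10.8, 3.5),
    "O_chg": (-10.00, -12.00, 10.8, 6.0),
    "S": (-3.24, -4.10, 14.7, 3.5),
    "H": (0.0, 0.0, 0.0, 3.5),
}

_AROMATIC_CARBONS = {
    "PHE": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TYR": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TRP": {"CG", "CD1", "CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"},
    "HIS": {"CG", "CD2", "CE1"},
}
_CHARGED_N = {("LYS", "NZ"), ("ARG", "NH1"), ("ARG", "NH2"), ("ARG", "NE"), ("ARG", "CZ")}
_CHARGED_O = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}

# --- simplified partial charges (e); unlisted atoms are neutral -------------
_BACKBONE_CHARGES = {"N": -0.47, "CA": 0.07, "C": 0.51, "O": -0.51, "H": 0.31, "OXT": -0.51}
_SIDECHAIN_CHARGES: dict[tuple[str, str], float] = {
    ("SER", "CB"): 0.25, ("SER", "OG"): -0.66,
    ("THR", "CB"): 0.25, ("THR", "OG1"): -0.66,
    ("CYS", "CB"): 0.11, ("CYS", "SG"): -0.23,
    ("ASP", "CB"): -0.10, ("ASP", "CG"): 0.62, ("ASP", "OD1"): -0.76, ("ASP", "OD2"): -0.76,
    ("GLU", "CG"): -0.10, ("GLU", "CD"): 0.62, ("GLU", "OE1"): -0.76, ("GLU", "OE2"): -0.76,
    ("ASN", "CG"): 0.55, ("ASN", "OD1"): -0.55,
    ("GLN", "CD"): 0.55, ("GLN", "OE1"): -0.55,
    ("LYS", "NZ"): 1.00,
    ("ARG", "CZ"): 0.64, ("ARG", "NH1"): 0.18, ("ARG", "NH2"): 0.18,
    ("HIS", "ND1"): -0.40, ("HIS", "NE2"): -0.40, ("HIS", "CE1"): 0.50,
    ("HIS", "CG"): 0.10, ("HIS", "CD2"): 0.20,
    ("TYR", "CZ"): 0.40, ("TYR", "OH"): -0.40,
    ("TRP", "NE1"): -0.35, ("TRP", "CD1"): 0.15, ("TRP", "CE2"): 0.20,
}

# --- Gly-X-Gly side-chain reference areas [A^2] for relative SASA -----------
_SIDECHAIN_REF_AREA = {
    "ALA": 67.0, "ARG": 196.0, "ASN": 113.0, "ASP": 106.0, "CYS": 104.0,
    "GLN": 144.0, "GLU": 138.0, "HIS": 151.0, "ILE": 140.0, "LEU": 137.0,
    "LYS": 167.0, "MET": 160.0, "PHE": 175.0, "PRO": 105.0, "SER": 80.0,
    "THR": 102.0, "TRP": 217.0, "TYR": 187.0, "VAL": 117.0,
}


def _solv_class(resname: str, name: str, element: str) -> str:
    if element == "C":
        if name in _AROMATIC_CARBONS.get(resname, ()):  # ring carbons
            return "C_aro"
        if name in {"C"} or (resname, name) in (
            ("ASP", "CG"), ("GLU", "CD"), ("ASN", "CG"), ("GLN", "CD"), ("ARG", "CZ")
        ):
            return "C_pol"
        return "C_ali"
    if element == "N":
        return "N_chg" if (resname, name) in _CHARGED_N else "N_pol"
    if element == "O":
        return "O_chg" if (resname, name) in _CHARGED_O or name == "OXT" else "O_pol"
    if element == "S":
        return "S"
    return "H"


def _charge(resname: str, name: str) -> float:
    if name in _BACKBONE_CHARGES:
        return _BACKBONE_CHARGES[name]
    return _SIDECHAIN_CHARGES.get((resname, name), 0.0)


@dataclass
class Atom:
    """A typed atom: coordinates plus vdW, charge and EEF1 parameters."""

    name: str
    element: str
    coord: np.ndarray
    charge: float = 0.0
    rmin: float = 1.9
    eps: float = 0.1
    dg_ref: float = 0.0
    dg_free: float = 0.0
    lam: float = 3.5
    volume: float = 0.0

    @classmethod
    def typed(cls, name: str, element: str, coord, resname: str) -> "Atom":
        rmin, eps = _VDW.get(element, _VDW["C"])
        dg_ref, dg_free, vol, lam = _EEF1[_solv_class(resname, name, element)]
        return cls(
            name=name,
            element=element,
            coord=np.asarray(coord, dtype=float),
            charge=_charge(resname, name),
            rmin=rmin,
            eps=eps,
            dg_ref=dg_ref,
            dg_free=dg_free,
            lam=lam,
            volume=vol,
        )


@dataclass
class Residue:
    chain: str
    resseq: int
    resname: str
    atoms: list[Atom] = field(default_factory=list)
    incomplete: tuple[str, ...] = ()

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"{self.resname}{self.resseq}: no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    @property
    def label(self) -> str:
        return f"{self.chain}{self.resseq}"

    def backbone_complete(self) -> bool:
        need = {"N", "CA", "C", "O"}
        if self.resname not in ("GLY",):
            need.add("CB")
        return all(self.has_atom(n) for n in need)

    def sidechain_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.name not in _BACKBONE_NAMES]


@dataclass
class ProteinStructure:
    residues: list[Residue] = field(default_factory=list)

    def residue_at(self, chain: str, resseq: int) -> Residue:
        for r in self.residues:
            if r.chain == chain and r.resseq == resseq:
                return r
        raise KeyError(f"no residue {chain}{resseq}")

    def index_of(self, chain: str, resseq: int) -> int:
        for i, r in enumerate(self.residues):
            if r.chain == chain and r.resseq == resseq:
                return i
        raise KeyError(f"no residue {chain}{resseq}")


@dataclass
class DesignSpec:
    """Mutable positions and their allowed amino-acid sets."""

    positions: list[tuple[str, int]]
    allowed: dict[tuple[str, int], set[str]]
    sasa_threshold: float | None = None
    substitutions_k: int = 5

    def __post_init__(self) -> None:
        for pos in self.positions:
            aset = self.allowed[pos]
            if not (1 <= len(aset) <= 21):
                raise ValueError(f"allowed set at {pos} must have 1..21 types")


# ---------------------------------------------------------------------------
# Geometry: dihedrals and NeRF placement
# ---------------------------------------------------------------------------

def measure_dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle p1-p2-p3-p4 in degrees, IUPAC convention."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    return math.degrees(math.atan2(-y, x))


def _nerf(a, b, c, bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom D bonded to C with angle(B,C,D) and dihedral(A,B,C,D)."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    theta = math.radians(angle_deg)
    phi = math.radians(dihedral_deg)
    bc = c - b
    bc_hat = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc_hat)
    n_hat = n / np.linalg.norm(n)
    m_hat = np.cross(n_hat, bc_hat)
    d_local = np.array(
        [
            -bond * math.cos(theta),
            bond * math.sin(theta) * math.cos(phi),
            bond * math.sin(theta) * math.sin(phi),
        ]
    )
    return c + d_local[0] * bc_hat + d_local[1] * m_hat + d_local[2] * n_hat


# Side-chain z-matrix templates.  Entry: (atom, (A, B, C), bond, angle, dihedral)
# where dihedral is a float or ("chi", k, offset) with k 1-based.
_chi = lambda k, off=0.0: ("chi", k, off)
SIDE_CHAIN_TOPOLOGY: dict[str, list] = {
    "GLY": [],
    "ALA": [],
    "SER": [("OG", ("N", "CA", "CB"), 1.417, 110.8, _chi(1))],
    "CYS": [("SG", ("N", "CA", "CB"), 1.808, 113.8, _chi(1))],
    "THR": [
        ("OG1", ("N", "CA", "CB"), 1.433, 109.6, _chi(1)),
        ("CG2", ("N", "CA", "CB"), 1.521, 110.5, _chi(1, -120.0)),
    ],
    "VAL": [
        ("CG1", ("N", "CA", "CB"), 1.527, 110.7, _chi(1)),
        ("CG2", ("N", "CA", "CB"), 1.527, 110.7, _chi(1, 122.0)),
    ],
    "LEU": [
        ("CG", ("N", "CA", "CB"), 1.530, 116.3, _chi(1)),
        ("CD1", ("CA", "CB", "CG"), 1.521, 110.7, _chi(2)),
        ("CD2", ("CA", "CB", "CG"), 1.521, 110.7, _chi(2, 122.0)),
    ],
    "ILE": [
        ("CG1", ("N", "CA", "CB"), 1.530, 110.4, _chi(1)),
        ("CG2", ("N", "CA", "CB"), 1.521, 110.5, _chi(1, -122.0)),
        ("CD1", ("CA", "CB", "CG1"), 1.513, 113.8, _chi(2)),
    ],
    "MET": [
        ("CG", ("N", "CA", "CB"), 1.520, 114.1, _chi(1)),
        ("SD", ("CA", "CB", "CG"), 1.803, 112.7, _chi(2)),
        ("CE", ("CB", "CG", "SD"), 1.791, 100.9, _chi(3)),
    ],
    "ASP": [
        ("CG", ("N", "CA", "CB"), 1.516, 112.6, _chi(1)),
        ("OD1", ("CA", "CB", "CG"), 1.249, 118.4, _chi(2)),
        ("OD2", ("CA", "CB", "CG"), 1.249, 118.4, _chi(2, 180.0)),
    ],
    "ASN": [
        ("CG", ("N", "CA", "CB"), 1.516, 112.6, _chi(1)),
        ("OD1", ("CA", "CB", "CG"), 1.231, 120.8, _chi(2)),
        ("ND2", ("CA", "CB", "CG"), 1.328, 116.4, _chi(2, 180.0)),
    ],
    "GLU": [
        ("CG", ("N", "CA", "CB"), 1.520, 114.1, _chi(1)),
        ("CD", ("CA", "CB", "CG"), 1.516, 112.6, _chi(2)),
        ("OE1", ("CB", "CG", "CD"), 1.249, 118.4, _chi(3)),
        ("OE2", ("CB", "CG", "CD"), 1.249, 118.4, _chi(3, 180.0)),
    ],
    "GLN": [
        ("CG", ("N", "CA", "CB"), 1.520, 114.1, _chi(1)),
        ("CD", ("CA", "CB", "CG"), 1.516, 112.6, _chi(2)),
        ("OE1", ("CB", "CG", "CD"), 1.231, 120.8, _chi(3)),
        ("NE2", ("CB", "CG", "CD"), 1.328, 116.4, _chi(3, 180.0)),
    ],
    "LYS": [
        ("CG", ("N", "CA", "CB"), 1.520, 114.1, _chi(1)),
        ("CD", ("CA", "CB", "CG"), 1.520, 111.3, _chi(2)),
        ("CE", ("CB", "CG", "CD"), 1.520, 111.3, _chi(3)),
        ("NZ", ("CG", "CD", "CE"), 1.489, 111.9, _chi(4)),
    ],
    "ARG": [
        ("CG", ("N", "CA", "CB"), 1.520, 114.1, _chi(1)),
        ("CD", ("CA", "CB", "CG"), 1.520, 111.3, _chi(2)),
        ("NE", ("CB", "CG", "CD"), 1.460, 112.0, _chi(3)),
        ("CZ", ("CG", "CD", "NE"), 1.330, 124.2, _chi(4)),
        ("NH1", ("CD", "NE", "CZ"), 1.326, 120.0, 0.0),
        ("NH2", ("CD", "NE", "CZ"), 1.326, 120.0, 180.0),
    ],
    "PHE": [
        ("CG", ("N", "CA", "CB"), 1.510, 113.8, _chi(1)),
        ("CD1", ("CA", "CB", "CG"), 1.390, 120.7, _chi(2)),
        ("CD2", ("CA", "CB", "CG"), 1.390, 120.7, _chi(2, 180.0)),
        ("CE1", ("CB", "CG", "CD1"), 1.390, 120.0, 180.0),
        ("CE2", ("CB", "CG", "CD2"), 1.390, 120.0, 180.0),
        ("CZ", ("CG", "CD1", "CE1"), 1.390, 120.0, 0.0),
    ],
    "HIS": [
        ("CG", ("N", "CA", "CB"), 1.504, 113.8, _chi(1)),
        ("ND1", ("CA", "CB", "CG"), 1.378, 122.7, _chi(2)),
        ("CD2", ("CA", "CB", "CG"), 1.356, 131.0, _chi(2, 180.0)),
        ("CE1", ("CB", "CG", "ND1"), 1.320, 109.0, 180.0),
        ("NE2", ("CB", "CG", "CD2"), 1.374, 107.0, 180.0),
    ],
    "TRP": [
        ("CG", ("N", "CA", "CB"), 1.498, 113.6, _chi(1)),
        ("CD1", ("CA", "CB", "CG"), 1.365, 126.9, _chi(2)),
        ("CD2", ("CA", "CB", "CG"), 1.433, 126.7, _chi(2, 180.0)),
        ("NE1", ("CB", "CG", "CD1"), 1.374, 110.0, 180.0),
        ("CE2", ("CB", "CG", "CD2"), 1.409, 107.2, 180.0),
        ("CE3", ("CD1", "CG", "CD2"), 1.398, 133.9, 180.0),
        ("CZ2", ("CG", "CD2", "CE2"), 1.394, 122.4, 180.0),
        ("CZ3", ("CG", "CD2", "CE3"), 1.382, 118.8, 180.0),
        ("CH2", ("CD2", "CE3", "CZ3"), 1.400, 121.2, 0.0),
    ],
    "PRO": [
        ("CG", ("N", "CA", "CB"), 1.495, 104.5, _chi(1)),
        ("CD", ("CA", "CB", "CG"), 1.507, 106.1, _chi(2)),
    ],
}
SIDE_CHAIN_TOPOLOGY["TYR"] = SIDE_CHAIN_TOPOLOGY["PHE"] + [
    ("OH", ("CD1", "CE1", "CZ"), 1.376, 119.9, 180.0)
]
for _aa in ("SER", "CYS", "THR", "VAL", "LEU", "ILE", "MET", "ASP", "ASN", "GLU",
            "GLN", "LYS", "ARG", "PHE", "TYR", "HIS", "TRP", "PRO", "ALA"):
    # CB is anchored on the backbone before the chi-driven chain starts
    SIDE_CHAIN_TOPOLOGY[_aa] = [
        ("CB", ("C", "N", "CA"), 1.536, 110.4, -122.0)
    ] + SIDE_CHAIN_TOPOLOGY[_aa]

#: Atom quadruples defining each canonical chi dihedral.
CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {
    "SER": [("N", "CA", "CB", "OG")],
    "CYS": [("N", "CA", "CB", "SG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "VAL": [("N", "CA", "CB", "CG1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"), ("CB", "CG", "SD", "CE")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"), ("CB", "CG", "CD", "OE1")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"), ("CB", "CG", "CD", "OE1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "PRO": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
    "GLY": [],
    "ALA": [],
}


def _element_of(name: str) -> str:
    for e in ("CL",):
        if name.upper().startswith(e):
            return e
    return name[0] if name[0] in "CNOSH" else "C"


def build_side_chain(
    n_coord, ca_coord, c_coord, amino_acid: str, chi: Sequence[float]
) -> list[Atom]:
    """Construct side-chain atoms on a backbone anchor with exact chi angles."""
    aa = amino_acid.upper()
    if aa not in SIDE_CHAIN_TOPOLOGY:
        raise ValueError(f"unknown amino acid {amino_acid!r}")
    if len(chi) != CHI_COUNT[aa]:
        raise ValueError(
            f"{aa}: got {len(chi)} chi angles, canonical count is {CHI_COUNT[aa]}"
        )
    coords = {
        "N": np.asarray(n_coord, dtype=float),
        "CA": np.asarray(ca_coord, dtype=float),
        "C": np.asarray(c_coord, dtype=float),
    }
    atoms: list[Atom] = []
    for name, (a, b, c), bond, angle, dihedral in SIDE_CHAIN_TOPOLOGY[aa]:
        if isinstance(dihedral, tuple):
            _, k, off = dihedral
            phi = normalize_angle(float(chi[k - 1]) + off)
        else:
            phi = dihedral
        pos = _nerf(coords[a], coords[b], coords[c], bond, angle, phi)
        coords[name] = pos
        atoms.append(Atom.typed(name, _element_of(name), pos, aa))
    return atoms


def place_side_chain(
    structure: ProteinStructure,
    position: tuple[str, int],
    amino_acid: str,
    chi: Sequence[float],
) -> list[Atom]:
    """Realize a side chain at a design position; template atoms untouched."""
    res = structure.residue_at(*position)
    return build_side_chain(
        res.atom("N").coord, res.atom("CA").coord, res.atom("C").coord,
        amino_acid, chi,
    )


def measure_chi(residue_atoms: dict[str, np.ndarray], amino_acid: str) -> list[float]:
    """Measure the canonical chi dihedrals from atom coordinates."""
    out = []
    for quad in CHI_ATOMS[amino_acid.upper()]:
        out.append(measure_dihedral(*(residue_atoms[n] for n in quad)))
    return out


@lru_cache(maxsize=None)
def _bond_separations(aa: str) -> dict[frozenset, int]:
    """Bond-graph separation (capped at 4) between atoms of one residue."""
    adj: dict[str, set[str]] = {n: set() for n in ("N", "CA", "C", "O")}
    for x, y in (("N", "CA"), ("CA", "C"), ("C", "O")):
        adj[x].add(y)
        adj[y].add(x)
    for name, (_, _, parent), *_rest in SIDE_CHAIN_TOPOLOGY[aa]:
        adj.setdefault(name, set())
        adj.setdefault(parent, set())
        adj[name].add(parent)
        adj[parent].add(name)
    seps: dict[frozenset, int] = {}
    import collections

    for start in adj:
        dist = {start: 0}
        dq = collections.deque([start])
        while dq:
            u = dq.popleft()
            if dist[u] >= 4:
                continue
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    dq.append(v)
        for other, d in dist.items():
            seps[frozenset((start, other))] = min(
                d, seps.get(frozenset((start, other)), 99)
            )
    return seps


def bond_separation(aa: str, name_a: str, name_b: str) -> int:
    """Bond count between two atoms of the same residue (>=4 means far)."""
    return _bond_separations(aa).get(frozenset((name_a, name_b)), 99)


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def read_pdb(text: str) -> ProteinStructure:
    """Read PDB text into a typed :class:`ProteinStructure`.

    Waters, ions and other non-amino-acid heteroatoms are dropped; hydrogens
    are retained when present; alternate locations resolve to the highest
    occupancy; residues with missing heavy side-chain atoms are flagged
    ``incomplete``.
    """
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM")):
            if len(line) < 54:
                raise PdbParseError(f"line {lineno}: truncated ATOM record")
            try:
                float(line[30:38]); float(line[38:46]); float(line[46:54])
                int(line[22:26])
            except ValueError:
                raise PdbParseError(
                    f"line {lineno}: unreadable coordinate or residue number"
                ) from None

    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    try:
        biostruct = parser.get_structure("x", io.StringIO(text))
    except Exception as exc:  # Biopython raises its own construction errors
        raise PdbParseError(str(exc)) from exc

    out = ProteinStructure()
    model = next(iter(biostruct))
    for chain in model:
        for res in chain:
            resname = res.get_resname().strip()
            if resname in _WATER_NAMES or resname in _ION_NAMES:
                continue
            if resname not in THREE_TO_ONE:
                continue
            atoms: list[Atom] = []
            for at in res:
                if at.is_disordered():
                    children = at.disordered_get_list()
                    at = max(children, key=lambda a: a.get_occupancy() or 0.0)
                name = at.get_name().strip()
                element = (at.element or _element_of(name)).strip().upper()
                coord = np.asarray(at.get_coord(), dtype=float)
                if not np.all(np.isfinite(coord)):
                    raise PdbParseError(
                        f"non-finite coordinates for {resname} {name}"
                    )
                atoms.append(Atom.typed(name, element, coord, resname))
            expected = {n for n, *_ in SIDE_CHAIN_TOPOLOGY[resname]}
            present = {a.name for a in atoms}
            missing = tuple(sorted(expected - present))
            out.residues.append(
                Residue(
                    chain=chain.id.strip() or "A",
                    resseq=res.get_id()[1],
                    resname=resname,
                    atoms=atoms,
                    incomplete=missing,
                )
            )
    return out


def to_pdb_text(structure: ProteinStructure) -> str:
    """Serialize a structure to minimal PDB text (ATOM records + TER)."""
    lines = []
    serial = 1
    for res in structure.residues:
        for a in res.atoms:
            name = a.name if len(a.name) == 4 else f" {a.name}"
            lines.append(
                f"ATOM  {serial:5d} {name:<4s}{res.resname:>4s} {res.chain}"
                f"{res.resseq:4d}    {a.coord[0]:8.3f}{a.coord[1]:8.3f}"
                f"{a.coord[2]:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                f"{a.element:>2s}"
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def ideal_backbone(
    sequence: Sequence[str],
    phi: float = -120.0,
    psi: float = 130.0,
    chain: str = "A",
    chis: Sequence[Sequence[float]] | None = None,
) -> ProteinStructure:
    """Build a poly-peptide with ideal backbone geometry (and side chains).

    Used to construct small self-consistent test and demo systems without
    any external structure file.  ``chis`` optionally gives the chi angles
    per residue; by default the first rotamer-free conformation (all chi
    at 180 degrees) is used.
    """
    seq = [ONE_TO_THREE.get(s, s).upper() for s in sequence]
    structure = ProteinStructure()
    prev_c = prev_ca = prev_n = None
    for i, aa in enumerate(seq):
        if i == 0:
            n = np.array([0.0, 0.0, 0.0])
            ca = np.array([1.458, 0.0, 0.0])
            c = _nerf(n + np.array([0.0, 1.0, 0.0]), n, ca, 1.525, 111.2, phi)
        else:
            n = _nerf(prev_n, prev_ca, prev_c, 1.329, 116.2, psi)
            ca = _nerf(prev_ca, prev_c, n, 1.458, 121.7, 180.0)
            c = _nerf(prev_c, n, ca, 1.525, 111.2, phi)
        o = _nerf(n, ca, c, 1.231, 120.8, normalize_angle(psi + 180.0))
        atoms = [
            Atom.typed("N", "N", n, aa),
            Atom.typed("CA", "C", ca, aa),
            Atom.typed("C", "C", c, aa),
            Atom.typed("O", "O", o, aa),
        ]
        chi = list(chis[i]) if chis is not None else [180.0] * CHI_COUNT[aa]
        atoms.extend(build_side_chain(n, ca, c, aa, chi))
        structure.residues.append(
            Residue(chain=chain, resseq=i + 1, resname=aa, atoms=atoms)
        )
        prev_n, prev_ca, prev_c = n, ca, c
    return structure


# ---------------------------------------------------------------------------
# SASA and design-site selection
# ---------------------------------------------------------------------------

@lru_cache(maxsize=4)
def _sphere_points(n: int) -> np.ndarray:
    """Quasi-uniform points on the unit sphere (golden-section spiral)."""
    k = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0**0.5) * k
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)],
        axis=1,
    )


def shrake_rupley(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area, Shrake-Rupley algorithm."""
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n = coords.shape[0]
    extended = radii + probe_radius
    sphere = _sphere_points(n_points)
    areas = np.zeros(n)
    for i in range(n):
        ri = extended[i]
        pts = coords[i] + ri * sphere
        d = np.linalg.norm(coords - coords[i], axis=1)
        neighbors = np.where((d < ri + extended) & (np.arange(n) != i))[0]
        buried = np.zeros(n_points, dtype=bool)
        for j in neighbors:
            dj = np.linalg.norm(pts - coords[j], axis=1)
            buried |= dj < extended[j]
        areas[i] = 4.0 * np.pi * ri * ri * float(np.mean(~buried))
    return areas


def relative_sidechain_sasa(structure: ProteinStructure) -> dict[tuple[str, int], float]:
    """Per-residue side-chain SASA as a percentage of Gly-X-Gly reference."""
    atoms = [a for r in structure.residues for a in r.atoms if a.element != "H"]
    owner = [
        (r.chain, r.resseq)
        for r in structure.residues
        for a in r.atoms
        if a.element != "H"
    ]
    coords = np.array([a.coord for a in atoms])
    radii = np.array([a.rmin for a in atoms])
    areas = shrake_rupley(coords, radii)
    out: dict[tuple[str, int], float] = {}
    for res in structure.residues:
        ref = _SIDECHAIN_REF_AREA.get(res.resname)
        if ref is None:  # Gly: no side chain to measure
            continue
        sc = sum(
            areas[k]
            for k, (a, o) in enumerate(zip(atoms, owner))
            if o == (res.chain, res.resseq) and a.name not in _BACKBONE_NAMES
        )
        out[(res.chain, res.resseq)] = 100.0 * sc / ref
    return out


def blosum_substitutions(
    wild_type_aa: str,
    k: int = 5,
    exclude: Iterable[str] = ("CYS", "PRO", "GLY"),
) -> set[str]:
    """Wild type plus the k best-scoring BLOSUM62 substitutions.

    Ties break by the standard BLOSUM62 amino-acid order; Cys/Pro/Gly are
    excluded as substitutions by default (the wild type always stays).
    """
    wt = wild_type_aa.upper()
    if wt not in THREE_TO_ONE:
        raise ValueError(f"unknown amino acid {wild_type_aa!r}")
    if k == 0:
        return {wt}
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load("BLOSUM62")
    order = "ARNDCQEGHILKMFPSTWYV"
    excluded = {ONE_TO_THREE[c] if len(c) == 1 else c.upper() for c in exclude}
    wt1 = THREE_TO_ONE[wt]
    scored = []
    for rank, aa1 in enumerate(order):
        aa3 = ONE_TO_THREE[aa1]
        if aa3 == wt or aa3 in excluded:
            continue
        scored.append((-float(mat[wt1, aa1]), rank, aa3))
    scored.sort()
    return {wt} | {aa3 for _, _, aa3 in scored[:k]}


def select_core_positions(
    structure: ProteinStructure,
    sasa_thresholds: Sequence[float] = (5.0, 10.0, 20.0),
    target_count: int = 12,
    substitutions_k: int = 5,
    sasa: dict[tuple[str, int], float] | None = None,
) -> DesignSpec:
    """Pick buried design sites by relative side-chain SASA.

    The smallest threshold yielding at least ``target_count`` positions is
    used; if fewer than ``target_count`` residues fall at or under the
    largest threshold, all of those are used.
    """
    if sasa is None:
        sasa = relative_sidechain_sasa(structure)
    thresholds = sorted(sasa_thresholds)
    chosen: list[tuple[str, int]] = []
    used = thresholds[-1]
    for t in thresholds:
        cand = [p for p, v in sasa.items() if v <= t]
        if len(cand) >= target_count:
            chosen, used = cand, t
            break
    else:
        chosen = [p for p, v in sasa.items() if v <= thresholds[-1]]
    chosen.sort(key=lambda p: structure.index_of(*p))
    allowed = {}
    for pos in chosen:
        wt = structure.residue_at(*pos).resname
        allowed[pos] = blosum_substitutions(wt, substitutions_k)
    return DesignSpec(
        positions=chosen,
        allowed=allowed,
        sasa_threshold=used,
        substitutions_k=substitutions_k,
    )


# ---------------------------------------------------------------------------
# Molecular energy model
# ---------------------------------------------------------------------------

def _pair_group_energy(atoms_a: list[Atom], atoms_b: list[Atom],
                       weights: EnergyWeights,
                       exclude: set[tuple[str, str]] | None = None) -> float:
    """Sum of vdW + Coulomb + EEF1 desolvation over an atom-group pair."""
    e = 0.0
    for a in atoms_a:
        for b in atoms_b:
            if exclude and (a.name, b.name) in exclude:
                continue
            e += weights.vdw_weight * vdw_pair(
                a, b, weights.radius_scale, weights.clash_cap
            )
            e += coulomb_pair(a, b, weights.dielectric, weights.clash_cap)
            e += solvation_pair(a, b, weights.solvation_weight)
    return e


class MolecularEnergyModel(EnergyModel):
    """Molecular implementation of the energy contract.

    The template is the backbone plus all non-design side chains; design
    side chains are rebuilt from chi angles on every evaluation.  Within a
    residue, atom pairs separated by fewer than three bonds are excluded.
    """

    vectorized = False

    def __init__(
        self,
        structure: ProteinStructure,
        design_indices: list[int],
        rotamers: list[list[DesignRotamer]],
        weights: EnergyWeights | None = None,
    ):
        self.structure = structure
        self.design_indices = list(design_indices)
        self.rotamers = rotamers
        self.weights = weights or EnergyWeights()
        design = set(design_indices)
        self._template_atoms: list[tuple[int, Atom]] = []
        for idx, res in enumerate(structure.residues):
            for a in res.atoms:
                if idx in design and a.name not in _BACKBONE_NAMES:
                    continue  # design side chains are not template
                self._template_atoms.append((idx, a))
        self._template_value: float | None = None

    # -- helpers ------------------------------------------------------------

    def _anchor(self, pos: int):
        res = self.structure.residues[self.design_indices[pos]]
        return res

    def _build(self, pos: int, rot: int, delta) -> list[Atom]:
        r = self.rotamers[pos][rot]
        delta = np.atleast_1d(np.asarray(delta, dtype=float))
        chi = [normalize_angle(m + d) for m, d in zip(r.chi_modal, delta)]
        res = self._anchor(pos)
        return build_side_chain(
            res.atom("N").coord, res.atom("CA").coord, res.atom("C").coord,
            r.amino_acid, chi,
        )

    # -- contract -----------------------------------------------------------

    def template_energy(self) -> float:
        if self._template_value is not None:
            return self._template_value
        w = self.weights
        e = 0.0
        atoms = self._template_atoms
        for k, (ri, a) in enumerate(atoms):
            for rj, b in atoms[k + 1:]:
                if ri == rj:
                    res = self.structure.residues[ri]
                    if bond_separation(res.resname, a.name, b.name) < 3:
                        continue
                elif abs(ri - rj) == 1:
                    # peptide-bond neighbourhood: 1-2 and 1-3 across the link
                    first, second = (a, b) if ri < rj else (b, a)
                    if (first.name, second.name) in {
                        ("C", "N"), ("C", "CA"), ("C", "H"), ("O", "N"),
                        ("CA", "N"),
                    }:
                        continue
                e += w.vdw_weight * vdw_pair(a, b, w.radius_scale, w.clash_cap)
                e += coulomb_pair(a, b, w.dielectric, w.clash_cap)
                e += solvation_pair(a, b, w.solvation_weight)
        e += w.solvation_weight * sum(a.dg_ref for _, a in atoms)
        self._template_value = float(e)
        return self._template_value

    def intra(self, pos: int, rot: int, delta) -> float:
        w = self.weights
        r = self.rotamers[pos][rot]
        sc = self._build(pos, rot, delta)
        own = self.design_indices[pos]
        aa = r.amino_acid
        e = 0.0
        # side chain vs template, excluding close bonded pairs in own residue
        for a in sc:
            for ridx, b in self._template_atoms:
                if ridx == own and bond_separation(aa, a.name, b.name) < 3:
                    continue
                e += w.vdw_weight * vdw_pair(a, b, w.radius_scale, w.clash_cap)
                e += coulomb_pair(a, b, w.dielectric, w.clash_cap)
                e += solvation_pair(a, b, w.solvation_weight)
        # internal side-chain energy (pairs three or more bonds apart)
        for i, a in enumerate(sc):
            for b in sc[i + 1:]:
                if bond_separation(aa, a.name, b.name) < 3:
                    continue
                e += w.vdw_weight * vdw_pair(a, b, w.radius_scale, w.clash_cap)
                e += coulomb_pair(a, b, w.dielectric, w.clash_cap)
                e += solvation_pair(a, b, w.solvation_weight)
        e += w.solvation_weight * sum(a.dg_ref for a in sc)
        e += w.reference_energies.get(aa, 0.0)
        e += w.entropy_penalties.get(aa, 0.0)
        return float(e)

    def pair(self, pos_i, rot_i, delta_i, pos_j, rot_j, delta_j) -> float:
        if pos_i == pos_j:
            raise ValueError("pair energy requires two distinct positions")
        if pos_i > pos_j:  # symmetry by canonical ordering
            pos_i, rot_i, delta_i, pos_j, rot_j, delta_j = (
                pos_j, rot_j, delta_j, pos_i, rot_i, delta_i
            )
        sc_i = self._build(pos_i, rot_i, delta_i)
        sc_j = self._build(pos_j, rot_j, delta_j)
        return float(_pair_group_energy(sc_i, sc_j, self.weights))


def build_molecular_instance(
    structure: ProteinStructure,
    spec: DesignSpec,
    library: RotamerLibrary,
    weights: EnergyWeights | None = None,
    half_width: float = 9.0,
) -> DesignInstance:
    """Assemble a molecular design instance from structure + spec + library."""
    design_indices = []
    for pos in spec.positions:
        idx = structure.index_of(*pos)
        res = structure.residues[idx]
        if not res.backbone_complete():
            raise StructureValidationError(
                f"design residue {res.label} has an incomplete backbone"
            )
        design_indices.append(idx)
    # chain-break check around design residues
    for idx in design_indices:
        for nb in (idx - 1, idx):
            if 0 <= nb < len(structure.residues) - 1:
                a, b = structure.residues[nb], structure.residues[nb + 1]
                if a.chain != b.chain:
                    continue
                if a.has_atom("C") and b.has_atom("N"):
                    d = float(np.linalg.norm(a.atom("C").coord - b.atom("N").coord))
                    if d > 2.0:
                        raise StructureValidationError(
                            f"chain break between {a.label} and {b.label} "
                            f"(C-N distance {d:.2f} A) in a design region"
                        )
    rotamers: list[list[DesignRotamer]] = []
    for pos in spec.positions:
        wt = structure.residue_at(*pos).resname
        allowed = sorted(spec.allowed[pos])
        if wt not in allowed:
            raise StructureValidationError(
                f"allowed set at {pos} must contain the wild type {wt}"
            )
        rots: list[DesignRotamer] = []
        for aa in allowed:
            for rec in library.records(aa):
                rots.append(
                    DesignRotamer(
                        amino_acid=aa,
                        rotamer_id=f"{pos[0]}{pos[1]}:{rec.source_id}",
                        chi_modal=rec.chi_modal,
                        half_width=(half_width,) * rec.n_chi,
                    )
                )
        if not rots:
            raise StructureValidationError(f"no rotamers available at {pos}")
        rotamers.append(rots)
    model = MolecularEnergyModel(structure, design_indices, rotamers, weights)
    labels = [f"{c}{i}" for c, i in spec.positions]
    return DesignInstance(position_labels=labels, rotamers=rotamers, model=model)
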