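"""Rotamer libraries: parsing, voxelization, and expansion.

A *rotamer* is a modal side-chain conformation given by its chi dihedral
angles.  A *continuous rotamer* is the axis-aligned voxel of chi space
centred on that modal point; the design search lets every side chain
minimize anywhere inside its voxel.  This module reads a tab-separated
rotamer table, attaches voxels, and builds the expanded libraries (RL1/RL2)
used to compare continuous rotamers against denser rigid sampling.

All angles are degrees in (-180, 180] with periodic arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Sequence

__all__ = [
    "CHI_COUNT",
    "RotamerRecord",
    "ContinuousRotamer",
    "RotamerLibrary",
    "RotamerParseError",
    "normalize_angle",
    "angle_in_interval",
    "parse_rotamer_library",
    "load_bundled_library",
    "voxelize",
    "expand_library",
    "count_expanded_pairs",
]

#: Canonical number of side-chain dihedrals per amino acid (3-letter code).
CHI_COUNT: dict[str, int] = {
    "GLY": 0, "ALA": 0,
    "SER": 1, "CYS": 1, "THR": 1, "VAL": 1,
    "PRO": 2, "LEU": 2, "ILE": 2, "PHE": 2, "TYR": 2, "TRP": 2,
    "ASP": 2, "ASN": 2, "HIS": 2,
    "MET": 3, "GLU": 3, "GLN": 3,
    "ARG": 4, "LYS": 4,
}


def normalize_angle(theta: float) -> float:
    """Map an angle in degrees onto (-180, 180]."""
    t = float(theta) % 360.0
    if t > 180.0:
        t -= 360.0
    # -180 maps to +180 under the half-open convention
    if t <= -180.0:
        t += 360.0
    return t


def angle_in_interval(theta: float, center: float, half_width: float) -> bool:
    """True if ``theta`` lies within ``center +/- half_width`` on the circle."""
    delta = normalize_angle(theta - center)
    return abs(delta) <= half_width + 1e-12


class RotamerParseError(ValueError):
    """Raised for malformed rotamer-table rows (message names the line)."""


@dataclass(frozen=True)
class RotamerRecord:
    """One modal rotamer: amino acid, chi angles, optional per-angle spreads."""

    amino_acid: str
    chi_modal: tuple[float, ...]
    chi_sigma: tuple[float, ...] | None
    source_id: str

    def __post_init__(self) -> None:
        aa = self.amino_acid.upper()
        if aa not in CHI_COUNT:
            raise ValueError(f"unknown amino acid {self.amino_acid!r}")
        object.__setattr__(self, "amino_acid", aa)
        expected = CHI_COUNT[aa]
        if len(self.chi_modal) != expected:
            raise ValueError(
                f"{aa} rotamer {self.source_id!r}: {len(self.chi_modal)} chi "
                f"angles given, canonical count is {expected}"
            )
        object.__setattr__(
            self, "chi_modal", tuple(normalize_angle(c) for c in self.chi_modal)
        )
        if self.chi_sigma is not None:
            if len(self.chi_sigma) != expected:
                raise ValueError(
                    f"{aa} rotamer {self.source_id!r}: sigma count mismatch"
                )
            object.__setattr__(self, "chi_sigma", tuple(float(s) for s in self.chi_sigma))

    @property
    def n_chi(self) -> int:
        return len(self.chi_modal)


@dataclass(frozen=True)
class ContinuousRotamer:
    """A rotamer voxel: ``chi_modal +/- half_width`` per dihedral, periodic."""

    base: RotamerRecord
    half_width: tuple[float, ...]

    def __post_init__(self) -> None:
        hw = tuple(float(h) for h in self.half_width)
        if len(hw) != self.base.n_chi:
            raise ValueError("half_width length must match dihedral count")
        if any(h <= 0 for h in hw):
            raise ValueError("half_width must be positive for every dihedral")
        object.__setattr__(self, "half_width", hw)

    def contains(self, chi: Sequence[float]) -> bool:
        if len(chi) != self.base.n_chi:
            return False
        return all(
            angle_in_interval(c, m, h)
            for c, m, h in zip(chi, self.base.chi_modal, self.half_width)
        )


@dataclass
class RotamerLibrary:
    """Rotamer records grouped by amino acid."""

    groups: dict[str, list[RotamerRecord]] = field(default_factory=dict)
    library_tag: str = "RL0"

    def __post_init__(self) -> None:
        ids: set[str] = set()
        for aa, records in self.groups.items():
            if not records:
                raise ValueError(f"amino acid {aa} present with no records")
            for rec in records:
                if rec.source_id in ids:
                    raise ValueError(f"duplicate rotamer id {rec.source_id!r}")
                ids.add(rec.source_id)

    def records(self, amino_acid: str) -> list[RotamerRecord]:
        return self.groups.get(amino_acid.upper(), [])

    def amino_acids(self) -> list[str]:
        return sorted(self.groups)

    @property
    def n_records(self) -> int:
        return sum(len(g) for g in self.groups.values())


# ---------------------------------------------------------------------------
# Parsing
#
# Dialect: header ``aa<TAB>id<TAB>chi1..chi4<TAB>sig1..sig4``; empty cells for
# absent dihedrals; lines starting with ``#`` are comments.
# ---------------------------------------------------------------------------

_HEADER = ["aa", "id", "chi1", "chi2", "chi3", "chi4", "sig1", "sig2", "sig3", "sig4"]


def parse_rotamer_library(text: str, library_tag: str = "RL0") -> RotamerLibrary:
    """Parse the rotamer TSV dialect into a :class:`RotamerLibrary`."""
    groups: dict[str, list[RotamerRecord]] = {}
    header_seen = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        cells = line.split("\t")
        if not header_seen:
            if [c.strip().lower() for c in cells] != _HEADER:
                raise RotamerParseError(
                    f"line {lineno}: expected header {' '.join(_HEADER)}"
                )
            header_seen = True
            continue
        if len(cells) != len(_HEADER):
            raise RotamerParseError(
                f"line {lineno}: expected {len(_HEADER)} tab-separated cells, "
                f"got {len(cells)}"
            )
        aa = cells[0].strip().upper()
        rid = cells[1].strip()
        if aa not in CHI_COUNT:
            raise RotamerParseError(f"line {lineno}: unknown amino acid {aa!r}")
        try:
            chi = [float(c) for c in cells[2:6] if c.strip() != ""]
            sig = [float(c) for c in cells[6:10] if c.strip() != ""]
        except ValueError as exc:
            raise RotamerParseError(f"line {lineno}: non-numeric cell ({exc})") from None
        try:
            rec = RotamerRecord(
                amino_acid=aa,
                chi_modal=tuple(chi),
                chi_sigma=tuple(sig) if sig else None,
                source_id=rid,
            )
        except ValueError as exc:
            raise RotamerParseError(f"line {lineno}: {exc}") from None
        groups.setdefault(aa, []).append(rec)
    if not header_seen:
        raise RotamerParseError("line 1: missing header row")
    return RotamerLibrary(groups=groups, library_tag=library_tag)


def load_bundled_library() -> RotamerLibrary:
    """Load the vendored Penultimate-style rotamer table."""
    text = (
        resources.files("voxeldee.data")
        .joinpath("penultimate_style_synthetic.tsv")
        .read_text()
    )
    return parse_rotamer_library(text)


# ---------------------------------------------------------------------------
# Voxelization and expansion
# ---------------------------------------------------------------------------

def voxelize(lib: RotamerLibrary, half_width: float = 9.0) -> list[ContinuousRotamer]:
    """Attach an axis-aligned voxel of the given half-width to every record."""
    if half_width <= 0:
        raise ValueError("half_width must be positive")
    out: list[ContinuousRotamer] = []
    for aa in lib.amino_acids():
        for rec in lib.records(aa):
            out.append(ContinuousRotamer(rec, (half_width,) * rec.n_chi))
    return out


def _perturb_deltas(rec: RotamerRecord, k: int, delta) -> list[float]:
    """Resolve the perturbation magnitude for dihedral ``k`` (0-based)."""
    if delta == "per-rotamer sigma":
        if rec.chi_sigma is not None:
            d = rec.chi_sigma[k]
        else:
            d = 10.0  # configured fallback when the record carries no sigma
    else:
        d = float(delta)
    if d <= 0:
        raise ValueError("perturbation delta must resolve to a positive angle")
    return [-d, 0.0, d]


def expand_library(
    lib: RotamerLibrary,
    mode: str,
    delta="per-rotamer sigma",
) -> RotamerLibrary:
    """Build an expanded library by perturbing chi1 (RL1) or chi1+chi2 (RL2).

    Each record with the perturbed dihedral spawns modal and ±delta copies
    (x3 per perturbed dihedral); records lacking a perturbed dihedral pass
    through unchanged.
    """
    if mode not in ("RL1", "RL2"):
        raise ValueError(f"unknown expansion mode {mode!r} (use 'RL1' or 'RL2')")
    n_perturb = 1 if mode == "RL1" else 2
    groups: dict[str, list[RotamerRecord]] = {}
    for aa in lib.amino_acids():
        out: list[RotamerRecord] = []
        for rec in lib.records(aa):
            axes = []
            for k in range(min(n_perturb, rec.n_chi)):
                axes.append(_perturb_deltas(rec, k, delta))
            if not axes:
                out.append(rec)
                continue
            combos: list[list[float]] = [[]]
            for ax in axes:
                combos = [c + [d] for c in combos for d in ax]
            for idx, offsets in enumerate(combos):
                chi = list(rec.chi_modal)
                for k, off in enumerate(offsets):
                    chi[k] = normalize_angle(chi[k] + off)
                sid = rec.source_id if all(o == 0 for o in offsets) else (
                    f"{rec.source_id}.{mode}{idx}"
                )
                out.append(replace(rec, chi_modal=tuple(chi), source_id=sid))
        groups[aa] = out
    return RotamerLibrary(groups=groups, library_tag=mode)


def count_expanded_pairs(
    n_base: int, n_dihedrals: int, samples_per_dihedral: int
) -> int:
    """Pairs between two identical positions after dense dihedral sampling.

    Expanding ``n_base`` rotamers with ``samples_per_dihedral`` samples on each
    of ``n_dihedrals`` dihedrals gives ``n_base * s**d`` rotamers per position,
    hence ``(n_base * s**d)**2`` pairs between two such positions.
    """
    if n_base < 1 or samples_per_dihedral < 1 or n_dihedrals < 0:
        raise ValueError("arguments must be positive (n_dihedrals may be 0)")
    per_position = n_base * samples_per_dihedral**n_dihedrals
    return per_position**2
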