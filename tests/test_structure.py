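"""PDB I/O, side-chain geometry, SASA, and design-site selection."""

import numpy as np
import pytest

from voxeldee import (
    PdbParseError,
    blosum_substitutions,
    ideal_backbone,
    place_side_chain,
    read_pdb,
    select_core_positions,
    shrake_rupley,
    to_pdb_text,
)
from voxeldee.rotamers import CHI_COUNT
from voxeldee.structure import (
    CHI_ATOMS,
    build_side_chain,
    measure_chi,
    measure_dihedral,
)

CHI_BEARING = sorted(aa for aa, n in CHI_COUNT.items() if n > 0)


class TestReadPdb:
    def test_roundtrip_tripeptide(self, tripeptide_pdb_text):
        s = read_pdb(tripeptide_pdb_text)
        assert [r.resname for r in s.residues] == ["SER", "LEU", "VAL"]
        assert all(r.backbone_complete() for r in s.residues)
        assert all(not r.incomplete for r in s.residues)

    def test_altloc_keeps_highest_occupancy(self):
        text = (
            "ATOM      1  N   SER A   1       0.000   0.000   0.000  1.00  0.00           N\n"
            "ATOM      2  CA ASER A   1       1.458   0.000   0.000  0.40  0.00           C\n"
            "ATOM      3  CA BSER A   1       1.500   0.100   0.000  0.60  0.00           C\n"
            "ATOM      4  C   SER A   1       2.009   1.420   0.000  1.00  0.00           C\n"
            "ATOM      5  O   SER A   1       1.251   2.390   0.000  1.00  0.00           O\n"
            "END\n"
        )
        s = read_pdb(text)
        ca = [a for a in s.residues[0].atoms if a.name == "CA"]
        assert len(ca) == 1
        assert ca[0].coord[0] == pytest.approx(1.5)

    def test_missing_sidechain_atom_flagged(self, tripeptide):
        text = "\n".join(
            line for line in to_pdb_text(tripeptide).splitlines()
            if " CG " not in line
        )
        s = read_pdb(text)
        leu = s.residues[1]
        assert "CG" in leu.incomplete

    def test_waters_dropped(self, tripeptide_pdb_text):
        text = tripeptide_pdb_text.replace(
            "END",
            "HETATM  99  O   HOH A  90      9.000   9.000   9.000  1.00  0.00           O\nEND",
        )
        s = read_pdb(text)
        assert len(s.residues) == 3

    def test_unreadable_record_names_line(self):
        with pytest.raises(PdbParseError, match="line 1"):
            read_pdb("ATOM      1  N   SER A   x       a.aaa   0.000   0.000\n")


class TestSideChainPlacement:
    @pytest.mark.parametrize("aa", CHI_BEARING)
    def test_chi_roundtrip_exact(self, aa):
        # place at arbitrary chi, re-measure each canonical dihedral
        rng = np.random.default_rng(hash(aa) % 2**31)
        chi = [float(c) for c in rng.uniform(-170, 170, CHI_COUNT[aa])]
        n = np.array([0.0, 0.0, 0.0])
        ca = np.array([1.458, 0.0, 0.0])
        c = np.array([2.0, 1.4, 0.0])
        atoms = build_side_chain(n, ca, c, aa, chi)
        coords = {"N": n, "CA": ca, "C": c}
        coords.update({a.name: a.coord for a in atoms})
        measured = measure_chi(coords, aa)
        assert measured == pytest.approx(chi, abs=1e-6)

    def test_glycine_places_nothing(self):
        atoms = build_side_chain(
            np.zeros(3), np.array([1.458, 0, 0]), np.array([2.0, 1.4, 0]), "GLY", []
        )
        assert atoms == []

    def test_chi1_flip_moves_only_distal_atoms(self):
        n = np.zeros(3)
        ca = np.array([1.458, 0.0, 0.0])
        c = np.array([2.0, 1.4, 0.0])
        a1 = {a.name: a.coord for a in build_side_chain(n, ca, c, "LEU", [60.0, 170.0])}
        a2 = {a.name: a.coord for a in build_side_chain(n, ca, c, "LEU", [-120.0, 170.0])}
        assert np.allclose(a1["CB"], a2["CB"])  # proximal to the chi1 bond
        for distal in ("CG", "CD1", "CD2"):
            assert not np.allclose(a1[distal], a2[distal])

    def test_template_atoms_untouched(self, tripeptide):
        before = {
            (r.resseq, a.name): a.coord.copy()
            for r in tripeptide.residues
            for a in r.atoms
        }
        place_side_chain(tripeptide, ("A", 2), "LEU", [55.0, 160.0])
        after = {
            (r.resseq, a.name): a.coord
            for r in tripeptide.residues
            for a in r.atoms
        }
        for key in before:
            assert np.array_equal(before[key], after[key])

    def test_chi_length_mismatch_rejected(self, tripeptide):
        with pytest.raises(ValueError):
            place_side_chain(tripeptide, ("A", 2), "LEU", [55.0])

    def test_dihedral_measure_sign_convention(self):
        # a +90 degree rotation about the z-axis bond
        p1 = np.array([1.0, 0.0, 1.0])
        p2 = np.array([0.0, 0.0, 1.0])
        p3 = np.array([0.0, 0.0, 0.0])
        p4 = np.array([0.0, -1.0, 0.0])
        assert measure_dihedral(p1, p2, p3, p4) == pytest.approx(90.0)


class TestSasa:
    def test_matches_reference_shrake_rupley(self, tripeptide):
        # internal implementation vs the Biopython reference, same radii
        from Bio.PDB.SASA import ShrakeRupley as BioSR
        from Bio.PDB import PDBParser
        import io

        atoms = [a for r in tripeptide.residues for a in r.atoms]
        coords = np.array([a.coord for a in atoms])
        radii = np.array([a.rmin for a in atoms])
        ours = shrake_rupley(coords, radii, probe_radius=1.4, n_points=960)

        parser = PDBParser(QUIET=True)
        bios = parser.get_structure("x", io.StringIO(to_pdb_text(tripeptide)))
        bio_atoms = list(bios.get_atoms())
        sr = BioSR(probe_radius=1.4, n_points=960)
        # align radii with ours, element by element
        radii_map = {}
        for a, rad in zip(bio_atoms, radii):
            radii_map[a.element.upper()] = rad
        sr.radii_dict.update(radii_map)
        sr.compute(bios, level="A")
        ref = np.array([a.sasa for a in bio_atoms])
        assert np.sum(ours) == pytest.approx(np.sum(ref), rel=0.05)

    def test_isolated_atom_is_full_sphere(self):
        area = shrake_rupley(np.zeros((1, 3)), np.array([1.9]))
        assert area[0] == pytest.approx(4 * np.pi * (1.9 + 1.4) ** 2, rel=1e-6)


class TestCoreSelection:
    def _structure(self, n):
        return ideal_backbone(["LEU"] * n)

    def test_smallest_sufficient_threshold_used(self):
        s = self._structure(20)
        sasa = {("A", i + 1): (2.0 if i < 14 else 50.0) for i in range(20)}
        spec = select_core_positions(s, sasa=sasa)
        assert spec.sasa_threshold == 5.0
        assert len(spec.positions) == 14

    def test_all_buried_used_when_below_target(self):
        s = self._structure(20)
        sasa = {("A", i + 1): (15.0 if i < 8 else 80.0) for i in range(20)}
        spec = select_core_positions(s, sasa=sasa)
        assert len(spec.positions) == 8

    def test_fully_exposed_gives_empty_selection(self):
        s = self._structure(5)
        sasa = {("A", i + 1): 90.0 for i in range(5)}
        spec = select_core_positions(s, sasa=sasa)
        assert spec.positions == []

    def test_allowed_sets_contain_wild_type(self):
        s = self._structure(15)
        sasa = {("A", i + 1): 1.0 for i in range(15)}
        spec = select_core_positions(s, sasa=sasa)
        for pos in spec.positions:
            assert "LEU" in spec.allowed[pos]


class TestBlosumSubstitutions:
    def test_isoleucine_top_five(self):
        out = blosum_substitutions("ILE", 5)
        assert len(out) == 6
        assert {"ILE", "VAL", "LEU", "MET"} <= out

    def test_k_zero_gives_wild_type_only(self):
        assert blosum_substitutions("ILE", 0) == {"ILE"}

    def test_tryptophan_contains_aromatics(self):
        out = blosum_substitutions("TRP", 5)
        assert {"TRP", "TYR", "PHE"} <= out

    def test_default_exclusions_respected(self):
        for wt in ("ILE", "LEU", "ARG"):
            out = blosum_substitutions(wt, 7)
            assert not ({"CYS", "PRO", "GLY"} & (out - {wt}))

    def test_unknown_amino_acid_rejected(self):
        with pytest.raises(ValueError):
            blosum_substitutions("XYZ", 5)
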