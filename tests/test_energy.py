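"""Molecular energy terms and the pairwise-decomposition contract."""

import math

import numpy as np
import pytest

from voxeldee import (
    DesignSpec,
    EnergyWeights,
    coulomb_pair,
    build_molecular_instance,
    ideal_backbone,
    parse_rotamer_library,
    solvation_pair,
    total_rigid_energy,
    vdw_pair,
)
from voxeldee.energy import COULOMB_CONSTANT, solvation_reference
from voxeldee.matrix import compute_rigid_matrix
from voxeldee.structure import Atom, bond_separation, _BACKBONE_NAMES

from conftest import make_matrix


def atom(x, charge=0.0, rmin=1.9, eps=0.1, dg_free=0.0, volume=20.0, lam=3.5):
    return Atom(
        name="X", element="C", coord=np.array([x, 0.0, 0.0]), charge=charge,
        rmin=rmin, eps=eps, dg_free=dg_free, dg_ref=0.0, lam=lam, volume=volume,
    )


class TestVdw:
    def test_minimum_at_scaled_rmin_sum(self):
        a, b = atom(0.0, eps=0.2), atom(0.9 * 3.8, eps=0.05)
        e = vdw_pair(a, b, radius_scale=0.9)
        assert e == pytest.approx(-math.sqrt(0.2 * 0.05), abs=1e-12)

    def test_long_range_limit_vanishes_from_below(self):
        a, b = atom(0.0), atom(40.0)
        e = vdw_pair(a, b)
        assert -1e-6 < e < 0.0

    def test_close_contact_strongly_repulsive(self):
        # direct evaluation of the 6-12 form at a compressed separation
        for frac, eps in ((0.7, 0.086), (0.65, 0.086)):
            a, b = atom(0.0, eps=eps), atom(frac * 3.8, eps=eps)
            q = (1.0 / frac) ** 6
            expected = eps * (q * q - 2.0 * q)
            assert vdw_pair(a, b) == pytest.approx(expected)
            assert expected > 0.0
        assert vdw_pair(atom(0.0, eps=0.086), atom(0.65 * 3.8, eps=0.086)) > 10.0

    def test_zero_distance_returns_clash_cap(self):
        assert vdw_pair(atom(0.0), atom(0.0), clash_cap=1e6) == 1e6


class TestCoulomb:
    def test_zero_charge_gives_zero(self):
        assert coulomb_pair(atom(0.0, charge=0.0), atom(1.0, charge=1.0), 4.0) == 0.0

    def test_unit_charges_at_one_angstrom(self):
        e = coulomb_pair(atom(0.0, charge=1.0), atom(1.0, charge=1.0), 4.0)
        assert e == pytest.approx(COULOMB_CONSTANT / 4.0)

    def test_odd_in_charge(self):
        plus = coulomb_pair(atom(0.0, charge=1.0), atom(2.0, charge=0.5), 6.0)
        minus = coulomb_pair(atom(0.0, charge=-1.0), atom(2.0, charge=0.5), 6.0)
        assert plus == pytest.approx(-minus)

    def test_distance_dependent_dielectric_scaling(self):
        # eps(r) = D r makes the energy fall as 1/r^2
        e1 = coulomb_pair(atom(0.0, charge=1.0), atom(2.0, charge=1.0), 4.0)
        e2 = coulomb_pair(atom(0.0, charge=1.0), atom(4.0, charge=1.0), 4.0)
        assert e1 / e2 == pytest.approx(4.0)


class TestSolvation:
    def test_isolated_atom_contributes_reference_only(self):
        a = atom(0.0, dg_free=-5.0)
        a.dg_ref = -5.0
        far = atom(500.0, dg_free=-5.0)
        assert solvation_pair(a, far) == pytest.approx(0.0, abs=1e-12)
        assert solvation_reference([a]) == -5.0

    def test_burial_of_polar_atom_costs_energy(self):
        polar = atom(0.0, dg_free=-6.0)
        c1, c2 = atom(3.5, volume=23.7), atom(-3.5, volume=23.7)
        e = solvation_pair(polar, c1) + solvation_pair(polar, c2)
        assert e > 0.0  # losing solvation of a polar atom is unfavourable

    def test_weight_zero_switches_term_off(self):
        polar = atom(0.0, dg_free=-6.0)
        c = atom(3.5)
        assert solvation_pair(polar, c, solvation_weight=0.0) == 0.0


class TestTotalRigidEnergy:
    def test_zero_matrix_returns_template(self):
        m = make_matrix([[0.0, 0.0], [0.0, 0.0]], {(0, 1): [[0, 0], [0, 0]]},
                        template=3.25)
        assert total_rigid_energy((1, 0), m) == 3.25

    def test_two_position_hand_sum(self):
        m = make_matrix([[1.0, 9.0], [5.0, 2.0]], {(0, 1): [[0.0, -0.5], [0, 0]]})
        assert total_rigid_energy((0, 1), m) == pytest.approx(2.5)

    def test_pair_lookup_symmetric(self):
        m = make_matrix([[0.0], [0.0]], {(0, 1): [[-0.7]]})
        assert m.pair_rigid_entry(1, 0, 0, 0) == m.pair_rigid_entry(0, 0, 1, 0)

    def test_unknown_rotamer_rejected(self):
        m = make_matrix([[1.0], [1.0]], {(0, 1): [[0.0]]})
        with pytest.raises(KeyError):
            total_rigid_energy((0, 5), m)


@pytest.fixture(scope="module")
def molecular_toy(bundled_library):
    """Five-residue peptide with two mutable positions, tiny rotamer sets."""
    text = (
        "aa\tid\tchi1\tchi2\tchi3\tchi4\tsig1\tsig2\tsig3\tsig4\n"
        "SER\tts1\t62\t\t\t\t9\t\t\t\n"
        "SER\tts2\t-65\t\t\t\t9\t\t\t\n"
        "VAL\ttv1\t175\t\t\t\t9\t\t\t\n"
    )
    lib = parse_rotamer_library(text)
    structure = ideal_backbone(["ALA", "SER", "GLY", "VAL", "ALA"])
    spec = DesignSpec(
        positions=[("A", 2), ("A", 4)],
        allowed={("A", 2): {"SER"}, ("A", 4): {"VAL"}},
    )
    return build_molecular_instance(structure, spec, lib, EnergyWeights())


class TestMolecularModel:
    def test_pair_symmetric_in_arguments(self, molecular_toy):
        model = molecular_toy.model
        d = np.array([3.0])
        e_ij = model.pair(0, 1, d, 1, 0, -d)
        e_ji = model.pair(1, 0, -d, 0, 1, d)
        assert e_ij == e_ji

    def test_intra_deterministic(self, molecular_toy):
        model = molecular_toy.model
        d = np.array([2.0])
        assert model.intra(0, 0, d) == model.intra(0, 0, d)

    def test_decomposition_matches_direct_all_atom_sum(self, molecular_toy):
        """Template + singles + pairs equals one direct evaluation over all
        atoms of the assembled conformation (tolerance 1e-6 kcal/mol)."""
        from voxeldee.energy import vdw_pair as vdw, coulomb_pair as coul
        from voxeldee.energy import solvation_pair as solv

        inst = molecular_toy
        model = inst.model
        w = model.weights
        conf = (0, 0)
        m = compute_rigid_matrix(inst)
        decomposed = total_rigid_energy(conf, m)

        # assemble every atom of the full conformation, tagged by residue
        groups = []  # (residue_index, resname, [atoms])
        design = dict(zip(model.design_indices, range(len(model.design_indices))))
        for idx, res in enumerate(model.structure.residues):
            if idx in design:
                pos = design[idx]
                rot = inst.rotamers[pos][conf[pos]]
                sc = model._build(pos, conf[pos], np.zeros(1))
                bb = [a for a in res.atoms if a.name in _BACKBONE_NAMES]
                groups.append((idx, rot.amino_acid, bb + sc))
            else:
                groups.append((idx, res.resname, list(res.atoms)))

        direct = 0.0
        flat = [(idx, rn, a) for idx, rn, atoms in groups for a in atoms]
        for k, (ri, rn_i, a) in enumerate(flat):
            for rj, rn_j, b in flat[k + 1:]:
                if ri == rj:
                    if bond_separation(rn_i, a.name, b.name) < 3:
                        continue
                elif abs(ri - rj) == 1:
                    first, second = (a, b) if ri < rj else (b, a)
                    if (first.name, second.name) in {
                        ("C", "N"), ("C", "CA"), ("C", "H"), ("O", "N"), ("CA", "N"),
                    }:
                        continue
                direct += w.vdw_weight * vdw(a, b, w.radius_scale, w.clash_cap)
                direct += coul(a, b, w.dielectric, w.clash_cap)
                direct += solv(a, b, w.solvation_weight)
        direct += w.solvation_weight * sum(a.dg_ref for _, _, a in flat)
        assert decomposed == pytest.approx(direct, abs=1e-6)

    def test_weights_validation(self):
        with pytest.raises(ValueError):
            EnergyWeights(dielectric=-1.0)
        with pytest.raises(ValueError):
            EnergyWeights(radius_scale=1.5)
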