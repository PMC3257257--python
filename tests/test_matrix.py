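"""Energy-matrix precomputation, voxel bounds, conformation minimization."""

import numpy as np
import pytest

from voxeldee import (
    compute_bounds,
    compute_rigid_matrix,
    generate_instance,
    minimize_conformation,
    total_rigid_energy,
)
from voxeldee.matrix import BoundsConfig, load_matrix, save_matrix
from voxeldee.synthetic import oracle_conformation_min

from conftest import box_instance


def const(v):
    return lambda x, *rest: np.full_like(np.asarray(x, dtype=float), v)


@pytest.fixture(scope="module")
def coupled_instance():
    return generate_instance(31, n_positions=3, rotamers_per_position=3,
                             coupling_strength=0.6)


class TestRigidMatrix:
    def test_constant_model_fills_constant(self):
        inst = box_instance(
            2, 2,
            intra_fns={(i, r): const(1.5) for i in range(2) for r in range(2)},
            pair_fns={(0, r, 1, s): const(-0.25) for r in range(2) for s in range(2)},
            template=2.0,
        )
        m = compute_rigid_matrix(inst)
        assert m.template == 2.0
        for i in range(2):
            assert np.allclose(m.single_rigid[i], 1.5)
        assert np.allclose(m.pair_rigid[(0, 1)], -0.25)
        # bounds fields start equal to the rigid values
        assert np.allclose(m.single_lo[0], m.single_rigid[0])

    def test_matrix_matches_direct_model_evaluation(self, coupled_instance):
        inst = coupled_instance
        m = compute_rigid_matrix(inst)
        model = inst.model
        z = np.zeros((1, 1))
        for i in range(inst.n_positions):
            for r in range(inst.n_rotamers(i)):
                assert m.single_rigid[i][r] == pytest.approx(
                    float(model.intra(i, r, z)[0])
                )
        assert m.pair_rigid_entry(2, 1, 0, 1) == pytest.approx(
            float(model.pair(0, 1, z, 2, 1, z)[0])
        )

    def test_entry_counts(self, coupled_instance):
        m = compute_rigid_matrix(coupled_instance)
        assert sum(s.size for s in m.single_rigid) == 9
        assert sum(b.size for b in m.pair_rigid.values()) == 27


class TestBounds:
    def test_separable_quadratic_pair_has_zero_lower_bound(self):
        inst = box_instance(
            2, 1,
            intra_fns={(0, 0): const(0.0), (1, 0): const(0.0)},
            pair_fns={(0, 0, 1, 0): lambda x, y: (x - 3.0) ** 2 + (y + 4.0) ** 2},
        )
        m = compute_bounds(compute_rigid_matrix(inst), inst, with_upper=True)
        assert m.pair_lo[(0, 1)][0, 0] == pytest.approx(0.0, abs=1e-8)

    def test_difference_quadratic_corner_bounds(self):
        # (x - y)^2 on [-9, 9]^2: minimum 0 on the diagonal, maximum 324
        inst = box_instance(
            2, 1,
            intra_fns={(0, 0): const(0.0), (1, 0): const(0.0)},
            pair_fns={(0, 0, 1, 0): lambda x, y: (x - y) ** 2},
        )
        m = compute_bounds(compute_rigid_matrix(inst), inst, with_upper=True)
        assert m.pair_lo[(0, 1)][0, 0] == pytest.approx(0.0, abs=1e-8)
        assert m.pair_up[(0, 1)][0, 0] == pytest.approx(324.0, abs=1e-6)

    def test_lower_never_exceeds_rigid(self, coupled_instance):
        m = compute_bounds(
            compute_rigid_matrix(coupled_instance), coupled_instance,
            with_upper=True,
        )
        for i in range(m.n_positions):
            assert np.all(m.single_lo[i] <= m.single_rigid[i] + 1e-12)
            assert np.all(m.single_up[i] >= m.single_rigid[i] - 1e-12)
        for k in m.pair_rigid:
            assert np.all(m.pair_lo[k] <= m.pair_rigid[k] + 1e-12)
            assert np.all(m.pair_up[k] >= m.pair_rigid[k] - 1e-12)

    def test_sandwich_property(self, coupled_instance):
        """Sum of lower bounds <= minimized energy <= sum of upper bounds."""
        inst = coupled_instance
        m = compute_bounds(compute_rigid_matrix(inst), inst, with_upper=True)
        rng = np.random.default_rng(5)
        for _ in range(6):
            conf = tuple(rng.integers(0, inst.n_rotamers(i))
                         for i in range(inst.n_positions))
            e_t, _ = minimize_conformation(inst, conf)
            lo = m.template + sum(m.single_lo[i][conf[i]] for i in range(3))
            up = m.template + sum(m.single_up[i][conf[i]] for i in range(3))
            for (i, j) in m.pair_lo:
                lo += m.pair_lo[(i, j)][conf[i], conf[j]]
                up += m.pair_up[(i, j)][conf[i], conf[j]]
            assert lo - 1e-8 <= e_t <= up + 1e-8

    def test_bounds_monotone_in_voxel_size(self):
        wide = generate_instance(11, 3, 3, 0.6, half_width=9.0)
        narrow = generate_instance(11, 3, 3, 0.6, half_width=5.0)
        mw = compute_bounds(compute_rigid_matrix(wide), wide, with_upper=True)
        mn = compute_bounds(compute_rigid_matrix(narrow), narrow, with_upper=True)
        for i in range(3):
            assert np.all(mw.single_lo[i] <= mn.single_lo[i] + 1e-9)
            assert np.all(mw.single_up[i] >= mn.single_up[i] - 1e-9)
        for k in mw.pair_lo:
            assert np.all(mw.pair_lo[k] <= mn.pair_lo[k] + 1e-9)
            assert np.all(mw.pair_up[k] >= mn.pair_up[k] - 1e-9)

    def test_deterministic_given_seed(self, coupled_instance):
        cfg = BoundsConfig(seed=3)
        m1 = compute_bounds(compute_rigid_matrix(coupled_instance),
                            coupled_instance, cfg, with_upper=True)
        m2 = compute_bounds(compute_rigid_matrix(coupled_instance),
                            coupled_instance, cfg, with_upper=True)
        for i in range(3):
            assert np.array_equal(m1.single_lo[i], m2.single_lo[i])
        for k in m1.pair_lo:
            assert np.array_equal(m1.pair_lo[k], m2.pair_lo[k])


class TestMinimizeConformation:
    def test_separable_equals_sum_of_independent_minima(self):
        inst = generate_instance(21, 3, 3, coupling_strength=0.0)
        model = inst.model
        conf = (1, 0, 2)
        expected = model.template_energy()
        axis = np.linspace(-9.0, 9.0, 3601)[:, None]
        for i, r in enumerate(conf):
            expected += float(np.min(model.intra(i, r, axis)))
        z = np.zeros((1, 1))
        for (i, j) in ((0, 1), (0, 2), (1, 2)):
            expected += float(model.pair(i, conf[i], z, j, conf[j], z)[0])
        e, deltas = minimize_conformation(inst, conf)
        assert e == pytest.approx(expected, abs=1e-6)
        for i, d in enumerate(deltas):
            assert np.all(np.abs(d) <= 9.0 + 1e-9)

    def test_never_exceeds_rigid_energy(self, coupled_instance):
        inst = coupled_instance
        m = compute_rigid_matrix(inst)
        rng = np.random.default_rng(9)
        for _ in range(5):
            conf = tuple(rng.integers(0, 3) for _ in range(3))
            e, _ = minimize_conformation(inst, conf)
            assert e <= total_rigid_energy(conf, m) + 1e-9

    def test_matches_joint_grid_oracle_on_coupled_landscape(self, coupled_instance):
        inst = coupled_instance
        for conf in ((0, 0, 0), (2, 1, 0), (1, 2, 2)):
            ours, _ = minimize_conformation(inst, conf)
            oracle = oracle_conformation_min(inst, conf, grid_step=1.0)
            assert ours == pytest.approx(oracle, abs=1e-5)


class TestSerialization:
    def test_roundtrip_bit_exact(self, coupled_instance, tmp_path):
        m = compute_bounds(
            compute_rigid_matrix(coupled_instance), coupled_instance,
            with_upper=True,
        )
        path = tmp_path / "matrix.vxm"
        save_matrix(m, path)
        m2 = load_matrix(path)
        assert m2.template == m.template
        assert m2.rotamer_ids == m.rotamer_ids
        for i in range(m.n_positions):
            assert np.array_equal(m.single_rigid[i], m2.single_rigid[i])
            assert np.array_equal(m.single_lo[i], m2.single_lo[i])
            assert np.array_equal(m.single_up[i], m2.single_up[i])
        for k in m.pair_rigid:
            assert np.array_equal(m.pair_rigid[k], m2.pair_rigid[k])
            assert np.array_equal(m.pair_lo[k], m2.pair_lo[k])
            assert np.array_equal(m.pair_up[k], m2.pair_up[k])

    def test_zero_width_copy_collapses_bounds(self, coupled_instance):
        m = compute_bounds(
            compute_rigid_matrix(coupled_instance), coupled_instance,
            with_upper=True,
        )
        z = m.zero_width()
        for i in range(z.n_positions):
            assert np.array_equal(z.single_lo[i], z.single_rigid[i])
            assert np.array_equal(z.single_up[i], z.single_rigid[i])
        for k in z.pair_rigid:
            assert np.array_equal(z.pair_lo[k], z.pair_rigid[k])
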