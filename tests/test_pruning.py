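"""Pruning criteria: steric filter, Goldstein singles/pairs, split flags,
bounds pruning, fixpoint iteration, and the provable-soundness guarantees."""

import itertools
import math

import numpy as np
import pytest

from voxeldee import (
    brute_force,
    generate_instance,
    prepare_matrix,
    total_rigid_energy,
)
from voxeldee.pruning import (
    PruneConfig,
    PruningState,
    bounds_prune,
    goldstein_imindee,
    goldstein_mindee,
    goldstein_rigid,
    pairs_flag,
    prune_to_fixpoint,
    steric_filter,
)

from conftest import make_matrix


def _oracle_interval(instance, matrix, oracle):
    """A provably valid interval: E_T(minGMEC) minus the lowest bound."""
    counts = [instance.n_rotamers(i) for i in range(instance.n_positions)]
    lbs = []
    for conf in itertools.product(*(range(c) for c in counts)):
        e = matrix.template + sum(
            matrix.single_lo[i][conf[i]] for i in range(len(conf))
        )
        for (i, j) in matrix.pair_lo:
            e += matrix.pair_lo[(i, j)][conf[i], conf[j]]
        lbs.append(e)
    return max(oracle.mingmec_energy - min(lbs), 0.0)


class TestStericFilter:
    def test_infinite_threshold_prunes_nothing(self):
        m = make_matrix([[50.0, 2.0]], {})
        state = steric_filter(m, math.inf)
        assert state.unpruned(0) == [0, 1]

    def test_high_lower_bound_pruned(self):
        m = make_matrix([[50.0, 2.0]], {})
        state = steric_filter(m, 30.0)
        assert state.unpruned(0) == [1]

    def test_rigid_clash_that_can_minimize_away_survives(self):
        # rigid 80, but the voxel minimum is 5: keep it
        m = make_matrix([[80.0]], {}, lo_singles=[[5.0]])
        state = steric_filter(m, 30.0)
        assert state.unpruned(0) == [0]


class TestGoldsteinRigid:
    def test_tie_never_prunes(self):
        m = make_matrix([[1.0, 1.0], [0.0, 0.0]], {(0, 1): [[0, 0], [0, 0]]})
        state = PruningState.fresh(m)
        goldstein_rigid(m, state, 0)
        assert state.unpruned(0) == [0, 1]

    def test_dominated_rotamer_pruned_and_brute_force_agrees(self):
        m = make_matrix([[0.0, 5.0], [1.0, 2.0]], {(0, 1): [[0, 0], [0, 0]]})
        state = PruningState.fresh(m)
        before = state.surviving_conformations()
        goldstein_rigid(m, state, 0)
        assert state.pruned[0] == {1}
        assert state.surviving_conformations() == before // 2
        # exhaustive check: no optimal conformation uses the pruned rotamer
        energies = {
            conf: total_rigid_energy(conf, m)
            for conf in itertools.product(range(2), range(2))
        }
        best = min(energies, key=energies.get)
        assert best[0] != 1

    def test_pair_terms_can_protect_a_rotamer(self):
        # rotamer 1 is worse alone but rescued by a strong pair interaction
        m = make_matrix(
            [[0.0, 2.0], [0.0, 0.0]],
            {(0, 1): [[0.0, 0.0], [-5.0, 0.0]]},
        )
        state = PruningState.fresh(m)
        goldstein_rigid(m, state, 0)
        assert state.unpruned(0) == [0, 1]


class TestGoldsteinMinDee:
    def test_zero_width_reduces_to_rigid(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            singles = [list(rng.uniform(0, 5, 3)) for _ in range(2)]
            pairs = {(0, 1): rng.uniform(-2, 2, (3, 3)).tolist()}
            m = make_matrix(singles, pairs)  # lo == up == rigid
            s_rigid = PruningState.fresh(m)
            s_min = PruningState.fresh(m)
            for i in range(2):
                goldstein_rigid(m, s_rigid, i)
                goldstein_mindee(m, s_min, i)
            assert s_rigid.pruned == s_min.pruned

    def test_range_terms_block_pruning(self):
        # candidate trails by 4 in bounds, but ranges sum to 6: keep it
        m = make_matrix(
            [[4.0, 0.0], [0.0, 0.0], [0.0, 0.0]],
            {k: [[0.0, 0.0], [0.0, 0.0]] for k in ((0, 1), (0, 2), (1, 2))},
            up_singles=[[4.0, 0.0], [3.0, 3.0], [3.0, 3.0]],
        )
        state = PruningState.fresh(m)
        goldstein_mindee(m, state, 0)
        assert state.unpruned(0) == [0, 1]

    def test_missing_upper_bounds_rejected(self):
        m = make_matrix([[0.0, 1.0]], {})
        m.single_up = None
        m.pair_up = None
        state = PruningState.fresh(m)
        with pytest.raises(ValueError, match="upper bounds"):
            goldstein_mindee(m, state, 0)


class TestGoldsteinIMinDee:
    def test_infinite_interval_prunes_nothing(self):
        m = make_matrix([[0.0, 50.0]], {})
        state = PruningState.fresh(m)
        goldstein_imindee(m, state, 0, math.inf)
        assert state.unpruned(0) == [0, 1]

    def test_interval_thresholds_decision(self):
        # lower-bound disadvantage of exactly 5
        m = make_matrix([[0.0, 5.0]], {})
        s1 = PruningState.fresh(m)
        goldstein_imindee(m, s1, 0, 1.0)
        assert s1.pruned[0] == {1}
        s2 = PruningState.fresh(m)
        goldstein_imindee(m, s2, 0, 6.0)
        assert s2.pruned[0] == set()

    def test_negative_interval_rejected(self):
        m = make_matrix([[0.0, 1.0]], {})
        with pytest.raises(ValueError):
            goldstein_imindee(m, PruningState.fresh(m), 0, -0.1)

    def test_pruned_count_monotone_in_interval(self):
        for seed in (101, 102, 103):
            inst = generate_instance(seed, 4, 3, 0.5)
            m = prepare_matrix(inst, with_upper=False)
            counts = []
            for interval in (0.0, 0.25, 0.5, 1.0, 2.0):
                state = PruningState.fresh(m)
                for i in range(4):
                    goldstein_imindee(m, state, i, interval)
                counts.append(sum(len(p) for p in state.pruned))
            assert counts == sorted(counts, reverse=True)


class TestPairsFlag:
    def test_identical_pairs_not_flagged(self):
        m = make_matrix(
            [[0.0, 0.0], [0.0, 0.0], [0.0, 0.0]],
            {k: [[0.0, 0.0], [0.0, 0.0]] for k in ((0, 1), (0, 2), (1, 2))},
        )
        state = pairs_flag(m, PruningState.fresh(m), "rigid")
        assert state.flagged == set()

    def test_dominated_pair_flagged_and_optimum_avoids_it(self):
        pairs = {
            (0, 1): [[0.0, 5.0], [0.0, 5.0]],
            (0, 2): [[0.0, 0.0], [0.0, 0.0]],
            (1, 2): [[0.0, 0.0], [0.0, 0.0]],
        }
        m = make_matrix([[0.0, 0.0]] * 3, pairs)
        state = pairs_flag(m, PruningState.fresh(m), "rigid")
        assert (((0, 0), (1, 1)) in state.flagged
                and ((0, 1), (1, 1)) in state.flagged)
        energies = {
            conf: total_rigid_energy(conf, m)
            for conf in itertools.product(*(range(2),) * 3)
        }
        best = min(energies, key=energies.get)
        assert ((0, best[0]), (1, best[1])) not in state.flagged


class TestBoundsPrune:
    def test_unknown_best_energy_prunes_nothing(self):
        m = make_matrix([[0.0, 100.0], [0.0, 0.0]], {(0, 1): [[0, 0], [0, 0]]})
        state = bounds_prune(m, PruningState.fresh(m), "rigid", math.inf)
        assert state.unpruned(0) == [0, 1]

    def test_optimistic_bound_above_best_known_pruned(self):
        # rotamer (0,1): best completion 12 > best known 10
        m = make_matrix([[0.0, 12.0], [0.0, 1.0]], {(0, 1): [[0, 0], [0, 0]]})
        state = bounds_prune(m, PruningState.fresh(m), "rigid", 10.0)
        assert state.pruned[0] == {1}
        assert state.pruned[1] == set()

    def test_interval_slack_in_imindee_mode(self):
        m = make_matrix([[0.0, 12.0], [0.0, 1.0]], {(0, 1): [[0, 0], [0, 0]]})
        state = bounds_prune(m, PruningState.fresh(m), "imindee", 10.0, 3.0)
        assert state.pruned[0] == set()  # 12 <= 10 + 3

    def test_never_prunes_oracle_optimum(self):
        for seed in (201, 202):
            inst = generate_instance(seed, 3, 3, 0.6)
            m = prepare_matrix(inst, with_upper=False)
            oracle = brute_force(inst)
            state = bounds_prune(
                m, PruningState.fresh(m), "imindee",
                oracle.mingmec_energy, _oracle_interval(inst, m, oracle),
            )
            for i, r in enumerate(oracle.mingmec):
                assert not state.is_pruned(i, r)


class TestFixpoint:
    def test_idempotent_at_fixpoint(self):
        inst = generate_instance(55, 3, 3, 0.5)
        m = prepare_matrix(inst, with_upper=True)
        s1 = prune_to_fixpoint(m, "rigid")
        # a second full run from the first run's surviving space changes nothing
        s2 = prune_to_fixpoint(m, "rigid")
        assert s1.pruned == s2.pruned
        assert s1.flagged == s2.flagged

    def test_cascading_prunes_across_positions(self):
        # position 1 rotamer b is protected only by position 0 rotamer b;
        # once 0b is pruned, 1b becomes dominated in the next cycle
        m = make_matrix(
            [[0.0, 3.0], [0.0, 2.0]],
            {(0, 1): [[0.0, 0.0], [0.0, -2.5]]},
        )
        state = prune_to_fixpoint(m, "rigid", config=PruneConfig(
            use_pairs=False, use_split=False, use_bounds=False))
        assert state.pruned[0] == {1}
        assert state.pruned[1] == {1}
        # exhaustive confirmation that the GMEC survives
        energies = {
            conf: total_rigid_energy(conf, m)
            for conf in itertools.product(range(2), range(2))
        }
        best = min(energies, key=energies.get)
        assert best == (0, 0)

    def test_gmec_survives_on_synthetic_instance(self):
        inst = generate_instance(77, 4, 3, 0.5)
        m = prepare_matrix(inst, with_upper=True)
        oracle = brute_force(inst)
        state = prune_to_fixpoint(m, "rigid")
        for i, r in enumerate(oracle.rigid_gmec):
            assert not state.is_pruned(i, r)

    def test_infeasible_state_reported_not_raised(self):
        m = make_matrix([[50.0, 60.0], [0.0, 0.0]], {(0, 1): [[0, 0], [0, 0]]})
        state = prune_to_fixpoint(m, "rigid", config=PruneConfig(
            steric_threshold=30.0))
        assert state.infeasible
        assert state.surviving_conformations() == 0


class TestSoundness:
    """The central guarantee: no criterion removes the optimum."""

    SEEDS = range(300, 325)

    def test_rigid_modes_never_prune_the_rigid_gmec(self):
        for seed in self.SEEDS:
            inst = generate_instance(seed, 3, 3, 0.5)
            m = prepare_matrix(inst, with_upper=True)
            oracle = brute_force(inst)
            state = prune_to_fixpoint(m, "rigid")
            g = oracle.rigid_gmec
            for i, r in enumerate(g):
                assert not state.is_pruned(i, r), f"seed {seed}"
            for i in range(3):
                for j in range(i + 1, 3):
                    assert not state.is_flagged(i, g[i], j, g[j]), f"seed {seed}"

    def test_min_modes_never_prune_the_mingmec(self):
        for seed in self.SEEDS:
            inst = generate_instance(seed, 3, 3, 0.5)
            m = prepare_matrix(inst, with_upper=True)
            oracle = brute_force(inst)
            interval = _oracle_interval(inst, m, oracle)
            for mode, I in (("mindee", 0.0), ("imindee", interval)):
                state = prune_to_fixpoint(
                    m, mode, I, PruneConfig(best_known_energy=oracle.mingmec_energy),
                )
                g = oracle.mingmec
                for i, r in enumerate(g):
                    assert not state.is_pruned(i, r), f"{mode} seed {seed}"
                for i in range(3):
                    for j in range(i + 1, 3):
                        assert not state.is_flagged(i, g[i], j, g[j]), (
                            f"{mode} seed {seed}"
                        )

    def test_imindee_prunes_at_least_as_much_as_mindee(self):
        wins = 0
        for seed in range(400, 410):
            inst = generate_instance(seed, 4, 3, 0.6)
            m = prepare_matrix(inst, with_upper=True)
            s_md = prune_to_fixpoint(m, "mindee")
            s_im = prune_to_fixpoint(m, "imindee", 0.5)
            wins += s_im.pruned_fraction() >= s_md.pruned_fraction()
        assert wins >= 8  # empirical ordering, not a theorem instance-by-instance
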