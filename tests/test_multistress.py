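import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import binom

from stressim import (
    ModelParameters,
    MultiState,
    StressSchedule,
    build_space,
    fitness_vector,
    initial_state,
    multiresistance_frequencies,
    multistress_derivative,
    mutation_rate_matrix,
    no_stress_derivative,
    run_cycles,
    simulate_schedule,
    stress_derivative,
)
from stressim.model_core import mutation_matrix


def state_vectors(n):
    return (
        st.lists(st.floats(1e-6, 1.0), min_size=n, max_size=n)
        .map(lambda xs: np.array(xs) / np.sum(xs))
    )


class TestGenotypeSpace:
    def test_single_stress_space_matches_two_locus_model(self):
        space = build_space(1)
        assert space.n_genotypes == 4
        assert [space.label(g) for g in range(4)] == ["mr", "Mr", "mR", "MR"]

    @pytest.mark.parametrize("chi,expected", [(1, 4), (2, 8), (4, 32)])
    def test_genotype_count(self, chi, expected):
        assert build_space(chi).n_genotypes == expected

    def test_each_genotype_has_one_neighbor_per_locus(self):
        space = build_space(3)
        for g in range(space.n_genotypes):
            neighbors = {g ^ (1 << b) for b in range(space.chi + 1)}
            assert len(neighbors) == space.chi + 1

    def test_oversized_space_rejected(self):
        with pytest.raises(ValueError):
            build_space(13)
        with pytest.raises(ValueError):
            build_space(0)


class TestFitness:
    def test_no_stress_is_neutral(self):
        space = build_space(4)
        np.testing.assert_array_equal(
            fitness_vector(space, frozenset(), 0.5), np.ones(32)
        )

    def test_additive_over_active_stresses(self):
        space = build_space(4)
        w = fitness_vector(space, {1, 2, 3, 4}, 0.5)
        fully_resistant_m = 0b11110  # all four R bits, no SIM
        assert w[fully_resistant_m] == pytest.approx(3.0)

    def test_independent_of_sim_bit(self):
        space = build_space(3)
        w = fitness_vector(space, {1, 3}, 0.7)
        for g in range(0, space.n_genotypes, 2):
            assert w[g] == w[g | 1]

    def test_no_cross_resistance(self):
        space = build_space(2)
        w = fitness_vector(space, {1}, 1.0)
        only_r2 = 0b100
        assert w[only_r2] == 1.0  # resistance to stress 2 is useless under stress 1


class TestMutationMatrix:
    def test_reduces_to_two_locus_matrices(self, reference_params):
        space = build_space(1)
        np.testing.assert_allclose(
            mutation_rate_matrix(space, reference_params, frozenset()),
            mutation_matrix(reference_params, stress=False),
            atol=1e-18,
        )
        np.testing.assert_allclose(
            mutation_rate_matrix(space, reference_params, {1}),
            mutation_matrix(reference_params, stress=True),
            atol=1e-18,
        )

    def test_no_amplification_without_stress(self, reference_params):
        space = build_space(3)
        Q = mutation_rate_matrix(space, reference_params, frozenset())
        # the mutator's SIM-loss rate stays mu_M for every background
        for g in range(1, space.n_genotypes, 2):
            assert Q[g ^ 1, g] == pytest.approx(reference_params.mu_M)

    def test_fully_resistant_mutator_not_amplified(self, reference_params):
        space = build_space(2)
        g = 0b111  # M + resistant to both stresses
        Q = mutation_rate_matrix(space, reference_params, {1, 2})
        assert Q[g ^ 1, g] == pytest.approx(reference_params.mu_M)

    def test_susceptible_mutator_amplified_at_all_loci(self, reference_params):
        space = build_space(2)
        g = 0b011  # M + resistant to stress 1, susceptible to stress 2
        Q = mutation_rate_matrix(space, reference_params, {2})
        sigma = reference_params.sigma
        assert Q[g ^ 1, g] == pytest.approx(sigma * reference_params.mu_M)
        assert Q[g ^ 0b010, g] == pytest.approx(sigma * reference_params.mu_R)
        assert Q[g ^ 0b100, g] == pytest.approx(sigma * reference_params.nu_R)

    def test_support_is_single_bit_neighbors(self, reference_params):
        space = build_space(3)
        Q = mutation_rate_matrix(space, reference_params, {1})
        for g in range(space.n_genotypes):
            for h in range(space.n_genotypes):
                if h != g and bin(g ^ h).count("1") != 1:
                    assert Q[h, g] == 0.0

    def test_columns_conserve_frequency(self, reference_params):
        space = build_space(3)
        for active in (frozenset(), {1}, {1, 2, 3}):
            Q = mutation_rate_matrix(space, reference_params, active)
            np.testing.assert_allclose(Q.sum(axis=0), 0.0, atol=1e-15)


class TestDerivative:
    @given(p=state_vectors(4))
    def test_single_stress_engine_matches_hand_coded_flows(self, p):
        params = ModelParameters(s=1.0, sigma=100.0, mu_M=1e-3, mu_R=1e-2, nu_R=1e-4)
        space = build_space(1)
        state = MultiState(frequencies=p)
        np.testing.assert_allclose(
            multistress_derivative(state, space, params, frozenset()),
            no_stress_derivative(p, params),
            atol=1e-14,
        )
        np.testing.assert_allclose(
            multistress_derivative(state, space, params, {1}),
            stress_derivative(p, params),
            atol=1e-14,
        )

    @given(p=state_vectors(16))
    def test_conservation(self, p):
        params = ModelParameters(s=0.5, sigma=100.0, mu_M=1e-3, mu_R=5e-3, nu_R=1e-4)
        space = build_space(3)
        d = multistress_derivative(MultiState(frequencies=p), space, params, {1, 2})
        assert abs(d.sum()) < 1e-13

    def test_uniform_neutral_state_is_stationary(self):
        params = ModelParameters(s=1e-12, sigma=2.0, mu_M=1e-13, mu_R=1e-13, nu_R=1e-13)
        space = build_space(2)
        p = np.full(8, 1.0 / 8)
        d = multistress_derivative(MultiState(frequencies=p), space, params, frozenset())
        np.testing.assert_allclose(d, 0.0, atol=1e-12)


class TestMultiresistance:
    def test_product_state_classes_are_binomial(self, reference_params):
        space = build_space(4)
        state = initial_state(space, reference_params)
        classes = multiresistance_frequencies(state, space)
        expected = binom.pmf(np.arange(5), 4, reference_params.epsilon)
        np.testing.assert_allclose(classes, expected, atol=1e-12)
        assert classes.sum() == pytest.approx(1.0, abs=1e-12)

    def test_all_susceptible_population(self, reference_params):
        space = build_space(3)
        p = np.zeros(16)
        p[0] = 1.0
        classes = multiresistance_frequencies(MultiState(frequencies=p), space)
        np.testing.assert_allclose(classes, [1.0, 0, 0, 0])


class TestSchedules:
    def test_randomized_schedule_is_seed_deterministic(self):
        a = StressSchedule.randomized(3, 10.0, 90.0, seed=7, n_iterations=50)
        b = StressSchedule.randomized(3, 10.0, 90.0, seed=7, n_iterations=50)
        c = StressSchedule.randomized(3, 10.0, 90.0, seed=8, n_iterations=50)
        assert a.phases == b.phases
        assert a.phases != c.phases

    def test_strategy_constructors_cover_all_stresses_in_tau(self):
        sequential = StressSchedule.sequential(4, 10.0, 400.0)
        assert len(sequential.phases) == 4
        assert sum(ts + tn for _, ts, tn in sequential.phases) == pytest.approx(400.0)
        paired = StressSchedule.paired(4, 10.0, 400.0)
        assert len(paired.phases) == 2
        assert paired.phases[0][0] == frozenset({1, 2})
        combined = StressSchedule.combined(4, 10.0, 400.0)
        assert combined.phases[0][0] == frozenset({1, 2, 3, 4})
        assert sum(ts + tn for _, ts, tn in combined.phases) == pytest.approx(400.0)

    def test_invalid_schedules_rejected(self):
        with pytest.raises(ValueError):
            StressSchedule.combined(4, 10.0, 5.0)
        with pytest.raises(ValueError):
            StressSchedule.paired(3, 10.0, 400.0)
        with pytest.raises(ValueError):
            StressSchedule(phases=((frozenset(), 10.0, 90.0),))


class TestSimulateSchedule:
    def test_single_stress_cycle_reduces_to_two_locus_recurrent(self, reference_params):
        space = build_space(1)
        sched = StressSchedule.cyclic(1, 10.0, 90.0)
        multi = simulate_schedule(space, reference_params, sched, max_supercycles=30,
                                  convergence_tol=0.0)
        two_locus = run_cycles(None, reference_params, "R", max_cycles=30,
                               convergence_tol=0.0)
        np.testing.assert_allclose(
            multi.history[:30], [h[0] for h in two_locus.history[:30]], atol=1e-10
        )

    def test_stress_relabeling_leaves_trajectory_unchanged(self, reference_params):
        space = build_space(3)
        base = StressSchedule.cyclic(3, 10.0, 190.0)
        relabeled = StressSchedule(
            phases=tuple((frozenset({(i % 3) + 1}), ts, tn)
                         for (a, ts, tn), i in zip(base.phases, [1, 2, 0])),
            mode="cyclic",
        )
        res_a = simulate_schedule(space, reference_params, base, max_supercycles=10,
                                  convergence_tol=0.0)
        res_b = simulate_schedule(space, reference_params, relabeled, max_supercycles=10,
                                  convergence_tol=0.0)
        np.testing.assert_allclose(res_a.history, res_b.history, atol=1e-12)

    def test_randomized_run_has_fixed_length_and_tail_summary(self, reference_params):
        space = build_space(2)
        sched = StressSchedule.randomized(2, 10.0, 90.0, seed=1, n_iterations=40)
        res = simulate_schedule(space, reference_params, sched, n_last=10)
        assert len(res.history) == 40
        tail = np.array(res.history[-10:])
        assert res.mean == pytest.approx(tail.mean())
        assert res.sd == pytest.approx(tail.std(ddof=0))

    def test_trajectory_recording_schema(self, reference_params):
        space = build_space(2)
        sched = StressSchedule.cyclic(2, 10.0, 90.0)
        res = simulate_schedule(space, reference_params, sched, max_supercycles=2,
                                convergence_tol=0.0, record_trajectory=True)
        assert len(res.trajectory) == 4  # 2 supercycles x 2 phases
        row = res.trajectory[0]
        for key in ("supercycle", "phase_index", "active_stresses", "p_M",
                    "p_R_1", "p_R_2", "multiresistance_0", "multiresistance_2"):
            assert key in row
        multi_sum = sum(row[f"multiresistance_{k}"] for k in range(3))
        assert multi_sum == pytest.approx(1.0, abs=1e-9)
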