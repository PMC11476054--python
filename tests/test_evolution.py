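"""Selection, mutation, the generational loop, and whole-run determinism."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest

from plastevo import (ModelParams, StateError, compute_fitness, mutate,
                      mutate_population, run_simulation, select_parent,
                      step_generation)

from oracle import naive_run_simulation


class TestSelectParent:
    def test_empty_population_rejected(self, rng):
        with pytest.raises(StateError):
            select_parent(np.array([], dtype=int), rng)

    def test_equal_fitness_is_uniform(self, rng):
        fitness = np.array([3, 3, 3, 3])
        counts = Counter(select_parent(fitness, rng) for _ in range(8000))
        for i in range(4):
            assert abs(counts[i] / 8000 - 0.25) < 3 * np.sqrt(0.25 * 0.75 / 8000)

    def test_zero_fitness_never_selected_against_positive(self, rng):
        fitness = np.array([0, 5])
        assert all(select_parent(fitness, rng) == 1 for _ in range(200))

    def test_all_zero_fitness_falls_back_to_uniform(self, rng):
        fitness = np.zeros(5, dtype=int)
        seen = {select_parent(fitness, rng) for _ in range(300)}
        assert seen == set(range(5))

    def test_marginal_law_proportional_to_fitness(self, rng):
        # fitness (1,2,3) -> marginal selection (1/6, 2/6, 3/6)
        fitness = np.array([1, 2, 3])
        n = 30_000
        counts = Counter(select_parent(fitness, rng) for _ in range(n))
        for i, p in enumerate([1 / 6, 2 / 6, 3 / 6]):
            se = np.sqrt(p * (1 - p) / n)
            assert abs(counts[i] / n - p) < 3 * se


class TestMutate:
    def test_mu_zero_is_identity(self, rng):
        p = ModelParams(N=2, L=50, A=4, P_e=25, C=5, mu=0.0, t=0)
        g = rng.integers(0, p.A, size=p.L)
        np.testing.assert_array_equal(mutate(g, p, rng), g)

    def test_mu_one_two_alleles_flips_everything(self, rng):
        p = ModelParams(N=2, L=50, A=2, P_e=25, C=5, mu=1.0, t=0)
        g = rng.integers(0, 2, size=p.L)
        np.testing.assert_array_equal(mutate(g, p, rng), 1 - g)

    def test_single_allele_is_noop(self, rng):
        p = ModelParams(N=2, L=30, A=1, P_e=10, C=5, mu=0.5, t=0)
        g = np.zeros(p.L, dtype=int)
        np.testing.assert_array_equal(mutate(g, p, rng), g)

    def test_mean_mutation_count_is_binomial(self, rng):
        p = ModelParams(N=2, L=400, A=5, P_e=200, C=10, mu=0.01, t=0)
        g = rng.integers(0, p.A, size=p.L)
        n = 3000
        changed = [(mutate(g, p, rng) != g).sum() for _ in range(n)]
        expect = p.mu * p.L  # = 4
        se = np.sqrt(p.L * p.mu * (1 - p.mu) / n)
        assert abs(np.mean(changed) - expect) < 3 * se

    def test_mutated_allele_never_equals_original(self, rng):
        p = ModelParams(N=2, L=200, A=3, P_e=100, C=10, mu=1.0, t=0)
        g = rng.integers(0, p.A, size=p.L)
        out = mutate(g, p, rng)
        assert (out != g).all()

    def test_population_path_row_major_protocol(self):
        p = ModelParams(N=3, L=20, A=4, P_e=20, C=5, mu=0.3, t=0)
        g = np.random.default_rng(0).integers(0, p.A, size=(p.N, p.L))
        a = mutate_population(g, p, np.random.default_rng(9))
        rng = np.random.default_rng(9)
        mask = rng.random((p.N, p.L)) < p.mu
        shifts = rng.integers(1, p.A, size=int(mask.sum()))
        expected = g.copy()
        pos = 0
        for i in range(p.N):
            for l in range(p.L):
                if mask[i, l]:
                    expected[i, l] = (expected[i, l] + shifts[pos]) % p.A
                    pos += 1
        np.testing.assert_array_equal(a, expected)


class TestGenerationLoop:
    def test_no_mutation_no_plasticity_creates_no_novel_genomes(self, rng):
        p = ModelParams(N=12, n_g=0, L=10, A=2, P_e=4, C=2, mu=0.0, t=0)
        run = run_simulation(p, seed=3)
        pop = run.final_state
        parents = {tuple(g) for g in pop.genomes}
        from plastevo import build_gp_map
        gp = build_gp_map(p, np.random.default_rng(1))
        nxt = step_generation(pop, gp, p, rng)
        for g in nxt.genomes:
            assert tuple(g) in parents

    def test_fitness_vector_matches_total_counts(self, rng):
        p = ModelParams(N=10, n_g=2, L=20, A=3, P_e=10, C=2, mu=0.1, t=1)
        pop = run_simulation(p, seed=11).final_state
        np.testing.assert_array_equal(compute_fitness(pop), pop.n_fs_total)
        assert (compute_fitness(pop) <= p.f).all()

    def test_max_fitness_cannot_rise_without_variation(self):
        # mu=0, t=0: no new genomes, so the best count can only drift down.
        p = ModelParams(N=30, n_g=60, L=20, A=2, P_e=10, C=2, mu=0.0, t=0)
        run = run_simulation(p, seed=21)
        traj = run.table["max_total"].to_numpy()
        assert traj.max() <= traj[0]

    def test_certain_plasticity_always_adds_a_system(self):
        p = ModelParams(N=15, n_g=3, L=24, A=2, P_e=12, C=3,
                        mu=0.05, p_e=1.0, t=1)
        pop = run_simulation(p, seed=5).final_state
        short = pop.n_fs_inherited < p.f
        assert (pop.n_fs_total[short] >= pop.n_fs_inherited[short] + 1).all()


class TestRunSimulation:
    def test_zero_generations_gives_initial_row_only(self):
        p = ModelParams(N=6, n_g=0, L=10, A=2, P_e=4, C=2, mu=0.1, t=1)
        run = run_simulation(p, seed=2)
        assert len(run.table) == 1
        assert run.table["generation"].iloc[0] == 0

    def test_same_seed_bit_identical(self):
        p = ModelParams(N=10, n_g=25, L=16, A=3, P_e=8, C=2,
                        mu=0.05, p_e=0.5, t=2)
        a = run_simulation(p, seed=42)
        b = run_simulation(p, seed=42)
        pd.testing.assert_frame_equal(a.table, b.table)
        np.testing.assert_array_equal(a.final_state.genomes,
                                      b.final_state.genomes)

    def test_trajectory_lengths_and_bounds(self):
        p = ModelParams(N=10, n_g=15, L=16, A=3, P_e=8, C=2, mu=0.05, t=1)
        run = run_simulation(p, seed=8)
        t = run.table
        assert len(t) == p.n_g + 1
        assert (t["max_inherited"] >= t["mean_inherited"] - 1e-12).all()
        assert (t["max_total"] >= t["max_inherited"]).all()
        assert (t["max_total"] <= p.f).all()

    @pytest.mark.parametrize("t", [0, 2])
    def test_matches_naive_reimplementation_run_for_run(self, t):
        # Library (vectorized) vs loop-based oracle under the shared RNG
        # protocol: identical trajectories and final genomes.
        p = ModelParams(N=20, n_g=30, L=12, A=2, P_e=6, C=3,
                        mu=0.05, p_e=0.5, t=t)
        run = run_simulation(p, seed=99)
        records, genomes = naive_run_simulation(p, seed=99)
        expected = pd.DataFrame(records, columns=run.table.columns)
        pd.testing.assert_frame_equal(run.table, expected, check_dtype=False)
        np.testing.assert_array_equal(run.final_state.genomes, genomes)
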