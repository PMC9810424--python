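"""Social-learning engine: initialisation, partition, selection, mutation."""

import numpy as np
import pytest

from colonygames import EnvironmentParams, LearningParams
from colonygames import engine as E
from colonygames.engine import (
    GamePartition,
    Population,
    RngStreams,
    compute_payoffs,
    cull_experiment,
    init_population,
    monomorphic,
    mutation_step,
    partition_games,
    project_to_simplex,
    recruitment_step,
    run,
    uniform_simplex,
)
from colonygames.payoffs import ConfigurationError, PartitionError
from tests.test_payoffs import scalar_payoff_oracle


def test_learning_params_divisibility():
    with pytest.raises(PartitionError):
        LearningParams(n=5, N=12)


class TestInitPopulation:
    def test_monomorphic(self, rng):
        p = LearningParams(N=10, T=10)
        pop = init_population(p, monomorphic(0.3, 0.7), rng)
        assert pop.traits.shape == (10, 2)
        assert np.all(pop.traits == [0.3, 0.7])
        assert np.allclose(pop.z, 0.0)

    def test_uniform_simplex_moments(self, rng):
        p = LearningParams(N=10_000, T=10)
        pop = init_population(p, uniform_simplex(), rng)
        # Dirichlet(1,1,1) has mean (1/3, 1/3, 1/3)
        assert np.allclose(pop.traits.mean(axis=0), [1 / 3, 1 / 3], atol=0.02)
        assert np.allclose(pop.z.mean(), 1 / 3, atol=0.02)

    def test_explicit_identity_and_length_check(self, rng):
        p = LearningParams(N=10, T=10)
        traits = [(0.05 * i, 0.04 * i) for i in range(10)]
        pop = init_population(p, E.explicit(traits), rng)
        assert np.allclose(pop.traits, traits)
        with pytest.raises(ConfigurationError):
            init_population(p, E.explicit(traits[:5]), rng)

    def test_submode_inits_stay_on_edge(self, rng):
        p = LearningParams(N=50, T=10)
        pop1 = init_population(p, uniform_simplex(), rng, mode="M1")
        assert np.all(pop1.traits[:, 0] == 0.0)
        pop2 = init_population(p, uniform_simplex(), rng, mode="M2")
        assert np.all(pop2.traits[:, 1] == 0.0)


class TestPartition:
    def test_cover_and_sizes(self, rng):
        p = LearningParams(N=10, T=10)
        pop = init_population(p, uniform_simplex(), rng)
        part = partition_games(pop, p, rng)
        assert part.groups.shape == (2, 5)
        assert sorted(part.groups.ravel()) == list(range(10))

    def test_deterministic_replay(self):
        p = LearningParams(N=20, T=10)
        pop = init_population(p, uniform_simplex(), np.random.default_rng(0))
        a = partition_games(pop, p, np.random.default_rng(42)).groups
        b = partition_games(pop, p, np.random.default_rng(42)).groups
        assert np.array_equal(a, b)

    def test_pair_frequency_matches_combinatorics(self, rng):
        # P(agents 0 and 1 share a group) = (n-1)/(N-1) = 4/9
        p = LearningParams(N=10, T=10)
        pop = init_population(p, uniform_simplex(), rng)
        hits = 0
        draws = 10_000
        for _ in range(draws):
            groups = partition_games(pop, p, rng).groups
            g0 = np.where(groups == 0)[0][0]
            hits += 1 in groups[g0]
        assert abs(hits / draws - 4 / 9) < 0.02

    def test_invalid_partition_rejected(self):
        with pytest.raises(PartitionError):
            GamePartition(np.array([[0, 1, 2, 3, 3]]))


class TestComputePayoffs:
    def test_monomorphic_equal(self, env_branching, rng):
        p = LearningParams(N=20, T=10)
        pop = init_population(p, monomorphic(0.2, 0.5), rng)
        part = partition_games(pop, p, rng)
        pays = compute_payoffs(pop, part, env_branching)
        assert np.allclose(pays, pays[0])

    def test_all_inactive_zero(self, env_branching, rng):
        p = LearningParams(N=20, T=10)
        pop = init_population(p, monomorphic(0.0, 0.0), rng)
        part = partition_games(pop, p, rng)
        assert np.allclose(compute_payoffs(pop, part, env_branching), 0.0)

    @pytest.mark.parametrize("mode", ["full", "M1", "M2"])
    def test_matches_scalar_oracle(self, env_branching, rng, mode):
        p = LearningParams(N=25, T=10)
        pop = init_population(p, uniform_simplex(), rng, mode=mode)
        part = partition_games(pop, p, rng)
        pays = compute_payoffs(pop, part, env_branching, mode)
        for grp in part.groups:
            want = scalar_payoff_oracle(pop.traits[grp], env_branching, 5, mode)
            np.testing.assert_allclose(pays[grp], want, atol=1e-12)


class TestRecruitment:
    def test_softmax_weights_two_agents(self):
        # weights (e^2, 1)/(e^2+1) for payoffs (1, 0) at alpha=2
        pop = Population(np.array([[0.5, 0.0], [0.0, 0.5]]))
        rng = np.random.default_rng(3)
        steps = 10_000
        count0 = 0
        for _ in range(steps):
            newpop = recruitment_step(pop, np.array([1.0, 0.0]), 2.0, rng)
            count0 += int(np.sum(newpop.traits[:, 0] == 0.5))
        want = np.exp(2) / (np.exp(2) + 1)  # 0.8808
        se = np.sqrt(want * (1 - want) / (2 * steps))
        assert abs(count0 / (2 * steps) - want) < 4 * se

    @pytest.mark.parametrize("payoffs", [np.zeros(20), np.full(20, 3.7)])
    def test_equal_payoffs_are_neutral(self, payoffs):
        # softmax is shift-invariant: all-equal payoffs = uniform sampling
        pop = Population(np.random.default_rng(0).dirichlet((1, 1, 1), 20)[:, :2])
        a = recruitment_step(pop, payoffs, 2.0, np.random.default_rng(5))
        b = recruitment_step(pop, np.zeros(20), 0.0, np.random.default_rng(5))
        assert np.array_equal(a.traits, b.traits)

    def test_nonfinite_payoffs_diagnosed(self):
        pop = Population(np.zeros((10, 2)))
        with pytest.raises(FloatingPointError):
            recruitment_step(pop, np.full(10, np.nan), 2.0,
                             np.random.default_rng(0))

    def test_population_size_conserved(self, rng):
        pop = Population(rng.dirichlet((1, 1, 1), 30)[:, :2])
        new = recruitment_step(pop, rng.normal(size=30), 2.0, rng)
        assert new.N == 30


class TestMutation:
    def test_mu_zero_identity(self, rng):
        pop = Population(rng.dirichlet((1, 1, 1), 30)[:, :2])
        new = mutation_step(pop, 0.0, 0.005, rng)
        assert np.array_equal(new.traits, pop.traits)

    def test_sigma_zero_identity(self, rng):
        pop = Population(rng.dirichlet((1, 1, 1), 30)[:, :2])
        new = mutation_step(pop, 1.0, 0.0, rng)
        assert np.array_equal(new.traits, pop.traits)

    def test_projection_example(self):
        got = project_to_simplex(np.array([[0.7, 0.5]]))[0]
        assert got == pytest.approx([0.6, 0.4])

    def test_projection_matches_grid_oracle(self, rng):
        # brute-force nearest feasible point on a fine grid
        grid = np.array(
            [(a, b) for a in np.linspace(0, 1, 201)
             for b in np.linspace(0, 1, 201) if a + b <= 1.0 + 1e-12]
        )
        pts = rng.normal(0.4, 0.6, size=(30, 2))
        proj = project_to_simplex(pts)
        for p, pr in zip(pts, proj):
            d_oracle = np.min(((grid - p) ** 2).sum(axis=1))
            d_mine = ((pr - p) ** 2).sum()
            assert d_mine <= d_oracle + 1e-9
            assert pr[0] >= 0 and pr[1] >= 0 and pr.sum() <= 1 + 1e-12

    def test_mutants_stay_feasible(self, rng):
        pop = Population(np.tile([0.99, 0.01], (200, 1)))
        new = mutation_step(pop, 1.0, 0.5, rng)
        assert E.feasible(new.traits)


class TestRun:
    def test_bitwise_determinism(self, env_branching):
        p = LearningParams(N=20, T=100, seed=11)
        t1 = run(env_branching, p, uniform_simplex())
        t2 = run(env_branching, p, uniform_simplex())
        assert np.array_equal(t1.snapshots[-1], t2.snapshots[-1])
        assert np.array_equal(t1.mean_payoff, t2.mean_payoff)

    def test_monomorphic_no_mutation_is_fixed_point(self, env_branching):
        p = LearningParams(N=20, T=200, mu=0.0, seed=3)
        traj = run(env_branching, p, monomorphic(0.3, 0.6))
        for snap in traj.snapshots:
            assert np.all(snap == [0.3, 0.6])

    def test_simplex_conserved_along_trajectory(self, env_branching):
        p = LearningParams(N=20, T=300, seed=5)
        traj = run(env_branching, p, uniform_simplex())
        for snap in traj.snapshots:
            assert E.feasible(snap)
        assert np.all(traj.mean_z >= -1e-9) and np.all(traj.mean_z <= 1 + 1e-9)

    def test_neutral_drift_unbiased(self, env_branching):
        # alpha = 0: mean trait performs an unbiased walk
        deltas = []
        for seed in range(30):
            p = LearningParams(N=30, T=300, alpha=0.0, seed=seed)
            traj = run(env_branching, p, monomorphic(0.3, 0.4),
                       record_every=300)
            deltas.append(traj.mean_x[-1] - traj.mean_x[0])
        deltas = np.array(deltas)
        se = deltas.std(ddof=1) / np.sqrt(len(deltas))
        assert abs(deltas.mean()) < 4 * max(se, 1e-4)

    def test_selection_favours_higher_payoff(self, env_zero_benefit):
        # without benefits, inactivity strictly out-earns any effort, so the
        # inactive strategy's frequency must rise in expectation
        gains = []
        for seed in range(20):
            p = LearningParams(N=20, T=5, mu=0.0, seed=seed)
            init = E.explicit([(0.35, 0.55)] * 10 + [(0.0, 0.0)] * 10)
            traj = run(env_zero_benefit, p, init, record_every=5)
            frac0 = np.mean(traj.snapshots[0].sum(axis=1) == 0)
            frac1 = np.mean(traj.snapshots[-1].sum(axis=1) == 0)
            gains.append(frac1 - frac0)
        assert np.mean(gains) > 0


class TestCull:
    def test_zero_fraction_identical_to_plain_run(self, env_rich):
        p = LearningParams(N=20, T=120, seed=9)
        plain = run(env_rich, p, uniform_simplex())
        culled = cull_experiment(env_rich, p, uniform_simplex(), t_cull=50,
                                 fraction=0.0)
        assert np.array_equal(plain.snapshots[-1], culled.snapshots[-1])

    def test_postcull_size_multiple_of_n(self, env_rich):
        p = LearningParams(N=50, T=150, seed=2)
        traj = cull_experiment(env_rich, p, uniform_simplex(), t_cull=60,
                               fraction=0.4)
        post = [s for t, s in zip(traj.snapshot_steps, traj.snapshots) if t >= 60]
        assert all(s.shape[0] % 5 == 0 for s in post)
        assert post[-1].shape[0] <= 50

    def test_activity_series_recorded(self, env_rich):
        p = LearningParams(N=20, T=100, seed=2)
        traj = cull_experiment(env_rich, p, uniform_simplex(), t_cull=50,
                               fraction=0.2)
        assert traj.cull_step == 50
        assert traj.active_frac.shape == traj.steps.shape


class TestRngStreams:
    def test_named_streams_independent_and_reproducible(self):
        s1, s2 = RngStreams(123), RngStreams(123)
        assert s1.partition.random() == s2.partition.random()
        a = RngStreams(123)
        b = RngStreams(124)
        assert a.mutation.random() != b.mutation.random()
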