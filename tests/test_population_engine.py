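"""Unit tests for the generation loop: encounters, reproduction, mutation,
replication, determinism, and agreement between the two engines."""

import numpy as np
import pytest

from decoysim.conflict_model import ModelParams
from decoysim.errors import ConfigurationError, SimulationError
from decoysim.population import (
    LOCI,
    Population,
    SimConfig,
    encounter_and_mate,
    initialize_population,
    mutate_gametes,
    pair_mating_rates,
    replicate_seed,
    reproduce,
    run_replicates,
    run_simulation,
)


class TestInitialize:
    def test_published_initial_state(self, params):
        cfg = SimConfig(N=1000, generations=500, window=500)
        pop = initialize_population(cfg, params)
        assert pop.size == 1000
        means = pop.locus_means()
        assert list(means) == [0.0, 5.0, 16.0, 30.0]
        assert pop.n_females == 500

    def test_smallest_population_has_both_sexes(self, params):
        cfg = SimConfig(N=2, generations=500, window=500)
        pop = initialize_population(cfg, params)
        assert pop.n_females == 1 and pop.size - pop.n_females == 1

    def test_out_of_range_initial_allele_rejected(self, params):
        cfg = SimConfig(
            N=10, generations=500, window=500,
            initial_alleles={"male": 0, "female": 5, "decoy": 60, "neutral": 30},
        )
        with pytest.raises(ConfigurationError):
            initialize_population(cfg, params)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"N": 11},
            {"generations": 501},
            {"mu": 1.5},
            {"jump_prob": -0.1},
            {"n_encounters": 0},
        ],
    )
    def test_invalid_config_rejected(self, kwargs, params):
        base = dict(N=100, generations=500, window=500)
        base.update(kwargs)
        with pytest.raises(ConfigurationError):
            SimConfig(**base).validate(params)


def _fixed_population(alleles_by_locus, params):
    """4 individuals (2 females, 2 males), homozygous at given values."""
    N = 4
    alleles = np.zeros((N, 4, 2), dtype=np.int64)
    for l, locus in enumerate(LOCI):
        for i in range(N):
            alleles[i, l, :] = alleles_by_locus[locus][i]
    is_female = np.array([True, True, False, False])
    return Population(alleles=alleles, is_female=is_female)


class TestEncounterAndMate:
    def test_zero_distance_gives_certain_mating(self, params, rng):
        pop = _fixed_population(
            {"male": [0, 0, 10, 10], "female": [10, 10, 0, 0],
             "decoy": [0, 0, 0, 0], "neutral": [0, 0, 0, 0]},
            params,
        )
        cfg = SimConfig(N=4, generations=500, window=500, n_encounters=10)
        out = encounter_and_mate(pop, params, cfg, rng)
        assert np.all(out.realized_rate == 1.0)

    def test_zero_rate_gives_no_matings(self, params, rng):
        pop = _fixed_population(
            {"male": [0, 0, 50, 50], "female": [0, 0, 0, 0],
             "decoy": [0, 0, 0, 0], "neutral": [0, 0, 0, 0]},
            params,
        )
        cfg = SimConfig(N=4, generations=500, window=500, n_encounters=10)
        out = encounter_and_mate(pop, params, cfg, rng)
        assert np.all(out.realized_rate < 1e-9)
        assert np.all(out.n_mates == 0)

    def test_mean_realized_rate_matches_analytic_mean(self, params, rng):
        """Monte-Carlo realized rate converges to the mean pairwise mating
        probability over the male pool (binomial expectation)."""
        pop = _fixed_population(
            {"male": [0, 0, 4, 8], "female": [6, 10, 0, 0],
             "decoy": [0, 0, 0, 0], "neutral": [0, 0, 0, 0]},
            params,
        )
        cfg = SimConfig(N=4, generations=500, window=500, n_encounters=20)
        z = pop.phenotypes(params)
        z_m = z[~pop.is_female, 0]
        z_f = z[pop.is_female, 1]
        z_d = z[pop.is_female, 2]
        expected = pair_mating_rates(
            z_m[None, :], z_f[:, None], z_d[:, None], params
        ).mean()
        draws = 400
        rates = [
            encounter_and_mate(pop, params, cfg, rng).realized_rate.mean()
            for _ in range(draws)
        ]
        se = np.std(rates) / np.sqrt(draws)
        assert np.mean(rates) == pytest.approx(expected, abs=4 * se + 1e-4)

    def test_no_males_raises(self, params, rng):
        pop = _fixed_population(
            {"male": [0] * 4, "female": [0] * 4, "decoy": [0] * 4, "neutral": [0] * 4},
            params,
        )
        pop.is_female[:] = True
        cfg = SimConfig(N=4, generations=500, window=500)
        with pytest.raises(SimulationError):
            encounter_and_mate(pop, params, cfg, rng)


class TestMutateGametes:
    def test_zero_rate_is_identity(self, rng):
        g = rng.integers(0, 51, size=(1000, 4))
        assert np.array_equal(mutate_gametes(g, 0.0, rng), g)

    def test_reflecting_boundary_at_zero(self):
        rng = np.random.default_rng(7)
        g = np.zeros(100_000, dtype=np.int64)
        out = mutate_gametes(g, 1.0, rng, allele_max=50, jump_prob=0.0)
        assert set(np.unique(out)) == {1}

    def test_mutated_fraction_matches_rate(self):
        rng = np.random.default_rng(11)
        mu = 5e-4
        n = 1_000_000
        g = np.full(n, 25, dtype=np.int64)
        out = mutate_gametes(g, mu, rng, jump_prob=0.0)
        frac = np.mean(out != g)
        sd = np.sqrt(mu * (1 - mu) / n)
        assert abs(frac - mu) < 3 * sd

    def test_jump_steps_stay_in_allele_space(self):
        rng = np.random.default_rng(13)
        g = rng.integers(0, 51, size=200_000)
        out = mutate_gametes(g, 1.0, rng, jump_prob=1.0)
        assert out.min() >= 0 and out.max() <= 50
        assert np.all(np.abs(out - g) <= 8)  # magnitude 2..4 with reflection


class TestReproduce:
    def _outcome(self, pop, params, cfg, rng):
        return encounter_and_mate(pop, params, cfg, rng)

    def test_population_size_conserved(self, params, rng):
        cfg = SimConfig(N=200, generations=500, window=500)
        pop = initialize_population(cfg, params)
        out = self._outcome(pop, params, cfg, rng)
        nxt = reproduce(pop, out, params, cfg, rng)
        assert nxt.size == 200
        assert nxt.n_females == 100

    def test_single_mated_female_mothers_everyone(self, params, rng):
        pop = _fixed_population(
            # female 0 at distance 0 from the males; female 1 unmatable
            {"male": [0, 0, 10, 10], "female": [10, 50, 0, 0],
             "decoy": [0, 0, 0, 0], "neutral": [7, 30, 0, 0]},
            params,
        )
        cfg = SimConfig(N=4, generations=500, window=500, n_encounters=20, mu=0.0)
        out = self._outcome(pop, params, cfg, rng)
        assert out.n_mates[0] > 0 and out.n_mates[1] == 0
        nxt = reproduce(pop, out, params, cfg, rng)
        # every offspring inherits the sole mother's neutral allele (7)
        maternal_neutral = nxt.alleles[:, 3, 0]
        assert np.all(maternal_neutral == 7)

    def test_no_mated_females_raises(self, params, rng):
        pop = _fixed_population(
            {"male": [0, 0, 50, 50], "female": [0, 0, 0, 0],
             "decoy": [0, 0, 0, 0], "neutral": [0, 0, 0, 0]},
            params,
        )
        cfg = SimConfig(N=4, generations=500, window=500)
        out = self._outcome(pop, params, cfg, rng)
        with pytest.raises(SimulationError):
            reproduce(pop, out, params, cfg, rng)


class TestRunSimulation:
    def test_trajectory_length_and_initial_record(self, params):
        cfg = SimConfig(N=200, generations=600, window=200)
        traj = run_simulation(cfg, params)
        assert traj.means.shape == (601, 4)
        assert list(traj.means[0]) == [0.0, 5.0, 16.0, 30.0]

    def test_no_mutation_keeps_monomorphic_population_constant(self, params):
        cfg = SimConfig(
            N=200, generations=300, window=300, mu=0.0,
            initial_alleles={"male": 10, "female": 10, "decoy": 30, "neutral": 20},
        )
        for engine in ("fast", "reference"):
            traj = run_simulation(cfg, params, engine=engine)
            assert np.all(traj.means == traj.means[0])

    def test_same_seed_same_trajectory(self, params, tiny_config):
        a = run_simulation(tiny_config, params)
        b = run_simulation(tiny_config, params)
        assert np.array_equal(a.means, b.means)

    def test_alleles_stay_in_bounds(self, params):
        cfg = SimConfig(N=200, generations=2000, window=500, seed=3)
        traj = run_simulation(cfg, params)
        assert traj.means.min() >= 0.0
        assert traj.means.max() <= params.allele_max

    def test_engines_agree_statistically(self, params):
        """Fast and reference engines share the model: early chase motion
        of the female locus should match between engines within noise."""
        cfg = SimConfig(N=400, generations=400, window=200, seed=21)
        fast = np.mean(
            [run_simulation(cfg.with_(seed=s), params, engine="fast").locus("female")[-1]
             for s in (21, 22, 23)]
        )
        ref = np.mean(
            [run_simulation(cfg.with_(seed=s), params, engine="reference").locus("female")[-1]
             for s in (21, 22, 23)]
        )
        assert fast == pytest.approx(ref, abs=4.0)

    def test_unknown_engine_rejected(self, params, tiny_config):
        with pytest.raises(ConfigurationError):
            run_simulation(tiny_config, params, engine="warp")


class TestRunReplicates:
    def test_replicate_count_and_determinism(self, params, tiny_config):
        batch1 = run_replicates(tiny_config, params)
        batch2 = run_replicates(tiny_config, params)
        assert len(batch1) == tiny_config.n_replicates
        for a, b in zip(batch1, batch2):
            assert np.array_equal(a.means, b.means)

    def test_single_replicate_independent_of_batch(self, params, tiny_config):
        batch = run_replicates(tiny_config, params)
        solo = run_simulation(tiny_config, params, replicate=1)
        assert np.array_equal(batch[1].means, solo.means)

    def test_replicate_seeds_distinct(self):
        seeds = [replicate_seed(1, k) for k in range(50)]
        assert len(set(seeds)) == 50
        assert all(0 <= s < 2**31 for s in seeds)
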