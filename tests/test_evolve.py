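"""Selection operators, generation step, controller and full search."""
import random

import pytest

from hpfold import (
    SQUARE,
    SearchConfig,
    SelectionConfig,
    build_population,
    convergence_rate,
    hc_controller,
    parse_hp_notation,
    rank_probability,
    rank_select,
    run_search,
    step_generation,
    tournament_select,
)
from hpfold.evolve import _share_sizes, age_and_cull, mode_share
from hpfold.initpop import Individual

from conftest import random_hp


def make_population(seq, size, seed=0):
    pop, _ = build_population(seq, SQUARE, size, "guided", random.Random(seed))
    return pop


class TestConvergenceRate:
    @pytest.mark.parametrize(
        "e,e_star,expected",
        [(-8, -9, 88.9), (-5, -9, 55.6), (-7, -9, 77.8), (-9, -9, 100.0)],
    )
    def test_reference_pairs(self, e, e_star, expected):
        assert round(convergence_rate(e, e_star), 1) == expected

    def test_not_clamped(self):
        assert convergence_rate(-20, -10) == pytest.approx(0.0)
        assert convergence_rate(0, -10) == pytest.approx(0.0)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            convergence_rate(-5, 0)


class TestRankSelection:
    def test_singleton(self):
        pop = [Individual(None, 3)]
        assert rank_select(pop, random.Random(0)) is pop[0]

    def test_two_individuals_nested_uniform(self):
        """P(rank 0) = 3/4: enumerating the 2x2 grid of (m, i) draws, rank 0
        is picked unless m = 1 and the inner draw lands on 1."""
        pop = [Individual(None, 5), Individual(None, 1)]
        rng = random.Random(42)
        n = 20000
        hits = sum(rank_select(pop, rng) is pop[0] for _ in range(n))
        assert hits / n == pytest.approx(0.75, abs=0.02)

    def test_closed_form_is_a_distribution(self):
        for n in (1, 2, 7, 50):
            assert sum(rank_probability(i, n) for i in range(n)) == pytest.approx(1.0)

    def test_frequencies_non_increasing_in_rank(self):
        pop = [Individual(None, 10 - r) for r in range(8)]
        rng = random.Random(7)
        counts = [0] * 8
        for _ in range(30000):
            ind = rank_select(pop, rng)
            counts[pop.index(ind)] += 1
        assert all(a >= b - 300 for a, b in zip(counts, counts[1:]))

    def test_exp_mode_prefers_best(self):
        pop = [Individual(None, 10 - r) for r in range(10)]
        cfg = SelectionConfig(rank_mode="exp")
        rng = random.Random(3)
        picks = [rank_select(pop, rng, cfg) for _ in range(5000)]
        assert picks.count(pop[0]) > picks.count(pop[-1])

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            rank_select([], random.Random(0))


class TestTournamentSelection:
    def test_singleton_pool(self, rng):
        seq = parse_hp_notation("HPHPPH")
        pop = make_population(seq, 4)
        pool = [pop[0]]
        assert tournament_select(pool, seq, rng) is pop[0]

    def test_requires_equal_fitness(self, rng):
        seq = parse_hp_notation("HPHPPH")
        a, b = Individual(None, 1), Individual(None, 2)
        with pytest.raises(ValueError):
            tournament_select([a, b], seq, rng)
        with pytest.raises(ValueError):
            tournament_select([], seq, rng)

    def test_deterministic_under_seed(self):
        seq = parse_hp_notation("HPHHPPHH")
        pop = make_population(seq, 6, seed=1)
        fit = pop[0].fitness
        pool = [i for i in pop if i.fitness == fit] or [pop[0]]
        a = tournament_select(pool, seq, random.Random(5))
        b = tournament_select(pool, seq, random.Random(5))
        assert a is b


class TestGenerationStep:
    def test_share_arithmetic(self):
        assert _share_sizes(100, SelectionConfig()) == (5, 20, 75)
        assert sum(_share_sizes(100, SelectionConfig())) == 100

    def test_fraction_validation(self):
        with pytest.raises(ValueError):
            SelectionConfig(tournament_fraction=0.5, rank_fraction=0.5, elite_fraction=0.5)

    def test_size_preserved_and_best_never_drops(self):
        seq = parse_hp_notation("HPH2P2HPH2PHP2H2PHPH", "prefix")
        cfg = SearchConfig(population_size=40, seed=2)
        rng = random.Random(2)
        pop = make_population(seq, 40, seed=2)
        best = max(i.fitness for i in pop)
        for _ in range(15):
            pop = step_generation(pop, seq, rng, cfg)
            assert len(pop) == 40
            new_best = max(i.fitness for i in pop)
            assert new_best >= best
            best = new_best

    def test_identical_population_stays_identical_size(self, rng):
        seq = parse_hp_notation("HPHP")
        base = make_population(seq, 12)[0]
        pop = [Individual(base.conformation, base.fitness) for _ in range(12)]
        out = step_generation(pop, seq, rng, SearchConfig(population_size=12))
        assert len(out) == 12


class TestAging:
    def test_no_aged_is_identity(self, rng):
        seq = parse_hp_notation("HPHPPH")
        pop = make_population(seq, 8)
        out = age_and_cull(list(pop), seq, SearchConfig(), rng)
        assert [i.conformation for i in out] == [i.conformation for i in pop]

    def test_aged_class_keeps_one_survivor(self, rng):
        seq = parse_hp_notation("HPHPPH")
        base = make_population(seq, 4)[0]
        limit = SelectionConfig().aging_limit
        pop = [Individual(base.conformation, base.fitness, age=limit) for _ in range(6)]
        out = age_and_cull(pop, seq, SearchConfig(), rng)
        survivors = [i for i in out if i.conformation is base.conformation]
        assert len(survivors) == 1
        assert all(i.conformation.valid for i in out)
        assert all(i.age == 0 for i in out)


class TestController:
    def test_converged_population_diversifies(self, rng):
        seq = parse_hp_notation("HPHHPPHH")
        base = make_population(seq, 10)[0]
        pop = [Individual(base.conformation, base.fitness) for _ in range(10)]
        action, out = hc_controller(pop, seq, SearchConfig(), rng)
        assert action == "diversify"
        assert len(out) == 10

    def test_diverse_population_intensifies(self, rng):
        seq = parse_hp_notation("HPHHPPHH")
        pop = make_population(seq, 10)
        for r, ind in enumerate(pop):
            ind.fitness = r  # force all-distinct fitness labels
        action, out = hc_controller(pop, seq, SearchConfig(), rng)
        assert action == "intensify"

    def test_intensify_never_decreases_fitness(self, rng):
        seq = parse_hp_notation("2H2P6(H2P)2H", "prefix")
        pop = make_population(seq, 10, seed=4)
        before = sorted((i.fitness for i in pop), reverse=True)
        action, out = hc_controller(pop, seq, SearchConfig(hc_diversity_threshold=0.99,
                                                          hc_convergence_threshold=0.995), rng)
        assert action == "intensify"
        after = sorted((i.fitness for i in out), reverse=True)
        assert all(a >= b for a, b in zip(after, before))

    def test_mode_share(self):
        pop = [Individual(None, f) for f in (3, 3, 3, 1)]
        assert mode_share(pop) == 0.75


class TestRunSearch:
    def test_all_polar_is_immediately_optimal(self):
        seq = parse_hp_notation("10P", "prefix")
        res = run_search(seq, SearchConfig(population_size=10, max_generations=5, seed=0,
                                           target_energy=0))
        assert res.best_energy == 0
        assert res.generations_to_best == 0

    def test_reproducible_histories(self):
        seq = parse_hp_notation("HPHP3H3P4H2P2H", "prefix")
        cfg = SearchConfig(population_size=20, max_generations=8, seed=11)
        a = run_search(seq, cfg)
        b = run_search(seq, cfg)
        assert a.history == b.history
        assert a.best.conformation.coords == b.best.conformation.coords

    def test_best_energy_monotone_in_history(self):
        seq = parse_hp_notation("HPH2P2HPH2PHP2H2PHPH", "prefix")
        res = run_search(seq, SearchConfig(population_size=30, max_generations=25, seed=5))
        energies = [h.best_energy for h in res.history]
        assert all(a >= b for a, b in zip(energies, energies[1:]))
        assert res.best_energy == energies[-1]

    def test_target_energy_stops_early(self):
        seq = parse_hp_notation("HPHP3H3P4H2P2H", "prefix")
        res = run_search(seq, SearchConfig(seed=1, target_energy=-1))
        assert res.best_energy <= -1

    def test_convergence_rate_reported(self):
        seq = parse_hp_notation("10P", "prefix")
        cfg = SearchConfig(population_size=10, max_generations=2, seed=0, target_energy=0)
        res = run_search(seq, cfg, e_star=-5)
        assert res.convergence_rate_pct == pytest.approx(
            convergence_rate(res.best_energy, -5))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SearchConfig(population_size=2)
        with pytest.raises(ValueError):
            SearchConfig(hc_convergence_threshold=1.5)
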