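"""Tier-2 search driver: selection, hill-climbing control, EP loop.

One generation of the evolutionary program partitions the population into
three selection shares — 20% tournament (drawn from the modal-fitness
class and all given the *same* mutation), 75% rank-based (nested-uniform
draw biased toward the best ranks), 5% elitism (carried unchanged) — and
every selected parent produces exactly one mutated offspring.  A
hill-climbing controller watches population convergence: when 70% of the
population share one fitness value it injects diversity by replacing a
fraction with fresh guided conformations, and when the population is very
diverse it intensifies with a greedy local search over corner/pull moves.
Elites that survive unchanged for 25 generations meet the aging operator:
a mutation tournament among equal-fitness aged elites keeps one and
replaces the rest.

The printed rank-selection probability 1 - exp(-rank/beta) assigns the
best individual (rank 0) probability zero; the nested-uniform draw
i ~ U(0, U(0, n_s - 1)) is therefore the default selector, and the
exponential weighting is available (with reversed rank) as mode "exp".
"""
from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

from .hp_model import HPSequence
from .initpop import Individual, build_population, guided_conformation
from .lattice import LatticeSpec, fitness as hh_fitness, get_lattice
from .operators import MutationPlan, corner_move, draw_plan, find_motif_sites, mutate, pull_move

__all__ = [
    "Individual",
    "SelectionConfig",
    "SearchConfig",
    "GenerationRecord",
    "SearchResult",
    "tournament_select",
    "rank_select",
    "rank_probability",
    "step_generation",
    "age_and_cull",
    "hc_controller",
    "run_search",
    "convergence_rate",
]


@dataclass(frozen=True)
class SelectionConfig:
    """Selection shares and parameters.

    The three fractions must sum to 1.  ``n_ts`` (tournament set size)
    defaults to the tournament share of the population.  ``lambda_`` is
    the linear-ranking offspring allocation (1 <= lambda <= 2, worst gets
    2 - lambda); the default 1.0 keeps one offspring per selected parent.
    """

    tournament_fraction: float = 0.20
    rank_fraction: float = 0.75
    elite_fraction: float = 0.05
    rank_mode: str = "nested"  # "nested" | "exp"
    beta: float | None = None  # normalisation for the "exp" mode; n_s/3 if None
    lambda_: float = 1.0
    aging_limit: int = 25
    n_ts: int | None = None

    def __post_init__(self) -> None:
        total = self.tournament_fraction + self.rank_fraction + self.elite_fraction
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"selection fractions must sum to 1, got {total}")
        if not 1.0 <= self.lambda_ <= 2.0:
            raise ValueError("lambda must lie in [1, 2]")


@dataclass(frozen=True)
class SearchConfig:
    """Run configuration for the memetic search."""

    population_size: int = 100
    max_generations: int = 500
    stagnation_window: int = 150
    hc_convergence_threshold: float = 0.70
    hc_diversity_threshold: float = 0.65
    diversify_fraction: float = 0.30
    intensify_budget_factor: int = 10
    intensify_top: int | None = 5
    intensify_temperature: float = 0.45
    accept_worse: float = 1.0  # chance a worse offspring displaces its parent
    lattice: str = "square"
    motif_prob: float = 0.5
    h_bias: float = 0.5
    init_method: str = "guided"
    target_energy: int | None = None
    seed: int = 0
    selection: SelectionConfig = field(default_factory=SelectionConfig)

    def __post_init__(self) -> None:
        if self.population_size < 4:
            raise ValueError("population size must be >= 4")
        for t in (self.hc_convergence_threshold, self.hc_diversity_threshold):
            if not 0.0 < t < 1.0:
                raise ValueError("hill-climbing thresholds must lie in (0, 1)")


@dataclass(frozen=True)
class GenerationRecord:
    generation: int
    best_energy: int
    mean_energy: float
    mode_share: float
    hc_action: str


@dataclass
class SearchResult:
    best: Individual
    best_energy: int
    generations_to_best: int  # G_c: generation at which best energy first attained
    history: list[GenerationRecord]
    init_stats: object = None
    convergence_rate_pct: float | None = None


def _clone(ind: Individual) -> Individual:
    return Individual(conformation=ind.conformation, fitness=ind.fitness,
                      age=ind.age, excursion=ind.excursion)


def _sorted_by_fitness(
    population: list[Individual], rng: random.Random
) -> list[Individual]:
    """Sort best-first; ties broken by index order after a seeded shuffle."""
    shuffled = list(population)
    rng.shuffle(shuffled)
    ordered = sorted(shuffled, key=lambda ind: -ind.fitness)
    for r, ind in enumerate(ordered):
        ind.rank = r
    return ordered


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------

def tournament_select(
    pool: list[Individual],
    seq: HPSequence,
    rng: random.Random,
    motif_prob: float = 0.5,
    plan: MutationPlan | None = None,
) -> Individual:
    """Subject every member of an equal-fitness pool to the same mutation
    and return the member whose offspring scored best (ties: first)."""
    if not pool:
        raise ValueError("empty tournament pool")
    if len({ind.fitness for ind in pool}) != 1:
        raise ValueError("tournament pool must have equal fitness")
    if plan is None:
        plan = draw_plan(seq, pool[0].conformation.length, rng, motif_prob)
    best_ind, best_fit = pool[0], -1
    for ind in pool:
        result = mutate(ind.conformation, seq, rng, plan=plan)
        fit = ind.fitness - result.delta_energy if result.accepted else ind.fitness
        if fit > best_fit:
            best_ind, best_fit = ind, fit
    return best_ind


def rank_probability(i: int, n_s: int) -> float:
    """Closed-form selection probability of rank i under the nested-uniform
    draw m ~ U{0..n_s-1}, i ~ U{0..m}:  P(i) = (1/n_s) * sum_{m>=i} 1/(m+1)."""
    return sum(1.0 / (m + 1) for m in range(i, n_s)) / n_s


def rank_select(
    population: list[Individual],
    rng: random.Random,
    cfg: SelectionConfig | None = None,
) -> Individual:
    """Pick an individual from a best-first sorted population.

    Default mode: nested-uniform (draw m uniform on 0..n_s-1, then the
    index uniform on 0..m), which biases selection toward the best ranks.
    Mode "exp": weights 1 - exp(-(n_s - 1 - rank)/beta) (reversed rank so
    the best individual gets the largest weight), beta defaulting to n_s/3.
    """
    if not population:
        raise ValueError("empty population")
    n_s = len(population)
    cfg = cfg or SelectionConfig()
    if cfg.rank_mode == "nested":
        m = rng.randrange(n_s)
        return population[rng.randint(0, m)]
    if cfg.rank_mode == "exp":
        import math

        beta = cfg.beta if cfg.beta is not None else n_s / 3.0
        weights = [1.0 - math.exp(-(n_s - 1 - r) / beta) for r in range(n_s)]
        total = sum(weights)
        if total <= 0:
            return population[0]
        x = rng.random() * total
        acc = 0.0
        for ind, w in zip(population, weights):
            acc += w
            if x <= acc:
                return ind
        return population[-1]
    raise ValueError(f"unknown rank mode {cfg.rank_mode!r}")


# ---------------------------------------------------------------------------
# Generation step
# ---------------------------------------------------------------------------

def _share_sizes(n_s: int, sel: SelectionConfig) -> tuple[int, int, int]:
    n_elite = max(1, round(sel.elite_fraction * n_s))
    n_tourn = round(sel.tournament_fraction * n_s)
    n_rank = n_s - n_elite - n_tourn
    if n_rank < 0:
        raise ValueError("population too small for the configured shares")
    return n_elite, n_tourn, n_rank


def step_generation(
    population: list[Individual],
    seq: HPSequence,
    rng: random.Random,
    cfg: SearchConfig,
    sites=None,
) -> list[Individual]:
    """One EP generation: elites carried, tournament share mutated with a
    shared plan, rank share mutated individually.  Size is preserved and
    the best fitness never decreases."""
    spec = get_lattice(cfg.lattice)
    sel = cfg.selection
    n_s = len(population)
    n_elite, n_tourn, n_rank = _share_sizes(n_s, sel)
    if sites is None:
        sites = find_motif_sites(seq)
    ordered = _sorted_by_fitness(population, rng)

    new_pop: list[Individual] = []
    for ind in ordered[:n_elite]:
        elite = _clone(ind)
        elite.age += 1
        new_pop.append(elite)

    if n_tourn:
        # tournament set: drawn from the modal-fitness class, padded by
        # resampling when the class is smaller than the share
        by_fitness: dict[int, list[Individual]] = {}
        for ind in ordered:
            by_fitness.setdefault(ind.fitness, []).append(ind)
        modal = max(by_fitness.values(), key=len)
        set_size = sel.n_ts or n_tourn
        pool = [modal[rng.randrange(len(modal))] for _ in range(set_size)]
        plan = draw_plan(seq, pool[0].conformation.length, rng, cfg.motif_prob, sites)
        offspring = []
        for parent in pool:
            result = mutate(parent.conformation, seq, rng, plan=plan)
            if result.accepted:
                child = Individual(result.offspring, parent.fitness - result.delta_energy)
            else:
                child = Individual(parent.conformation, parent.fitness)
            offspring.append(child)
        offspring.sort(key=lambda c: -c.fitness)
        new_pop.extend(_clone(c) for c in offspring[:n_tourn])
        while len(new_pop) < n_elite + n_tourn:  # set smaller than share
            new_pop.append(_clone(offspring[rng.randrange(len(offspring))]))

    for _ in range(n_rank):
        parent = rank_select(ordered, rng, sel)
        result = mutate(parent.conformation, seq, rng,
                        motif_prob=cfg.motif_prob, sites=sites)
        keep_offspring = result.accepted and (
            result.delta_energy <= 0 or rng.random() < cfg.accept_worse
        )
        if keep_offspring:
            new_pop.append(Individual(result.offspring,
                                      parent.fitness - result.delta_energy))
        else:
            new_pop.append(Individual(parent.conformation, parent.fitness))
    for ind in new_pop[n_elite:]:
        ind.age = 0
    return new_pop


def age_and_cull(
    population: list[Individual],
    seq: HPSequence,
    cfg: SearchConfig,
    rng: random.Random,
) -> list[Individual]:
    """Aging operator: elites unchanged for ``aging_limit`` generations
    compete in a mutation tournament per fitness class; one survives, the
    rest are replaced by fresh guided conformations."""
    spec = get_lattice(cfg.lattice)
    limit = cfg.selection.aging_limit
    aged = [ind for ind in population if ind.age >= limit]
    if not aged:
        return population
    by_fitness: dict[int, list[Individual]] = {}
    for ind in aged:
        by_fitness.setdefault(ind.fitness, []).append(ind)
    survivors: set[int] = set()
    for group in by_fitness.values():
        winner = tournament_select(group, seq, rng, cfg.motif_prob)
        survivors.add(id(winner))
    out: list[Individual] = []
    for ind in population:
        if ind.age >= limit and id(ind) not in survivors:
            conf = guided_conformation(seq, spec, rng, h_bias=cfg.h_bias)
            out.append(Individual(conf, hh_fitness(conf.coords, seq.residues, spec)))
        else:
            if ind.age >= limit:
                ind.age = 0  # winner earns another aging window
            out.append(ind)
    return out


# ---------------------------------------------------------------------------
# Hill-climbing controller
# ---------------------------------------------------------------------------

def _local_search(
    ind: Individual,
    seq: HPSequence,
    rng: random.Random,
    budget: int,
    temperature: float = 0.3,
) -> Individual:
    """Stochastic hill climbing over the corner/pull neighbourhood.

    Random trials; improvements always accepted, neutral and worsening
    moves with Boltzmann probability exp(-dE/T), which lets the walk cross
    the fitness plateaus and shallow barriers that separate compact HP
    folds.  The walk head persists on the individual (``excursion``) so
    successive refinements continue one long chain instead of restarting;
    the individual itself keeps the best conformation the chain has
    visited, so its fitness never decreases.
    """
    conf, fit = ind.excursion if ind.excursion is not None else (
        ind.conformation, ind.fitness)
    best_conf, best_fit = ind.conformation, ind.fitness
    L = conf.length
    for _ in range(budget):
        if rng.random() < 0.5 and L >= 3:
            result = corner_move(conf, seq, rng.randrange(1, L - 1), rng)
        else:
            result = pull_move(conf, seq, rng.randrange(L), rng)
        if not result.accepted:
            continue
        d = result.delta_energy
        if d <= 0 or rng.random() < math.exp(-d / temperature):
            conf = result.offspring
            fit = fit - d
            if fit > best_fit:
                best_conf, best_fit = conf, fit
    return Individual(best_conf, best_fit, age=ind.age, excursion=(conf, fit))


def mode_share(population: list[Individual]) -> float:
    counts: dict[int, int] = {}
    for ind in population:
        counts[ind.fitness] = counts.get(ind.fitness, 0) + 1
    return max(counts.values()) / len(population)


def hc_controller(
    population: list[Individual],
    seq: HPSequence,
    cfg: SearchConfig,
    rng: random.Random,
) -> tuple[str, list[Individual]]:
    """Convergence watchdog of the memetic layer.

    Mode-fitness share >= the convergence threshold: *diversify* — the
    worst non-elite individuals are replaced with fresh guided walks, and
    the top individuals are refined as well, so a converged population
    keeps climbing instead of idling.  Share <= the diversity threshold:
    *intensify* — stochastic local search (see :func:`_local_search`) on
    the top individuals.  Otherwise: no action.
    """
    spec = get_lattice(cfg.lattice)
    share = mode_share(population)
    budget = cfg.intensify_budget_factor * seq.length

    def refine_top(ordered: list[Individual]) -> list[Individual]:
        k = len(ordered) if cfg.intensify_top is None else min(cfg.intensify_top, len(ordered))
        return [
            _local_search(ind, seq, rng, budget, cfg.intensify_temperature)
            for ind in ordered[:k]
        ] + ordered[k:]

    if share >= cfg.hc_convergence_threshold:
        # converged: refresh the tail with fresh guided walks, and keep
        # climbing from the incumbents so convergence is not an idle state
        n_elite, _, _ = _share_sizes(len(population), cfg.selection)
        ordered = _sorted_by_fitness(population, rng)
        keep, rest = ordered[:n_elite], ordered[n_elite:]
        n_replace = min(int(cfg.diversify_fraction * len(population)), len(rest))
        for k in range(1, n_replace + 1):
            conf = guided_conformation(seq, spec, rng, h_bias=cfg.h_bias)
            rest[-k] = Individual(conf, hh_fitness(conf.coords, seq.residues, spec))
        return "diversify", refine_top(keep + rest)
    if share <= cfg.hc_diversity_threshold:
        return "intensify", refine_top(_sorted_by_fitness(population, rng))
    return "none", population


# ---------------------------------------------------------------------------
# Full search
# ---------------------------------------------------------------------------

def run_search(
    seq: HPSequence,
    cfg: SearchConfig,
    e_star: int | None = None,
) -> SearchResult:
    """Run the two-tier memetic search on one sequence.

    Guided (or random) initialization, then the EP generation loop with
    hill-climbing control and aging, until the generation cap, the target
    energy (if set), or stagnation.  Fully reproducible from ``cfg.seed``.
    ``e_star`` is an optional reference optimum used only to report the
    convergence rate of the final energy.
    """
    spec = get_lattice(cfg.lattice)
    rng = random.Random(cfg.seed)
    sites = find_motif_sites(seq)
    population, init_stats = build_population(
        seq, spec, cfg.population_size, cfg.init_method, rng, h_bias=cfg.h_bias
    )
    best = max(population, key=lambda ind: ind.fitness)
    best = _clone(best)
    g_c = 0
    last_improvement = 0
    history: list[GenerationRecord] = [
        GenerationRecord(0, -best.fitness,
                         -sum(i.fitness for i in population) / len(population),
                         mode_share(population), "none")
    ]
    gen = 0
    while gen < cfg.max_generations:
        if cfg.target_energy is not None and -best.fitness <= cfg.target_energy:
            break
        if gen - last_improvement >= cfg.stagnation_window:
            break
        gen += 1
        population = step_generation(population, seq, rng, cfg, sites)
        action, population = hc_controller(population, seq, cfg, rng)
        population = age_and_cull(population, seq, cfg, rng)
        gen_best = max(population, key=lambda ind: ind.fitness)
        if gen_best.fitness > best.fitness:
            best = _clone(gen_best)
            g_c = gen
            last_improvement = gen
        history.append(
            GenerationRecord(gen, -best.fitness,
                             -sum(i.fitness for i in population) / len(population),
                             mode_share(population), action)
        )
    rate = None
    if e_star is not None and e_star != 0:
        rate = convergence_rate(-best.fitness, e_star)
    return SearchResult(
        best=best,
        best_energy=-best.fitness,
        generations_to_best=g_c,
        history=history,
        init_stats=init_stats,
        convergence_rate_pct=rate,
    )


def convergence_rate(e: float, e_star: float) -> float:
    """Percent closeness of an achieved energy to a reference optimum:
    (1 - |E - E*| / |E*|) * 100, not clamped."""
    if e_star == 0:
        raise ValueError("reference optimum must be nonzero")
    return (1.0 - abs(e - e_star) / abs(e_star)) * 100.0
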