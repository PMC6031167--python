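"""Tier-1 population construction.

Two initializers are provided:

* ``random_conformation`` — the naive baseline: after the fixed first two
  residues every move is drawn uniformly, the walk is decoded and simply
  reported as self-avoiding or not.  Validity decays quickly with chain
  length, which is exactly why the guided method exists.
* ``guided_conformation`` — the constraint-aware initializer.  It keeps a
  hash of occupied sites while the chain grows; a move into an occupied
  site is cancelled and another free neighbour is tried, and a dead end
  (all neighbours occupied) is escaped by stepping back one residue and
  re-entering the retry loop.  The result is always a self-avoiding walk.
  An optional hydrophobic bias steers H residues toward sites that touch
  already-placed H residues, seeding a hydrophobic core in the initial
  population.

``build_population`` wraps either method into a population of evaluated
individuals plus the validity statistics (N_v, N_i, N_k) used by the
initializer benchmark reports.
"""
from __future__ import annotations

import random
from dataclasses import dataclass

from .hp_model import HPSequence
from .lattice import Conformation, LatticeSpec, canonicalize, decode, fitness

__all__ = [
    "Individual",
    "InitStats",
    "random_conformation",
    "guided_conformation",
    "build_population",
]


@dataclass
class Individual:
    """A conformation plus its cached fitness and selection bookkeeping.

    ``fitness`` is the H-H contact count (non-negative); ``energy`` its
    negation.  ``age`` counts consecutive generations spent as an elite.
    ``excursion`` holds the head of this individual's ongoing local-search
    walk (conformation, fitness), which may sit below ``fitness``: the
    walk continues across generations while ``conformation`` always holds
    the best state it has visited.
    """

    conformation: Conformation
    fitness: int
    age: int = 0
    rank: int | None = None
    excursion: tuple[Conformation, int] | None = None

    @property
    def energy(self) -> int:
        return -self.fitness


@dataclass
class InitStats:
    """Validity statistics of one initialization batch.

    n_generated = N_v + N_i for the random method; the guided method never
    produces an invalid walk, so N_k equals the batch size there.
    """

    n_generated: int = 0
    n_valid: int = 0
    n_invalid: int = 0
    n_guided: int = 0
    best_hh: int = 0


def random_conformation(
    seq: HPSequence,
    spec: LatticeSpec,
    rng: random.Random,
    avoid_reversal: bool = False,
) -> tuple[Conformation, bool]:
    """Uniformly random move string (first move fixed); no repair.

    Returns the decoded conformation and its self-avoidance verdict.
    With ``avoid_reversal`` each move is drawn uniformly from the moves
    that do not immediately backtrack (which always collides); the walk
    is otherwise unbiased.
    """
    L = seq.length
    if L < 2:
        raise ValueError("need at least 2 residues to place a chain")
    moves = ["F"]
    for _ in range(L - 2):
        if avoid_reversal:
            px, py = spec.step_vectors[moves[-1]]
            back = spec.move_of_step((-px, -py))
            choices = [m for m in spec.moves if m != back]
            moves.append(rng.choice(choices))
        else:
            moves.append(rng.choice(spec.moves))
    conf = decode(moves, spec)
    return conf, conf.valid


def guided_conformation(
    seq: HPSequence,
    spec: LatticeSpec,
    rng: random.Random,
    h_bias: float = 0.5,
) -> Conformation:
    """Constraint-aware initializer; always returns a self-avoiding walk.

    Moves are drawn in random order at each position, skipping occupied
    sites; dead ends are escaped by backtracking one residue at a time,
    so the walk always completes on the unbounded lattice.  With
    probability ``h_bias`` an H residue prefers free sites adjacent to an
    already-placed H residue (when any exist).
    """
    L = seq.length
    if L < 2:
        raise ValueError("need at least 2 residues to place a chain")
    residues = seq.residues
    steps = [spec.step_vectors[m] for m in spec.moves]
    contact = spec.contact_vectors
    coords: list[tuple[int, int]] = [(0, 0), (1, 0)]
    if L == 2:
        return Conformation(moves=("F",), coords=tuple(coords), spec=spec)
    occupied: dict[tuple[int, int], int] = {(0, 0): 0, (1, 0): 1}
    # per-depth stack of not-yet-tried target sites
    pending: list[list[tuple[int, int]]] = []

    def candidates(k: int) -> list[tuple[int, int]]:
        px, py = coords[-1]
        free = [(px + dx, py + dy) for dx, dy in steps
                if (px + dx, py + dy) not in occupied]
        rng.shuffle(free)
        if free and residues[k] == "H" and rng.random() < h_bias:
            def touches_h(q: tuple[int, int]) -> bool:
                qx, qy = q
                for cx, cy in contact:
                    j = occupied.get((qx + cx, qy + cy))
                    if j is not None and j < k - 1 and residues[j] == "H":
                        return True
                return False
            preferred = [q for q in free if touches_h(q)]
            if preferred:
                # options are consumed from the end of the list, so the
                # preferred sites go last to be tried first
                free = [q for q in free if q not in preferred] + preferred
        return free

    pending.append(candidates(2))
    while len(coords) < L:
        opts = pending[-1]
        placed = False
        while opts:
            q = opts.pop()
            if q in occupied:  # may have been filled after backtracking
                continue
            occupied[q] = len(coords)
            coords.append(q)
            placed = True
            break
        if placed:
            if len(coords) < L:
                pending.append(candidates(len(coords)))
        else:
            # dead end: drop the tail residue and resume one level up
            pending.pop()
            if len(coords) <= 2:
                # unreachable: the straight-line completion of the fixed
                # start always exists, so the root level cannot exhaust
                raise AssertionError("guided initializer exhausted the root level")
            dropped = coords.pop()
            del occupied[dropped]
    return Conformation(moves=tuple(
        spec.move_of_step((b[0] - a[0], b[1] - a[1]))
        for a, b in zip(coords, coords[1:])
    ), coords=tuple(coords), spec=spec)


def build_population(
    seq: HPSequence,
    spec: LatticeSpec,
    size: int,
    method: str,
    rng: random.Random,
    h_bias: float = 0.5,
) -> tuple[list[Individual], InitStats]:
    """Build exactly ``size`` valid individuals and record validity stats.

    For ``method="random"`` invalid draws are discarded, counted in
    ``n_invalid`` and redrawn; for ``method="guided"`` every draw is valid
    by construction.  Conformations are stored in canonical encoding.

    Population construction (unlike the fixed-attempt statistics of
    :func:`validity_batch`) excludes the immediate-reversal move from the
    random draws: a uniform walk of 30+ steps is self-avoiding with
    vanishing probability, so plain rejection sampling would effectively
    never assemble a long-chain population.
    """
    if size < 1:
        raise ValueError("population size must be >= 1")
    if method not in ("guided", "random"):
        raise ValueError(f"unknown initialization method {method!r}")
    stats = InitStats()
    population: list[Individual] = []
    while len(population) < size:
        if method == "guided":
            conf = guided_conformation(seq, spec, rng, h_bias=h_bias)
            stats.n_generated += 1
            stats.n_guided += 1
            stats.n_valid += 1
        else:
            conf, valid = random_conformation(seq, spec, rng, avoid_reversal=True)
            stats.n_generated += 1
            if not valid:
                stats.n_invalid += 1
                continue
            stats.n_valid += 1
        conf = canonicalize(conf.coords, spec)
        fit = fitness(conf.coords, seq.residues, spec)
        stats.best_hh = max(stats.best_hh, fit)
        population.append(Individual(conformation=conf, fitness=fit))
    return population, stats


def validity_batch(
    seq: HPSequence,
    spec: LatticeSpec,
    n: int,
    method: str,
    rng: random.Random,
    h_bias: float = 0.5,
    avoid_reversal: bool = False,
) -> InitStats:
    """Generate exactly ``n`` conformations (valid or not) and tally them.

    This is the fixed-attempt protocol of the initializer benchmark: the
    random method counts its invalid draws instead of redrawing.  With
    ``avoid_reversal`` the random method skips the always-colliding
    immediate reversal; fully uniform walks beyond ~15 residues are
    practically never self-avoiding, which makes the uniform baseline
    column flat zero for the longer benchmarks.
    """
    stats = InitStats()
    for _ in range(n):
        if method == "guided":
            conf = guided_conformation(seq, spec, rng, h_bias=h_bias)
            stats.n_guided += 1
            stats.n_valid += 1
            valid = True
        else:
            conf, valid = random_conformation(seq, spec, rng, avoid_reversal)
            if valid:
                stats.n_valid += 1
            else:
                stats.n_invalid += 1
        stats.n_generated += 1
        if valid:
            stats.best_hh = max(
                stats.best_hh, fitness(conf.coords, seq.residues, spec)
            )
    return stats
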