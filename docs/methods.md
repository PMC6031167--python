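# Methods

## The model

`hpfold` predicts coarse protein structure in Dill's hydrophobic–polar
(HP) model.  Each residue is classed hydrophobic (H) or polar (P); the
chain is embedded on a 2D lattice as a self-avoiding walk (SAW), and the
free energy counts hydrophobic contacts:

    E(c) = - |{ (i, j) : j > i + 1, s_i = s_j = H, ||x_i - x_j|| = one lattice step }|

Minimising E is equivalent to maximising the H-H contact count f = -E,
which is the fitness used throughout.  Finding the ground state is
NP-complete even in this reduced model, hence the heuristic search.

Amino-acid sequences are mapped onto {H, P} with the residue classes
H = {A, G, I, L, M, F, P, W, V} and P = {R, N, D, C, E, Q, H, K, S, T, Y}.
These classes are deliberately coarse (proline hydrophobic, histidine
polar); they are the classes the packaged protein benchmarks were built
with, and `fasta_to_hp` accepts an override map for studies that prefer a
different partition.

### Lattices

* `square` — moves F, B, U, D with steps (±1,0), (0,±1); contacts across
  the same four vectors.
* `tri8` — the square moves plus the four diagonals FU, BU, BD, FD;
  contacts across all eight vectors.  This is the "triangular" encoding
  used by the packaged triangular benchmark results: every diagonal step
  is a legal bond of graph length one, even though its Euclidean length
  is √2.  Energies on `tri8` are therefore not comparable to a true
  6-neighbour triangular lattice.
* `tri6` — a genuine 6-neighbour triangular lattice in sheared (axial)
  coordinates: the square steps plus (1,1) and (−1,−1).  Provided so
  results can be cross-checked against literature values that assume six
  neighbours.

### Encoding and symmetry

Conformations are relative move strings decoded from the fixed start
x_0 = (0,0), x_1 = (1,0).  `canonicalize` maps a chain to the
lexicographically smallest move string over all lattice automorphisms
(the dihedral group of order 8 for `square`/`tri8`, order 12 for `tri6`),
so every rotation/reflection image of a structure has one genotype.  On
the square lattice this pins the first move to F and the first off-axis
turn to +y.  On `tri8` a diagonal first step cannot be rotated onto
(1,0) by a lattice automorphism, so canonical encodings there begin with
F or FU depending on the orbit of the first step.  Populations are built
from canonical encodings; the mutation hot path keeps raw origin-anchored
encodings and canonicalises only when results are reported.

## Tier 1 — initialization

`guided_conformation` grows the chain one residue at a time over a hash
of occupied sites, drawing moves in random order, skipping occupied
targets, and escaping dead ends by backtracking one residue (the walk is
a full randomised depth-first search, so it always terminates with a
valid SAW — the guarantee the initializer statistics N_k report).  With
probability `h_bias` (default 0.5) an H residue restricts its choice to
free sites adjacent to an already-placed H residue when any exist,
seeding a hydrophobic core; this is our operational reading of the
loosely stated "folding rule" memory, and it is flagged as an
interpretation.

`random_conformation` is the baseline: uniform moves, no repair, validity
merely reported.  Population construction from the random method rejects
and redraws, but excludes the immediate-reversal move (which always
collides): fully uniform 30-step walks are self-avoiding with probability
of order 1e-6, so literal rejection sampling cannot assemble long-chain
populations in reasonable time.  The fixed-attempt statistics
(`validity_batch`, the initializer benchmark) keep the fully uniform
generator.  We make no attempt to reproduce any particular published
validity percentage for the random method; the published rates imply a
non-uniform generator whose details are not stated.

## Tier 2 — the evolutionary program

Mutation is the only variation operator.  One call applies exactly one
operator, chosen by the sequence: with probability `motif_prob` (default
0.5) a motif rewrite when the sequence offers sites — the downward-helix
pattern PPHPPHPP or upward-helix pattern HPPHHPPH rewritten onto a tight
two-wide serpentine template, or a run of ≥ 3 identical residues
straightened into a sheet — otherwise a corner flip or pull move at a
random residue.  Motif patterns are matched on the expanded HP string
(the only well-defined choice).  The helix/sheet drawings fix no move
symbols, so the templates here are the tight square-lattice serpentine
and the straight strand, config-overridable; the `tri8` helix substitutes
diagonal steps.  Pull moves act in both chain directions (relocate
residue i beside a neighbour and drag the far side along vacated sites
until the chain reconnects); one-directional pulls are not ergodic and
were measurably weaker.  Operators enforce feasibility only — a clashing
offspring is rejected and the parent kept; selection owns quality.

Selection partitions each generation of n_s = 100 individuals into

* 5% elitism — the best individuals carried unchanged (ages increment);
* 20% tournament — one set drawn from the modal-fitness class, every
  member given the *same* mutation plan, offspring ranked and the share
  filled from them (the best performer is what `tournament_select`
  returns);
* 75% rank-based — parents drawn by the nested-uniform rule
  i ~ U(0, U(0, n_s − 1)), biased toward the best ranks, each producing
  one offspring that takes the slot.

The printed exponential rank weighting 1 − exp(−rank/β) gives the best
individual (rank 0) probability zero, contradicting its stated intent;
it is available as mode `"exp"` with the rank reversed and β = n_s/3,
but the nested-uniform draw is the default.  λ-based offspring allocation
is exposed (`lambda_`, worst gets 2 − λ) but defaults to one offspring
per parent.  Ties are broken by index order after a seeded shuffle, which
keeps runs deterministic without positional bias.

Elites unchanged for 25 consecutive generations are "aged": a mutation
tournament among equal-fitness aged elites keeps one (its age resets),
the rest are replaced by fresh guided conformations.

### Hill-climbing controller

After each generation the controller inspects the population's
mode-fitness share (the fraction holding the single most common fitness
value):

* share ≥ 0.70 — *diversify*: the worst 30% of non-elite individuals are
  replaced by fresh guided conformations, **and** the top 5 are refined
  (see below).  Refining on convergence matters: a pure either/or rule
  makes share ≈ 0.70 an absorbing state in which the search stops
  improving exactly when the incumbent needs work.
* share ≤ 0.65 — *intensify*: the top 5 individuals are refined.
* otherwise — no action.

Refinement is stochastic hill climbing over the corner/pull
neighbourhood: 10·L random trials accepting improvements always and
neutral/worsening moves with Boltzmann probability exp(−ΔE/T) at fixed
T = 0.45 contacts.  Each individual's walk head persists across
generations (`Individual.excursion`), so successive refinements continue
one long chain rather than restarting at the incumbent — restart-
fragmented walks cannot make the long excursions needed to cross the
barriers between compact folds.  The individual itself always keeps the
best conformation its chain has visited, so refinement never lowers any
individual's fitness.  The temperature is in units of contacts; 0.45 was
selected by measuring standalone chain hit-rates on the hard square
benchmarks (colder chains stall on the H-dense 18-mer, hotter ones
dissolve the 36-mer's core).

A greedy-only intensifier (the textbook reading of hill climbing) was
tried first and plateaus one to three contacts above the benchmark
ground states; the thresholds and the Metropolis form above are the
package's design resolution of a controller that the source framework
only sketches.

### Stopping and metrics

A run stops at `max_generations` (default 500), when `target_energy` is
reached, or after 150 generations without improvement (no stagnation
span is stated anywhere; 150 exceeds the largest gap between reported
attainment generations).  `G_c` is the generation at which the final
best energy was first attained (0 = initial population).  The
convergence rate of an achieved energy E against a reference optimum E*
is (1 − |E − E*|/|E*|) · 100, not clamped.  Benchmark protocol: best of
up to 20 independently seeded restarts (50 for the 36-mer), population
100, early stop at the reference optimum.

## Exhaustive oracle

`exhaustive_optimum` enumerates all nonisomorphic SAWs by depth-first
search with occupancy pruning: the first step is fixed to one
representative per symmetry orbit and the first step that leaves the
initial axis must turn to the positive side (removing reflections).  It
returns the exact ground-state energy and the count of optimal
nonisomorphic conformations, refuses chains longer than a guard (default
16), and serves as the reference the search is tested against for short
chains.  The oracle itself is cross-checked in the test suite against an
independent brute-force enumeration over all move strings.

## Packaged benchmarks

Three fixture sets ship as plain text and are length-validated on load:
eight classical square-lattice sequences in prefix run-length notation
with their reference optima; eleven triangular-lattice sequences in caret
notation with the best previously published energies; four protein
sequences with their published HP strings.  Known defects of the printed
sources are carried as flagged metadata rather than silently corrected:
B9's notation expands to 84 residues against a printed length of 85; the
square set's printed results include one value below the sequence's own
reference optimum and one obvious sign typo.  Disputed cells are excluded
from tests.

## What the tests do and do not show

The suite verifies exact arithmetic (parser expansions, energy, the
convergence-rate formula), structural invariants (SAW preservation under
every operator, monotone best-so-far energy, canonical-encoding
uniqueness over symmetry images, selection frequencies against the
closed form), oracle equivalence on short random chains, and attainment
of the published square/triangular benchmark optima under the standard
protocol.  Stochastic-search results are best-of-restarts with fixed
seeds: they demonstrate that the implementation reaches the published
ground states, not that any single run will.  HP-model optima on 2D
lattices are themselves coarse abstractions; nothing here speaks to
real protein geometry beyond the model.

## Numerical and degenerate-input choices

Coordinates are unbounded Python integers (no grid edge, no overflow);
occupancy is a hash of sites.  All randomness flows from one
`random.Random(seed)` per run; restart seeds are derived as
`seed · 1000003 + r (mod 2^31)`.  Chains of length 1 have energy 0 and
no moves; length-2 chains are the fixed two-site walk.  Sequences are
validated to the {H, P} alphabet at construction; the notation parser
reports the exact offending position.  Fitness values are small
non-negative integers, so equality tests and mode-share counts are
exact.
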