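# hpfold

*Ab initio* coarse protein structure prediction in the hydrophobic–polar
(HP) lattice model, using a two-tier memetic search: an evolutionary
program hybridised with hill climbing.

## The problem

In the HP model each residue of a protein is classed hydrophobic (H) or
polar (P) and the chain is embedded on a 2D lattice as a self-avoiding
walk.  The free energy of a conformation `c` counts hydrophobic
contacts:

    E(c) = − |{ (i, j) : j > i+1,  s_i = s_j = H,  x_i and x_j adjacent on the lattice }|

The native structure is the walk minimising `E` — equivalently,
maximising the H-H contact count.  Even in this reduced model the
optimisation is NP-complete, so practical prediction needs a good
heuristic.  `hpfold` implements one for structural-bioinformatics
practitioners who want reproducible HP-model baselines: square and
triangular 2D lattices, the classical benchmark suites included, and an
exact enumeration oracle for short chains.

## The method

**Tier 1** converts the input (FASTA amino-acid sequence, run-length HP
notation like `2H5P…` or `H^2P^5…`, or a plain HP string) into an HP
sequence and builds an initial population of 100 conformations with a
constraint-aware initializer: the chain grows over a hash of occupied
sites, retries occupied targets, backtracks out of dead ends, and can
bias hydrophobic residues toward already-placed H neighbours.  Every
initial conformation is a valid self-avoiding walk by construction.

**Tier 2** refines the population with an evolutionary program in which
mutation is the only variation: sequence-motif rewrites (helix templates
for `PPHPPHPP` / `HPPHHPPH`, sheet straightening for runs ≥ 3) plus
corner flips and pull moves.  Selection splits each generation 20%
tournament / 75% rank-based (nested-uniform draw) / 5% elitism, with an
aging rule that retires elites stuck for 25 generations.  A
hill-climbing controller watches population convergence and either
injects fresh conformations or intensifies the best individuals with a
fixed-temperature stochastic local search over corner/pull moves.
Details, defaults and design rationale are in
[docs/methods.md](docs/methods.md).

## Worked example

Fold the classical 20-residue square-lattice benchmark (id 4 of the
packaged `square8` set), stopping when the known optimum −9 is reached:

```sh
$ hpfold fold --seq-id 4 --seed 1 --restarts 20 --target-energy -9
sequence      HPHPPHHPHPPHPHHPPHPH
length        20  (H% 50.0)
lattice       square
best energy   -9
H-H contacts  9
generations   37 (G_c), 1 run(s)
moves         FUUBDBUBBDFDFDBDFFU
```

Reading the output: the run-length notation `HPH2P2HPH2PHP2H2PHPH`
expands to the 20-mer shown, half of whose residues are hydrophobic.
The search found a self-avoiding conformation with 9 H-H contacts (free
energy −9, the best known for this sequence) at generation 37 of the
first restart.  The move string is the conformation's canonical relative
encoding (`F`orward/`B`ack/`U`p/`D`own from residue 1 at the origin);
`--out conf.tsv` writes the residue coordinates, `--log run.jsonl` the
per-generation trace.

Other entry points:

```sh
hpfold convert --seq "P^2HP^2(H^2P^4)^3H^2"     # expand notation / FASTA to HP
hpfold enumerate --seq HPPH                     # exact optimum by enumeration: -1
hpfold init-bench --n 100 --seed 7              # initializer validity statistics
hpfold bench --bench-set tri11 --ids B1         # fold packaged benchmark sets
```

The same functionality is available as a library:

```python
from hpfold import parse_hp_notation, run_search, SearchConfig
seq = parse_hp_notation("HPH2P2HPH2PHP2H2PHPH")
result = run_search(seq, SearchConfig(seed=1, target_energy=-9))
print(result.best_energy, result.generations_to_best)
```

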