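"""Lattice geometry, relative move encoding, SAW validation and HP energy.

Conformations are relative move strings decoded onto integer coordinates.
The first residue sits at the origin and the second at (1, 0), so a chain
of L residues is encoded by L-1 move symbols whose first entry is the
canonical representative of its symmetry orbit (``F`` on the square
lattice).  This "nonisomorphic" encoding, together with the reflection
rule applied by :func:`canonicalize`, gives every rotation/reflection
image of a structure the same genotype, keeping the search space free of
degenerate duplicates.

Three lattice variants are provided:

* ``square`` — 4 axis moves F, B, U, D; contacts across the same 4 vectors.
* ``tri8``   — the 8-move encoding (axis moves plus the four diagonals
  FU, BU, BD, FD); contacts across all 8 vectors.  This is the variant the
  triangular-lattice benchmarks in this package are folded on.
* ``tri6``   — a true 6-neighbour triangular lattice in sheared (axial)
  coordinates: axis moves plus (1, 1) and (-1, -1).  Provided for
  cross-checking against literature values that assume 6 neighbours.

Energy is the standard HP contact potential: every pair (i, j), j > i+1,
of H residues sitting on contact-adjacent sites contributes -1.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .hp_model import HPSequence

__all__ = [
    "LatticeSpec",
    "Conformation",
    "ContactSet",
    "SQUARE",
    "TRI8",
    "TRI6",
    "LATTICES",
    "get_lattice",
    "decode",
    "encode",
    "canonicalize",
    "parse_moves",
    "format_moves",
    "energy",
    "exhaustive_optimum",
    "write_conformation_tsv",
    "read_conformation_tsv",
]

Vec = tuple[int, int]
Mat = tuple[tuple[int, int], tuple[int, int]]


def _apply(m: Mat, v: Vec) -> Vec:
    return (m[0][0] * v[0] + m[0][1] * v[1], m[1][0] * v[0] + m[1][1] * v[1])


# Dihedral group of the square lattice (order 8): rotations by 90 degrees
# and reflections.  These are the contact-preserving automorphisms of both
# the square and the 8-neighbour lattice.
_D4: tuple[Mat, ...] = (
    ((1, 0), (0, 1)),
    ((0, -1), (1, 0)),
    ((-1, 0), (0, -1)),
    ((0, 1), (-1, 0)),
    ((1, 0), (0, -1)),
    ((-1, 0), (0, 1)),
    ((0, 1), (1, 0)),
    ((0, -1), (-1, 0)),
)

# Automorphisms of the triangular lattice in axial coordinates (order 12):
# powers of the 60-degree rotation (x, y) -> (x - y, x), with and without
# the reflection (x, y) -> (y, x).
def _tri6_group() -> tuple[Mat, ...]:
    rot: Mat = ((1, -1), (1, 0))
    mats: list[Mat] = []
    m: Mat = ((1, 0), (0, 1))
    for _ in range(6):
        mats.append(m)
        m = (
            (rot[0][0] * m[0][0] + rot[0][1] * m[1][0],
             rot[0][0] * m[0][1] + rot[0][1] * m[1][1]),
            (rot[1][0] * m[0][0] + rot[1][1] * m[1][0],
             rot[1][0] * m[0][1] + rot[1][1] * m[1][1]),
        )
    refl: Mat = ((0, 1), (1, 0))
    for m in list(mats):
        mats.append(
            (
                (refl[0][0] * m[0][0] + refl[0][1] * m[1][0],
                 refl[0][0] * m[0][1] + refl[0][1] * m[1][1]),
                (refl[1][0] * m[0][0] + refl[1][1] * m[1][0],
                 refl[1][0] * m[0][1] + refl[1][1] * m[1][1]),
            )
        )
    return tuple(mats)


@dataclass(frozen=True)
class LatticeSpec:
    """Move alphabet, step vectors and contact neighbourhood of a lattice."""

    name: str
    moves: tuple[str, ...]
    step_vectors: dict[str, Vec]
    contact_vectors: tuple[Vec, ...]
    automorphisms: tuple[Mat, ...]
    # one first-step per symmetry orbit, for exhaustive enumeration
    enum_first_moves: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "_move_of_step", {v: m for m, v in self.step_vectors.items()}
        )
        object.__setattr__(
            self, "_rank", {m: i for i, m in enumerate(self.moves)}
        )

    def move_of_step(self, v: Vec) -> str:
        try:
            return self._move_of_step[v]  # type: ignore[attr-defined]
        except KeyError:
            raise ValueError(f"{v} is not a single step on lattice {self.name}")

    def rank(self, move: str) -> int:
        return self._rank[move]  # type: ignore[attr-defined]

    def __repr__(self) -> str:  # pragma: no cover
        return f"LatticeSpec({self.name!r})"


SQUARE = LatticeSpec(
    name="square",
    moves=("F", "B", "U", "D"),
    step_vectors={"F": (1, 0), "B": (-1, 0), "U": (0, 1), "D": (0, -1)},
    contact_vectors=((1, 0), (-1, 0), (0, 1), (0, -1)),
    automorphisms=_D4,
    enum_first_moves=("F",),
)

TRI8 = LatticeSpec(
    name="tri8",
    moves=("F", "B", "U", "D", "FU", "BU", "BD", "FD"),
    step_vectors={
        "F": (1, 0),
        "B": (-1, 0),
        "U": (0, 1),
        "D": (0, -1),
        "FU": (1, 1),
        "BU": (-1, 1),
        "BD": (-1, -1),
        "FD": (1, -1),
    },
    contact_vectors=(
        (1, 0), (-1, 0), (0, 1), (0, -1), (1, 1), (-1, 1), (-1, -1), (1, -1),
    ),
    automorphisms=_D4,
    # diagonal first steps are not rotation images of (1, 0) under D4
    enum_first_moves=("F", "FU"),
)

TRI6 = LatticeSpec(
    name="tri6",
    moves=("F", "B", "U", "D", "FU", "BD"),
    step_vectors={
        "F": (1, 0),
        "B": (-1, 0),
        "U": (0, 1),
        "D": (0, -1),
        "FU": (1, 1),
        "BD": (-1, -1),
    },
    contact_vectors=((1, 0), (-1, 0), (0, 1), (0, -1), (1, 1), (-1, -1)),
    automorphisms=_tri6_group(),
    enum_first_moves=("F",),
)

LATTICES: dict[str, LatticeSpec] = {"square": SQUARE, "tri8": TRI8, "tri6": TRI6}


def get_lattice(name: str) -> LatticeSpec:
    try:
        return LATTICES[name]
    except KeyError:
        raise ValueError(f"unknown lattice {name!r}; choose from {sorted(LATTICES)}")


# ---------------------------------------------------------------------------
# Conformations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Conformation:
    """A relative move string and its decoded coordinates.

    ``valid`` reports whether the walk is self-avoiding; decoding never
    enforces it, so infeasible genotypes can still be inspected.
    """

    moves: tuple[str, ...]
    coords: tuple[Vec, ...]
    spec: LatticeSpec

    @property
    def valid(self) -> bool:
        return len(set(self.coords)) == len(self.coords)

    @property
    def length(self) -> int:
        return len(self.coords)

    def move_string(self) -> str:
        return format_moves(self.moves, self.spec)

    def canonical(self) -> "Conformation":
        return canonicalize(self.coords, self.spec)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.coords)


def parse_moves(text: str, spec: LatticeSpec) -> tuple[str, ...]:
    """Parse a move string; '-' or whitespace separated, or compact.

    Compact text is tokenised greedily, longest symbol first, so diagonal
    moves like ``FU`` bind tighter than ``F`` followed by ``U``; emit with
    separators (see :func:`format_moves`) when that ambiguity matters.
    """
    text = text.strip()
    if "-" in text or " " in text:
        toks = [t for t in text.replace("-", " ").split() if t]
        for t in toks:
            if t not in spec.step_vectors:
                raise ValueError(f"unknown move symbol {t!r} on {spec.name}")
        return tuple(toks)
    toks = []
    i = 0
    symbols = sorted(spec.moves, key=len, reverse=True)
    while i < len(text):
        for s in symbols:
            if text.startswith(s, i):
                toks.append(s)
                i += len(s)
                break
        else:
            raise ValueError(f"unknown move symbol at position {i} in {text!r}")
    return tuple(toks)


def format_moves(moves: tuple[str, ...], spec: LatticeSpec) -> str:
    if any(len(m) > 1 for m in spec.moves):
        return "-".join(moves)
    return "".join(moves)


def decode(moves, spec: LatticeSpec) -> Conformation:
    """Build coordinates from a move string, starting (0,0) -> step 1.

    Validity (self-avoidance) is reported via ``Conformation.valid``, not
    enforced.
    """
    if isinstance(moves, str):
        moves = parse_moves(moves, spec)
    moves = tuple(moves)
    coords: list[Vec] = [(0, 0)]
    x, y = 0, 0
    for m in moves:
        try:
            dx, dy = spec.step_vectors[m]
        except KeyError:
            raise ValueError(f"unknown move symbol {m!r} on lattice {spec.name}")
        x, y = x + dx, y + dy
        coords.append((x, y))
    return Conformation(moves=moves, coords=tuple(coords), spec=spec)


def encode(coords, spec: LatticeSpec) -> tuple[str, ...]:
    """Recover the move string of a coordinate chain (inverse of decode)."""
    out = []
    for (x0, y0), (x1, y1) in zip(coords, coords[1:]):
        out.append(spec.move_of_step((x1 - x0, y1 - y0)))
    return tuple(out)


def canonicalize(coords, spec: LatticeSpec) -> Conformation:
    """Canonical representative of a chain under lattice symmetries.

    All rotation/reflection images of a structure share one canonical
    encoding: translate the first residue to the origin, apply every
    lattice automorphism, and keep the move string that is smallest under
    the lattice's move-alphabet order.  On the square lattice this fixes
    the first move to F and the first off-axis deviation to +y.
    """
    coords = list(coords)
    x0, y0 = coords[0]
    rel = [(x - x0, y - y0) for x, y in coords]
    best_moves: tuple[str, ...] | None = None
    best_rank: tuple[int, ...] | None = None
    best_coords: tuple[Vec, ...] | None = None
    for m in spec.automorphisms:
        img = [_apply(m, v) for v in rel]
        try:
            mv = encode(img, spec)
        except ValueError:
            continue  # automorphism does not preserve this chain's steps
        rank = tuple(spec.rank(s) for s in mv)
        if best_rank is None or rank < best_rank:
            best_rank, best_moves, best_coords = rank, mv, tuple(img)
    assert best_moves is not None and best_coords is not None
    return Conformation(moves=best_moves, coords=best_coords, spec=spec)


# ---------------------------------------------------------------------------
# Energy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContactSet:
    """Topological H-H contacts of a conformation and the implied energy."""

    pairs: frozenset[tuple[int, int]]
    energy: int

    @property
    def fitness(self) -> int:
        """Number of H-H contacts (the maximisation view of the energy)."""
        return -self.energy


def energy(conf: Conformation, seq: HPSequence | str) -> ContactSet:
    """HP contact energy: -1 per nonconsecutive adjacent H-H pair.

    Raises on length mismatch or a non-self-avoiding conformation.
    """
    residues = seq.residues if isinstance(seq, HPSequence) else seq
    if len(residues) != len(conf.coords):
        raise ValueError(
            f"sequence length {len(residues)} != conformation length {len(conf.coords)}"
        )
    if not conf.valid:
        raise ValueError("conformation is not self-avoiding")
    pairs = count_contacts(conf.coords, residues, conf.spec, collect=True)
    return ContactSet(pairs=frozenset(pairs), energy=-len(pairs))


def count_contacts(coords, residues: str, spec: LatticeSpec, collect: bool = False):
    """Count (or list) H-H contact pairs (i, j), j > i + 1.

    The workhorse behind :func:`energy`; callers on hot paths use the
    count form directly.
    """
    index_of: dict[Vec, int] = {p: i for i, p in enumerate(coords)}
    pairs: list[tuple[int, int]] = []
    n = 0
    for i, p in enumerate(coords):
        if residues[i] != "H":
            continue
        px, py = p
        for dx, dy in spec.contact_vectors:
            j = index_of.get((px + dx, py + dy))
            if j is not None and j > i + 1 and residues[j] == "H":
                if collect:
                    pairs.append((i, j))
                n += 1
    return pairs if collect else n


def fitness(coords, residues: str, spec: LatticeSpec) -> int:
    """H-H contact count of a coordinate chain (fast path, no checks)."""
    return count_contacts(coords, residues, spec)


def cached_fitness(conf: "Conformation", residues: str) -> int:
    """H-H contact count memoised on the conformation object.

    Search loops score the same parent conformation against the same
    sequence many times; the cache keeps that O(L) walk to one evaluation
    per conformation (re-evaluated if a different sequence is supplied).
    """
    hit = conf.__dict__.get("_hh")
    if hit is not None and hit[0] == residues:
        return hit[1]
    f = count_contacts(conf.coords, residues, conf.spec)
    object.__setattr__(conf, "_hh", (residues, f))
    return f


# ---------------------------------------------------------------------------
# Exhaustive oracle
# ---------------------------------------------------------------------------

def _cross(a: Vec, b: Vec) -> int:
    return a[0] * b[1] - a[1] * b[0]


def exhaustive_optimum(
    seq: HPSequence | str,
    spec: LatticeSpec = SQUARE,
    max_length_guard: int = 16,
) -> tuple[int, int]:
    """Exact ground-state energy by depth-first SAW enumeration.

    Enumerates the nonisomorphic encoding only: the first step is fixed to
    one representative per symmetry orbit and reflection is removed by
    requiring the first step that leaves the initial direction's axis to
    turn to the positive side.  Returns ``(best_energy, n_optimal)`` where
    ``n_optimal`` counts distinct nonisomorphic conformations attaining it.

    Intended as the test oracle for short chains; refuses sequences longer
    than ``max_length_guard``.
    """
    residues = seq.residues if isinstance(seq, HPSequence) else seq
    L = len(residues)
    if L > max_length_guard:
        raise ValueError(
            f"sequence length {L} exceeds enumeration guard {max_length_guard}"
        )
    if L < 2:
        return 0, 1
    is_h = [r == "H" for r in residues]
    steps = [spec.step_vectors[m] for m in spec.moves]
    best = [0, 0]  # best contact count, number of optima

    def dfs(coords: list[Vec], occ: dict[Vec, int], contacts: int, chiral_fixed: bool, first: Vec):
        k = len(coords)
        if k == L:
            if contacts > best[0]:
                best[0], best[1] = contacts, 1
            elif contacts == best[0]:
                best[1] += 1
            return
        hx = is_h[k]
        px, py = coords[-1]
        for dx, dy in steps:
            q = (px + dx, py + dy)
            if q in occ:
                continue
            fixed = chiral_fixed
            if not fixed:
                c = _cross(first, (dx, dy))
                if c < 0:
                    continue  # mirror image; its reflection is enumerated
                if c > 0:
                    fixed = True
            gained = 0
            if hx:
                qx, qy = q
                for cx, cy in spec.contact_vectors:
                    j = occ.get((qx + cx, qy + cy))
                    if j is not None and j < k - 1 and is_h[j]:
                        gained += 1
            occ[q] = k
            coords.append(q)
            dfs(coords, occ, contacts + gained, fixed, first)
            coords.pop()
            del occ[q]

    for first_move in spec.enum_first_moves:
        fv = spec.step_vectors[first_move]
        # contacts need j > i + 1, so the first two residues contribute none
        dfs([(0, 0), fv], {(0, 0): 0, fv: 1}, 0, False, fv)
    return -best[0], best[1]


# ---------------------------------------------------------------------------
# Conformation TSV I/O
# ---------------------------------------------------------------------------

def write_conformation_tsv(
    path: str | Path, conf: Conformation, seq: HPSequence | str
) -> None:
    """Write a conformation as TSV: header lines, then index/residue/x/y."""
    residues = seq.residues if isinstance(seq, HPSequence) else seq
    e = energy(conf, residues).energy
    lines = [
        f"# lattice\t{conf.spec.name}",
        f"# moves\t{conf.move_string()}",
        f"# energy\t{e}",
        "index\tresidue\tx\ty",
    ]
    for i, ((x, y), r) in enumerate(zip(conf.coords, residues), start=1):
        lines.append(f"{i}\t{r}\t{x}\t{y}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_conformation_tsv(path: str | Path) -> tuple[Conformation, str]:
    """Read the format written by :func:`write_conformation_tsv`.

    Returns the conformation and the residue string; coordinates are
    re-derived from the move header and checked against the table.
    """
    lattice_name = "square"
    moves_text = ""
    residues: list[str] = []
    coords: list[Vec] = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        if line.startswith("#"):
            key, value = line[1:].strip().split("\t", 1)
            if key == "lattice":
                lattice_name = value.strip()
            elif key == "moves":
                moves_text = value.strip()
            continue
        if line.startswith("index\t"):
            continue
        _idx, r, x, y = line.split("\t")
        residues.append(r)
        coords.append((int(x), int(y)))
    spec = get_lattice(lattice_name)
    conf = decode(moves_text, spec)
    if conf.coords != tuple(coords):
        raise ValueError(f"coordinate table in {path} disagrees with move header")
    return conf, "".join(residues)
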