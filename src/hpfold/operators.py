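"""Tier-2 variation operators.

Mutation is the only source of variation in the evolutionary program.  An
offspring x'(t) = x(t) + dx(t) is produced by exactly one operator attempt
per call, chosen by the HP sequence itself:

* residues matching the downward-helix pattern ``PPHPPHPP`` or the
  upward-helix pattern ``HPPHHPPH`` can be rewritten onto a tight
  serpentine helix template;
* runs of three or more identical residues can be straightened into a
  sheet (extended strand);
* anywhere else, a corner flip or a pull move perturbs the chain locally.

Operators enforce feasibility only: an offspring that clashes with the
rest of the chain is rejected and the parent kept.  Quality is left to
selection.  Offspring keep their raw (origin-anchored) encoding on the
hot path; canonical re-encoding (see :func:`hpfold.lattice.canonicalize`)
is applied where symmetry-free genotypes matter, e.g. when populations
are built or results reported.
"""
from __future__ import annotations

import random
from dataclasses import dataclass

from .hp_model import HPSequence
from .lattice import Conformation, LatticeSpec, Vec, cached_fitness

__all__ = [
    "MotifSite",
    "MutationResult",
    "MutationPlan",
    "HELIX_DOWN_PATTERN",
    "HELIX_UP_PATTERN",
    "find_motif_sites",
    "apply_helix",
    "apply_sheet",
    "corner_move",
    "pull_move",
    "draw_plan",
    "apply_plan",
    "mutate",
]

HELIX_DOWN_PATTERN = "PPHPPHPP"  # P2HP2HP2
HELIX_UP_PATTERN = "HPPHHPPH"    # HP2H2P2H

# Helix templates as local move symbols relative to the entering direction
# (F = keep going, U = turn left/+y, D = turn right/-y in the local frame).
# Both are 2-wide serpentines advancing along the entering direction; the
# up variant oscillates to the +y side, the down variant to the -y side.
# On the 8-move lattice the serpentine closes through diagonal steps.
_HELIX_TEMPLATES: dict[tuple[str, str], tuple[str, ...]] = {
    ("square", "helix_up"): ("U", "F", "D", "F", "U", "F", "D"),
    ("square", "helix_down"): ("D", "F", "U", "F", "D", "F", "U"),
    ("tri8", "helix_up"): ("U", "FD", "U", "FD", "U", "FD", "U"),
    ("tri8", "helix_down"): ("D", "FU", "D", "FU", "D", "FU", "D"),
    ("tri6", "helix_up"): ("U", "F", "D", "F", "U", "F", "D"),
    ("tri6", "helix_down"): ("D", "F", "U", "F", "D", "F", "U"),
}

_LOCAL_FRAME = {"F": (1, 0), "B": (-1, 0), "U": (0, 1), "D": (0, -1),
                "FU": (1, 1), "BU": (-1, 1), "BD": (-1, -1), "FD": (1, -1)}


@dataclass(frozen=True)
class MotifSite:
    """A sequence-triggered mutation site.

    ``kind`` is ``helix_down``, ``helix_up`` or ``sheet``; ``start`` is the
    0-based residue index where the pattern begins and ``span`` the number
    of residues it covers (8 for helices, the full run length for sheets).
    """

    kind: str
    start: int
    span: int


@dataclass(frozen=True)
class MutationPlan:
    """A fully specified operator application (used to repeat the *same*
    mutation across a tournament set)."""

    operator: str            # helix_down | helix_up | sheet | corner | pull
    site: MotifSite | None = None
    index: int | None = None


@dataclass(frozen=True)
class MutationResult:
    offspring: Conformation
    operator_used: str
    accepted: bool
    delta_energy: int


def find_motif_sites(seq: HPSequence | str) -> list[MotifSite]:
    """All non-overlapping motif sites, scanned left to right.

    Helix patterns take precedence over sheet runs at the same position;
    sheet runs are maximal (span >= 3).
    """
    residues = seq.residues if isinstance(seq, HPSequence) else seq
    sites: list[MotifSite] = []
    i = 0
    n = len(residues)
    while i < n:
        window = residues[i : i + 8]
        if window == HELIX_DOWN_PATTERN:
            sites.append(MotifSite("helix_down", i, 8))
            i += 8
            continue
        if window == HELIX_UP_PATTERN:
            sites.append(MotifSite("helix_up", i, 8))
            i += 8
            continue
        j = i
        while j < n and residues[j] == residues[i]:
            j += 1
        if j - i >= 3:
            sites.append(MotifSite("sheet", i, j - i))
            i = j
        else:
            i += 1
    return sites


# ---------------------------------------------------------------------------
# Structural rewrites
# ---------------------------------------------------------------------------

def _rotate_local(template: tuple[str, ...], entering: Vec, spec: LatticeSpec) -> list[str]:
    """Map local template symbols into absolute moves given the entering
    step vector (the local +x axis)."""
    fx, fy = entering
    # local frame: f = entering, u = 90 deg CCW of entering
    ux, uy = -fy, fx
    out = []
    for sym in template:
        lx, ly = _LOCAL_FRAME[sym]
        v = (lx * fx + ly * ux, lx * fy + ly * uy)
        out.append(spec.move_of_step(v))
    return out


def _rewrite_moves(
    conf: Conformation,
    seq: HPSequence,
    start: int,
    new_segment: list[str],
    name: str,
) -> MutationResult:
    """Replace the moves linking residues start..start+len(segment) and
    re-validate the whole chain."""
    moves = list(conf.moves)
    moves[start : start + len(new_segment)] = new_segment
    from .lattice import decode

    cand = decode(tuple(moves), conf.spec)
    if not cand.valid:
        return MutationResult(conf, name, False, 0)
    delta = -(cached_fitness(cand, seq.residues)
              - cached_fitness(conf, seq.residues))
    return MutationResult(cand, name, True, delta)


def apply_helix(conf: Conformation, seq: HPSequence, site: MotifSite) -> MutationResult:
    """Rewrite the moves over a helix site to the serpentine template."""
    if site.kind not in ("helix_down", "helix_up"):
        raise ValueError(f"not a helix site: {site.kind}")
    if site.start < 0 or site.start + site.span > conf.length:
        raise IndexError("motif site out of range")
    template = _HELIX_TEMPLATES[(conf.spec.name, site.kind)]
    if site.start == 0:
        entering = conf.spec.step_vectors[conf.moves[0]]
        seg_start = 1
        segment = template[: site.span - 2]
    else:
        entering = conf.spec.step_vectors[conf.moves[site.start - 1]]
        seg_start = site.start
        segment = template[: site.span - 1]
    try:
        absolute = _rotate_local(tuple(segment), entering, conf.spec)
    except ValueError:
        # a diagonal entering direction cannot carry the axis-aligned
        # template (45-degree rotation is not a lattice automorphism)
        return MutationResult(conf, site.kind, False, 0)
    return _rewrite_moves(conf, seq, seg_start, absolute, site.kind)


def apply_sheet(conf: Conformation, seq: HPSequence, site: MotifSite) -> MutationResult:
    """Straighten the moves over a repeat run (extended strand)."""
    if site.kind != "sheet":
        raise ValueError(f"not a sheet site: {site.kind}")
    if site.start < 0 or site.start + site.span > conf.length:
        raise IndexError("motif site out of range")
    if site.start == 0:
        entering_move = conf.moves[0]
        seg_start = 1
        seg_len = site.span - 2
    else:
        entering_move = conf.moves[site.start - 1]
        seg_start = site.start
        seg_len = site.span - 1
    return _rewrite_moves(conf, seq, seg_start, [entering_move] * seg_len, "sheet")


# ---------------------------------------------------------------------------
# Local moves
# ---------------------------------------------------------------------------

def _finish(conf: Conformation, seq: HPSequence, coords: list[Vec], name: str) -> MutationResult:
    if len(set(coords)) != len(coords):
        return MutationResult(conf, name, False, 0)
    steps = set(conf.spec.step_vectors.values())
    for a, b in zip(coords, coords[1:]):
        if (b[0] - a[0], b[1] - a[1]) not in steps:
            return MutationResult(conf, name, False, 0)
    spec = conf.spec
    from .lattice import encode

    x0, y0 = coords[0]
    if (x0, y0) != (0, 0):  # residue 0 may have moved; re-anchor the origin
        coords = [(x - x0, y - y0) for x, y in coords]
    moves = encode(coords, spec)
    cand = Conformation(moves=moves, coords=tuple(coords), spec=spec)
    delta = -(cached_fitness(cand, seq.residues)
              - cached_fitness(conf, seq.residues))
    return MutationResult(cand, name, True, delta)


def corner_move(
    conf: Conformation, seq: HPSequence, i: int, rng: random.Random | None = None
) -> MutationResult:
    """Flip residue i across the diagonal of the corner it sits on.

    Requires the two bonds at residue i to span a corner whose opposite
    site (coords[i-1] + coords[i+1] - coords[i]) is a free site one step
    from both neighbours.
    """
    if not 0 < i < conf.length - 1:
        raise IndexError(f"corner index {i} out of range")
    coords = list(conf.coords)
    a, b, c = coords[i - 1], coords[i], coords[i + 1]
    target = (a[0] + c[0] - b[0], a[1] + c[1] - b[1])
    steps = set(conf.spec.step_vectors.values())
    if (
        target == b
        or target in set(coords)
        or (target[0] - a[0], target[1] - a[1]) not in steps
        or (c[0] - target[0], c[1] - target[1]) not in steps
    ):
        return MutationResult(conf, "corner", False, 0)
    coords[i] = target
    return _finish(conf, seq, coords, "corner")


def _pull_candidates(coords: list[Vec], i: int, spec: LatticeSpec) -> list[list[Vec]]:
    """All pull relocations of residue i anchored on residue i+1, dragging
    the preceding residues along the vacated sites until the chain
    reconnects.  Returns candidate coordinate lists (not yet SAW-checked)."""
    L = len(coords)
    occupied = set(coords)
    steps = set(spec.step_vectors.values())
    anchor = coords[i + 1]
    out: list[list[Vec]] = []
    for dx, dy in steps:
        q = (anchor[0] + dx, anchor[1] + dy)
        if q in occupied:
            continue
        trial = list(coords)
        # residue i moves to q; if q already bonds to residue i-1 that is
        # the whole move, otherwise drag predecessors through the corner
        # site c and the vacated positions until the chain reconnects.
        dprev = (coords[i - 1][0] - q[0], coords[i - 1][1] - q[1]) if i > 0 else None
        if i == 0:
            trial[0] = q
        elif dprev in steps:
            trial[i] = q
        else:
            c = (q[0] + coords[i][0] - anchor[0], q[1] + coords[i][1] - anchor[1])
            if c in occupied and c != coords[i - 1]:
                continue
            trial[i] = q
            if c != coords[i - 1]:
                trial[i - 1] = c
                j = i - 2
                while j >= 0:
                    nxt = trial[j + 1]
                    d = (coords[j][0] - nxt[0], coords[j][1] - nxt[1])
                    if d in steps:
                        break
                    trial[j] = coords[j + 2]
                    j -= 1
        out.append(trial)
    return out


def pull_move(
    conf: Conformation, seq: HPSequence, i: int, rng: random.Random
) -> MutationResult:
    """Pull move at residue i: relocate it to a free site adjacent to one
    of its chain neighbours and drag the residues on the far side along
    the vacated sites until the chain reconnects.

    Both pull directions are offered (dragging the preceding or the
    following residues); a random one is tried first so the neighbourhood
    is symmetric along the chain, which pull-move ergodicity requires.
    End residues degenerate to a hop around their single neighbour.
    Candidates are tried in random order and the first self-avoiding
    result is accepted, otherwise the parent is returned.
    """
    L = conf.length
    if not 0 <= i < L:
        raise IndexError(f"pull index {i} out of range")
    coords = list(conf.coords)
    spec = conf.spec

    directions = []
    if i < L - 1:
        directions.append("fwd")
    if i > 0:
        directions.append("rev")
    rng.shuffle(directions)
    for d in directions:
        if d == "fwd":
            candidates = _pull_candidates(coords, i, spec)
        else:
            rev = list(reversed(coords))
            candidates = [list(reversed(t))
                          for t in _pull_candidates(rev, L - 1 - i, spec)]
        rng.shuffle(candidates)
        for trial in candidates:
            res = _finish(conf, seq, trial, "pull")
            if res.accepted:
                return res
    return MutationResult(conf, "pull", False, 0)


# ---------------------------------------------------------------------------
# Dispatch
# ---------------------------------------------------------------------------

def draw_plan(
    seq: HPSequence,
    conf_length: int,
    rng: random.Random,
    motif_prob: float = 0.5,
    sites: list[MotifSite] | None = None,
) -> MutationPlan:
    """Sample one mutation plan: a motif rewrite with probability
    ``motif_prob`` when the sequence offers sites, else a corner or pull
    move at a random residue."""
    if sites is None:
        sites = find_motif_sites(seq)
    if sites and rng.random() < motif_prob:
        site = rng.choice(sites)
        return MutationPlan(operator=site.kind, site=site)
    if rng.random() < 0.5 and conf_length >= 3:
        return MutationPlan(operator="corner", index=rng.randrange(1, conf_length - 1))
    return MutationPlan(operator="pull", index=rng.randrange(conf_length))


def apply_plan(
    conf: Conformation, seq: HPSequence, plan: MutationPlan, rng: random.Random
) -> MutationResult:
    if plan.operator in ("helix_down", "helix_up"):
        return apply_helix(conf, seq, plan.site)
    if plan.operator == "sheet":
        return apply_sheet(conf, seq, plan.site)
    if plan.operator == "corner":
        return corner_move(conf, seq, plan.index, rng)
    if plan.operator == "pull":
        return pull_move(conf, seq, plan.index, rng)
    raise ValueError(f"unknown operator {plan.operator!r}")


def mutate(
    conf: Conformation,
    seq: HPSequence,
    rng: random.Random,
    motif_prob: float = 0.5,
    sites: list[MotifSite] | None = None,
    plan: MutationPlan | None = None,
) -> MutationResult:
    """One operator attempt on one parent.

    ``plan`` may pin the operator and target (tournament sets mutate every
    member identically); otherwise a fresh plan is drawn.
    """
    if plan is None:
        plan = draw_plan(seq, conf.length, rng, motif_prob=motif_prob, sites=sites)
    return apply_plan(conf, seq, plan, rng)
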