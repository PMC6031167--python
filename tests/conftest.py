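"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately written from scratch (explicit contact
vector sets, O(L^2) pair loops, full move-string enumeration) so they
cross-check the package implementation rather than restating it.
"""
from __future__ import annotations

import random
from itertools import combinations, product

import pytest

from hpfold import SQUARE, TRI6, TRI8, parse_hp_notation

# contact neighbourhoods written out literally, independent of the package
CONTACTS = {
    "square": {(1, 0), (-1, 0), (0, 1), (0, -1)},
    "tri8": {(1, 0), (-1, 0), (0, 1), (0, -1), (1, 1), (-1, 1), (-1, -1), (1, -1)},
    "tri6": {(1, 0), (-1, 0), (0, 1), (0, -1), (1, 1), (-1, -1)},
}


def brute_energy(coords, residues, lattice_name="square"):
    """Independent O(L^2) pair enumeration of the HP contact energy."""
    contacts = CONTACTS[lattice_name]
    e = 0
    for i, j in combinations(range(len(coords)), 2):
        if j > i + 1 and residues[i] == residues[j] == "H":
            d = (coords[j][0] - coords[i][0], coords[j][1] - coords[i][1])
            if d in contacts:
                e -= 1
    return e


def naive_optimum(residues, lattice_name="square"):
    """Ground-state energy by enumerating *all* move strings (no symmetry
    reduction, no pruning beyond the SAW check).  Exponential; tiny L only."""
    steps = {
        "square": [(1, 0), (-1, 0), (0, 1), (0, -1)],
        "tri8": [(1, 0), (-1, 0), (0, 1), (0, -1), (1, 1), (-1, 1), (-1, -1), (1, -1)],
        "tri6": [(1, 0), (-1, 0), (0, 1), (0, -1), (1, 1), (-1, -1)],
    }[lattice_name]
    L = len(residues)
    best = 0
    for moves in product(steps, repeat=L - 1):
        x = y = 0
        coords = [(0, 0)]
        for dx, dy in moves:
            x, y = x + dx, y + dy
            coords.append((x, y))
        if len(set(coords)) != L:
            continue
        best = min(best, brute_energy(coords, residues, lattice_name))
    return best


def random_hp(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("HP") for _ in range(length))


@pytest.fixture
def rng():
    return random.Random(20240901)


@pytest.fixture(params=["square", "tri8", "tri6"])
def lattice(request):
    return {"square": SQUARE, "tri8": TRI8, "tri6": TRI6}[request.param]


@pytest.fixture
def seq20():
    """The 20-mer whose showcase conformation is used in several tests."""
    return parse_hp_notation("3H2P2(HP)H2P2(HP)H2PH", "prefix")
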