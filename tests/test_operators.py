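"""Variation operators: motif detection, structural rewrites, local moves."""
import random

import pytest

from hpfold import (
    SQUARE,
    TRI8,
    apply_helix,
    apply_sheet,
    corner_move,
    decode,
    exhaustive_optimum,
    find_motif_sites,
    guided_conformation,
    mutate,
    parse_hp_notation,
    pull_move,
)
from hpfold.lattice import fitness
from hpfold.operators import MotifSite, draw_plan

from conftest import random_hp


def straight(seq, spec=SQUARE):
    return decode(("F",) * (seq.length - 1), spec)


class TestMotifDetection:
    def test_downward_helix_pattern(self):
        assert find_motif_sites("PPHPPHPP") == [MotifSite("helix_down", 0, 8)]

    def test_upward_helix_pattern(self):
        assert find_motif_sites("HPPHHPPH") == [MotifSite("helix_up", 0, 8)]

    def test_sheet_runs_are_maximal(self):
        assert find_motif_sites("HHHH") == [MotifSite("sheet", 0, 4)]
        assert find_motif_sites("PPHHHHHPP") == [MotifSite("sheet", 2, 5)]

    def test_no_sites(self):
        assert find_motif_sites("HPHP") == []

    def test_sites_do_not_overlap(self):
        sites = find_motif_sites("PPHPPHPPHHHPPHPPHPP")
        spans = [(s.start, s.start + s.span) for s in sites]
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            assert a1 <= b0


class TestHelixAndSheet:
    def test_helix_on_straight_chain_is_accepted(self):
        seq = parse_hp_notation("PPHPPHPP")
        conf = straight(seq)
        site = find_motif_sites(seq)[0]
        res = apply_helix(conf, seq, site)
        assert res.accepted and res.offspring.valid
        assert res.operator_used == "helix_down"
        assert res.offspring.moves != conf.moves

    def test_helix_is_idempotent(self):
        seq = parse_hp_notation("PPHPPHPP")
        site = find_motif_sites(seq)[0]
        once = apply_helix(straight(seq), seq, site)
        twice = apply_helix(once.offspring, seq, site)
        assert twice.accepted
        assert twice.offspring.moves == once.offspring.moves
        assert twice.delta_energy == 0

    def test_helix_preserves_validity_on_random_parents(self, rng):
        seq = parse_hp_notation("H" + "PPHPPHPP" + "HPH")
        sites = [s for s in find_motif_sites(seq) if s.kind.startswith("helix")]
        assert sites and sites[0].start == 1
        for _ in range(200):
            conf = guided_conformation(seq, SQUARE, rng)
            res = apply_helix(conf, seq, sites[0])
            if res.accepted:
                assert res.offspring.valid

    def test_sheet_straightens_run(self):
        seq = parse_hp_notation("PHHHHP")
        conf = guided_conformation(seq, SQUARE, random.Random(3))
        site = [s for s in find_motif_sites(seq) if s.kind == "sheet"][0]
        res = apply_sheet(conf, seq, site)
        if res.accepted:
            segment = res.offspring.moves[site.start : site.start + site.span - 1]
            assert len(set(segment)) == 1  # extended strand

    def test_sheet_on_straight_chain_is_identity(self):
        seq = parse_hp_notation("HHHHH")
        conf = straight(seq)
        site = find_motif_sites(seq)[0]
        res = apply_sheet(conf, seq, site)
        assert res.accepted and res.offspring.moves == conf.moves

    def test_kind_and_range_checks(self):
        seq = parse_hp_notation("PPHPPHPP")
        conf = straight(seq)
        with pytest.raises(ValueError):
            apply_helix(conf, seq, MotifSite("sheet", 0, 3))
        with pytest.raises(ValueError):
            apply_sheet(conf, seq, MotifSite("helix_up", 0, 8))
        with pytest.raises(IndexError):
            apply_helix(conf, seq, MotifSite("helix_up", 4, 8))

    def test_triangular_helix_template(self):
        seq = parse_hp_notation("PPHPPHPP")
        conf = straight(seq, TRI8)
        res = apply_helix(conf, seq, find_motif_sites(seq)[0])
        assert res.accepted and res.offspring.valid


class TestCornerMove:
    def test_forced_corner_flip(self):
        seq = parse_hp_notation("HHH")
        conf = decode("FU", SQUARE)  # (0,0),(1,0),(1,1)
        res = corner_move(conf, seq, 1, random.Random(0))
        assert res.accepted
        assert res.offspring.coords[1] == (0, 1)

    def test_collinear_triple_rejected(self):
        seq = parse_hp_notation("HHH")
        res = corner_move(decode("FF", SQUARE), seq, 1, random.Random(0))
        assert not res.accepted
        assert res.offspring.coords == decode("FF", SQUARE).coords

    def test_index_bounds(self):
        seq = parse_hp_notation("HHH")
        conf = decode("FU", SQUARE)
        for i in (0, 2, -1, 5):
            with pytest.raises(IndexError):
                corner_move(conf, seq, i, random.Random(0))


class TestPullMove:
    def test_end_pull_on_straight_chain(self):
        seq = parse_hp_notation("5H")
        conf = straight(seq)
        rng = random.Random(1)
        res = pull_move(conf, seq, seq.length - 1, rng)
        assert res.accepted
        # the freed end sits one step from its chain neighbour
        end, nb = res.offspring.coords[-1], res.offspring.coords[-2]
        assert (abs(end[0] - nb[0]), abs(end[1] - nb[1])) in {(1, 0), (0, 1)}

    def test_interior_pull_keeps_chain_connected(self, rng, lattice):
        seq = parse_hp_notation(random_hp(rng, 14))
        steps = set(lattice.step_vectors.values())
        for _ in range(300):
            conf = guided_conformation(seq, lattice, rng)
            res = pull_move(conf, seq, rng.randrange(seq.length), rng)
            if res.accepted:
                assert res.offspring.valid
                for a, b in zip(res.offspring.coords, res.offspring.coords[1:]):
                    assert (b[0] - a[0], b[1] - a[1]) in steps

    def test_index_bounds(self):
        seq = parse_hp_notation("4H")
        with pytest.raises(IndexError):
            pull_move(straight(seq), seq, 4, random.Random(0))

    def test_pull_moves_reach_the_ground_state(self):
        """Repeated pull/corner moves from a straight chain find the exact
        optimum of short sequences (neighbourhood reachability)."""
        for s, seed in [("HPHPPHH", 3), ("HHPHHPHH", 4)]:
            seq = parse_hp_notation(s)
            target, _ = exhaustive_optimum(seq, SQUARE)
            rng = random.Random(seed)
            conf = straight(seq)
            best = fitness(conf.coords, seq.residues, SQUARE)
            for _ in range(4000):
                i = rng.randrange(seq.length)
                res = (corner_move(conf, seq, i, rng)
                       if 0 < i < seq.length - 1 and rng.random() < 0.5
                       else pull_move(conf, seq, i, rng))
                if res.accepted:
                    conf = res.offspring
                    best = max(best, fitness(conf.coords, seq.residues, SQUARE))
                if -best == target:
                    break
            assert -best == target


class TestMutateDispatch:
    def test_no_motifs_uses_local_moves(self, rng):
        seq = parse_hp_notation("HPHP")
        conf = guided_conformation(seq, SQUARE, rng)
        used = {mutate(conf, seq, rng).operator_used for _ in range(50)}
        assert used <= {"corner", "pull"} and used

    def test_motif_rich_with_full_probability(self, rng):
        seq = parse_hp_notation("PPHPPHPPHHHH")
        conf = guided_conformation(seq, SQUARE, rng)
        used = {mutate(conf, seq, rng, motif_prob=1.0).operator_used for _ in range(50)}
        assert used <= {"helix_down", "helix_up", "sheet"} and used

    def test_accepted_offspring_are_always_valid(self, rng, lattice):
        seq = parse_hp_notation(random_hp(rng, 18))
        for _ in range(400):
            conf = guided_conformation(seq, lattice, rng)
            res = mutate(conf, seq, rng)
            if res.accepted:
                assert res.offspring.valid
                f0 = fitness(conf.coords, seq.residues, lattice)
                f1 = fitness(res.offspring.coords, seq.residues, lattice)
                assert res.delta_energy == f0 - f1
            else:
                assert res.offspring.coords == conf.coords

    def test_plan_reuse_is_deterministic(self, rng):
        seq = parse_hp_notation("HPHPPHHP")
        conf = guided_conformation(seq, SQUARE, rng)
        plan = draw_plan(seq, conf.length, random.Random(5))
        a = mutate(conf, seq, random.Random(9), plan=plan)
        b = mutate(conf, seq, random.Random(9), plan=plan)
        assert a.offspring.coords == b.offspring.coords
        assert a.operator_used == b.operator_used == plan.operator
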