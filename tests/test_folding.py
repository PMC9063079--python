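"""Restricted folding: DP vs exhaustive oracle, constraints, transformations."""

import dataclasses
import random

import pytest

from covafold.energy_model import density_ok, structure_energy
from covafold.folding import (
    brute_force_mfe,
    extract_relaxed_stems,
    open_outer_pairs,
    restricted_pk_mfe,
    restricted_pkfree_mfe,
)
from covafold.guide import GuideStructure, empty_guide
from covafold.msa_io import any_crossing, parse_dotbracket, render_dotbracket

from conftest import random_guide, random_sequence


def h_type_instance():
    """Guide hairpin whose loop pairs with the 3' tail: the optimum crosses."""
    seq = "GGGGGGGUCCUCCCCC"
    guide = GuideStructure(length=16, pairs=frozenset({(0, 9), (1, 8)}))
    return seq, guide


def kissing_instance():
    """Two guide hairpins joined by a loop-loop helix (three-band chain)."""
    seq = list("N" * 18)
    pairs = {(0, 7), (1, 6), (10, 17), (11, 16)}
    for i, j in pairs:
        seq[i], seq[j] = "A", "U"
    for x, y in [(2, 15), (3, 14), (4, 13), (5, 12)]:
        seq[x], seq[y] = "G", "C"
    seq[8] = seq[9] = "A"
    return "".join(seq), GuideStructure(length=18, pairs=frozenset(pairs))


class TestPkfreeAgainstBruteForce:
    def test_short_hairpin_equals_enumeration(self, params):
        res = restricted_pkfree_mfe("GGGAAACCC", empty_guide(9), params)
        bf = brute_force_mfe("GGGAAACCC", params=params)
        assert render_dotbracket(res.structure) == "(((...)))"
        assert res.energy == pytest.approx(bf.energy)

    def test_forced_unpaired_position_honored(self, params):
        guide = GuideStructure(length=9, unpaired=frozenset({0}))
        res = restricted_pkfree_mfe("GGGAAACCC", guide, params)
        bf = brute_force_mfe("GGGAAACCC", guide, params=params)
        assert res.energy == pytest.approx(bf.energy)
        assert all(0 not in p for p in res.structure.pairs)

    def test_guide_matching_unconstrained_optimum_changes_nothing(self, params):
        guide = GuideStructure.from_string("(((...)))".replace(".", "_"))
        res = restricted_pkfree_mfe("GGGAAACCC", guide, params)
        free = restricted_pkfree_mfe("GGGAAACCC", empty_guide(9), params)
        assert res.energy == pytest.approx(free.energy)
        assert res.structure == free.structure

    def test_random_instances_match_oracle(self, params):
        rng = random.Random(101)
        for _ in range(80):
            n = rng.randint(8, 14)
            seq = random_sequence(rng, n)
            guide = random_guide(rng, seq)
            dp = restricted_pkfree_mfe(seq, guide, params)
            bf = brute_force_mfe(seq, guide, params=params)
            assert dp.energy == pytest.approx(bf.energy, abs=1e-9)
            assert guide.pairs <= dp.structure.pairs
            assert not any_crossing(dp.structure.pairs)


class TestPkAgainstExhaustiveSearch:
    def test_h_type_crosses_and_matches_exhaustive(self, params):
        seq, guide = h_type_instance()
        dp = restricted_pk_mfe(seq, guide, params)
        bf = brute_force_mfe(seq, guide, allow_crossing=True, params=params)
        pkfree = restricted_pkfree_mfe(seq, guide, params)
        assert any_crossing(dp.structure.pairs)
        assert dp.energy == pytest.approx(bf.energy, abs=1e-9)
        assert dp.energy <= pkfree.energy

    def test_kissing_hairpin_chain_matches_exhaustive(self, params):
        seq, guide = kissing_instance()
        dp = restricted_pk_mfe(seq, guide, params)
        bf = brute_force_mfe(seq, guide, allow_crossing=True, params=params)
        assert any_crossing(dp.structure.pairs)
        assert dp.energy == pytest.approx(bf.energy, abs=1e-9)

    def test_empty_guide_reduces_to_pkfree(self, params):
        rng = random.Random(5)
        for _ in range(5):
            seq = random_sequence(rng, 20)
            pk = restricted_pk_mfe(seq, empty_guide(20), params)
            free = restricted_pkfree_mfe(seq, empty_guide(20), params)
            assert pk.energy == pytest.approx(free.energy)

    def test_random_instances_with_soft_penalties(self, params):
        # lighter pseudoknot penalties make crossing optima frequent, which
        # exercises the chain recursion rather than the nested fallback
        soft = dataclasses.replace(params, pk_init=2.0, pk_band=0.3, pk_unpaired=0.05)
        rng = random.Random(55)
        crossing_seen = 0
        for _ in range(50):
            n = rng.randint(10, 15)
            seq = random_sequence(rng, n, "GCGCAU")
            guide = random_guide(rng, seq, x_rate=0.05)
            dp = restricted_pk_mfe(seq, guide, soft)
            bf = brute_force_mfe(seq, guide, allow_crossing=True, params=soft)
            assert dp.energy == pytest.approx(bf.energy, abs=1e-9)
            assert density_ok(dp.structure.pairs)
            crossing_seen += any_crossing(bf.structure.pairs)
        assert crossing_seen >= 10

    def test_density_two_postcondition(self, params):
        rng = random.Random(77)
        for _ in range(20):
            seq = random_sequence(rng, rng.randint(15, 40), "GCGCAU")
            guide = random_guide(rng, seq, max_pairs=4)
            res = restricted_pk_mfe(seq, guide, params)
            assert density_ok(res.structure.pairs)
            assert guide.pairs <= res.structure.pairs
            assert not (
                {k for p in res.structure.pairs for k in p} & guide.unpaired
            )


class TestConstraintMonotonicity:
    def test_extra_constraints_never_lower_the_optimum(self, params):
        rng = random.Random(33)
        for _ in range(20):
            seq = random_sequence(rng, 25)
            base = restricted_pkfree_mfe(seq, empty_guide(25), params)
            guide = random_guide(rng, seq, max_pairs=2, x_rate=0.2)
            constrained = restricted_pkfree_mfe(seq, guide, params)
            assert constrained.energy >= base.energy - 1e-9

    def test_energy_equals_recomputed_structure_energy(self, params):
        rng = random.Random(44)
        for _ in range(10):
            seq = random_sequence(rng, 30, "GCGCAU")
            guide = random_guide(rng, seq)
            for fold in (restricted_pkfree_mfe, restricted_pk_mfe):
                res = fold(seq, guide, params)
                assert res.energy == pytest.approx(
                    structure_energy(seq, res.structure, params), abs=1e-6
                )


class TestBruteForce:
    def test_refuses_long_sequences(self, params):
        with pytest.raises(ValueError):
            brute_force_mfe("A" * 19, params=params)

    def test_no_pair_possible_gives_empty_structure(self, params):
        res = brute_force_mfe("ACGU", params=params)
        assert res.structure.pairs == frozenset()
        assert res.energy == 0.0

    def test_minimum_beats_every_enumerated_competitor(self, params):
        from covafold.folding import _enum_nested
        from covafold.msa_io import SecondaryStructure, is_canonical

        seq = "GGCGAAACGCC"
        res = brute_force_mfe(seq, params=params)
        for pairs in _enum_nested(
            0, len(seq) - 1, lambda i: True,
            lambda i, k: is_canonical(seq[i], seq[k]),
        ):
            e = structure_energy(
                seq, SecondaryStructure(length=len(seq), pairs=pairs), params
            )
            assert res.energy <= e + 1e-9

    def test_infeasible_guide_pair_dropped_with_warning(self, params, caplog):
        import logging

        caplog.set_level(logging.WARNING, logger="covafold.folding")
        guide = GuideStructure(length=9, pairs=frozenset({(0, 8)}))
        res = restricted_pkfree_mfe("GGGAAACCG", guide, params)  # G-G invalid
        assert (0, 8) not in res.structure.pairs
        assert any("infeasible guide pair" in r.message for r in caplog.records)


class TestRelaxedStems:
    def test_lone_pair_removed(self):
        st = parse_dotbracket("..(....)..")
        assert extract_relaxed_stems(st).pairs == frozenset()

    def test_bulged_helix_retained_whole(self):
        # 5 stacked pairs interrupted by a 1-base bulge remain one stem
        st = parse_dotbracket("((((.((...)).))))")
        stems = extract_relaxed_stems(st, min_len=3, max_interruption=2)
        assert stems.pairs == st.pairs

    def test_large_interruption_splits_the_chain(self):
        st = parse_dotbracket("((...........((((...))))...........))")
        stems = extract_relaxed_stems(st, min_len=3, max_interruption=2)
        assert stems.pairs == frozenset({(13, 23), (14, 22), (15, 21), (16, 20)})

    def test_empty_structure_gives_free_guide(self):
        from covafold.msa_io import SecondaryStructure

        stems = extract_relaxed_stems(SecondaryStructure(length=8))
        assert stems.to_string() == "________"


class TestOpenOuterPairs:
    def test_single_stem_loses_outer_pair(self):
        guide = GuideStructure.from_string("((___))")
        assert open_outer_pairs(guide).to_string() == "_(___)_"

    def test_each_disjoint_stem_opens(self):
        guide = GuideStructure.from_string("((___))_((___))")
        assert open_outer_pairs(guide).to_string() == "_(___)___(___)_"

    def test_empty_guide_unchanged(self):
        guide = GuideStructure.from_string("____x___")
        opened = open_outer_pairs(guide)
        assert opened.pairs == frozenset()
        assert opened.unpaired == guide.unpaired
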