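"""Guide construction and per-sequence projection."""

import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from covafold.covariation import MIMatrix, adjusted_mutual_information
from covafold.guide import (
    GuideStructure,
    build_alignment_guide,
    empty_guide,
    guide_from_covariation,
    project_guide,
    restricted_unpaired_columns,
    select_intermediary_pairs,
    threshold_sweep,
)
from covafold.msa_io import MIN_HAIRPIN_LOOP, Alignment, any_crossing


def mim_from_scores(n_a, scores, grand_avg=0.0, mi=None):
    mip = np.zeros((n_a, n_a))
    for (a, b), s in scores.items():
        mip[a, b] = mip[b, a] = s
    mi_m = np.zeros((n_a, n_a)) if mi is None else mi
    return MIMatrix(
        n_a=n_a, mi=mi_m, apc=mi_m - mip, mip=mip,
        col_avg=np.zeros(n_a), grand_avg=grand_avg,
    )


class TestSelectIntermediaryPairs:
    def test_greedy_rejects_column_reuse(self):
        # the highest score takes its columns; (2,12) then loses column 2
        mim = mim_from_scores(14, {(2, 10): 1.2, (2, 12): 0.9, (5, 12): 0.8})
        accepted = select_intermediary_pairs(mim, threshold=0.4)
        assert [p for p, _ in accepted] == [(2, 10), (5, 12)]

    def test_all_below_threshold_gives_empty_set(self):
        mim = mim_from_scores(10, {(0, 8): 0.4, (1, 7): 0.2})  # strict >
        assert select_intermediary_pairs(mim, threshold=0.4) == []

    def test_min_span_excludes_local_pairs(self):
        mim = mim_from_scores(10, {(0, 3): 1.5, (0, 8): 1.0})
        assert [p for p, _ in select_intermediary_pairs(mim)] == [(0, 8)]

    def test_deterministic_under_ties(self):
        scores = {(0, 5): 0.9, (1, 6): 0.9, (2, 7): 0.9}
        mim = mim_from_scores(8, scores)
        runs = [select_intermediary_pairs(mim) for _ in range(3)]
        assert runs[0] == runs[1] == runs[2]
        assert [p for p, _ in runs[0]] == [(0, 5), (1, 6), (2, 7)]

    def test_raising_threshold_never_adds_pairs(self):
        rng = np.random.default_rng(0)
        m = rng.random((20, 20)) * 1.5
        m = (m + m.T) / 2
        mim = mim_from_scores(20, {})
        mim.mip[:, :] = m
        prev = None
        for thr, accepted in threshold_sweep(mim):
            pairs = {p for p, _ in accepted}
            if prev is not None:
                assert pairs <= prev
            prev = pairs


class TestRestrictedUnpaired:
    def test_zero_mi_column_below_positive_mean(self):
        mi = np.zeros((10, 10))
        mi[0, 8] = mi[8, 0] = 1.0  # drives grand_avg above 0
        mim = mim_from_scores(10, {}, grand_avg=0.5, mi=mi)
        restricted = restricted_unpaired_columns(mim)
        assert 3 in restricted and 0 not in restricted

    def test_maximally_covarying_column_never_restricted(self):
        mi = np.zeros((10, 10))
        mi[2, 9] = mi[9, 2] = 2.0
        mim = mim_from_scores(10, {}, grand_avg=1.99, mi=mi)
        assert 2 not in restricted_unpaired_columns(mim)

    def test_matches_naive_scan(self):
        rng = np.random.default_rng(1)
        m = rng.random((15, 15))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        g = 0.45
        mim = mim_from_scores(15, {}, grand_avg=g, mi=m)
        expected = {
            a
            for a in range(15)
            if max(m[a, z] for z in range(15) if z != a) < g
        }
        assert restricted_unpaired_columns(mim) == expected


class TestBuildGuide:
    def test_states_rendered(self):
        guide = build_alignment_guide([((0, 9), 1.0)], {4}, 10)
        assert guide.to_string() == "(___x____)"

    def test_crossing_resolved_by_score(self):
        guide = build_alignment_guide([((0, 7), 1.0), ((3, 11), 0.8)], set(), 12)
        assert guide.pairs == frozenset({(0, 7)})
        assert not any_crossing(guide.pairs)

    def test_max_weight_resolution_can_prefer_two_pairs(self):
        # the 1.0 arc crosses both 0.7 arcs; greedy keeps it, max-weight
        # prefers the two non-crossing 0.7 arcs
        pairs = [((4, 12), 1.0), ((0, 8), 0.7), ((9, 16), 0.7)]
        greedy = build_alignment_guide(pairs, set(), 18, "greedy")
        maxw = build_alignment_guide(pairs, set(), 18, "max-weight")
        assert greedy.pairs == frozenset({(4, 12)})
        assert maxw.pairs == frozenset({(0, 8), (9, 16)})

    def test_pair_wins_over_restriction(self):
        guide = build_alignment_guide([((1, 8), 1.0)], {1, 5}, 10)
        assert guide.pairs == frozenset({(1, 8)})
        assert guide.unpaired == frozenset({5})

    def test_empty_inputs_give_all_free(self):
        assert build_alignment_guide([], set(), 6).to_string() == "______"


class TestProjectGuide:
    def test_gap_shrinks_hairpin_below_minimum(self):
        guide = GuideStructure.from_string("(___)")
        seq, projected = project_guide(guide, "AC-GU")
        assert seq == "ACGU"
        assert projected.pairs == frozenset()

    def test_kept_pair_and_x_on_gapless_row(self):
        guide = GuideStructure.from_string("(___x___)")
        seq, projected = project_guide(guide, "AAAAGAAAU")
        assert projected.pairs == frozenset({(0, 8)})
        assert projected.unpaired == frozenset({4})

    def test_gap_at_paired_column_orphans_partner(self):
        guide = GuideStructure.from_string("(______)")
        seq, projected = project_guide(guide, "-ACGUACG")
        assert seq == "ACGUACG"
        assert projected.pairs == frozenset()

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            project_guide(empty_guide(5), "ACGUAC")


@st.composite
def guides_and_rows(draw):
    n_a = draw(st.integers(8, 30))
    pairs = set()
    used = set()
    for _ in range(draw(st.integers(0, 5))):
        i = draw(st.integers(0, n_a - 6))
        j = draw(st.integers(i + 5, n_a - 1))
        if i in used or j in used:
            continue
        if any_crossing(pairs | {(i, j)}):
            continue
        pairs.add((i, j))
        used.update((i, j))
    unpaired = {
        k for k in range(n_a) if k not in used and draw(st.booleans())
    }
    guide = GuideStructure(length=n_a, pairs=frozenset(pairs), unpaired=frozenset(unpaired))
    row = "".join(
        draw(st.sampled_from(["A", "C", "G", "U", "-"])) for _ in range(n_a)
    )
    return guide, row


@settings(derandomize=True, max_examples=150)
@given(guides_and_rows())
def test_projection_preserves_guide_invariants(gr):
    guide, row = gr
    seq, projected = project_guide(guide, row)
    assert projected.length == len(seq) == sum(c != "-" for c in row)
    for i, j in projected.pairs:
        assert j - i > MIN_HAIRPIN_LOOP
    assert not any_crossing(projected.pairs)
    assert not ({k for p in projected.pairs for k in p} & projected.unpaired)


def test_guide_from_covariation_on_covarying_alignment():
    rows = []
    rng = random.Random(7)
    choices = [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")]
    for _ in range(24):
        row = list("AAAACAAAAACAAAA")
        x, y = rng.choice(choices)
        w, z = rng.choice(choices)
        row[0], row[14] = x, y
        row[2], row[9] = w, z
        rows.append("".join(row))
    aln = Alignment(ids=tuple(map(str, range(24))), rows=tuple(rows))
    guide = guide_from_covariation(adjusted_mutual_information(aln))
    assert {(0, 14), (2, 9)} <= set(guide.pairs)
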