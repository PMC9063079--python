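"""Covariation statistics against independent per-definition oracles."""

import math
import random

import numpy as np
import pytest

from covafold.covariation import (
    APC_MIN_SEPARATION,
    MIMatrix,
    adjusted_mutual_information,
    average_product_correction,
    mutual_information,
    pair_frequencies,
    write_mip_tsv,
)
from covafold.msa_io import Alignment

CANONICAL = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


def make_aln(rows):
    return Alignment(ids=tuple(f"s{i}" for i in range(len(rows))), rows=tuple(rows))


def random_alignment(rng, n, n_a):
    return make_aln(
        ["".join(rng.choice("ACGU-") for _ in range(n_a)) for _ in range(n)]
    )


# -- independent oracles (plain double loops over the definitions) ----------


def oracle_mi(aln, a, b):
    n = aln.n
    joint = {}
    ca = {}
    cb = {}
    for row in aln.rows:
        x, y = row[a], row[b]
        if x != "-":
            ca[x] = ca.get(x, 0) + 1
        if y != "-":
            cb[y] = cb.get(y, 0) + 1
        if (x, y) in CANONICAL:
            joint[(x, y)] = joint.get((x, y), 0) + 1
    total = 0.0
    for (x, y), c in joint.items():
        fj = c / n
        total += fj * math.log2(fj / ((ca[x] / n) * (cb[y] / n)))
    return max(total, 0.0)


def oracle_apc(mi):
    n_a = mi.shape[0]
    col = np.zeros(n_a)
    for a in range(n_a):
        s = 0.0
        for z in range(n_a):
            if abs(a - z) > APC_MIN_SEPARATION:
                s += mi[a, z]
        col[a] = s / (n_a - 1)
    g = 0.0
    for w in range(n_a):
        for z in range(w + 1, n_a):
            if abs(w - z) > APC_MIN_SEPARATION:
                g += mi[w, z]
    g *= 2.0 / (n_a * (n_a - 1))
    apc = np.zeros((n_a, n_a))
    if g != 0.0:
        for a in range(n_a):
            for b in range(n_a):
                apc[a, b] = col[a] * col[b] / g
    return col, g, apc


class TestPairFrequencies:
    def test_uniform_canonical_columns(self):
        aln = make_aln(["AU", "UA", "GC", "CG"])
        fj, fa, fb = pair_frequencies(aln, 0, 1)
        assert fj == {("A", "U"): 0.25, ("U", "A"): 0.25, ("G", "C"): 0.25, ("C", "G"): 0.25}

    def test_no_canonical_combination(self):
        aln = make_aln(["AC", "AC"])
        fj, fa, fb = pair_frequencies(aln, 0, 1)
        assert fj == {}
        assert fa == {"A": 1.0}

    def test_gapped_rows_carry_no_joint_mass(self):
        # columns (A,-,A) vs (U,U,U): rows 1 and 3 form A-U; marginals / N
        aln = make_aln(["AU", "-U", "AU"])
        fj, fa, fb = pair_frequencies(aln, 0, 1)
        assert fj == {("A", "U"): pytest.approx(2 / 3)}
        assert fa == {"A": pytest.approx(2 / 3)}
        assert fb == {"U": pytest.approx(1.0)}


class TestMutualInformation:
    def test_maximal_covariation_is_two_bits(self):
        aln = make_aln(["AU", "UA", "GC", "CG"])
        assert mutual_information(aln)[0, 1] == pytest.approx(2.0, abs=1e-12)

    def test_conserved_canonical_pair_carries_no_information(self):
        aln = make_aln(["AU"] * 4)
        assert mutual_information(aln)[0, 1] == 0.0

    def test_matches_oracle_on_mixed_alignment(self):
        rng = random.Random(0)
        aln = random_alignment(rng, 8, 6)
        mi = mutual_information(aln)
        for a in range(6):
            for b in range(6):
                if a != b:
                    assert mi[a, b] == pytest.approx(oracle_mi(aln, a, b), abs=1e-12)

    def test_range_and_symmetry(self):
        rng = random.Random(1)
        for _ in range(10):
            aln = random_alignment(rng, rng.randint(2, 10), rng.randint(2, 12))
            mi = mutual_information(aln)
            assert (mi >= 0).all() and (mi <= 2 + 1e-12).all()
            assert np.allclose(mi, mi.T)
            assert np.allclose(np.diag(mi), 0.0)


class TestAverageProductCorrection:
    def test_matches_naive_loops_on_random_matrix(self):
        rng = np.random.default_rng(2)
        m = rng.random((12, 12))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        col, g, apc = average_product_correction(m)
        ocol, og, oapc = oracle_apc(m)
        assert np.allclose(col, ocol, atol=1e-12)
        assert g == pytest.approx(og, abs=1e-12)
        assert np.allclose(apc, oapc, atol=1e-12)

    def test_constant_mi_gives_vanishing_mip_in_the_limit(self):
        # MI(a,b) = c for all |a-b| > 3: column averages approach the grand
        # average as n_a grows, so APC -> c and MIp -> 0
        c = 0.8
        errors = {}
        for n_a in (60, 240):
            m = np.full((n_a, n_a), c)
            offs = np.abs(np.subtract.outer(np.arange(n_a), np.arange(n_a)))
            m[offs <= APC_MIN_SEPARATION] = 0.0
            _, _, apc = average_product_correction(m)
            far = offs > APC_MIN_SEPARATION
            errors[n_a] = np.abs(apc[far] / c - 1.0).mean()
        assert errors[60] < 0.12
        assert errors[240] < errors[60] / 3  # O(1/n_a) convergence

    def test_all_zero_mi_degenerates_cleanly(self):
        _, g, apc = average_product_correction(np.zeros((8, 8)))
        assert g == 0.0
        assert not apc.any()


class TestAdjustedMutualInformation:
    def test_mip_is_mi_minus_apc_exactly(self):
        rng = random.Random(3)
        aln = random_alignment(rng, 9, 14)
        mim = adjusted_mutual_information(aln)
        assert np.array_equal(mim.mip, mim.mi - mim.apc)
        assert np.allclose(mim.mip, mim.mip.T)

    def test_single_covarying_pair_attains_max_mip(self):
        rng = random.Random(4)
        n = 12
        # columns 2 and 9 perfectly covary; all others conserved
        pairs = [rng.choice([("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")]) for _ in range(n)]
        rows = []
        for x, y in pairs:
            row = list("AAGGCCUUGGAA")
            row[2], row[9] = x, y
            rows.append("".join(row))
        mim = adjusted_mutual_information(make_aln(rows))
        iu = np.triu_indices(12, 1)
        best = np.argmax(mim.mip[iu])
        assert (iu[0][best], iu[1][best]) == (2, 9)

    def test_full_matrix_matches_oracles(self):
        rng = random.Random(5)
        aln = random_alignment(rng, 10, 15)
        mim = adjusted_mutual_information(aln)
        omi = np.zeros((15, 15))
        for a in range(15):
            for b in range(15):
                if a != b:
                    omi[a, b] = oracle_mi(aln, a, b)
        ocol, og, oapc = oracle_apc(omi)
        assert np.allclose(mim.mi, omi, atol=1e-12)
        assert np.allclose(mim.apc, oapc, atol=1e-12)
        assert np.allclose(mim.mip, omi - oapc, atol=1e-12)


def test_tsv_export(tmp_path):
    aln = make_aln(["AU", "UA", "GC", "CG"])
    mim = adjusted_mutual_information(aln)
    out = tmp_path / "mip.tsv"
    write_mip_tsv(mim, out)
    lines = out.read_text().strip().splitlines()
    assert lines[0] == "a\tb\tMI\tAPC\tMIp"
    assert lines[1].startswith("1\t2\t2.000000")
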