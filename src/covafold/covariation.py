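"""Column-pair covariation statistics: MI, APC and MIp.

Mutual information between two alignment columns is the usual sum
``f_ab(x,y) * log2(f_ab(x,y) / (f_a(x) f_b(y)))`` in bits, restricted to
the six canonical base pairs (A-U, U-A, G-C, C-G, G-U, U-G): non-valid
residue combinations — including anything involving a gap — contribute no
term.  All frequencies are plain counts over the N alignment rows:
``f_a(x)`` is the frequency of base x in column a, and the joint likewise.
Restricting the sum can in principle leave a slightly negative total
(canonical combinations rarer than independence predicts); such estimates
carry no pairing signal and are floored at 0, keeping MI within [0, 2].
Two conserved columns always score 0, even when they pair in every
sequence — the statistic sees covariation, not complementarity.

The average product correction (APC) estimates the background (random plus
phylogenetic) component of MI for a column pair as the product of the two
column-average MIs over the grand average; the adjusted score is
``MIp = MI - APC``.  Column averages exclude near-diagonal terms
(|a - z| <= 3), which are replaced by zero while the stated denominators
(n_a - 1, and 2 / (n_a (n_a - 1))) are kept as printed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from covafold.msa_io import Alignment, CANONICAL_PAIRS

logger = logging.getLogger(__name__)

BASES = "ACGU"
_BASE_INDEX = {b: k for k, b in enumerate(BASES)}

#: Offset beyond which column pairs contribute to the APC averages.
APC_MIN_SEPARATION = 3


@dataclass(frozen=True)
class MIMatrix:
    """MI, APC and MIp matrices (bits) for one alignment.

    ``col_avg[a]`` is the average MI of column ``a`` against all columns at
    offset > 3, and ``grand_avg`` the corresponding alignment-wide average;
    both feed the APC.  All matrices are symmetric with zero diagonal.
    """

    n_a: int
    mi: np.ndarray
    apc: np.ndarray
    mip: np.ndarray
    col_avg: np.ndarray
    grand_avg: float


def pair_frequencies(
    aln: Alignment, a: int, b: int
) -> tuple[dict[tuple[str, str], float], dict[str, float], dict[str, float]]:
    """Joint (canonical combinations only) and marginal frequencies at
    columns ``a``, ``b``, all normalized by the number of rows N.

    Absent keys mean frequency 0; gaps are not bases, so a fully gapped
    column has all-zero marginals.  Joint mass is collected only for rows
    whose residue combination is one of the six canonical pairs.
    """
    col_a = aln.column(a)
    col_b = aln.column(b)
    n = aln.n
    joint: dict[tuple[str, str], int] = {}
    ca: dict[str, int] = {}
    cb: dict[str, int] = {}
    for x, y in zip(col_a, col_b):
        if x != "-":
            ca[x] = ca.get(x, 0) + 1
        if y != "-":
            cb[y] = cb.get(y, 0) + 1
        if (x, y) in CANONICAL_PAIRS:
            joint[(x, y)] = joint.get((x, y), 0) + 1
    fj = {k: v / n for k, v in joint.items()}
    fa = {k: v / n for k, v in ca.items()}
    fb = {k: v / n for k, v in cb.items()}
    return fj, fa, fb


def _encode(aln: Alignment) -> np.ndarray:
    """Rows as int codes: A,C,G,U -> 0..3, gap -> 4."""
    mapping = {b: k for k, b in enumerate(BASES)}
    mapping["-"] = 4
    return np.array([[mapping[c] for c in row] for row in aln.rows], dtype=np.int8)


# canonical-pair lookup on (code_a, code_b); 5x5 grid, gap row/col all False
_CANON = np.zeros((5, 5), dtype=bool)
for _x, _y in CANONICAL_PAIRS:
    _CANON[_BASE_INDEX[_x], _BASE_INDEX[_y]] = True


def mutual_information(aln: Alignment) -> np.ndarray:
    """Symmetric matrix of MI(a, b) in bits; diagonal is 0."""
    codes = _encode(aln)
    n = aln.n
    n_a = aln.n_a
    # per-column base frequencies (gaps excluded from counts, / N)
    marg = np.zeros((n_a, 4))
    for k in range(4):
        marg[:, k] = (codes == k).sum(axis=0) / n
    mi = np.zeros((n_a, n_a))
    for a in range(n_a):
        ca = codes[:, a]
        fa = marg[a]
        for b in range(a + 1, n_a):
            cb = codes[:, b]
            keep = _CANON[ca, cb]
            if not keep.any():
                continue
            counts = np.bincount(ca[keep] * 4 + cb[keep], minlength=16).reshape(4, 4)
            fj = counts / n
            nz = fj > 0
            denom = np.outer(fa, marg[b])
            val = float(np.sum(fj[nz] * np.log2(fj[nz] / denom[nz])))
            mi[a, b] = mi[b, a] = max(val, 0.0)
    return mi


def average_product_correction(
    mi: np.ndarray,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Column averages, grand average and the APC matrix.

    Terms at column offset <= 3 are replaced by zero in both averages; the
    denominators remain (n_a - 1) and 2 / (n_a (n_a - 1)).  A zero grand
    average (no covariation signal at all) defines APC as identically zero.
    """
    n_a = mi.shape[0]
    if mi.shape != (n_a, n_a):
        raise ValueError("MI matrix must be square")
    masked = mi.copy()
    offsets = np.abs(np.subtract.outer(np.arange(n_a), np.arange(n_a)))
    masked[offsets <= APC_MIN_SEPARATION] = 0.0
    if n_a > 1:
        col_avg = masked.sum(axis=1) / (n_a - 1)
        grand_avg = float(masked.sum() / (n_a * (n_a - 1)))
    else:
        col_avg = np.zeros(1)
        grand_avg = 0.0
    if grand_avg == 0.0:
        logger.info("grand-average MI is 0; APC defined as 0 everywhere")
        apc = np.zeros_like(mi)
    else:
        apc = np.outer(col_avg, col_avg) / grand_avg
    return col_avg, grand_avg, apc


def adjusted_mutual_information(aln: Alignment) -> MIMatrix:
    """Full covariation summary: MI, APC and MIp = MI - APC."""
    mi = mutual_information(aln)
    col_avg, grand_avg, apc = average_product_correction(mi)
    return MIMatrix(
        n_a=aln.n_a,
        mi=mi,
        apc=apc,
        mip=mi - apc,
        col_avg=col_avg,
        grand_avg=grand_avg,
    )


def write_mip_tsv(mim: MIMatrix, path: str | Path) -> None:
    """Export column-pair scores as TSV (1-based indices, upper triangle)."""
    with open(path, "w") as fh:
        fh.write("a\tb\tMI\tAPC\tMIp\n")
        for a in range(mim.n_a):
            for b in range(a + 1, mim.n_a):
                fh.write(
                    f"{a + 1}\t{b + 1}\t{mim.mi[a, b]:.6f}\t"
                    f"{mim.apc[a, b]:.6f}\t{mim.mip[a, b]:.6f}\n"
                )


def mi_oracle(aln: Alignment, a: int, b: int) -> float:
    """Naive per-definition MI for one column pair (test oracle).

    Independent of the vectorized :func:`mutual_information`: counts with
    plain Python dictionaries and applies the defining sum directly.
    """
    fj, fa, fb = pair_frequencies(aln, a, b)
    total = 0.0
    for (x, y), f in fj.items():
        if f > 0:
            total += f * math.log2(f / (fa[x] * fb[y]))
    return max(total, 0.0)
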