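"""Base-pair accuracy metrics and the resampling significance test.

Sensitivity, PPV and F-measure are computed over exact base-pair identity.
The *adjusted* variant excludes *compatible* predicted pairs from the
false positives: a predicted pair i.j absent from the reference is
inconsistent only if the reference pairs i or j with some other partner;
otherwise it contradicts nothing and is not penalized.

The significance test is the printed resampling procedure: both score
vectors are resampled with replacement to their own sizes, the difference
of means is recomputed, and the p-value is the proportion of resampled
differences at least as large as the observed one.  On constant vectors
this literal procedure is degenerate (every resampled difference equals
the observed one, so p = 1); a conventional label-permutation test with a
two-sided tail is available as ``method="permutation"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from covafold.msa_io import MIN_HAIRPIN_LOOP, SecondaryStructure, is_canonical

SIGNIFICANCE_LEVEL = 0.05
DEFAULT_REPS = 10_000


@dataclass(frozen=True)
class EvaluationScores:
    tp: int
    fp: int
    fn: int
    sensitivity: float
    ppv: float
    f_measure: float
    adjusted: bool


def clean_reference(
    seq: str, ref: SecondaryStructure
) -> SecondaryStructure:
    """Drop non-canonical reference pairs (hairpins < 3 cannot be
    represented at all and are rejected at construction)."""
    pairs = frozenset(
        (i, j) for i, j in ref.pairs if is_canonical(seq[i], seq[j])
    )
    return SecondaryStructure(length=ref.length, pairs=pairs)


def confusion_counts(
    ref: SecondaryStructure, pred: SecondaryStructure, adjusted: bool = False
) -> tuple[int, int, int]:
    """(TP, FP, FN) over exact base-pair identity.

    In adjusted mode, predicted pairs that are neither in the reference nor
    inconsistent with it (no endpoint paired differently in the reference)
    are excluded from the false positives.
    """
    if ref.length != pred.length:
        raise ValueError("reference/prediction length mismatch")
    tp = len(ref.pairs & pred.pairs)
    fn = len(ref.pairs - pred.pairs)
    extra = pred.pairs - ref.pairs
    if not adjusted:
        fp = len(extra)
    else:
        ref_partner = ref.partner
        fp = sum(
            1
            for i, j in extra
            if i in ref_partner or j in ref_partner
        )
    return tp, fp, fn


def scores(
    ref: SecondaryStructure, pred: SecondaryStructure, adjusted: bool = False
) -> EvaluationScores:
    """Sensitivity, PPV and F-measure from the confusion counts.

    An empty reference compared against an empty prediction is vacuously
    perfect (all rates 1); F is 0 whenever PPV or sensitivity is 0.
    """
    tp, fp, fn = confusion_counts(ref, pred, adjusted)
    if tp == fp == fn == 0:
        sen = ppv = f = 1.0
    else:
        sen = tp / (tp + fn) if tp + fn else 1.0
        ppv = tp / (tp + fp) if tp + fp else 1.0
        f = 2 * ppv * sen / (ppv + sen) if ppv > 0 and sen > 0 else 0.0
    return EvaluationScores(tp, fp, fn, sen, ppv, f, adjusted)


def permutation_test(
    f1,
    f2,
    reps: int = DEFAULT_REPS,
    seed: int | np.random.Generator | None = None,
    method: str = "bootstrap",
) -> float:
    """Significance of the difference in mean F-measure between two methods.

    ``method="bootstrap"`` (default) is the literal resampling procedure:
    t_s = mean(f1) - mean(f2); each vector is resampled with replacement to
    its own size, t'_s recomputed, and p = #(t'_s >= t_s) / reps.
    ``method="permutation"`` pools the scores, permutes the labels and uses
    the two-sided tail #(|t'_s| >= |t_s|) / reps.
    """
    f1 = np.asarray(f1, dtype=float)
    f2 = np.asarray(f2, dtype=float)
    if f1.size == 0 or f2.size == 0:
        raise ValueError("score vectors must be non-empty")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t_s = f1.mean() - f2.mean()
    if method == "bootstrap":
        s1 = rng.choice(f1, size=(reps, f1.size), replace=True).mean(axis=1)
        s2 = rng.choice(f2, size=(reps, f2.size), replace=True).mean(axis=1)
        return float(np.mean(s1 - s2 >= t_s))
    if method == "permutation":
        pool = np.concatenate([f1, f2])
        count = 0
        for _ in range(reps):
            perm = rng.permutation(pool)
            t = perm[: f1.size].mean() - perm[f1.size :].mean()
            if abs(t) >= abs(t_s):
                count += 1
        return count / reps
    raise ValueError(f"unknown method {method!r}")


def is_significant(p_value: float, alpha: float = SIGNIFICANCE_LEVEL) -> bool:
    return p_value < alpha
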