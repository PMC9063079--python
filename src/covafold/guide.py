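"""Guide-structure construction from covariation scores.

A guide structure assigns each position one of four states: part of a
forced base pair (``(`` / ``)``), forced unpaired (``x``), or free (``_``).
At alignment level the guide collects *intermediary base pairs* — high-MIp,
non-conflicting column pairs — and *restricted unpaired* columns whose
maximum MI falls below the alignment-wide mean.  Projection onto one row
deletes its gap columns, drops orphaned pairs and removes pairs whose
hairpin loop shrank below the minimum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from covafold.covariation import MIMatrix
from covafold.msa_io import MIN_HAIRPIN_LOOP, SecondaryStructure, any_crossing, pairs_cross

logger = logging.getLogger(__name__)

DEFAULT_MIP_THRESHOLD = 0.4

#: Minimum candidate span b - a, consistent with hairpin loops >= 3.
DEFAULT_MIN_SPAN = 4


@dataclass
class GuideStructure:
    """Per-position constraints for restricted energy minimization.

    ``pairs`` is a pseudoknot-free set of forced pairs (0-based);
    ``unpaired`` holds forced-unpaired positions; everything else is free.
    ``source_scores`` carries the MIp score that selected each pair, when
    the guide came from covariation.
    """

    length: int
    pairs: frozenset[tuple[int, int]] = field(default_factory=frozenset)
    unpaired: frozenset[int] = field(default_factory=frozenset)
    source_scores: dict[tuple[int, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pairs = frozenset(tuple(p) for p in self.pairs)
        self.unpaired = frozenset(self.unpaired)
        seen: set[int] = set()
        for i, j in self.pairs:
            if not (0 <= i < j < self.length):
                raise ValueError(f"guide pair ({i + 1},{j + 1}) out of range")
            if i in seen or j in seen:
                raise ValueError(f"position in guide pair ({i + 1},{j + 1}) reused")
            seen.update((i, j))
        if seen & self.unpaired:
            clash = sorted(seen & self.unpaired)[0]
            raise ValueError(f"position {clash + 1} both paired and forced-unpaired")
        if any_crossing(self.pairs):
            raise ValueError("guide pair set must be pseudoknot-free")

    @property
    def partner(self) -> dict[int, int]:
        d: dict[int, int] = {}
        for i, j in self.pairs:
            d[i] = j
            d[j] = i
        return d

    def to_string(self) -> str:
        chars = ["_"] * self.length
        for i, j in self.pairs:
            chars[i] = "("
            chars[j] = ")"
        for k in self.unpaired:
            chars[k] = "x"
        return "".join(chars)

    @classmethod
    def from_string(cls, s: str) -> "GuideStructure":
        stack: list[int] = []
        pairs: set[tuple[int, int]] = set()
        unpaired: set[int] = set()
        for pos, ch in enumerate(s):
            if ch == "(":
                stack.append(pos)
            elif ch == ")":
                if not stack:
                    raise ValueError(f"unbalanced ')' at position {pos + 1}")
                pairs.add((stack.pop(), pos))
            elif ch == "x":
                unpaired.add(pos)
            elif ch in "._-":
                continue
            elif ch != "_":
                raise ValueError(f"illegal guide character {ch!r}")
        if stack:
            raise ValueError("unbalanced '(' in guide string")
        return cls(length=len(s), pairs=frozenset(pairs), unpaired=frozenset(unpaired))


def empty_guide(length: int) -> GuideStructure:
    return GuideStructure(length=length)


def select_intermediary_pairs(
    mim: MIMatrix,
    threshold: float = DEFAULT_MIP_THRESHOLD,
    min_span: int = DEFAULT_MIN_SPAN,
) -> list[tuple[tuple[int, int], float]]:
    """Greedy selection of non-conflicting high-MIp column pairs.

    Candidates are column pairs with ``MIp > threshold`` (strict) and span
    ``b - a >= min_span``, sorted by MIp descending (ties broken by (a, b)
    ascending for determinism); a candidate is accepted iff both columns
    are still unpaired.  The result may contain crossing pairs; crossing
    resolution happens in :func:`build_alignment_guide`.
    """
    n_a = mim.n_a
    candidates = [
        ((a, b), float(mim.mip[a, b]))
        for a in range(n_a)
        for b in range(a + min_span, n_a)
        if mim.mip[a, b] > threshold
    ]
    candidates.sort(key=lambda item: (-item[1], item[0]))
    taken: set[int] = set()
    accepted: list[tuple[tuple[int, int], float]] = []
    for (a, b), score in candidates:
        if a not in taken and b not in taken:
            accepted.append(((a, b), score))
            taken.update((a, b))
    return accepted


def restricted_unpaired_columns(mim: MIMatrix, use_mip: bool = False) -> set[int]:
    """Columns unlikely to pair: max MI over partners below the mean MI.

    Uses the raw MI matrix and the alignment-wide average that also feeds
    the APC; ``use_mip=True`` switches the maxima to MIp scores instead.
    """
    matrix = mim.mip if use_mip else mim.mi
    n_a = mim.n_a
    restricted: set[int] = set()
    for a in range(n_a):
        row = np.delete(matrix[a], a) if n_a > 1 else np.array([0.0])
        if float(row.max()) < mim.grand_avg:
            restricted.add(a)
    return restricted


def _max_noncrossing_subset(
    scored: list[tuple[tuple[int, int], float]],
) -> list[tuple[tuple[int, int], float]]:
    """Maximum-weight non-crossing subset (interval DP over arcs)."""
    if not scored:
        return []
    # O(k^2) DP over pairs sorted by right endpoint: weighted interval
    # scheduling generalized to nesting is overkill here; with at most a few
    # dozen intermediary pairs a simple exact branch-and-bound suffices.
    arcs = sorted(scored, key=lambda it: it[0])
    best: list[tuple[tuple[int, int], float]] = []
    best_w = -1.0

    def rec(idx: int, chosen: list, w: float, remaining: float) -> None:
        nonlocal best, best_w
        if w + remaining <= best_w:
            return
        if idx == len(arcs):
            if w > best_w:
                best, best_w = list(chosen), w
            return
        pair, score = arcs[idx]
        rest = remaining - score
        if all(not pairs_cross(pair, p) for p, _ in chosen):
            chosen.append(arcs[idx])
            rec(idx + 1, chosen, w + score, rest)
            chosen.pop()
        rec(idx + 1, chosen, w, rest)

    rec(0, [], 0.0, sum(s for _, s in arcs))
    return best


def build_alignment_guide(
    pairs: list[tuple[tuple[int, int], float]],
    restricted: set[int],
    n_a: int,
    crossing_resolution: str = "greedy",
) -> GuideStructure:
    """Combine intermediary pairs and restricted columns into a guide.

    The guide must be pseudoknot-free: crossing conflicts among accepted
    pairs are resolved by keeping the higher-MIp pair (``greedy``, score
    order with deterministic tie-breaks) or by the maximum non-crossing
    weight subset (``max-weight``).  A restricted column that is also an
    endpoint of a kept pair loses its restriction — pairs carry direct
    covariation evidence — with a warning.
    """
    if crossing_resolution == "max-weight":
        kept = _max_noncrossing_subset(pairs)
    elif crossing_resolution == "greedy":
        kept = []
        for pair, score in sorted(pairs, key=lambda it: (-it[1], it[0])):
            if all(not pairs_cross(pair, p) for p, _ in kept):
                kept.append((pair, score))
            else:
                logger.debug(
                    "dropping crossing intermediary pair (%d,%d)",
                    pair[0] + 1,
                    pair[1] + 1,
                )
    else:
        raise ValueError(f"unknown crossing_resolution {crossing_resolution!r}")
    pair_set = frozenset(p for p, _ in kept)
    endpoints = {k for p in pair_set for k in p}
    overlap = restricted & endpoints
    if overlap:
        logger.warning(
            "%d restricted-unpaired column(s) are intermediary pair endpoints; "
            "the pairs win",
            len(overlap),
        )
    return GuideStructure(
        length=n_a,
        pairs=pair_set,
        unpaired=frozenset(restricted - endpoints),
        source_scores={p: s for p, s in kept},
    )


def guide_from_covariation(
    mim: MIMatrix,
    threshold: float = DEFAULT_MIP_THRESHOLD,
    min_span: int = DEFAULT_MIN_SPAN,
    use_restricted: bool = True,
    crossing_resolution: str = "greedy",
) -> GuideStructure:
    """Alignment-level guide: intermediary pairs plus restricted columns."""
    accepted = select_intermediary_pairs(mim, threshold=threshold, min_span=min_span)
    restricted = restricted_unpaired_columns(mim) if use_restricted else set()
    return build_alignment_guide(
        accepted, restricted, mim.n_a, crossing_resolution=crossing_resolution
    )


def project_guide(
    guide: GuideStructure, row: str
) -> tuple[str, GuideStructure]:
    """Project an alignment-level guide onto one aligned row.

    Gap columns are deleted from both the sequence and the guide; a pair
    with a gapped endpoint is dropped entirely (the surviving endpoint
    becomes free), and pairs whose hairpin loop shrank below
    ``MIN_HAIRPIN_LOOP`` after gap removal are removed.
    """
    if len(row) != guide.length:
        raise ValueError("row length does not match guide length")
    new_index: dict[int, int] = {}
    seq_chars: list[str] = []
    for col, ch in enumerate(row):
        if ch != "-":
            new_index[col] = len(seq_chars)
            seq_chars.append(ch)
    pairs: set[tuple[int, int]] = set()
    scores: dict[tuple[int, int], float] = {}
    for i, j in guide.pairs:
        if i in new_index and j in new_index:
            ni, nj = new_index[i], new_index[j]
            if nj - ni > MIN_HAIRPIN_LOOP:
                pairs.add((ni, nj))
                if (i, j) in guide.source_scores:
                    scores[(ni, nj)] = guide.source_scores[(i, j)]
    unpaired = frozenset(new_index[k] for k in guide.unpaired if k in new_index)
    projected = GuideStructure(
        length=len(seq_chars),
        pairs=frozenset(pairs),
        unpaired=unpaired,
        source_scores=scores,
    )
    return "".join(seq_chars), projected


def guide_as_structure(guide: GuideStructure) -> SecondaryStructure:
    """View the guide's forced pairs as a plain structure (for scoring)."""
    return SecondaryStructure(length=guide.length, pairs=guide.pairs)


def threshold_sweep(
    mim: MIMatrix,
    thresholds: np.ndarray | None = None,
    min_span: int = DEFAULT_MIN_SPAN,
) -> list[tuple[float, list[tuple[tuple[int, int], float]]]]:
    """Intermediary pair sets across a threshold grid (default -0.2..1.5 by 0.1)."""
    if thresholds is None:
        thresholds = np.round(np.arange(-0.2, 1.5001, 0.1), 10)
    return [
        (float(t), select_intermediary_pairs(mim, threshold=float(t), min_span=min_span))
        for t in thresholds
    ]
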