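"""Restricted minimum-free-energy folding under a guide structure.

Two exact optimizers share one engine: :func:`restricted_pkfree_mfe` adds a
nested layer to the guide (the union stays pseudoknot-free) and
:func:`restricted_pk_mfe` adds a disjoint pseudoknot-free layer that may
cross the guide, producing a density-2 structure.  Both force every guide
pair into the result and never pair a forced-unpaired position.
:func:`brute_force_mfe` is an exhaustive-enumeration oracle for small
sequences, and :func:`extract_relaxed_stems` / :func:`open_outer_pairs`
are the guide transformations used by the relaxed-minimization paths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator

from covafold._dp import MAXLOOP, Engine  # noqa: F401  (MAXLOOP re-exported)
from covafold.energy_model import (
    INF,
    EnergyParameters,
    default_parameters,
    density_ok,
    structure_energy,
)
from covafold.guide import GuideStructure, empty_guide
from covafold.msa_io import MIN_HAIRPIN_LOOP, SecondaryStructure, is_canonical

logger = logging.getLogger(__name__)

BRUTE_FORCE_CAP = 18

ENERGY_TOL = 1e-6


class FoldingError(RuntimeError):
    """Raised when no structure satisfies the folding constraints."""


@dataclass
class FoldResult:
    """Outcome of one restricted fold."""

    structure: SecondaryStructure
    energy: float
    guide_pairs_retained: frozenset[tuple[int, int]] = field(default_factory=frozenset)
    method_tag: str = ""


def _sanitize_guide(seq: str, guide: GuideStructure | None) -> GuideStructure:
    if guide is None:
        return empty_guide(len(seq))
    if guide.length != len(seq):
        raise ValueError("guide length does not match sequence length")
    bad = [
        (i, j)
        for i, j in guide.pairs
        if not is_canonical(seq[i], seq[j]) or j - i <= MIN_HAIRPIN_LOOP
    ]
    if not bad:
        return guide
    for i, j in bad:
        logger.warning(
            "dropping infeasible guide pair (%d,%d): %s-%s",
            i + 1,
            j + 1,
            seq[i],
            seq[j],
        )
    return GuideStructure(
        length=guide.length,
        pairs=guide.pairs - frozenset(bad),
        unpaired=guide.unpaired,
        source_scores={
            p: s for p, s in guide.source_scores.items() if p not in bad
        },
    )


def _finish(
    seq: str,
    guide: GuideStructure,
    params: EnergyParameters,
    engine: Engine,
    tag: str,
) -> FoldResult:
    if engine.energy == INF:
        raise FoldingError(f"no structure satisfies the guide constraints ({tag})")
    pairs = engine.traceback() | set(guide.pairs)
    st = SecondaryStructure(length=len(seq), pairs=frozenset(pairs))
    recomputed = structure_energy(seq, st, params)
    if abs(recomputed - engine.energy) > ENERGY_TOL:
        raise AssertionError(
            f"traceback energy mismatch ({tag}): dp={engine.energy:.6f} "
            f"recomputed={recomputed:.6f}"
        )
    st.energy = engine.energy
    return FoldResult(
        structure=st,
        energy=engine.energy,
        guide_pairs_retained=frozenset(guide.pairs),
        method_tag=tag,
    )


def restricted_pkfree_mfe(
    seq: str,
    guide: GuideStructure | None = None,
    params: EnergyParameters | None = None,
) -> FoldResult:
    """Minimum-energy pseudoknot-free structure containing all guide pairs.

    O(n^3) time, O(n^2) space.  Guide pairs that are non-canonical for this
    sequence are dropped with a warning rather than failing the fold.
    """
    params = params or default_parameters()
    guide = _sanitize_guide(seq, guide)
    engine = Engine(seq, guide, params, pk=False)
    engine.fill()
    return _finish(seq, guide, params, engine, "pkfree")


def restricted_pk_mfe(
    seq: str,
    guide: GuideStructure | None = None,
    params: EnergyParameters | None = None,
) -> FoldResult:
    """Minimum-energy density-2 structure: guide plus a disjoint
    pseudoknot-free layer that may cross the guide.

    With an empty guide no crossing component can form (both layers would
    have to come from the added pseudoknot-free set), so the result then
    coincides with :func:`restricted_pkfree_mfe`.
    """
    params = params or default_parameters()
    guide = _sanitize_guide(seq, guide)
    engine = Engine(seq, guide, params, pk=True)
    engine.fill()
    result = _finish(seq, guide, params, engine, "pk")
    if not density_ok(result.structure.pairs):
        raise AssertionError("pk fold violated the density-2 contract")
    return result


# ---------------------------------------------------------------------------
# exhaustive oracle
# ---------------------------------------------------------------------------


def _enum_nested(
    i: int,
    j: int,
    may_unpair,
    may_pair,
) -> Iterator[frozenset[tuple[int, int]]]:
    """All pseudoknot-free pair sets on [i..j] under the given predicates."""
    if i > j:
        yield frozenset()
        return
    if may_unpair(i):
        yield from _enum_nested(i + 1, j, may_unpair, may_pair)
    for k in range(i + MIN_HAIRPIN_LOOP + 1, j + 1):
        if not may_pair(i, k):
            continue
        for inner in _enum_nested(i + 1, k - 1, may_unpair, may_pair):
            for outer in _enum_nested(k + 1, j, may_unpair, may_pair):
                yield inner | outer | {(i, k)}


def brute_force_mfe(
    seq: str,
    guide: GuideStructure | None = None,
    allow_crossing: bool = False,
    params: EnergyParameters | None = None,
) -> FoldResult:
    """Exhaustive-enumeration fold for test oracles (n <= 18).

    Enumerates every structure satisfying the same constraints as the
    corresponding DP (guide pairs forced, forced-unpaired respected,
    canonical pairs, hairpins >= 3; with ``allow_crossing``, every
    base-disjoint pseudoknot-free added layer whose union with the guide
    passes the density-2 check).  Ties are broken lexicographically on the
    sorted pair list.
    """
    n = len(seq)
    if n > BRUTE_FORCE_CAP:
        raise ValueError(f"brute force capped at n = {BRUTE_FORCE_CAP}, got {n}")
    params = params or default_parameters()
    guide = _sanitize_guide(seq, guide)
    gpartner = guide.partner
    forb = guide.unpaired

    def nested_unpair(i: int) -> bool:
        return i not in gpartner

    def nested_pair(i: int, k: int) -> bool:
        if i in forb or k in forb or not is_canonical(seq[i], seq[k]):
            return False
        if gpartner.get(i, k) != k or gpartner.get(k, i) != i:
            return False
        return True

    def layer_pair(i: int, k: int) -> bool:
        return (
            i not in gpartner
            and k not in gpartner
            and i not in forb
            and k not in forb
            and is_canonical(seq[i], seq[k])
        )

    candidates: set[frozenset[tuple[int, int]]] = set()
    if allow_crossing:
        for layer in _enum_nested(0, n - 1, lambda i: True, layer_pair):
            union = layer | guide.pairs
            if density_ok(union):
                candidates.add(frozenset(union))
    else:
        candidates.update(_enum_nested(0, n - 1, nested_unpair, nested_pair))

    best: tuple[float, list[tuple[int, int]]] | None = None
    for pairs in candidates:
        st = SecondaryStructure(length=n, pairs=pairs)
        e = structure_energy(seq, st, params)
        if e == INF:
            continue
        key = (e, sorted(pairs))
        if best is None or key < best:
            best = key
    if best is None:
        raise FoldingError("no feasible structure in brute-force enumeration")
    st = SecondaryStructure(length=n, pairs=frozenset(best[1]), energy=best[0])
    return FoldResult(
        structure=st,
        energy=best[0],
        guide_pairs_retained=frozenset(guide.pairs),
        method_tag="brute" + ("-pk" if allow_crossing else ""),
    )


# ---------------------------------------------------------------------------
# guide transformations for the relaxed paths
# ---------------------------------------------------------------------------


def _nesting_children(
    pairs: list[tuple[int, int]],
) -> tuple[dict[tuple[int, int], list[tuple[int, int]]], list[tuple[int, int]]]:
    """Direct-children map and root list of a pseudoknot-free pair forest."""
    children: dict[tuple[int, int], list[tuple[int, int]]] = {p: [] for p in pairs}
    roots: list[tuple[int, int]] = []
    stack: list[tuple[int, int]] = []
    for pair in sorted(pairs):
        while stack and stack[-1][1] < pair[0]:
            stack.pop()
        if stack:
            children[stack[-1]].append(pair)
        else:
            roots.append(pair)
        stack.append(pair)
    return children, roots


def extract_relaxed_stems(
    st: SecondaryStructure,
    min_len: int = 3,
    max_interruption: int = 2,
) -> GuideStructure:
    """Keep only pairs in relaxed stable stems of a pseudoknot-free structure.

    A relaxed stem is a maximal chain of nested pairs where each pair is the
    sole branch of its predecessor and the two sides of the interruption
    between consecutive pairs are each at most ``max_interruption`` unpaired
    bases; stems shorter than ``min_len`` pairs are discarded.
    """
    if not st.is_pseudoknot_free():
        raise ValueError("relaxed-stem extraction expects a pseudoknot-free structure")
    children, roots = _nesting_children(sorted(st.pairs))
    kept: set[tuple[int, int]] = set()
    todo = list(roots)
    while todo:
        head = todo.pop()
        chain = [head]
        while True:
            kids = children[chain[-1]]
            if len(kids) != 1:
                todo.extend(kids)
                break
            (ci, cj) = kids[0]
            (pi, pj) = chain[-1]
            if ci - pi - 1 <= max_interruption and pj - cj - 1 <= max_interruption:
                chain.append((ci, cj))
            else:
                todo.append((ci, cj))
                break
        if len(chain) >= min_len:
            kept.update(chain)
    return GuideStructure(length=st.length, pairs=frozenset(kept))


def open_outer_pairs(guide: GuideStructure) -> GuideStructure:
    """Remove the exterior-most pair of each disjoint substructure.

    For every root of the guide's nesting forest the root pair is deleted
    (its endpoints become free); forced-unpaired marks are untouched.
    """
    _, roots = _nesting_children(sorted(guide.pairs))
    remaining = guide.pairs - frozenset(roots)
    return GuideStructure(
        length=guide.length,
        pairs=remaining,
        unpaired=guide.unpaired,
        source_scores={p: s for p, s in guide.source_scores.items() if p in remaining},
    )
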