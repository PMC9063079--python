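"""Synthetic alignments with planted consensus structures.

The generator emulates the covariation signal the method relies on:
compensatory mutations at planted base pairs keep the pair canonical while
changing both bases, leaving a detectable correlation between the two
columns, whereas unpaired columns mutate independently at a background
rate.  Single-column gaps exercise the guide-projection logic.  All
randomness flows through a seeded generator, so fixtures are fully
reproducible and no external data is needed anywhere in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from covafold.msa_io import (
    MIN_HAIRPIN_LOOP,
    Alignment,
    SecondaryStructure,
    parse_dotbracket,
)

CANONICAL = [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")]
BASES = "ACGU"

#: Default weights of the six canonical pairs at planted stems: GC-enriched
#: with a minor wobble fraction, as in real structured RNA helices.
DEFAULT_PAIR_WEIGHTS = (0.20, 0.20, 0.25, 0.25, 0.05, 0.05)

#: Default base composition of unpaired columns (A-rich, pairing-poor
#: loops, echoing real loop composition).
DEFAULT_LOOP_WEIGHTS = (0.45, 0.25, 0.10, 0.20)


@dataclass
class FixtureSpec:
    """Recipe for one synthetic alignment.

    ``consensus`` is a dot-bracket string (extra bracket layers allowed for
    a planted crossing layer); ``compensatory_rate`` is the per-sequence
    probability that a planted pair is jointly resampled to a random
    canonical pair, ``background_rate`` the per-position substitution
    probability elsewhere, and ``gap_rate`` the per-position deletion
    probability.  ``pair_distribution`` optionally reweights the six
    canonical pairs (order A-U, U-A, G-C, C-G, G-U, U-G).
    """

    n_sequences: int
    consensus: str
    compensatory_rate: float = 1.0
    background_rate: float = 0.05
    gap_rate: float = 0.0
    seed: int = 0
    pair_distribution: tuple[float, ...] = DEFAULT_PAIR_WEIGHTS
    loop_distribution: tuple[float, ...] = DEFAULT_LOOP_WEIGHTS

    def __post_init__(self) -> None:
        st = parse_dotbracket(self.consensus)  # validates balance and hairpins
        if self.n_sequences < 2:
            raise ValueError("need at least 2 sequences")
        if len(self.pair_distribution) != 6:
            raise ValueError("pair_distribution must have 6 weights")
        if len(self.loop_distribution) != 4:
            raise ValueError("loop_distribution must have 4 weights (A,C,G,U)")
        self._planted = st


def _project_structure(
    pairs: frozenset[tuple[int, int]], row: str
) -> SecondaryStructure:
    """Planted truth for one row: remove gap columns, orphaned pairs and
    pairs whose span shrank below the hairpin minimum."""
    new_index: dict[int, int] = {}
    count = 0
    for col, ch in enumerate(row):
        if ch != "-":
            new_index[col] = count
            count += 1
    projected = set()
    for i, j in pairs:
        if i in new_index and j in new_index:
            ni, nj = new_index[i], new_index[j]
            if nj - ni > MIN_HAIRPIN_LOOP:
                projected.add((ni, nj))
    return SecondaryStructure(length=count, pairs=frozenset(projected))


def synthesize_alignment(
    spec: FixtureSpec,
) -> tuple[Alignment, list[SecondaryStructure]]:
    """Generate an alignment and the per-sequence planted truth structures.

    A root sequence consistent with the planted pairs is drawn first; each
    aligned row then mutates it: planted pairs are jointly resampled to a
    canonical pair with probability ``compensatory_rate`` (else each
    endpoint substitutes independently at the background rate), unpaired
    columns substitute independently, and positions are deleted (gapped)
    at ``gap_rate``.  Truth structures are the planted pairs projected
    through each row's gaps, in ungapped coordinates.
    """
    rng = np.random.default_rng(spec.seed)
    planted = spec._planted
    n_a = planted.length
    pair_list = sorted(planted.pairs)
    paired_cols = {k for p in pair_list for k in p}
    pair_probs = np.asarray(spec.pair_distribution, dtype=float)
    pair_probs = pair_probs / pair_probs.sum()
    loop_probs = np.asarray(spec.loop_distribution, dtype=float)
    loop_probs = loop_probs / loop_probs.sum()

    def draw_pair() -> tuple[str, str]:
        return CANONICAL[int(rng.choice(6, p=pair_probs))]

    def draw_loop_base() -> str:
        return BASES[int(rng.choice(4, p=loop_probs))]

    root = [""] * n_a
    for i, j in pair_list:
        root[i], root[j] = draw_pair()
    for k in range(n_a):
        if k not in paired_cols:
            root[k] = draw_loop_base()

    rows: list[str] = []
    truths: list[SecondaryStructure] = []
    for _ in range(spec.n_sequences):
        row = list(root)
        for i, j in pair_list:
            if rng.random() < spec.compensatory_rate:
                row[i], row[j] = draw_pair()
            else:
                for k in (i, j):
                    if rng.random() < spec.background_rate:
                        row[k] = BASES[rng.integers(4)]
        for k in range(n_a):
            if k not in paired_cols and rng.random() < spec.background_rate:
                row[k] = draw_loop_base()
        if spec.gap_rate > 0:
            for k in range(n_a):
                if rng.random() < spec.gap_rate:
                    row[k] = "-"
        aligned = "".join(row)
        rows.append(aligned)
        truths.append(_project_structure(planted.pairs, aligned))
    ids = tuple(f"seq{k + 1}" for k in range(spec.n_sequences))
    return Alignment(ids=ids, rows=tuple(rows)), truths


#: Cloverleaf consensus used by the bundled tRNA-like fixture: acceptor
#: stem (7 bp), D stem (4 bp), anticodon stem (5 bp), T stem (5 bp).
TRNA_CONSENSUS = (
    "(((((((" "..((((" "........" "))))." "((((("
    "......." ")))))" "....." "(((((" "......." ")))))"
    ")))))))" "...."
)


def tRNA_like_fixture(
    n_sequences: int = 20, seed: int = 7
) -> tuple[Alignment, list[SecondaryStructure]]:
    """Small deterministic cloverleaf fixture for end-to-end tests."""
    spec = FixtureSpec(
        n_sequences=n_sequences,
        consensus=TRNA_CONSENSUS,
        compensatory_rate=1.0,
        background_rate=0.05,
        gap_rate=0.02,
        seed=seed,
    )
    return synthesize_alignment(spec)


def write_fixture(path_fasta, path_truth, aln: Alignment, truths) -> None:
    """Persist a fixture as aligned FASTA plus per-sequence truth file."""
    from covafold.msa_io import render_dotbracket

    with open(path_fasta, "w") as fh:
        for rid, row in zip(aln.ids, aln.rows):
            fh.write(f">{rid}\n{row}\n")
    with open(path_truth, "w") as fh:
        for rid, st in zip(aln.ids, truths):
            fh.write(f">{rid}\n{render_dotbracket(st)}\n")
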