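"""Aligned-FASTA and dot-bracket I/O.

Coordinates are 0-based half-open internally; all user-facing rendering
(error messages, prediction files, TSV exports) uses 1-based inclusive
positions.  Crossing base pairs are serialized with additional bracket
layers ``[]``, ``{}``, ``<>`` assigned greedily.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

RNA_ALPHABET = frozenset("ACGU-")
GAP_CHARS = frozenset(".-_")

#: The six canonical (Watson-Crick + wobble) base pairs.
CANONICAL_PAIRS = frozenset(
    [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")]
)

#: Minimum number of unpaired bases enclosed by a hairpin loop.
MIN_HAIRPIN_LOOP = 3

BRACKET_LAYERS = [("(", ")"), ("[", "]"), ("{", "}"), ("<", ">")]
_OPEN_TO_LAYER = {o: k for k, (o, _) in enumerate(BRACKET_LAYERS)}
_CLOSE_TO_LAYER = {c: k for k, (_, c) in enumerate(BRACKET_LAYERS)}


class AlignmentFormatError(ValueError):
    """Raised for malformed alignment or structure files."""


class AlignmentValidationError(ValueError):
    """Raised when a record contains residues outside {A,C,G,U,-}."""


def is_canonical(x: str, y: str) -> bool:
    return (x, y) in CANONICAL_PAIRS


@dataclass(frozen=True)
class Alignment:
    """A multiple RNA sequence alignment over the alphabet {A,C,G,U,-}."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.rows:
            raise AlignmentFormatError("alignment has no sequences")
        n_a = len(self.rows[0])
        if n_a < 1:
            raise AlignmentFormatError("alignment length must be >= 1")
        for rid, row in zip(self.ids, self.rows):
            if len(row) != n_a:
                raise AlignmentFormatError(
                    f"record {rid!r} has length {len(row)}, expected {n_a}"
                )
            for col, ch in enumerate(row):
                if ch not in RNA_ALPHABET:
                    raise AlignmentValidationError(
                        f"record {rid!r}, column {col + 1}: illegal residue {ch!r}"
                    )

    @property
    def n(self) -> int:
        """Number of sequences."""
        return len(self.rows)

    @property
    def n_a(self) -> int:
        """Alignment (column) length."""
        return len(self.rows[0])

    def column(self, a: int) -> str:
        return "".join(row[a] for row in self.rows)


def normalize_sequence(seq: str) -> str:
    """Uppercase, map T->U and any accepted gap character to '-'."""
    out = []
    for ch in seq.upper():
        if ch == "T":
            ch = "U"
        elif ch in GAP_CHARS:
            ch = "-"
        out.append(ch)
    return "".join(out)


def read_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA file into a normalized :class:`Alignment`.

    Rows are uppercased, ``T`` becomes ``U`` and ``.``/``_`` gaps become
    ``-``.  Unequal row lengths raise :class:`AlignmentFormatError`; any
    other residue (including IUPAC ambiguity codes) raises
    :class:`AlignmentValidationError` naming the record and column.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) < 2:
        raise AlignmentFormatError(
            f"{path}: need at least 2 aligned sequences, found {len(records)}"
        )
    ids = tuple(r.id for r in records)
    rows = tuple(normalize_sequence(str(r.seq)) for r in records)
    return Alignment(ids=ids, rows=rows)


@dataclass
class SecondaryStructure:
    """A set of base pairs over an ungapped sequence, possibly crossing.

    ``pairs`` holds 0-based ``(i, j)`` tuples with ``i < j``; each index
    participates in at most one pair and every pair spans at least
    ``MIN_HAIRPIN_LOOP + 1`` positions.  ``energy`` is a free energy in
    kcal/mol when known.
    """

    length: int
    pairs: frozenset[tuple[int, int]] = field(default_factory=frozenset)
    energy: float | None = None

    def __post_init__(self) -> None:
        self.pairs = frozenset(tuple(p) for p in self.pairs)
        seen: set[int] = set()
        for i, j in self.pairs:
            if not (0 <= i < j < self.length):
                raise ValueError(f"pair ({i + 1},{j + 1}) out of range 1..{self.length}")
            if j - i <= MIN_HAIRPIN_LOOP:
                raise ValueError(
                    f"pair ({i + 1},{j + 1}) encloses a hairpin loop of size "
                    f"{j - i - 1} < {MIN_HAIRPIN_LOOP}"
                )
            if i in seen or j in seen:
                raise ValueError(f"base in pair ({i + 1},{j + 1}) pairs more than once")
            seen.add(i)
            seen.add(j)

    @property
    def partner(self) -> dict[int, int]:
        d: dict[int, int] = {}
        for i, j in self.pairs:
            d[i] = j
            d[j] = i
        return d

    def is_pseudoknot_free(self) -> bool:
        return not any_crossing(self.pairs)

    def __eq__(self, other: object) -> bool:  # energy deliberately ignored
        if not isinstance(other, SecondaryStructure):
            return NotImplemented
        return self.length == other.length and self.pairs == other.pairs


def pairs_cross(p: tuple[int, int], q: tuple[int, int]) -> bool:
    """True if arcs p and q cross (i < i' < j < j' in either order)."""
    (i, j), (k, l) = sorted([p, q])
    return i < k < j < l


def any_crossing(pairs: Iterable[tuple[int, int]]) -> bool:
    ps = sorted(pairs)
    for a in range(len(ps)):
        for b in range(a + 1, len(ps)):
            if ps[b][0] >= ps[a][1]:
                break
            if pairs_cross(ps[a], ps[b]):
                return True
    return False


def parse_dotbracket(s: str) -> SecondaryStructure:
    """Parse dot-bracket notation with up to four bracket layers.

    Layers ``()``, ``[]``, ``{}`` and ``<>`` are matched independently, so
    pairs from different layers may cross.  ``.``, ``-`` and ``_`` all denote
    an unpaired position.
    """
    stacks: list[list[int]] = [[] for _ in BRACKET_LAYERS]
    pairs: set[tuple[int, int]] = set()
    for pos, ch in enumerate(s):
        if ch in _OPEN_TO_LAYER:
            stacks[_OPEN_TO_LAYER[ch]].append(pos)
        elif ch in _CLOSE_TO_LAYER:
            layer = _CLOSE_TO_LAYER[ch]
            if not stacks[layer]:
                raise AlignmentFormatError(
                    f"unbalanced {ch!r} at position {pos + 1} in {s!r}"
                )
            pairs.add((stacks[layer].pop(), pos))
        elif ch in (".", "-", "_"):
            continue
        else:
            raise AlignmentFormatError(f"illegal structure character {ch!r} in {s!r}")
    for layer, stack in enumerate(stacks):
        if stack:
            o = BRACKET_LAYERS[layer][0]
            raise AlignmentFormatError(
                f"unbalanced {o!r} at position {stack[-1] + 1} in {s!r}"
            )
    return SecondaryStructure(length=len(s), pairs=frozenset(pairs))


def render_dotbracket(st: SecondaryStructure) -> str:
    """Render a structure using the minimal greedy bracket-layer assignment.

    Pairs are visited in order of opening position; each is placed on the
    first layer where it crosses no previously placed pair of that layer.
    ``parse_dotbracket(render_dotbracket(st)) == st``.
    """
    chars = ["."] * st.length
    layers: list[list[tuple[int, int]]] = [[] for _ in BRACKET_LAYERS]
    for pair in sorted(st.pairs):
        for k, placed in enumerate(layers):
            if not any(pairs_cross(pair, q) for q in placed):
                placed.append(pair)
                chars[pair[0]] = BRACKET_LAYERS[k][0]
                chars[pair[1]] = BRACKET_LAYERS[k][1]
                break
        else:
            raise ValueError(
                f"structure needs more than {len(BRACKET_LAYERS)} bracket layers"
            )
    return "".join(chars)


def write_predictions(
    path: str | Path,
    records: Sequence[tuple[str, str, SecondaryStructure, float | None]],
) -> None:
    """Write prediction blocks: header, ungapped sequence, dot-bracket, energy."""
    with open(path, "w") as fh:
        _write_prediction_stream(fh, records)


def _write_prediction_stream(fh: io.TextIOBase, records) -> None:
    for rid, seq, st, energy in records:
        if len(seq) != st.length:
            raise ValueError(f"record {rid!r}: sequence/structure length mismatch")
        fh.write(f">{rid}\n{seq}\n{render_dotbracket(st)}\n")
        fh.write("ENERGY = %.2f kcal/mol\n" % energy if energy is not None else "\n")


def read_predictions(
    path: str | Path,
) -> list[tuple[str, str, SecondaryStructure, float | None]]:
    """Read a file written by :func:`write_predictions`."""
    out = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        if not lines[i].startswith(">"):
            raise AlignmentFormatError(f"{path}: expected header at line {i + 1}")
        rid = lines[i][1:].strip()
        seq = lines[i + 1].strip()
        st = parse_dotbracket(lines[i + 2].strip())
        energy = None
        i += 3
        if i < len(lines) and lines[i].startswith("ENERGY"):
            energy = float(lines[i].split("=")[1].split()[0])
            i += 1
        elif i < len(lines) and not lines[i].strip():
            i += 1
        out.append((rid, seq, st, energy))
    return out


def read_reference_structures(path: str | Path) -> list[tuple[str, SecondaryStructure]]:
    """Read reference dot-bracket structures, one per FASTA-style record.

    Accepts either ``>id`` / structure-line pairs, or ``>id`` / sequence /
    structure triples (the sequence line is ignored).
    """
    out = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    i = 0
    structure_chars = set(".-_()[]{}<>")
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise AlignmentFormatError(f"{path}: expected header at line {i + 1}")
        rid = lines[i][1:].strip()
        i += 1
        if i < len(lines) and not set(lines[i].strip()) <= structure_chars:
            i += 1  # sequence line
        if i >= len(lines):
            raise AlignmentFormatError(f"{path}: missing structure for {rid!r}")
        out.append((rid, parse_dotbracket(lines[i].strip())))
        i += 1
    return out
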