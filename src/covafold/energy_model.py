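"""Nearest-neighbor free-energy model with affine pseudoknot penalties.

The model is a deliberately compact Turner-style parameter set for 37 degC,
1 M NaCl: sequence-dependent stacking energies over the six canonical
pairs, length-dependent hairpin/bulge/internal loop tables with logarithmic
extrapolation and a Ninio-style asymmetry term, an affine multiloop cost,
and an affine pseudoknot cost (one initiation per crossing component, one
penalty per band, one small penalty per unpaired base inside a pseudoknot
loop).  Terminal mismatches, dangling ends and coaxial stacking are
omitted; bulge and internal loop energies depend on loop lengths only.
All parameters load from (and round-trip through) a sectioned plain-text
file, so an alternative table can be substituted wholesale.

Free energies are kcal/mol; geometrically or chemically disallowed loops
(hairpin shorter than three unpaired bases, a non-canonical pair) score
``INF``, a finite sentinel treated as +infinity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from covafold.msa_io import (
    MIN_HAIRPIN_LOOP,
    SecondaryStructure,
    is_canonical,
    pairs_cross,
)

#: Energy sentinel for disallowed configurations (never NaN).
INF = math.inf

PAIR_CODES = ("AU", "UA", "GC", "CG", "GU", "UG")

MAX_TABULATED_LOOP = 30

#: 1.75 * R * T at 310.15 K, the Jacobson-Stockmayer extrapolation slope.
LOOP_EXTRAPOLATION = 1.079


class ParameterError(ValueError):
    """Raised for missing or malformed energy parameters."""


@dataclass
class EnergyParameters:
    """A complete, validated parameter set.

    ``stack[(outer, inner)]`` is the energy of inner pair ``(i+1, j-1)``
    stacked under outer pair ``(i, j)``, both written 5'-base/3'-base.
    Loop tables are indexed by loop size (total unpaired bases) and
    extended past :data:`MAX_TABULATED_LOOP` logarithmically.
    """

    stack: dict[tuple[str, str], float]
    hairpin: dict[int, float]
    bulge: dict[int, float]
    internal: dict[int, float]
    internal_asymmetry: float
    internal_asymmetry_max: float
    ml_closing: float
    ml_branch: float
    ml_unpaired: float
    pk_init: float
    pk_band: float
    pk_unpaired: float
    loop_extrapolation: float = LOOP_EXTRAPOLATION
    temperature: str = "37C"

    def __post_init__(self) -> None:
        for outer in PAIR_CODES:
            for inner in PAIR_CODES:
                if (outer, inner) not in self.stack:
                    raise ParameterError(f"missing STACK entry {outer}/{inner}")
        for name, table, lo in (
            ("HAIRPIN", self.hairpin, MIN_HAIRPIN_LOOP),
            ("BULGE", self.bulge, 1),
            ("INTERNAL", self.internal, 2),
        ):
            for size in range(lo, MAX_TABULATED_LOOP + 1):
                if size not in table:
                    raise ParameterError(f"missing {name} entry for size {size}")


def _extrapolate(table: dict[int, float], size: int, coeff: float) -> float:
    if size <= MAX_TABULATED_LOOP:
        return table[size]
    return table[MAX_TABULATED_LOOP] + coeff * math.log(size / MAX_TABULATED_LOOP)


def hairpin_energy(params: EnergyParameters, size: int) -> float:
    """Hairpin loop of ``size`` unpaired bases; INF below the minimum."""
    if size < MIN_HAIRPIN_LOOP:
        return INF
    return _extrapolate(params.hairpin, size, params.loop_extrapolation)


def stack_energy(params: EnergyParameters, outer: str, inner: str) -> float:
    """Stack of canonical ``inner`` directly inside canonical ``outer``."""
    key = (outer, inner)
    if key not in params.stack:
        return INF
    return params.stack[key]


def internal_energy(params: EnergyParameters, n1: int, n2: int) -> float:
    """Bulge (one side empty) or internal loop with ``n1``/``n2`` unpaired."""
    if n1 < 0 or n2 < 0 or (n1 == 0 and n2 == 0):
        raise ValueError("not an internal loop context")
    if n1 == 0 or n2 == 0:
        return _extrapolate(params.bulge, n1 + n2, params.loop_extrapolation)
    base = _extrapolate(params.internal, n1 + n2, params.loop_extrapolation)
    asym = min(params.internal_asymmetry * abs(n1 - n2), params.internal_asymmetry_max)
    return base + asym


def multiloop_energy(params: EnergyParameters, branches: int, unpaired: int) -> float:
    """Affine multiloop cost; ``branches`` counts enclosed helices only."""
    return params.ml_closing + params.ml_branch * branches + params.ml_unpaired * unpaired


def pk_component_energy(
    params: EnergyParameters, n_bands: int, band_stack_sum: float, unpaired: int
) -> float:
    """One crossing component: initiation + per-band penalty + band stacks
    + per-unpaired-base penalty for bases lying directly in its loops."""
    return (
        params.pk_init
        + params.pk_band * n_bands
        + band_stack_sum
        + params.pk_unpaired * unpaired
    )


def loop_energy(kind: str, context: dict, params: EnergyParameters) -> float:
    """Uniform entry point over the loop kinds (mostly for tests/tools)."""
    if kind == "hairpin":
        return hairpin_energy(params, context["size"])
    if kind == "stack":
        return stack_energy(params, context["outer"], context["inner"])
    if kind in ("bulge", "internal"):
        return internal_energy(params, context["n1"], context["n2"])
    if kind == "multiloop-part":
        return multiloop_energy(params, context["branches"], context["unpaired"])
    if kind == "pk-part":
        return pk_component_energy(
            params,
            context["n_bands"],
            context.get("band_stack_sum", 0.0),
            context["unpaired"],
        )
    raise ValueError(f"unknown loop kind {kind!r}")


# ---------------------------------------------------------------------------
# default parameter set ("default37")
# ---------------------------------------------------------------------------

# Watson-Crick x Watson-Crick stacks, Turner-style 37C values, keyed
# (outer, inner).  Completed below by helix-direction symmetry
# stack[(X Y),(W Z)] == stack[(Z W),(Y X)].
_WC_STACKS = {
    ("AU", "AU"): -0.9,
    ("AU", "UA"): -1.1,
    ("UA", "AU"): -1.3,
    ("CG", "UA"): -2.1,
    ("CG", "AU"): -2.1,
    ("GC", "UA"): -2.2,
    ("GC", "AU"): -2.4,
    ("CG", "GC"): -2.4,
    ("GC", "GC"): -3.3,
    ("GC", "CG"): -3.4,
}


def _flip(pair: str) -> str:
    return pair[::-1]


def _gu_stack(outer: str, inner: str) -> float:
    """Simplified wobble stacks: strength set by the non-wobble neighbor."""
    wobble = {"GU", "UG"}
    other = inner if outer in wobble else outer
    if other in wobble:
        return -0.4
    if other in ("GC", "CG"):
        return -1.5
    return -0.8


def _default_stacks() -> dict[tuple[str, str], float]:
    table: dict[tuple[str, str], float] = {}
    for outer, inner in _WC_STACKS:
        table[(outer, inner)] = _WC_STACKS[(outer, inner)]
        table[(_flip(inner), _flip(outer))] = _WC_STACKS[(outer, inner)]
    for outer in PAIR_CODES:
        for inner in PAIR_CODES:
            if (outer, inner) not in table:
                table[(outer, inner)] = _gu_stack(outer, inner)
    return table


def _length_table(anchors: dict[int, float], lo: int) -> dict[int, float]:
    table = dict(anchors)
    top = max(anchors)
    for size in range(lo, MAX_TABULATED_LOOP + 1):
        if size not in table:
            if size < top:
                below = max(k for k in anchors if k < size)
                above = min(k for k in anchors if k > size)
                frac = (size - below) / (above - below)
                table[size] = anchors[below] + frac * (anchors[above] - anchors[below])
            else:
                table[size] = anchors[top] + LOOP_EXTRAPOLATION * math.log(size / top)
    return {k: round(v, 2) for k, v in table.items() if lo <= k <= MAX_TABULATED_LOOP}


def default_parameters() -> EnergyParameters:
    """The builtin ``default37`` parameter set."""
    return EnergyParameters(
        stack=_default_stacks(),
        hairpin=_length_table({3: 5.4, 4: 5.6, 5: 5.7, 6: 5.4, 7: 6.0, 8: 5.5, 9: 6.4}, 3),
        bulge=_length_table({1: 3.8, 2: 2.8, 3: 3.2, 4: 3.6, 5: 4.0, 6: 4.4}, 1),
        internal=_length_table({2: 1.7, 3: 2.3, 4: 2.7, 5: 3.0, 6: 3.3}, 2),
        internal_asymmetry=0.6,
        internal_asymmetry_max=3.0,
        ml_closing=3.4,
        ml_branch=0.4,
        ml_unpaired=0.0,
        pk_init=10.0,
        pk_band=2.0,
        pk_unpaired=0.3,
    )


def save_parameters(params: EnergyParameters, path: str | Path) -> None:
    """Write the sectioned plain-text parameter file."""
    with open(path, "w") as fh:
        fh.write(f"# covafold energy parameters (kcal/mol), T = {params.temperature}\n")
        fh.write("STACK\n")
        for outer in PAIR_CODES:
            for inner in PAIR_CODES:
                fh.write(f"{outer} {inner} {params.stack[(outer, inner)]:.2f}\n")
        for name, table in (
            ("HAIRPIN", params.hairpin),
            ("BULGE", params.bulge),
            ("INTERNAL", params.internal),
        ):
            fh.write(f"{name}\n")
            for size in sorted(table):
                fh.write(f"{size} {table[size]:.2f}\n")
        fh.write("MULTI\n")
        fh.write(f"closing {params.ml_closing:.2f}\n")
        fh.write(f"branch {params.ml_branch:.2f}\n")
        fh.write(f"unpaired {params.ml_unpaired:.2f}\n")
        fh.write("PSEUDOKNOT\n")
        fh.write(f"init {params.pk_init:.2f}\n")
        fh.write(f"band {params.pk_band:.2f}\n")
        fh.write(f"unpaired {params.pk_unpaired:.2f}\n")
        fh.write("MISC\n")
        fh.write(f"internal_asymmetry {params.internal_asymmetry:.2f}\n")
        fh.write(f"internal_asymmetry_max {params.internal_asymmetry_max:.2f}\n")
        fh.write(f"loop_extrapolation {params.loop_extrapolation:.4f}\n")


_SECTIONS = {"STACK", "HAIRPIN", "BULGE", "INTERNAL", "MULTI", "PSEUDOKNOT", "MISC"}


def load_parameters(source: str | Path = "default37") -> EnergyParameters:
    """Load parameters from a file, or the builtin ``default37`` set.

    The file format is sectioned (STACK / HAIRPIN / BULGE / INTERNAL /
    MULTI / PSEUDOKNOT / MISC), whitespace-delimited, with ``#`` comments.
    Missing entries raise :class:`ParameterError` naming the entry.
    """
    if str(source) == "default37":
        return default_parameters()
    path = Path(source)
    stack: dict[tuple[str, str], float] = {}
    tables: dict[str, dict[int, float]] = {"HAIRPIN": {}, "BULGE": {}, "INTERNAL": {}}
    scalars: dict[str, float] = {}
    section = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if line in _SECTIONS:
                section = line
                continue
            fields = line.split()
            try:
                if section == "STACK":
                    outer, inner, value = fields
                    stack[(outer, inner)] = float(value)
                elif section in tables:
                    size, value = fields
                    tables[section][int(size)] = float(value)
                elif section in ("MULTI", "PSEUDOKNOT", "MISC"):
                    name, value = fields
                    scalars[f"{section}.{name}"] = float(value)
                else:
                    raise ValueError("data before any section header")
            except (ValueError, KeyError) as exc:
                raise ParameterError(f"{path}:{lineno}: {exc}") from exc
    try:
        return EnergyParameters(
            stack=stack,
            hairpin=tables["HAIRPIN"],
            bulge=tables["BULGE"],
            internal=tables["INTERNAL"],
            internal_asymmetry=scalars["MISC.internal_asymmetry"],
            internal_asymmetry_max=scalars["MISC.internal_asymmetry_max"],
            ml_closing=scalars["MULTI.closing"],
            ml_branch=scalars["MULTI.branch"],
            ml_unpaired=scalars["MULTI.unpaired"],
            pk_init=scalars["PSEUDOKNOT.init"],
            pk_band=scalars["PSEUDOKNOT.band"],
            pk_unpaired=scalars["PSEUDOKNOT.unpaired"],
            loop_extrapolation=scalars.get("MISC.loop_extrapolation", LOOP_EXTRAPOLATION),
        )
    except KeyError as exc:
        raise ParameterError(f"{path}: missing entry {exc}") from exc


# ---------------------------------------------------------------------------
# whole-structure scoring
# ---------------------------------------------------------------------------


def pair_code(seq: str, pair: tuple[int, int]) -> str:
    return seq[pair[0]] + seq[pair[1]]


def crossing_components(
    pairs: Iterable[tuple[int, int]],
) -> tuple[list[list[tuple[int, int]]], set[tuple[int, int]]]:
    """Connected components of the crossing graph; only crossing pairs belong
    to a component.  Returns (components, set of crossing pairs)."""
    ps = sorted(pairs)
    k = len(ps)
    parent = list(range(k))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    crossing: set[int] = set()
    for a in range(k):
        for b in range(a + 1, k):
            if pairs_cross(ps[a], ps[b]):
                crossing.update((a, b))
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[ra] = rb
    comps: dict[int, list[tuple[int, int]]] = {}
    for idx in crossing:
        comps.setdefault(find(idx), []).append(ps[idx])
    return [sorted(c) for c in comps.values()], {ps[i] for i in crossing}


def bands_of_component(comp: list[tuple[int, int]]) -> list[list[tuple[int, int]]]:
    """Maximal runs of consecutively stacked pairs within one component."""
    bands: list[list[tuple[int, int]]] = []
    for pair in sorted(comp):
        if bands and bands[-1][-1] == (pair[0] - 1, pair[1] + 1):
            bands[-1].append(pair)
        else:
            bands.append([pair])
    return bands


def density_ok(pairs: Iterable[tuple[int, int]], max_density: int = 2) -> bool:
    """Density check: no index lies under more than ``max_density`` band
    spans, bands being maximal stacked runs of crossing pairs."""
    comps, _ = crossing_components(pairs)
    spans: list[tuple[int, int]] = []
    for comp in comps:
        for band in bands_of_component(comp):
            spans.append((band[0][0], band[0][1]))
    if not spans:
        return True
    hi = max(s[1] for s in spans) + 1
    cover = [0] * (hi + 1)
    for lo_, hi_ in spans:
        for x in range(lo_, hi_ + 1):
            cover[x] += 1
            if cover[x] > max_density:
                return False
    return True


@dataclass
class _Node:
    span: tuple[int, int]
    pair: tuple[int, int] | None  # None for a crossing component
    comp: list[tuple[int, int]] | None
    children: list["_Node"] = field(default_factory=list)


def _build_forest(
    nested: list[tuple[int, int]], comps: list[list[tuple[int, int]]]
) -> list[_Node]:
    nodes = [_Node(span=p, pair=p, comp=None) for p in nested]
    for comp in comps:
        span = (min(p[0] for p in comp), max(p[1] for p in comp))
        nodes.append(_Node(span=span, pair=None, comp=comp))
    nodes.sort(key=lambda nd: (nd.span[0], -nd.span[1]))
    roots: list[_Node] = []
    stack: list[_Node] = []
    for node in nodes:
        while stack and stack[-1].span[1] < node.span[0]:
            stack.pop()
        if stack:
            if node.span[1] > stack[-1].span[1]:
                raise ValueError("crossing spans in loop decomposition")
            stack[-1].children.append(node)
        else:
            roots.append(node)
        stack.append(node)
    return roots


def structure_energy(
    seq: str, st: SecondaryStructure, params: EnergyParameters
) -> float:
    """Total free energy as the sum over the loop decomposition.

    Non-crossing pairs are scored with the standard nested loop
    decomposition (a crossing component counts as one branch of its
    enclosing loop, and a loop whose single branch is a component is
    scored as a multiloop).  Each crossing component contributes one
    pseudoknot term via :func:`pk_component_energy`.  Returns ``INF`` for
    a structure containing a non-canonical pair.
    """
    if len(seq) != st.length:
        raise ValueError("sequence/structure length mismatch")
    for i, j in st.pairs:
        if not is_canonical(seq[i], seq[j]):
            return INF
    comps, crossing = crossing_components(st.pairs)
    nested = sorted(p for p in st.pairs if p not in crossing)
    roots = _build_forest(nested, comps)
    total = 0.0

    def visit(node: _Node) -> None:
        nonlocal total
        lo, hi = node.span
        covered = sum(c.span[1] - c.span[0] + 1 for c in node.children)
        if node.pair is not None:
            unpaired = (hi - lo - 1) - covered
            kids = node.children
            if not kids:
                total += hairpin_energy(params, unpaired)
            elif len(kids) == 1 and kids[0].pair is not None:
                (k, l) = kids[0].pair
                if unpaired == 0:
                    total += stack_energy(
                        params, pair_code(seq, node.pair), pair_code(seq, (k, l))
                    )
                else:
                    total += internal_energy(params, k - lo - 1, hi - l - 1)
            else:
                total += multiloop_energy(params, len(kids), unpaired)
        else:
            comp = node.comp or []
            paired_positions = {x for p in comp for x in p}
            unpaired = (hi - lo + 1) - covered - len(paired_positions)
            bands = bands_of_component(comp)
            stack_sum = 0.0
            for band in bands:
                for outer, inner in zip(band, band[1:]):
                    stack_sum += stack_energy(
                        params, pair_code(seq, outer), pair_code(seq, inner)
                    )
            total += pk_component_energy(params, len(bands), stack_sum, unpaired)
        for child in node.children:
            visit(child)

    for root in roots:
        visit(root)
    return total
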