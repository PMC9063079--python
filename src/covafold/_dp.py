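"""Dynamic-programming engine for restricted energy minimization.

Implements minimum-free-energy folding of a single sequence under a guide
structure: guide pairs are forced, forced-unpaired positions may not pair,
and either only nested pairs may be added (pseudoknot-free mode) or a
disjoint pseudoknot-free layer may additionally cross the guide so that the
union is a density-2 structure (pseudoknotted mode).

The nested part is a Zuker-style recursion (arrays V / WM plus a 1-D
external array).  The crossing part exploits a structural fact of the
density-2 class: when a pseudoknot-free guide G is fixed and the added
layer G' is pseudoknot-free and base-disjoint from G, every crossing
component of G union G' is a *chain* of bands that strictly alternates
between complete maximal stacked runs of G and perfectly stacked runs of
G', with consecutive bands fully crossing.  Chains are therefore
enumerated by walking the (precomputed) G runs left to right and choosing
the connecting G' bands, which keeps the whole computation O(n^3) time and
O(n^2) space.  Gap regions inside a chain are scored by a pseudoknot-loop
array WI whose unpaired bases cost the pk-unpaired penalty; because an
index under a band span may be covered by at most two bands, WI admits no
nested crossing component, and the nested subtrees it uses are the
"no-pseudoknot-inside" variants Vn / WMn.

Energies follow :mod:`covafold.energy_model` exactly; the invariant
``dp energy == structure_energy(traceback)`` is asserted by the public
wrappers in :mod:`covafold.folding`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from covafold.energy_model import (
    EnergyParameters,
    hairpin_energy,
    internal_energy,
)
from covafold.guide import GuideStructure
from covafold.msa_io import MIN_HAIRPIN_LOOP, is_canonical

INF = math.inf

#: Largest tabulated interior loop (total unpaired bases).
MAXLOOP = 30

_BASES = "ACGU"
_CODE = {b: k for k, b in enumerate(_BASES)}


@dataclass
class _Run:
    """One maximal stacked run of guide pairs."""

    rid: int
    pairs: list[tuple[int, int]]  # outermost first
    galpha: int
    gbeta: int
    gp: int
    gq: int
    stack_e: float
    ctx_out: tuple[int, int] | None  # innermost guide pair enclosing the run


def _guide_runs(pairs: list[tuple[int, int]]) -> list[list[tuple[int, int]]]:
    runs: list[list[tuple[int, int]]] = []
    for pair in sorted(pairs):
        if runs and runs[-1][-1] == (pair[0] - 1, pair[1] + 1):
            runs[-1].append(pair)
        else:
            runs.append([pair])
    return runs


class Engine:
    """One restricted fold of ``seq`` under ``guide``."""

    def __init__(
        self,
        seq: str,
        guide: GuideStructure,
        params: EnergyParameters,
        pk: bool,
    ) -> None:
        if len(seq) != guide.length:
            raise ValueError("sequence/guide length mismatch")
        self.seq = seq
        self.params = params
        self.pk = pk
        self.n = n = len(seq)
        self.codes = np.array([_CODE[c] for c in seq], dtype=np.int64)

        self.gpair = np.full(n, -1, dtype=np.int64)
        for i, j in guide.pairs:
            self.gpair[i] = j
            self.gpair[j] = i
        self.forb = np.zeros(n, dtype=bool)
        for k in guide.unpaired:
            self.forb[k] = True
        self.gpaired = self.gpair >= 0
        self.free = ~self.gpaired & ~self.forb

        # next/prev guide-paired position (inclusive scan helpers)
        self.nextG = np.full(n + 1, n, dtype=np.int64)
        for i in range(n - 1, -1, -1):
            self.nextG[i] = i if self.gpaired[i] else self.nextG[i + 1]
        self.prevG = np.full(n + 1, -1, dtype=np.int64)  # prevG[i+1] = last <= i
        for i in range(n):
            self.prevG[i + 1] = i if self.gpaired[i] else self.prevG[i]

        self._pack_energies()
        self._pair_allowed_matrix()
        if pk:
            self._prepare_runs(sorted(guide.pairs))

    # -- parameter packing ---------------------------------------------------

    def _pack_energies(self) -> None:
        p = self.params
        self.stackM = np.full((16, 16), INF)
        for (o, i_), e in p.stack.items():
            oc = _CODE[o[0]] * 4 + _CODE[o[1]]
            ic = _CODE[i_[0]] * 4 + _CODE[i_[1]]
            self.stackM[oc, ic] = e
        self.hairpinE = np.full(max(self.n, MIN_HAIRPIN_LOOP + 1), INF)
        for size in range(MIN_HAIRPIN_LOOP, len(self.hairpinE)):
            self.hairpinE[size] = hairpin_energy(p, size)
        fint = np.full((MAXLOOP + 1, MAXLOOP + 1), INF)
        for n1 in range(MAXLOOP + 1):
            for n2 in range(MAXLOOP + 1):
                if n1 + n2 == 0 or n1 + n2 > MAXLOOP:
                    continue
                fint[n1, n2] = internal_energy(p, n1, n2)
        self.Fint = fint
        self.ml_a = p.ml_closing
        self.ml_b = p.ml_branch
        self.ml_u = p.ml_unpaired
        self.pk_init = p.pk_init
        self.pk_band = p.pk_band
        self.pk_u = p.pk_unpaired

    def _pair_allowed_matrix(self) -> None:
        n = self.n
        canon = np.zeros((4, 4), dtype=bool)
        for x, y in (("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")):
            canon[_CODE[x], _CODE[y]] = True
        cm = canon[self.codes[:, None], self.codes[None, :]]
        span_ok = (np.arange(n)[None, :] - np.arange(n)[:, None]) > MIN_HAIRPIN_LOOP
        ok = cm & span_ok
        ok &= ~self.forb[:, None] & ~self.forb[None, :]
        gi = self.gpair[:, None]
        gj = self.gpair[None, :]
        cols = np.arange(n)[None, :]
        rows = np.arange(n)[:, None]
        ok &= (gi < 0) | (gi == cols)
        ok &= (gj < 0) | (gj == rows)
        self.allowed = ok

    def _pc(self, i: int, j: int) -> int:
        return int(self.codes[i]) * 4 + int(self.codes[j])

    def _stack(self, i: int, j: int, k: int, l: int) -> float:
        return float(self.stackM[self._pc(i, j), self._pc(k, l)])

    # -- guide runs and chain precomputation ---------------------------------

    def _prepare_runs(self, gpairs: list[tuple[int, int]]) -> None:
        self.runs: list[_Run] = []
        # innermost enclosing guide pair per position
        ctx: list[tuple[int, int] | None] = [None] * self.n
        stack: list[tuple[int, int]] = []
        partner = {i: j for i, j in gpairs} | {j: i for i, j in gpairs}
        for pos in range(self.n):
            if pos in partner and partner[pos] > pos:
                ctx[pos] = stack[-1] if stack else None
                stack.append((pos, partner[pos]))
            elif pos in partner:
                stack.pop()
                ctx[pos] = stack[-1] if stack else None
            else:
                ctx[pos] = stack[-1] if stack else None
        self.ctx = ctx
        for rid, run in enumerate(_guide_runs(gpairs)):
            galpha, gbeta = run[0]
            gp, gq = run[-1]
            stack_e = 0.0
            for (a, b), (c, d) in zip(run, run[1:]):
                stack_e += self._stack(a, b, c, d)
            outer_ctx = ctx[galpha]
            self.runs.append(
                _Run(rid, run, galpha, gbeta, gp, gq, stack_e, outer_ctx)
            )
        # top-level free positions of each run's loop
        self.loop_top: list[list[int]] = []
        for r in self.runs:
            inner = (r.gp, r.gq)
            self.loop_top.append(
                [
                    x
                    for x in range(r.gp + 1, r.gq)
                    if self.free[x] and self.ctx[x] == inner
                ]
            )
        self.runs_ending_at: dict[int, list[_Run]] = {}
        for r in self.runs:
            self.runs_ending_at.setdefault(r.gbeta, []).append(r)
        # prefix count of runs fully inside [0..x]
        self._run_spans = [(r.galpha, r.gbeta) for r in self.runs]

    def _runs_inside(self, i: int, j: int) -> list[_Run]:
        return [r for r in self.runs if i <= r.galpha and r.gbeta <= j]

    # -- fill ----------------------------------------------------------------

    def fill(self) -> None:
        n = self.n
        self.V = np.full((n, n), INF)
        self.WM = np.full((n, n), INF)
        if self.pk:
            self.Vn = np.full((n, n), INF)
            self.WMn = np.full((n, n), INF)
            self.WIarr = np.full((n, n), INF)
            self.WMB = np.full((n, n), INF)
            self.WMBpad = np.full((n, n), INF)
            self._A: dict[tuple[int, int, int, bool], float] = {}
            self._A2: dict[tuple[int, int, int, bool], float] = {}
        for span in range(1, n):
            for i in range(0, n - span):
                j = i + span
                if self.pk:
                    if span > MIN_HAIRPIN_LOOP:
                        self.Vn[i, j] = self._compute_V(i, j, self.Vn, self.WMn, False)
                    self.WMn[i, j] = self._compute_WM(i, j, self.Vn, self.WMn, None)
                    self.WIarr[i, j] = self._compute_WI(i, j)
                    if self.runs:
                        self.WMB[i, j] = self._compute_WMB(i, j)
                    self._compute_WMBpad(i, j)
                    if span > MIN_HAIRPIN_LOOP:
                        self.V[i, j] = self._compute_V(i, j, self.V, self.WM, True)
                    self.WM[i, j] = self._compute_WM(i, j, self.V, self.WM, self.WMB)
                else:
                    if span > MIN_HAIRPIN_LOOP:
                        self.V[i, j] = self._compute_V(i, j, self.V, self.WM, False)
                    self.WM[i, j] = self._compute_WM(i, j, self.V, self.WM, None)
        # external, left-anchored
        W = np.zeros(n + 1)
        for j in range(n):
            best = W[j] if not self.gpaired[j] else INF
            cand = W[: j + 1] + self.V[: j + 1, j]
            if cand.size:
                best = min(best, float(cand.min()))
            if self.pk and self.runs:
                cand = W[: j + 1] + self.WMB[: j + 1, j]
                best = min(best, float(cand.min()))
            W[j + 1] = best
        self.W = W

    @property
    def energy(self) -> float:
        return float(self.W[self.n])

    def _compute_V(
        self, i: int, j: int, Varr: np.ndarray, WMarr: np.ndarray, pk_case: bool
    ) -> float:
        if not self.allowed[i, j]:
            return INF
        best = INF
        # hairpin: no guide-paired base may sit in the loop
        if self.nextG[i + 1] > j - 1:
            best = float(self.hairpinE[j - i - 1])
        # stack
        if j - i - 2 > MIN_HAIRPIN_LOOP:
            v = self._stack(i, j, i + 1, j - 1) + Varr[i + 1, j - 1]
            if v < best:
                best = v
        # interior loops (>=1 unpaired base total); invalid (k,l) are INF in V
        kmax = min(i + 1 + MAXLOOP, int(self.nextG[i + 1]), j - 1)
        lmin = max(j - 1 - MAXLOOP, int(self.prevG[j]), i + 1)
        if kmax >= i + 1 and lmin <= j - 1:
            sub = Varr[i + 1 : kmax + 1, lmin:j]
            fb = self.Fint[0 : kmax - i, j - 1 - lmin :: -1]
            if sub.size:
                v = float((sub + fb).min())
                if v < best:
                    best = v
        # multiloop: closing pair + two interior fragments, each >= 1 branch
        if j - i - 2 >= 2:
            row = WMarr[i + 1]
            col = WMarr[:, j - 1]
            acc = INF
            for k in range(i + 1, j - 1):
                v = row[k] + col[k + 1]
                if v < acc:
                    acc = v
            v = self.ml_a + acc
            if v < best:
                best = v
        # single crossing component inside the closing pair
        if pk_case and self.pk and self.runs and j - i - 2 >= 2:
            v = self.ml_a + self.ml_b + self.WMBpad[i + 1, j - 1]
            if v < best:
                best = v
        return best

    def _compute_WM(
        self,
        i: int,
        j: int,
        Varr: np.ndarray,
        WMarr: np.ndarray,
        WMBarr: np.ndarray | None,
    ) -> float:
        best = INF
        if not self.gpaired[j] and j - 1 >= i:
            best = WMarr[i, j - 1] + self.ml_u
        if not self.gpaired[i] and j >= i + 1:
            v = WMarr[i + 1, j] + self.ml_u
            if v < best:
                best = v
        v = Varr[i, j] + self.ml_b
        if v < best:
            best = v
        if WMBarr is not None and self.runs:
            v = WMBarr[i, j] + self.ml_b
            if v < best:
                best = v
        if j > i:
            row = WMarr[i]
            col = WMarr[:, j]
            acc = INF
            for k in range(i, j):
                v = row[k] + col[k + 1]
                if v < acc:
                    acc = v
            if acc < best:
                best = acc
        return best

    def _wi(self, i: int, j: int) -> float:
        """WI with empty-interval convention WI(i, i-1) = 0."""
        if j < i:
            return 0.0
        if j == i:
            return self.pk_u if not self.gpaired[i] else INF
        return float(self.WIarr[i, j])

    def _compute_WI(self, i: int, j: int) -> float:
        best = INF
        if not self.gpaired[j]:
            best = self._wi(i, j - 1) + self.pk_u
        for k in range(i, j - MIN_HAIRPIN_LOOP):
            v = self._wi(i, k - 1) + self.Vn[k, j]
            if v < best:
                best = v
        return best

    # -- chains ---------------------------------------------------------------

    def _band_ok(self, x: int, y: int, d: int) -> bool:
        """[x..x+d-1] pairs [y-d+1..y]: free positions, canonical, span ok."""
        if (y - d + 1) - (x + d - 1) <= MIN_HAIRPIN_LOOP:
            return False
        for t in range(d):
            if not (self.free[x + t] and self.free[y - t]):
                return False
            if not is_canonical(self.seq[x + t], self.seq[y - t]):
                return False
        return True

    def _band_stack(self, x: int, y: int, d: int) -> float:
        total = 0.0
        for t in range(d - 1):
            total += self._stack(x + t, y - t, x + t + 1, y - t - 1)
        return total

    def _chain_A(self, i: int, rid: int, e: int, flag: bool) -> float:
        """Partial chain from ``i`` whose last placed G band is run ``rid``,
        with run-loop content consumed through position ``e``; ``flag`` is
        True iff at least one G' band has been placed."""
        key = (i, rid, e, flag)
        if key in self._A:
            return self._A[key]
        r = self.runs[rid]
        best = INF
        if e == r.gp:
            # run is the first band of the chain
            if not flag and i == r.galpha:
                best = self.pk_init + self.pk_band + r.stack_e
            elif flag:
                # chain starts with a leading G' band whose left run begins at i
                best = self._chain_start_gp(i, r, e_is_y=None)
        elif flag and self.free[e] and self.ctx[e] == (r.gp, r.gq):
            # e is the right end of a G' connector or leading band
            best = min(self._chain_start_gp(i, r, e_is_y=e), self._chain_cc(i, r, e))
        self._A[key] = best
        return best

    def _chain_start_gp(self, i: int, r: _Run, e_is_y: int | None) -> float:
        """Chain starting with a G' band from position i into run r's loop.

        ``e_is_y`` is the right end y of the G' band inside the loop; when
        None the case is vacuous (a leading band must land in the loop)."""
        if e_is_y is None:
            return INF
        y = e_is_y
        if self.ctx[i] is not r.ctx_out and self.ctx[i] != r.ctx_out:
            return INF
        best = INF
        dmax = min(r.galpha - i, y - r.gp)
        for d in range(1, dmax + 1):
            # left run [i..i+d-1] before the run, right run [y-d+1..y] in loop
            if i + d - 1 >= r.galpha or y - d + 1 <= r.gp:
                break
            if not (self.free[i + d - 1] and self.ctx[i + d - 1] == self.ctx[i]):
                break
            if not self._band_ok(i, y, d):
                if not (self.free[i + d - 1] and self.free[y - d + 1]):
                    break
                continue
            v = (
                self.pk_init
                + 2 * self.pk_band
                + self._band_stack(i, y, d)
                + r.stack_e
                + self._wi(i + d, r.galpha - 1)
                + self._wi(r.gp + 1, y - d)
            )
            if v < best:
                best = v
        return best

    def _chain_cc(self, i: int, r2: _Run, y: int) -> float:
        """Connector transition: some earlier sibling run r1, a G' band from
        r1's loop ending at ``y`` inside r2's loop, r2 appended."""
        best = INF
        for r1 in self.runs:
            if r1.gbeta >= r2.galpha or r1.ctx_out != r2.ctx_out:
                continue
            if r1.galpha < i:
                continue
            mid_gap = self._wi(r1.gbeta + 1, r2.galpha - 1)
            if mid_gap == INF:
                continue
            for x in self.loop_top[r1.rid]:
                a2 = min(
                    self._chain_A2(i, r1.rid, x, True),
                    self._chain_A2(i, r1.rid, x, False),
                )
                if a2 == INF:
                    continue
                dmax = min(r1.gq - x, y - r2.gp)
                for d in range(1, dmax + 1):
                    if x + d - 1 >= r1.gq or y - d + 1 <= r2.gp:
                        break
                    if not (
                        self.free[x + d - 1]
                        and self.ctx[x + d - 1] == (r1.gp, r1.gq)
                    ):
                        break
                    if not self._band_ok(x, y, d):
                        if not (self.free[x + d - 1] and self.free[y - d + 1]):
                            break
                        continue
                    v = (
                        a2
                        + self.pk_band
                        + self._band_stack(x, y, d)
                        + self._wi(x + d, r1.gq - 1)
                        + mid_gap
                        + self._wi(r2.gp + 1, y - d)
                        + self.pk_band
                        + r2.stack_e
                    )
                    if v < best:
                        best = v
        return best

    def _chain_A2(self, i: int, rid: int, x: int, flag: bool) -> float:
        """Best partial chain with run ``rid`` last and its loop consumed up
        to position x-1, ready to start a G' left run (or terminate) at x."""
        key = (i, rid, x, flag)
        if key in self._A2:
            return self._A2[key]
        r = self.runs[rid]
        # iterative fill from the loop start to avoid deep recursion
        for xx in range(r.gp + 1, x + 1):
            kk = (i, rid, xx, flag)
            if kk in self._A2:
                continue
            best = self._chain_A(i, rid, xx - 1, flag)
            if xx - 1 > r.gp and not self.gpaired[xx - 1]:
                v = self._A2[(i, rid, xx - 1, flag)] + self.pk_u
                if v < best:
                    best = v
            for k in range(r.gp + 1, xx - 1 - MIN_HAIRPIN_LOOP):
                v = self._A2[(i, rid, k, flag)] + float(self.Vn[k, xx - 1])
                if v < best:
                    best = v
            self._A2[kk] = best
        return self._A2[key]

    def _compute_WMB(self, i: int, j: int) -> float:
        best = INF
        # termination with a final G band
        for r in self.runs_ending_at.get(j, []):
            if r.galpha < i:
                continue
            v = self._chain_A2(i, r.rid, r.gq, True)
            if v < best:
                best = v
        # termination with a trailing G' band ending at j
        if self.free[j]:
            for r in self.runs:
                if not (i <= r.galpha and r.gbeta < j):
                    continue
                if self.ctx[j] != r.ctx_out:
                    continue
                tail_gap_end = j  # right run [j-d+1..j], gap (gbeta, j-d+1)
                for x in self.loop_top[r.rid]:
                    a2 = min(
                        self._chain_A2(i, r.rid, x, True),
                        self._chain_A2(i, r.rid, x, False),
                    )
                    if a2 == INF:
                        continue
                    dmax = min(r.gq - x, j - r.gbeta)
                    for d in range(1, dmax + 1):
                        if x + d - 1 >= r.gq or j - d + 1 <= r.gbeta:
                            break
                        if not (
                            self.free[x + d - 1]
                            and self.ctx[x + d - 1] == (r.gp, r.gq)
                        ):
                            break
                        if not (
                            self.free[j - d + 1]
                            and self.ctx[j - d + 1] == r.ctx_out
                        ):
                            break
                        if not self._band_ok(x, j, d):
                            continue
                        v = (
                            a2
                            + self.pk_band
                            + self._band_stack(x, j, d)
                            + self._wi(x + d, r.gq - 1)
                            + self._wi(r.gbeta + 1, j - d)
                        )
                        if v < best:
                            best = v
        return best

    def _compute_WMBpad(self, i: int, j: int) -> None:
        best = float(self.WMB[i, j]) if self.runs else INF
        if not self.gpaired[i] and i + 1 <= j:
            v = self.WMBpad[i + 1, j] + self.ml_u
            if v < best:
                best = v
        if not self.gpaired[j] and j - 1 >= i:
            v = self.WMBpad[i, j - 1] + self.ml_u
            if v < best:
                best = v
        self.WMBpad[i, j] = best

    # -- traceback ------------------------------------------------------------
    #
    # Each trace method re-enumerates the candidate cases of the corresponding
    # recurrence in a fixed order (unpaired end, closed pair, bifurcation at
    # the smallest split point) and descends into the first case that
    # reproduces the stored optimum; this makes the reported structure a
    # deterministic function of the filled tables.  Guide pairs are not
    # collected here — the public wrappers add them to the result wholesale.

    _TOL = 1e-9

    def traceback(self) -> set[tuple[int, int]]:
        out: set[tuple[int, int]] = set()
        j = self.n - 1
        W = self.W
        while j >= 0:
            if not self.gpaired[j] and self._close(W[j + 1], W[j]):
                j -= 1
                continue
            hit = False
            for k in range(j + 1):
                if self._close(W[j + 1], W[k] + self.V[k, j]):
                    self._trace_V(k, j, out, pk_case=self.pk)
                    j = k - 1
                    hit = True
                    break
                if (
                    self.pk
                    and self.runs
                    and self._close(W[j + 1], W[k] + self.WMB[k, j])
                ):
                    self._trace_WMB(k, j, out)
                    j = k - 1
                    hit = True
                    break
            if not hit:
                raise AssertionError(f"external traceback failed at {j}")
        return out

    @staticmethod
    def _close(target: float, value: float) -> bool:
        if value == INF or target == INF:
            return value == target
        return abs(value - target) <= Engine._TOL

    def _trace_V(self, i: int, j: int, out: set, pk_case: bool) -> None:
        if self.pk and not pk_case:
            Varr, WMarr = self.Vn, self.WMn
        else:
            Varr, WMarr = self.V, self.WM
        target = float(Varr[i, j])
        if target == INF:
            raise AssertionError(f"V traceback into infeasible cell ({i},{j})")
        out.add((i, j))
        if self.nextG[i + 1] > j - 1 and self._close(
            target, float(self.hairpinE[j - i - 1])
        ):
            return
        if j - i - 2 > MIN_HAIRPIN_LOOP and self._close(
            target, self._stack(i, j, i + 1, j - 1) + Varr[i + 1, j - 1]
        ):
            self._trace_V(i + 1, j - 1, out, pk_case)
            return
        kmax = min(i + 1 + MAXLOOP, int(self.nextG[i + 1]), j - 1)
        lmin = max(j - 1 - MAXLOOP, int(self.prevG[j]), i + 1)
        for k in range(i + 1, kmax + 1):
            for l in range(max(lmin, k + 1), j):
                n1, n2 = k - i - 1, j - l - 1
                if n1 + n2 == 0 or n1 + n2 > MAXLOOP:
                    continue
                if self._close(target, float(self.Fint[n1, n2]) + Varr[k, l]):
                    self._trace_V(k, l, out, pk_case)
                    return
        for k in range(i + 1, j - 1):
            if self._close(
                target, self.ml_a + WMarr[i + 1, k] + WMarr[k + 1, j - 1]
            ):
                self._trace_WM(i + 1, k, out, pk_case)
                self._trace_WM(k + 1, j - 1, out, pk_case)
                return
        if pk_case and self.pk and self.runs:
            if self._close(
                target, self.ml_a + self.ml_b + self.WMBpad[i + 1, j - 1]
            ):
                self._trace_WMBpad(i + 1, j - 1, out)
                return
        raise AssertionError(f"V traceback failed at ({i},{j})")

    def _trace_WM(self, i: int, j: int, out: set, pk_case: bool) -> None:
        if not self.pk or pk_case:
            Varr, WMarr = self.V, self.WM
            WMBarr = self.WMB if (self.pk and self.runs) else None
        else:
            Varr, WMarr, WMBarr = self.Vn, self.WMn, None
        target = float(WMarr[i, j])
        if not self.gpaired[j] and j - 1 >= i and self._close(
            target, WMarr[i, j - 1] + self.ml_u
        ):
            self._trace_WM(i, j - 1, out, pk_case)
            return
        if not self.gpaired[i] and j >= i + 1 and self._close(
            target, WMarr[i + 1, j] + self.ml_u
        ):
            self._trace_WM(i + 1, j, out, pk_case)
            return
        if self._close(target, Varr[i, j] + self.ml_b):
            self._trace_V(i, j, out, pk_case)
            return
        if WMBarr is not None and self._close(target, WMBarr[i, j] + self.ml_b):
            self._trace_WMB(i, j, out)
            return
        for k in range(i, j):
            if self._close(target, WMarr[i, k] + WMarr[k + 1, j]):
                self._trace_WM(i, k, out, pk_case)
                self._trace_WM(k + 1, j, out, pk_case)
                return
        raise AssertionError(f"WM traceback failed at ({i},{j})")

    def _trace_WI(self, i: int, j: int, out: set) -> None:
        if j < i:
            return
        target = self._wi(i, j)
        if j == i:
            return
        if not self.gpaired[j] and self._close(target, self._wi(i, j - 1) + self.pk_u):
            self._trace_WI(i, j - 1, out)
            return
        for k in range(i, j - MIN_HAIRPIN_LOOP):
            if self._close(target, self._wi(i, k - 1) + self.Vn[k, j]):
                self._trace_V(k, j, out, pk_case=False)
                self._trace_WI(i, k - 1, out)
                return
        raise AssertionError(f"WI traceback failed at ({i},{j})")

    def _trace_WMBpad(self, i: int, j: int, out: set) -> None:
        target = float(self.WMBpad[i, j])
        if self.runs and self._close(target, float(self.WMB[i, j])):
            self._trace_WMB(i, j, out)
            return
        if not self.gpaired[i] and i + 1 <= j and self._close(
            target, self.WMBpad[i + 1, j] + self.ml_u
        ):
            self._trace_WMBpad(i + 1, j, out)
            return
        if not self.gpaired[j] and j - 1 >= i and self._close(
            target, self.WMBpad[i, j - 1] + self.ml_u
        ):
            self._trace_WMBpad(i, j - 1, out)
            return
        raise AssertionError(f"WMBpad traceback failed at ({i},{j})")

    def _trace_WMB(self, i: int, j: int, out: set) -> None:
        target = float(self.WMB[i, j])
        for r in self.runs_ending_at.get(j, []):
            if r.galpha < i:
                continue
            if self._close(target, self._chain_A2(i, r.rid, r.gq, True)):
                self._trace_A2(i, r.rid, r.gq, True, out)
                return
        if self.free[j]:
            for r in self.runs:
                if not (i <= r.galpha and r.gbeta < j):
                    continue
                if self.ctx[j] != r.ctx_out:
                    continue
                for x in self.loop_top[r.rid]:
                    for flag in (True, False):
                        a2 = self._chain_A2(i, r.rid, x, flag)
                        if a2 == INF:
                            continue
                        dmax = min(r.gq - x, j - r.gbeta)
                        for d in range(1, dmax + 1):
                            if x + d - 1 >= r.gq or j - d + 1 <= r.gbeta:
                                break
                            if not (
                                self.free[x + d - 1]
                                and self.ctx[x + d - 1] == (r.gp, r.gq)
                            ):
                                break
                            if not (
                                self.free[j - d + 1]
                                and self.ctx[j - d + 1] == r.ctx_out
                            ):
                                break
                            if not self._band_ok(x, j, d):
                                continue
                            v = (
                                a2
                                + self.pk_band
                                + self._band_stack(x, j, d)
                                + self._wi(x + d, r.gq - 1)
                                + self._wi(r.gbeta + 1, j - d)
                            )
                            if self._close(target, v):
                                for t in range(d):
                                    out.add((x + t, j - t))
                                self._trace_WI(x + d, r.gq - 1, out)
                                self._trace_WI(r.gbeta + 1, j - d, out)
                                self._trace_A2(i, r.rid, x, flag, out)
                                return
        raise AssertionError(f"WMB traceback failed at ({i},{j})")

    def _trace_A2(self, i: int, rid: int, x: int, flag: bool, out: set) -> None:
        r = self.runs[rid]
        while x > r.gp:
            target = self._chain_A2(i, rid, x, flag)
            if self._close(target, self._chain_A(i, rid, x - 1, flag)):
                self._trace_A(i, rid, x - 1, flag, out)
                return
            if x - 1 > r.gp and not self.gpaired[x - 1] and self._close(
                target, self._chain_A2(i, rid, x - 1, flag) + self.pk_u
            ):
                x -= 1
                continue
            hit = False
            for k in range(r.gp + 1, x - 1 - MIN_HAIRPIN_LOOP):
                if self._close(
                    target, self._chain_A2(i, rid, k, flag) + float(self.Vn[k, x - 1])
                ):
                    self._trace_V(k, x - 1, out, pk_case=False)
                    x = k
                    hit = True
                    break
            if not hit:
                raise AssertionError(f"A2 traceback failed at x={x}")
        self._trace_A(i, rid, r.gp, flag, out)

    def _trace_A(self, i: int, rid: int, e: int, flag: bool, out: set) -> None:
        r = self.runs[rid]
        target = self._chain_A(i, rid, e, flag)
        if e == r.gp and not flag:
            return  # chain started with this G band at i == galpha
        # leading G' band from i into r's loop, ending at e
        if self.free[i] and self.ctx[i] == r.ctx_out:
            dmax = min(r.galpha - i, e - r.gp)
            for d in range(1, dmax + 1):
                if i + d - 1 >= r.galpha or e - d + 1 <= r.gp:
                    break
                if not (self.free[i + d - 1] and self.ctx[i + d - 1] == self.ctx[i]):
                    break
                if not self._band_ok(i, e, d):
                    continue
                v = (
                    self.pk_init
                    + 2 * self.pk_band
                    + self._band_stack(i, e, d)
                    + r.stack_e
                    + self._wi(i + d, r.galpha - 1)
                    + self._wi(r.gp + 1, e - d)
                )
                if self._close(target, v):
                    for t in range(d):
                        out.add((i + t, e - t))
                    self._trace_WI(i + d, r.galpha - 1, out)
                    self._trace_WI(r.gp + 1, e - d, out)
                    return
        # connector from an earlier sibling run
        for r1 in self.runs:
            if r1.gbeta >= r.galpha or r1.ctx_out != r.ctx_out:
                continue
            if r1.galpha < i:
                continue
            mid_gap = self._wi(r1.gbeta + 1, r.galpha - 1)
            if mid_gap == INF:
                continue
            for x in self.loop_top[r1.rid]:
                for pflag in (True, False):
                    a2 = self._chain_A2(i, r1.rid, x, pflag)
                    if a2 == INF:
                        continue
                    dmax = min(r1.gq - x, e - r.gp)
                    for d in range(1, dmax + 1):
                        if x + d - 1 >= r1.gq or e - d + 1 <= r.gp:
                            break
                        if not (
                            self.free[x + d - 1]
                            and self.ctx[x + d - 1] == (r1.gp, r1.gq)
                        ):
                            break
                        if not self._band_ok(x, e, d):
                            continue
                        v = (
                            a2
                            + self.pk_band
                            + self._band_stack(x, e, d)
                            + self._wi(x + d, r1.gq - 1)
                            + mid_gap
                            + self._wi(r.gp + 1, e - d)
                            + self.pk_band
                            + r.stack_e
                        )
                        if self._close(target, v):
                            for t in range(d):
                                out.add((x + t, e - t))
                            self._trace_WI(x + d, r1.gq - 1, out)
                            self._trace_WI(r1.gbeta + 1, r.galpha - 1, out)
                            self._trace_WI(r.gp + 1, e - d, out)
                            self._trace_A2(i, r1.rid, x, pflag, out)
                            return
        raise AssertionError(f"A traceback failed at run {rid}, e={e}")
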