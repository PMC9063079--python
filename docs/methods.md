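# Methods

## Covariation statistics

Mutual information between alignment columns *a* and *b* is the sum of
`f_ab(x,y) log2(f_ab/(f_a f_b))` over the six canonical base pairs only.
All frequencies are counts divided by the number of rows N: `f_a(x)` is
the frequency of base *x* in column *a* (gaps are not bases and add no
count), and the joint collects only rows whose residue combination is
canonical.  Two consequences are worth stating plainly:

- Restricting the sum to canonical combinations can leave a slightly
  negative total when canonical combinations are rarer than independence
  predicts.  Such values carry no pairing signal and are floored at 0,
  which keeps MI inside the printed [0, 2] range.
- The alternative convention — renormalizing both joint and marginals
  over the canonical-retained rows — was evaluated and rejected: it gives
  two *independent* columns MI ≈ 1.1 bits purely from conditioning on
  canonicity, and near-conserved columns with two or three retained rows
  MI up to 2 bits.  Under that convention the product correction absorbs
  the genuine signal and no planted pair survives the 0.4 threshold.
  With per-column marginals, independent columns score ≈ 0 and perfectly
  covarying columns ≈ 1.25 bits (uniform over six pairs), so the 0.4
  threshold separates cleanly.

The average product correction is `APC(a,b) = MI(a,z̄) MI(b,z̄)/MI_avg`
with column averages `MI(a,z̄) = (1/(n_a-1)) Σ_z MI(a,z)` where terms at
offset |a−z| ≤ 3 are replaced by zero, and `MI_avg` the mean of the same
masked values over unordered column pairs (`2/(n_a(n_a−1))` times the
sum over a < b).  `MIp = MI − APC` may be negative.  A zero `MI_avg`
(no signal anywhere) defines APC as identically zero.

Conserved-column blindness is inherent: columns with a single residue
each yield MI = 0 even when they always form a canonical pair.  The
statistic sees covariation, not complementarity.

## Guide construction

Intermediary base pairs: all column pairs with MIp strictly above the
threshold (default 0.4) and span ≥ 4, sorted by MIp descending (ties by
position), greedily accepted when both columns are still free.  The
accepted set may still contain crossing arcs; since the folding guide
must be pseudoknot-free, crossings are resolved by keeping the
higher-MIp arc (a maximum non-crossing-weight alternative is available).
Restricted unpaired bases are columns whose maximum MI over all partners
falls below the alignment-mean MI; a restriction colliding with an
accepted pair endpoint yields to the pair, which carries direct
covariation evidence.

Projection onto a row removes gap columns from sequence and guide,
removes a pair when either endpoint was gapped, and removes pairs whose
hairpin loop shrank below 3 unpaired bases.

## Energy model

A deliberately compact nearest-neighbor set for 37 °C, 1 M NaCl:

| component | form | default |
|---|---|---|
| stacks | table over (outer pair, inner pair), kcal/mol | Turner-style WC values; wobble stacks by neighbor class (−1.5 next to G·C/C·G, −0.8 next to A·U/U·A, −0.4 wobble-on-wobble) |
| hairpin | length table 3–30, log extrapolation (coefficient 1.079 ≈ 1.75 RT) | 5.4 at size 3 |
| bulge / internal | length tables + Ninio asymmetry 0.6·\|n1−n2\| capped at 3.0 | — |
| multiloop | closing + branch·(#branches) + unpaired·u | 3.4 / 0.4 / 0.0 |
| pseudoknot | init + band·(#bands) + band stacks + 0.3·(unpaired in pk loops) | 10.0 / 2.0 / 0.3 |

Terminal mismatches, dangling ends and coaxial stacking are omitted;
bulge and internal loops depend on lengths only.  This keeps the
interior-loop block of the DP a precomputable constant matrix and makes
the model easy to restate exactly in the exhaustive-enumeration oracle.
Interior loops are capped at 30 total unpaired bases in the DP (the
standard restriction); at oracle scales (n ≤ 16) no loop can exceed it,
so the DP and the cap-free enumerator optimize the same objective.

The pseudoknot constants were chosen so that a pseudoknot loop carries an
entropic cost comparable to other loops.  With a near-zero per-base cost,
threading a 2–3-pair band through two facing hairpin loops "releases"
both hairpin penalties (≈ 11 kcal/mol) almost for free — a physically
absurd preference that floods predictions with marginal mini-pseudoknots.
At 10.0 / 2.0 / 0.3 such bands are rejected while genuine crossing
helices of four or more stacked pairs remain favorable.  All constants
are configuration: the sectioned text format (STACK / HAIRPIN / BULGE /
INTERNAL / MULTI / PSEUDOKNOT / MISC) round-trips exactly, so a
different table — e.g. one transcribed from a published pseudoknot
model — can be substituted wholesale.

Whole-structure energy is the sum over the loop decomposition.  Crossing
pairs are grouped into components; each component contributes one
initiation, one penalty and the internal stacking per band (bands are
maximal stacked runs), and the per-base penalty for bases lying directly
in its loops.  Nested substructure inside a pseudoknot loop is scored as
its own subtree without a branch premium; a component sitting in a
multiloop counts as one branch; a closing pair whose only child is a
component is scored as a multiloop with one branch.

## Restricted folding

Both optimizers force every guide pair, never pair a forced-unpaired
position, and require canonical pairs and hairpin loops ≥ 3 throughout.

*Pseudoknot-free*: a Zuker-style recursion (V for closed substructures,
WM for multiloop interiors with at least one branch, a one-dimensional
external array), O(n³) time / O(n²) space.  Constraints enter as an
admissibility mask on pairs and a "no forced position may sit in an
unpaired stretch" rule enforced with next/previous-forced-position
indices.

*Pseudoknotted (density-2)*: the union of the fixed pseudoknot-free
guide G and a disjoint pseudoknot-free added layer G′.  Two structural
facts make an exact O(n³) enumeration possible.  First, in such a union
every crossing component is a *chain* of bands, strictly alternating
between bands of G and bands of G′, with consecutive bands fully
crossing; hybrid bands are impossible (a pair stacked onto a crossed G
band would cross the neighboring G′ band of its own layer).  Second,
every G band in a chain is a *complete* maximal stacked run of G, so the
chain alternatives can be enumerated by walking the precomputed G runs
left to right and choosing the perfectly stacked G′ connector bands
between their loops.  Chain gaps are scored by a pseudoknot-loop array
WI (per-base penalty, nested branches free); because a gap already lies
under one or two band spans, the density-2 limit forbids any crossing
component inside it, so WI and the subtrees it uses are the
no-pseudoknot variants of V and WM.  The traceback re-derives each
decision from the filled tables in a fixed case order (unpaired end,
closed pair, bifurcation at the smallest split), making the reported
structure deterministic; the wrapper re-scores the traced structure with
the standalone energy function and rejects any disagreement beyond
1e−6 kcal/mol.

With an empty guide no crossing component can form (both layers would
have to come from the single added pseudoknot-free set), so the
pseudoknotted optimizer then reproduces the pseudoknot-free one — the
engine predicts pseudoknots only where covariation or an intermediate
path supplies a guide to cross.

An exhaustive enumerator (`brute_force_mfe`, n ≤ 18) generates every
admissible nested structure, or every disjoint pseudoknot-free added
layer whose union passes the density-2 check, scores them with the same
standalone energy function, and breaks ties lexicographically.  It is
the oracle for both optimizers and shares no code with the DP beyond the
energy tables.

## Pipeline

Covariation is computed once per alignment; each row gets a projected
guide and four relaxed minimizations: P5 folds the guide directly; P6
re-folds constrained only by the crossing pairs of the P5 result (when
the P5 result has none, the path simply returns it — an empty crossing
guide would otherwise degenerate to an unconstrained fold that always
wins the energy comparison and discards the covariation evidence); P7
extracts relaxed stable stems (chains of single-child pairs with ≤ 2
unpaired bases per side between consecutive pairs, ≥ 3 pairs; defaults
chosen as the smallest helix commonly considered stable and the largest
interruption still read as one helix) from the pseudoknot-free fold and
re-folds on those; P8 first opens the outermost pair of every disjoint
guide substructure and then proceeds as P7.  The minimum-energy result
is reported (ties to the earliest path).  Paths are pure functions, so
sequential and concurrent execution coincide.

## Synthetic data

The generator plants a consensus structure (dot-bracket, extra bracket
layers allowed) and emulates the one signal the method needs:
compensatory mutation.  A root sequence consistent with the planted
pairs is drawn; per sequence, each planted pair is jointly resampled to
a canonical pair with the compensatory rate (otherwise its endpoints
substitute independently at the background rate), unpaired columns
substitute independently, and positions are deleted at the gap rate.
Truth structures are the planted pairs projected through each row's
gaps.

Defaults are chosen for realism rather than simplicity: planted pairs
draw from a GC-enriched distribution (A·U/U·A 0.20 each, G·C/C·G 0.25
each, wobble 0.05 each) and unpaired columns from an A-rich composition
(A 0.45, C 0.25, G 0.10, U 0.20), because real helices are GC-enriched
with a minor wobble fraction and real loops are A-rich and pairing-poor.
A generator that plants a thermodynamically arbitrary structure in an
otherwise random sequence does not emulate structured RNA — functional
structures are near-optimal for their sequences — and under uniform
compositions the planted structure routinely loses the energy
minimization to spurious helices.  Background substitution defaults to
0.05 per position (0.15 in the end-to-end fixtures, a moderate-divergence
family), gap rate to 0.02.

What the generator does *not* emulate: phylogenetically correlated
substitution (rows are independent draws from the root).  Consequently
the background MI noise floor is low and few columns fall below the
alignment-mean MI, so the restricted-unpaired mechanism is exercised
mainly by engineered conserved regions rather than arising broadly as it
would on real families.  Passing tests therefore demonstrate the
machinery under clean covariation, not robustness to alignment error or
phylogenetic autocorrelation.

## Problem sizes in the tests

The test and acceptance workloads use alignments of 20–50 sequences and
64–80 columns, exhaustive-oracle comparisons at n ≤ 16 (500 instances
pseudoknot-free, ~40 pseudoknotted including engineered H-type and
kissing-hairpin chains plus a soft-penalty batch that makes crossing
optima frequent), and runtime scaling measured at n ∈ {50, 100, 200,
400}.  The cubic term of the nested DP is carried by the explicit
bifurcation loops, so the measured log-log slope sits near 2.7 over that
range (the constant-size interior-loop block still dominates at n = 50).

## Known limitations

- The energy constants are a documented compact set, not a reproduction
  of any published table to the digit; absolute energies should not be
  compared against other software.
- The density-2 class excludes pseudoknots nested inside other
  pseudoknots' bands and anything beyond two mutually crossing band
  systems.
- The guide is hard: a wrong intermediary pair cannot be displaced by
  folding (only the relaxation paths can drop it).
- The literal resampling significance test is degenerate on constant
  score vectors (p = 1 regardless of separation); the label-permutation
  variant is provided for that case.
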