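"""End-to-end orchestration: alignment in, one structure per sequence out.

Covariation is computed once per alignment; each row then gets a projected
guide structure and four relaxed energy minimizations:

* path 5 — restricted pseudoknotted minimization on the guide itself;
* path 6 — crossing pairs of the path-5 result (those that cross at least
  one guide pair) become a new guide, allowing competing crossing pairs;
* path 7 — pseudoknot-free minimization, relaxed stable stems extracted,
  then pseudoknotted minimization, allowing competing nested pairs;
* path 8 — like path 7 after first opening the outermost pair of every
  disjoint guide substructure.

The lowest-energy result of the four paths is reported.  All paths are
pure functions of (sequence, guide, parameters), so the default sequential
execution and any concurrent execution give identical results.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from covafold.covariation import adjusted_mutual_information
from covafold.energy_model import EnergyParameters, default_parameters
from covafold.folding import (
    FoldResult,
    FoldingError,
    extract_relaxed_stems,
    open_outer_pairs,
    restricted_pk_mfe,
    restricted_pkfree_mfe,
)
from covafold.guide import (
    DEFAULT_MIN_SPAN,
    DEFAULT_MIP_THRESHOLD,
    GuideStructure,
    guide_from_covariation,
    project_guide,
)
from covafold.msa_io import Alignment
from covafold.msa_io import pairs_cross

logger = logging.getLogger(__name__)

PATH_NAMES = ("P5", "P6", "P7", "P8")


@dataclass
class PipelineConfig:
    threshold: float = DEFAULT_MIP_THRESHOLD
    min_span: int = DEFAULT_MIN_SPAN
    use_restricted_unpaired: bool = True
    min_stem: int = 3
    max_interruption: int = 2
    crossing_resolution: str = "greedy"
    params: EnergyParameters = field(default_factory=default_parameters)


@dataclass
class PredictionRecord:
    """Per-sequence outcome: the four path results and the chosen one."""

    seq_id: str
    sequence: str
    guide: GuideStructure
    path_results: dict[str, FoldResult]
    chosen: FoldResult

    @property
    def energy(self) -> float:
        return self.chosen.energy


def _path5(seq: str, guide: GuideStructure, cfg: PipelineConfig) -> FoldResult:
    return restricted_pk_mfe(seq, guide, cfg.params)


def _path6(seq: str, guide: GuideStructure, cfg: PipelineConfig) -> FoldResult:
    base = restricted_pk_mfe(seq, guide, cfg.params)
    crossing = frozenset(
        p
        for p in base.structure.pairs
        if any(pairs_cross(p, g) for g in guide.pairs)
    )
    if not crossing:
        # no crossing pairs identified: this path contributes no competing
        # candidate and simply hands back the restricted result
        return base
    new_guide = GuideStructure(
        length=guide.length, pairs=crossing, unpaired=guide.unpaired
    )
    return restricted_pk_mfe(seq, new_guide, cfg.params)


def _path7(seq: str, guide: GuideStructure, cfg: PipelineConfig) -> FoldResult:
    nested = restricted_pkfree_mfe(seq, guide, cfg.params)
    stems = extract_relaxed_stems(
        nested.structure, min_len=cfg.min_stem, max_interruption=cfg.max_interruption
    )
    stem_guide = GuideStructure(
        length=guide.length,
        pairs=stems.pairs - frozenset(
            p for p in stems.pairs if p[0] in guide.unpaired or p[1] in guide.unpaired
        ),
        unpaired=guide.unpaired,
    )
    return restricted_pk_mfe(seq, stem_guide, cfg.params)


def _path8(seq: str, guide: GuideStructure, cfg: PipelineConfig) -> FoldResult:
    return _path7(seq, open_outer_pairs(guide), cfg)


_PATHS = {"P5": _path5, "P6": _path6, "P7": _path7, "P8": _path8}


def run_paths(
    seq: str, guide: GuideStructure, config: PipelineConfig | None = None,
    seq_id: str = "",
) -> PredictionRecord:
    """Run the four relaxed-minimization paths and pick the energy minimum.

    A path failing on a degenerate input falls back to the empty-guide fold
    for that path (logged); ties between paths go to the earliest path.
    """
    cfg = config or PipelineConfig()
    results: dict[str, FoldResult] = {}
    for name in PATH_NAMES:
        try:
            results[name] = _PATHS[name](seq, guide, cfg)
        except FoldingError as exc:
            logger.warning("%s failed for %r (%s); falling back to empty guide",
                           name, seq_id, exc)
            fallback = GuideStructure(length=len(seq), unpaired=guide.unpaired)
            results[name] = restricted_pk_mfe(seq, fallback, cfg.params)
        results[name].method_tag = name
    chosen = min(results.values(), key=lambda r: (r.energy, PATH_NAMES.index(r.method_tag)))
    return PredictionRecord(
        seq_id=seq_id, sequence=seq, guide=guide, path_results=results, chosen=chosen
    )


def predict_alignment(
    aln: Alignment, config: PipelineConfig | None = None
) -> list[PredictionRecord]:
    """Predict one possibly pseudoknotted structure per aligned sequence.

    Covariation (MI, APC, MIp) is computed once; the alignment-level guide
    is projected per sequence.  Output order is input order; the whole run
    is deterministic for a fixed configuration.  Per-sequence failures are
    logged and skipped (the record is omitted).
    """
    cfg = config or PipelineConfig()
    mim = adjusted_mutual_information(aln)
    alignment_guide = guide_from_covariation(
        mim,
        threshold=cfg.threshold,
        min_span=cfg.min_span,
        use_restricted=cfg.use_restricted_unpaired,
        crossing_resolution=cfg.crossing_resolution,
    )
    records: list[PredictionRecord] = []
    for rid, row in zip(aln.ids, aln.rows):
        try:
            seq, projected = project_guide(alignment_guide, row)
            records.append(run_paths(seq, projected, cfg, seq_id=rid))
        except Exception:
            logger.exception("prediction failed for %r; skipping", rid)
    return records
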