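"""Structure-Influence (SI) scoring of chromosomal rearrangements.

For each rearrangement (CR) that passes filtering, two raw features are
measured against one cell line's Hi-C-derived boundaries and its
strong-enhancer track:

* **Insulation Score** — the highest strength among TAD boundaries inside
  the CR.
* **Enhancer Score** — the sum of strong-enhancer base pairs in the three
  400 kb windows around the two CR breakpoints and the strongest contained
  boundary (windowed variant), or enhancer bp over the whole CR divided by
  CR length (whole-region variant).

Each feature is percentile-transformed across the CR set within the cell
line, and SI = pct(insulation) x pct(enhancer). A mean SI across cell lines
averages the per-cell-line SI values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .boundaries import BoundaryCall
from .genome_intervals import (
    CREvent,
    EnhancerTrack,
    interval_length,
    overlap_bp,
    window_around,
)

__all__ = [
    "CRScore",
    "FilterConfig",
    "FilterReport",
    "filter_crs",
    "contained_boundaries",
    "top_boundary",
    "cr_insulation_score",
    "cr_enhancer_score_windows",
    "cr_enhancer_score_whole",
    "percentile_transform",
    "si_scores",
    "mean_si",
    "score_crs",
]

SCORED_TYPES = frozenset({"deletion", "duplication", "inversion"})


@dataclass
class CRScore:
    cr_id: str
    cell_line: str
    insulation_score: float
    enhancer_score: float
    pct_ins: float = float("nan")
    pct_enh: float = float("nan")
    si: float = float("nan")
    si_sum: float = float("nan")  # alternate statistic: pct_ins + pct_enh


@dataclass(frozen=True)
class FilterConfig:
    """Filtering stages: genome loci, CR length, boundary containment.

    Length bounds are mandatory and echoed into the FilterReport; types
    outside the scored set (deletion/duplication/inversion) are dropped
    first.
    """

    chromosomes: Optional[frozenset] = None  # None = any chromosome
    min_len: int = 100_000
    max_len: int = 10_000_000
    types: frozenset = SCORED_TYPES


@dataclass
class FilterReport:
    n_input: int
    n_after_type: int
    n_after_loci: int
    n_after_length: int
    n_after_boundary: int
    dropped: Dict[str, str] = field(default_factory=dict)  # cr_id -> reason
    config: Optional[FilterConfig] = None

    def to_dict(self) -> dict:
        d = {
            "n_input": self.n_input,
            "n_after_type": self.n_after_type,
            "n_after_loci": self.n_after_loci,
            "n_after_length": self.n_after_length,
            "n_after_boundary": self.n_after_boundary,
            "n_dropped": len(self.dropped),
        }
        if self.config is not None:
            d["min_len"] = self.config.min_len
            d["max_len"] = self.config.max_len
        return d


def contained_boundaries(cr: CREvent, boundaries: Sequence[BoundaryCall]) -> list[BoundaryCall]:
    iv = cr.interval
    return [b for b in boundaries
            if b.chrom == iv.chrom and iv.start <= b.position < iv.end]


def filter_crs(
    crs: Sequence[CREvent],
    boundaries: Sequence[BoundaryCall],
    config: FilterConfig = FilterConfig(),
) -> tuple[list[CREvent], FilterReport]:
    """Apply the CR-filtering workflow: type, genome loci, length, and
    proximity to TAD boundaries (a CR must contain at least one boundary).
    """
    if len(boundaries) == 0:
        raise ValueError("empty boundary list: cannot apply the boundary-containment stage")
    dropped: Dict[str, str] = {}

    stage1 = [c for c in crs if c.cr_type in config.types]
    for c in crs:
        if c.cr_type not in config.types:
            dropped[c.cr_id] = "type"

    if config.chromosomes is None:
        stage2 = list(stage1)
    else:
        stage2 = []
        for c in stage1:
            if c.interval.chrom in config.chromosomes:
                stage2.append(c)
            else:
                dropped[c.cr_id] = "loci"

    stage3 = []
    for c in stage2:
        if config.min_len <= interval_length(c.interval) <= config.max_len:
            stage3.append(c)
        else:
            dropped[c.cr_id] = "length"

    stage4 = []
    for c in stage3:
        if contained_boundaries(c, boundaries):
            stage4.append(c)
        else:
            dropped[c.cr_id] = "no boundary"

    report = FilterReport(
        n_input=len(crs),
        n_after_type=len(stage1),
        n_after_loci=len(stage2),
        n_after_length=len(stage3),
        n_after_boundary=len(stage4),
        dropped=dropped,
        config=config,
    )
    return stage4, report


def top_boundary(cr: CREvent, boundaries: Sequence[BoundaryCall]) -> Optional[BoundaryCall]:
    """The strongest boundary contained in the CR, or None."""
    inside = contained_boundaries(cr, boundaries)
    if not inside:
        return None
    return max(inside, key=lambda b: b.strength)


def cr_insulation_score(
    cr: CREvent,
    boundaries: Sequence[BoundaryCall],
    missing: str = "error",
) -> float:
    """Highest boundary strength inside the CR.

    ``missing='error'`` (default) raises when the CR contains no boundary —
    filtering guarantees at least one; ``missing='zero'`` returns 0.0
    instead (used when scoring unfiltered CR sets for benchmarking).
    """
    tb = top_boundary(cr, boundaries)
    if tb is None:
        if missing == "zero":
            return 0.0
        raise ValueError(f"CR {cr.cr_id} contains no TAD boundary")
    return tb.strength


def cr_enhancer_score_windows(
    cr: CREvent,
    top_boundary: Optional[BoundaryCall],
    enhancers: EnhancerTrack,
    window_bp: int = 400_000,
    union: bool = False,
) -> int:
    """Strong-enhancer base pairs in the three 400 kb windows around the
    two CR breakpoints and the strongest contained boundary.

    The three tallies are summed per-window by default; ``union=True``
    deduplicates overlapping windows (short CRs) by merging them first.
    """
    chrom = cr.interval.chrom
    anchors = [cr.interval.start, cr.interval.end]
    if top_boundary is not None:
        anchors.append(top_boundary.position)
    windows = [window_around(p, window_bp, chrom) for p in anchors]
    if union:
        merged = EnhancerTrack(windows).merged().intervals
        return sum(overlap_bp(w, enhancers) for w in merged)
    return sum(overlap_bp(w, enhancers) for w in windows)


def cr_enhancer_score_whole(cr: CREvent, enhancers: EnhancerTrack) -> float:
    """Enhancer bp over the whole CR region, normalized by CR length."""
    return overlap_bp(cr.interval, enhancers) / interval_length(cr.interval)


def percentile_transform(values: Sequence[float]) -> np.ndarray:
    """Map each value to (number of values <= it) / N.

    Ties take the maximal rank, so the transform is deterministic and the
    largest value always maps to 1.0; outputs lie in (0, 1].
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("percentile_transform requires a nonempty list")
    return rankdata(v, method="max") / v.size


def si_scores(
    ins: Sequence[float],
    enh: Sequence[float],
    cr_ids: Optional[Sequence[str]] = None,
    cell_line: str = "",
) -> list[CRScore]:
    """Percentile-transform the two raw score vectors and form
    SI = pct_ins * pct_enh (plus the alternate sum statistic)."""
    ins = np.asarray(ins, dtype=float)
    enh = np.asarray(enh, dtype=float)
    if ins.shape != enh.shape:
        raise ValueError(f"length mismatch: {ins.shape} vs {enh.shape}")
    if cr_ids is None:
        cr_ids = [str(i) for i in range(ins.size)]
    pct_i = percentile_transform(ins)
    pct_e = percentile_transform(enh)
    return [
        CRScore(
            cr_id=cid,
            cell_line=cell_line,
            insulation_score=float(a),
            enhancer_score=float(b),
            pct_ins=float(pi),
            pct_enh=float(pe),
            si=float(pi * pe),
            si_sum=float(pi + pe),
        )
        for cid, a, b, pi, pe in zip(cr_ids, ins, enh, pct_i, pct_e)
    ]


def mean_si(per_cell_scores: Dict[str, Sequence[CRScore]]) -> pd.Series:
    """Arithmetic mean of SI per CR across cell lines.

    CRs missing from some cell lines average over the lines where they are
    present; a CR present nowhere is absent from the output.
    """
    acc: Dict[str, list[float]] = {}
    for scores in per_cell_scores.values():
        for s in scores:
            acc.setdefault(s.cr_id, []).append(s.si)
    return pd.Series({cid: float(np.mean(v)) for cid, v in acc.items()},
                     name="mean_si")


def score_crs(
    crs: Sequence[CREvent],
    boundaries: Sequence[BoundaryCall],
    enhancers: EnhancerTrack,
    cell_line: str = "",
    window_bp: int = 400_000,
    enhancer_variant: str = "windows",
    missing_boundary: str = "error",
) -> pd.DataFrame:
    """Full per-cell-line scoring of a CR set.

    Returns a DataFrame with one row per CR: raw scores, percentiles, SI and
    the alternate sum statistic.
    """
    ins_scores = []
    enh_scores = []
    for cr in crs:
        tb = top_boundary(cr, boundaries)
        ins_scores.append(
            cr_insulation_score(cr, boundaries, missing=missing_boundary)
        )
        if enhancer_variant == "windows":
            enh_scores.append(
                cr_enhancer_score_windows(cr, tb, enhancers, window_bp=window_bp)
            )
        elif enhancer_variant == "whole":
            enh_scores.append(cr_enhancer_score_whole(cr, enhancers))
        else:
            raise ValueError(f"unknown enhancer_variant {enhancer_variant!r}")
    scores = si_scores(
        ins_scores, enh_scores, cr_ids=[c.cr_id for c in crs], cell_line=cell_line
    )
    return pd.DataFrame(
        {
            "cr_id": [s.cr_id for s in scores],
            "cell_line": [s.cell_line for s in scores],
            "insulation_score": [s.insulation_score for s in scores],
            "enhancer_score": [s.enhancer_score for s in scores],
            "pct_ins": [s.pct_ins for s in scores],
            "pct_enh": [s.pct_enh for s in scores],
            "si": [s.si for s in scores],
            "si_sum": [s.si_sum for s in scores],
        }
    )
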