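"""Recruitment scoring: overlap of prey spots with anchors, replicate pooling,
condition normalization and testing.

The recruitment score of a field is the summed raw GFP intensity over the
"yellow" pixels (prey-spot ∩ anchor overlap) divided by the total segmented
anchor area — equivalently the mean GFP in the overlap times the overlap area
over the summed red area. Replicates pool intensities and areas across all
fields before dividing, so a replicate behaves as one measurement over tens
of small image regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import stats

from .segmentation import LabeledSpots

__all__ = [
    "OverlapSet",
    "RecruitmentResult",
    "ConditionSummary",
    "overlap_regions",
    "recruitment_score",
    "pool_replicate",
    "summarize_condition",
]

log = logging.getLogger("pictquant")


@dataclass
class OverlapSet:
    mask: np.ndarray  # bool, prey ∩ anchor
    yellow_area: int
    pairs: list[tuple[int, int]]  # (prey label, anchor label) sharing >= 1 px


@dataclass
class RecruitmentResult:
    yellow_area: int
    sum_green_in_yellow: float
    red_area: int
    scope: str = "field"  # or "replicate"
    meta: dict = dc_field(default_factory=dict)

    @property
    def mean_green_in_yellow(self) -> float:
        return self.sum_green_in_yellow / self.yellow_area if self.yellow_area else 0.0

    @property
    def score(self) -> float:
        # mean_green * yellow_area / red_area == sum_green_over_yellow / red_area
        return self.sum_green_in_yellow / self.red_area if self.yellow_area else 0.0


def overlap_regions(prey: LabeledSpots, anchors: LabeledSpots) -> OverlapSet:
    """Pixelwise AND of the two spot masks plus the contributing label pairs."""
    if prey.labels.shape != anchors.labels.shape:
        raise ValueError("prey and anchor label images must share a shape")
    mask = prey.mask & anchors.mask
    pl = prey.labels[mask]
    al = anchors.labels[mask]
    pairs = sorted({(int(a), int(b)) for a, b in zip(pl, al)})
    return OverlapSet(mask, int(mask.sum()), pairs)


def recruitment_score(raw_green: np.ndarray, prey: LabeledSpots,
                      anchors: LabeledSpots, area_mode: str = "overlap",
                      meta: dict | None = None) -> RecruitmentResult | None:
    """Score one field. Returns None (with a warning) if no anchor was segmented.

    ``area_mode='overlap'`` counts only the yellow (intersection) pixels;
    ``'whole_spot'`` counts every pixel of each prey spot that touches an
    anchor.
    """
    raw_green = np.asarray(raw_green, dtype=np.float64)
    red_area = anchors.total_area
    if red_area == 0:
        log.warning("field %s excluded: no segmented anchors (red_area = 0)",
                    (meta or {}).get("field_id", "?"))
        return None
    ov = overlap_regions(prey, anchors)
    if area_mode == "overlap":
        region = ov.mask
    elif area_mode == "whole_spot":
        touching = {p for p, _ in ov.pairs}
        region = np.isin(prey.labels, sorted(touching)) if touching \
            else np.zeros_like(ov.mask)
    else:
        raise ValueError(f"unknown area_mode {area_mode!r}")
    area = int(region.sum())
    total = float(raw_green[region].sum()) if area else 0.0
    return RecruitmentResult(area, total, red_area, "field", dict(meta or {}))


def pool_replicate(field_results: list[RecruitmentResult],
                   meta: dict | None = None) -> RecruitmentResult:
    """Pool fields of one biological replicate: sum intensities and areas
    across fields before dividing (not a mean of per-field scores)."""
    results = [r for r in field_results if r is not None]
    if not results:
        raise ValueError("pool_replicate needs at least one scored field")
    red_area = sum(r.red_area for r in results)
    if red_area == 0:
        raise ValueError("pooled red area is zero")
    return RecruitmentResult(
        yellow_area=sum(r.yellow_area for r in results),
        sum_green_in_yellow=sum(r.sum_green_in_yellow for r in results),
        red_area=red_area, scope="replicate", meta=dict(meta or {}))


@dataclass
class ConditionSummary:
    condition: str
    replicate_scores: np.ndarray
    mean: float
    sd: float
    n: int
    normalized_mean: float | None = None
    normalized_sd: float | None = None
    reference: str | None = None
    comparison: str | None = None
    p_value: float | None = None

    def to_row(self) -> dict:
        return {"condition": self.condition, "mean": self.mean, "sd": self.sd,
                "n": self.n, "normalized_mean": self.normalized_mean,
                "normalized_sd": self.normalized_sd, "reference": self.reference,
                "comparison": self.comparison, "p_value": self.p_value}


def summarize_condition(condition: str, replicate_scores,
                        reference: "ConditionSummary | None" = None,
                        comparison: "ConditionSummary | None" = None,
                        ) -> ConditionSummary:
    """Mean ± SD over replicate scores, normalization to a reference
    condition's mean, and a two-sided Welch t-test against a comparison."""
    scores = np.asarray(list(replicate_scores), dtype=float)
    if scores.size == 0:
        raise ValueError("no replicate scores")
    mean = float(scores.mean())
    sd = float(scores.std(ddof=1)) if scores.size > 1 else 0.0
    summary = ConditionSummary(condition, scores, mean, sd, int(scores.size))
    if reference is not None:
        if reference.mean == 0:
            raise ValueError("reference condition mean is zero; cannot normalize")
        norm = scores / reference.mean
        summary.normalized_mean = float(norm.mean())
        summary.normalized_sd = float(norm.std(ddof=1)) if norm.size > 1 else 0.0
        summary.reference = reference.condition
    if comparison is not None:
        if scores.size < 2 or comparison.replicate_scores.size < 2:
            raise ValueError("t-test needs >= 2 replicates per condition")
        other = comparison.replicate_scores
        if scores.std() == 0 and other.std() == 0:
            # degenerate zero-variance samples: identical means are a perfect
            # null (p = 1); different means are a certain difference (p = 0)
            p = 1.0 if scores.mean() == other.mean() else 0.0
        else:
            _, p = stats.ttest_ind(scores, other, equal_var=False)
        summary.p_value = float(p)
        summary.comparison = comparison.condition
    return summary
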