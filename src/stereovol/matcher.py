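"""End-to-end stereo matching: cost fusion, aggregation, WTA and refinement.

The right-referenced disparity map needed by the left-right consistency
check is produced by re-running the identical matcher on the horizontally
mirrored, swapped pair: right-referenced matching of (L, R) equals
left-referenced matching of (mirror(R), mirror(L)) with the result mirrored
back, so both maps come from the same code path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .cost_volume import ALL_TERMS, CostParams, CostVolume, fused_cost
from .cross_aggregation import AggregationParams, aggregate, build_arms
from .disparity_pipeline import (
    DisparityMap,
    OutlierLabels,
    fill_outliers,
    lr_check,
    median_smooth,
    subpixel,
    wta,
)

__all__ = ["MatchResult", "match_pair"]

log = logging.getLogger(__name__)


@dataclass
class MatchResult:
    """Refined disparity plus the intermediates useful for evaluation."""

    disparity: DisparityMap
    raw_disparity: DisparityMap
    right_disparity: DisparityMap
    labels: OutlierLabels
    volume: CostVolume
    report: dict = field(default_factory=dict)


def _left_reference(
    left: np.ndarray,
    right: np.ndarray,
    cost_params: CostParams,
    agg_params: AggregationParams,
    terms: tuple[str, ...],
) -> tuple[DisparityMap, CostVolume]:
    volume = fused_cost(left, right, cost_params, terms=terms)
    arms_l = build_arms(left, agg_params)
    arms_r = build_arms(right, agg_params)
    volume = aggregate(volume, arms_l, arms_r, agg_params)
    return wta(volume), volume


def _mirror(image: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(image[:, ::-1])


def match_pair(
    left: np.ndarray,
    right: np.ndarray,
    cost_params: CostParams | None = None,
    agg_params: AggregationParams | None = None,
    refine: bool = True,
    median_kernel: int = 3,
    terms: tuple[str, ...] = ALL_TERMS,
) -> MatchResult:
    """Match a rectified pair and return the refined left disparity map.

    Refinement order: left-right consistency labelling, directional filling
    of occlusions/mismatches, subpixel interpolation on the aggregated
    costs, then median smoothing.  ``refine=False`` stops at the raw WTA
    map.  ``terms`` restricts the fused cost components (e.g. ``("sd",)``
    for an SD-only baseline).
    """
    cost_params = cost_params or CostParams()
    agg_params = agg_params or AggregationParams()
    disp_l, volume = _left_reference(left, right, cost_params, agg_params, terms)
    if not refine:
        empty = OutlierLabels(labels=np.zeros(disp_l.shape, dtype=np.uint8))
        return MatchResult(
            disparity=disp_l,
            raw_disparity=disp_l.copy(),
            right_disparity=DisparityMap(np.full(disp_l.shape, np.inf), reference="right"),
            labels=empty,
            volume=volume,
            report={"refined": False},
        )

    disp_r_m, _ = _left_reference(
        _mirror(right), _mirror(left), cost_params, agg_params, terms
    )
    disp_r = DisparityMap(values=disp_r_m.values[:, ::-1].copy(), reference="right")

    labels = lr_check(disp_l, disp_r, cost_params.d_min, cost_params.d_max)
    filled = fill_outliers(disp_l, labels, left)
    sub = subpixel(filled, volume)
    final = median_smooth(sub, kernel=median_kernel)
    counts = labels.counts()
    log.info(
        "match_pair: %(valid)d valid, %(occlusion)d occlusion, %(mismatch)d mismatch", counts
    )
    return MatchResult(
        disparity=final,
        raw_disparity=disp_l,
        right_disparity=disp_r,
        labels=labels,
        volume=volume,
        report={"refined": True, "outliers": counts, "median_kernel": median_kernel},
    )
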