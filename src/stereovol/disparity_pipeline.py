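"""Disparity computation and refinement.

From the aggregated cost volume: winner-takes-all disparity selection,
left-right consistency outlier detection, directional interpolation of
occluded/mismatched pixels, quadratic-polynomial subpixel refinement and
median smoothing; plus the bad-pixel-rate metric used for evaluation
(a pixel is wrong when |d_true - d_est| > 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .cost_volume import CostVolume, to_rgb

__all__ = [
    "INVALID",
    "DisparityMap",
    "OutlierLabels",
    "VALID",
    "OCCLUSION",
    "MISMATCH",
    "wta",
    "lr_check",
    "fill_outliers",
    "subpixel",
    "median_smooth",
    "error_rate",
]

log = logging.getLogger(__name__)

#: sentinel for pixels with no disparity estimate (serialized as PFM infinity)
INVALID = np.inf

VALID, OCCLUSION, MISMATCH = 0, 1, 2


@dataclass
class DisparityMap:
    """Per-pixel disparity in pixels; ``INVALID`` marks missing estimates."""

    values: np.ndarray  # (H, W) float64
    reference: str = "left"

    def __post_init__(self) -> None:
        if self.reference not in ("left", "right"):
            raise ValueError("reference must be 'left' or 'right'")
        self.values = np.asarray(self.values, dtype=np.float64)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    def copy(self) -> "DisparityMap":
        return DisparityMap(values=self.values.copy(), reference=self.reference)


@dataclass
class OutlierLabels:
    """Per-pixel outlier classification: VALID / OCCLUSION / MISMATCH."""

    labels: np.ndarray  # (H, W) uint8

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def counts(self) -> dict[str, int]:
        return {
            "valid": int((self.labels == VALID).sum()),
            "occlusion": int((self.labels == OCCLUSION).sum()),
            "mismatch": int((self.labels == MISMATCH).sum()),
        }


def wta(volume: CostVolume, reference: str = "left") -> DisparityMap:
    """Winner-takes-all: per-pixel argmin cost; ties break toward smaller d."""
    values = volume.values
    if not np.isfinite(values).all():
        raise ValueError("cost volume contains non-finite entries")
    idx = np.argmin(values, axis=2)  # first occurrence = smallest disparity
    n_ties = int((values == np.take_along_axis(values, idx[:, :, None], 2)).sum() - idx.size)
    if n_ties:
        log.debug("WTA: %d tied cost entries broken toward smaller disparity", n_ties)
    return DisparityMap(values=(volume.d_min + idx).astype(np.float64), reference=reference)


def lr_check(
    left_disp: DisparityMap,
    right_disp: DisparityMap,
    d_min: int,
    d_max: int,
) -> OutlierLabels:
    """Left-right consistency test on integer disparity maps.

    Pixel p with disparity d is valid iff |d - d_right(x - d, y)| <= 1.
    Invalid pixels are sub-classified: *occlusion* when no integer d' in
    [d_min, d_max] satisfies d' = d_right(x - d', y) exactly (no surface
    can explain the pixel at all), *mismatch* otherwise.  The exact-match
    discrimination follows the cross-based aggregation refinement
    convention; the tolerant +-1 rule applies only to validity.
    """
    if left_disp.reference != "left" or right_disp.reference != "right":
        raise ValueError("expected a left-referenced and a right-referenced map")
    if left_disp.shape != right_disp.shape:
        raise ValueError("disparity map sizes differ")
    dl, dr = left_disp.values, right_disp.values
    if not (np.all(dl[np.isfinite(dl)] == np.round(dl[np.isfinite(dl)]))):
        raise ValueError("lr_check expects integer disparities (run before subpixel)")
    height, width = dl.shape
    cols = np.arange(width)[None, :]
    target = cols - np.where(np.isfinite(dl), dl, 0).astype(np.int64)
    reachable = np.isfinite(dl) & (target >= 0)
    tclip = np.clip(target, 0, width - 1)
    dr_at = dr[np.arange(height)[:, None], tclip]
    valid = reachable & np.isfinite(dr_at) & (np.abs(dl - dr_at) <= 1)

    # occlusion test: does any candidate disparity pass the consistency check?
    consistent_any = np.zeros((height, width), dtype=bool)
    for d in range(d_min, d_max + 1):
        t = cols - d
        ok = t >= 0
        dr_shift = dr[np.arange(height)[:, None], np.clip(t, 0, width - 1)]
        with np.errstate(invalid="ignore"):
            consistent_any |= ok & np.isfinite(dr_shift) & (dr_shift == d)

    labels = np.full((height, width), MISMATCH, dtype=np.uint8)
    labels[valid] = VALID
    labels[~valid & ~consistent_any] = OCCLUSION
    return OutlierLabels(labels=labels)


_DIRECTIONS_8 = (
    (0, -1), (0, 1), (-1, 0), (1, 0), (-1, -1), (-1, 1), (1, -1), (1, 1),
)


def fill_outliers(
    disp: DisparityMap, labels: OutlierLabels, image: np.ndarray
) -> DisparityMap:
    """Interpolate invalid pixels from the nearest valid pixel in 8 directions.

    Occlusions take the *smallest* candidate disparity (occluded pixels are
    very likely background); mismatches take the candidate whose color is
    closest to the pixel (max per-channel absolute difference).  Pixels with
    no candidate in any direction stay invalid.
    """
    if disp.shape != labels.shape:
        raise ValueError("disparity/label sizes differ")
    rgb = to_rgb(image)
    if rgb.shape[:2] != disp.shape:
        raise ValueError("image size does not match the disparity map")
    height, width = disp.shape
    values = disp.values.copy()
    src_valid = labels.labels == VALID
    invalid_rc = np.argwhere(~src_valid)
    n_unfilled = 0
    for r, c in invalid_rc:
        cand_d: list[float] = []
        cand_color: list[np.ndarray] = []
        for dr, dc in _DIRECTIONS_8:
            rr, cc = r + dr, c + dc
            while 0 <= rr < height and 0 <= cc < width:
                if src_valid[rr, cc]:
                    cand_d.append(disp.values[rr, cc])
                    cand_color.append(rgb[rr, cc])
                    break
                rr += dr
                cc += dc
        if not cand_d:
            n_unfilled += 1
            continue
        if labels.labels[r, c] == OCCLUSION:
            values[r, c] = min(cand_d)
        else:
            diffs = [np.abs(col - rgb[r, c]).max() for col in cand_color]
            values[r, c] = cand_d[int(np.argmin(diffs))]
    if n_unfilled:
        log.info("fill_outliers: %d pixels had no valid candidate in any direction", n_unfilled)
    return DisparityMap(values=values, reference=disp.reference)


def subpixel(disp: DisparityMap, volume: CostVolume) -> DisparityMap:
    """Quadratic-polynomial subpixel refinement around the integer disparity.

    d_sub = d - (C(d+1) - C(d-1)) / (2 (C(d+1) + C(d-1) - 2 C(d))), applied
    only where d-1 and d+1 are in range, the denominator is strictly
    positive, and C(d) does not exceed either neighbor (the integer d is a
    cost minimum, which bounds the shift by +-0.5); elsewhere d is kept.
    """
    if disp.shape != volume.values.shape[:2]:
        raise ValueError("disparity map does not match the cost volume")
    values = disp.values.copy()
    finite = disp.valid_mask()
    d_int = np.where(finite, np.round(disp.values), volume.d_min).astype(np.int64)
    interior = finite & (d_int > volume.d_min) & (d_int < volume.d_max)
    idx = np.clip(d_int - volume.d_min, 1, volume.n_disparities - 2)
    take = lambda off: np.take_along_axis(volume.values, (idx + off)[:, :, None], 2)[:, :, 0]
    c0, cm, cp = take(0), take(-1), take(1)
    denom = cp + cm - 2.0 * c0
    ok = interior & (denom > 0) & (c0 <= cm) & (c0 <= cp)
    shift = np.zeros_like(values)
    np.divide(cp - cm, 2.0 * denom, out=shift, where=ok)
    values[ok] = d_int[ok] - shift[ok]
    return DisparityMap(values=values, reference=disp.reference)


def median_smooth(disp: DisparityMap, kernel: int = 3) -> DisparityMap:
    """Median filter ignoring invalid entries; all-invalid windows stay invalid."""
    if kernel % 2 == 0 or kernel < 3:
        raise ValueError("median kernel must be odd and >= 3")
    pad = kernel // 2
    src = np.where(disp.valid_mask(), disp.values, np.nan)
    padded = np.pad(src, pad, mode="constant", constant_values=np.nan)
    win = np.lib.stride_tricks.sliding_window_view(padded, (kernel, kernel))
    flat = win.reshape(*disp.shape, kernel * kernel)
    with np.errstate(all="ignore"):
        med = np.nanmedian(flat, axis=2)
    out = np.where(np.isnan(med), INVALID, med)
    return DisparityMap(values=out, reference=disp.reference)


def error_rate(
    disp: DisparityMap,
    gt_disparity: np.ndarray,
    occlusion_mask: np.ndarray | None = None,
    exclude_occluded: bool = False,
) -> float:
    """Bad-pixel rate R: fraction of evaluated pixels with |d_t - d_r| > 1.

    Ground-truth pixels marked invalid (non-finite) are excluded; invalid
    *estimated* pixels count as errors.  ``exclude_occluded`` drops pixels
    flagged in ``occlusion_mask`` from the evaluation set.
    """
    gt = np.asarray(gt_disparity, dtype=np.float64)
    if gt.shape != disp.shape:
        raise ValueError("ground-truth size does not match the disparity map")
    evaluate = np.isfinite(gt)
    if exclude_occluded:
        if occlusion_mask is None:
            raise ValueError("exclude_occluded requires an occlusion mask")
        evaluate &= ~np.asarray(occlusion_mask, dtype=bool)
    n_eval = int(evaluate.sum())
    if n_eval == 0:
        raise ValueError("no pixels to evaluate")
    est = disp.values
    with np.errstate(invalid="ignore"):
        bad = evaluate & (~np.isfinite(est) | (np.abs(gt - est) > 1.0))
    return float(bad.sum()) / n_eval
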