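"""Cross-based cost aggregation over adaptive support regions.

Every pixel grows four arms (left/right/up/down) along runs of similar
color; the support region U(p) is the union, over the pixels q on p's
vertical arm, of q's horizontal arms (or the transpose).  Aggregation
averages the cost volume over the *joint* region

    U_d(p) = { q in U(p) : q - (d, 0) in U'(p - (d, 0)) }

where U' is the support region built from the right image, so that both
views agree on the averaging footprint.  Because arms are contiguous runs,
U_d(p) decomposes into per-row (or per-column) intervals whose bounds are
element-wise minima of the two views' arms; the implementation exploits
this with prefix sums while keeping the contract of the enumerated mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cost_volume import CostVolume, to_rgb

__all__ = [
    "AggregationParams",
    "CrossArms",
    "build_arms",
    "support_region",
    "aggregate",
]

#: direction -> (dx, dy) unit steps, image coordinates (x = col, y = row)
_DIRS = {"left": (-1, 0), "right": (1, 0), "up": (0, -1), "down": (0, 1)}


@dataclass(frozen=True)
class AggregationParams:
    """Arm-growing thresholds and aggregation schedule.

    ``tau1`` is the loose color threshold (max per-channel absolute
    difference) that stops arms at edges; ``tau2 < tau1`` is the tight
    threshold applied once an arm is longer than ``L2``, so long arms extend
    only through near-uniform color.  ``L1`` bounds the arm length strictly
    (max arm = L1 - 1 pixels).  Defaults are the calibrated experiment
    values (tau1=20, tau2=6, L1=34, L2=17).  ``orientation_schedule`` gives,
    per aggregation pass, whether the region is built vertical-then-
    horizontal (``"vertical_first"``) or the transpose.
    """

    tau1: float = 20.0
    tau2: float = 6.0
    L1: int = 34
    L2: int = 17
    iterations: int = 2
    orientation_schedule: tuple[str, ...] = ("vertical_first", "horizontal_first")

    def __post_init__(self) -> None:
        if not self.tau2 < self.tau1:
            raise ValueError("tau2 must be < tau1")
        if not self.L2 < self.L1:
            raise ValueError("L2 must be < L1")
        if self.L1 < 1 or self.L2 < 0:
            raise ValueError("arm length thresholds must be positive")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        bad = set(self.orientation_schedule) - {"vertical_first", "horizontal_first"}
        if bad:
            raise ValueError(f"unknown orientations: {sorted(bad)}")

    def orientation(self, iteration: int) -> str:
        return self.orientation_schedule[iteration % len(self.orientation_schedule)]


@dataclass
class CrossArms:
    """Per-pixel arm lengths in pixels (anchor excluded from the count)."""

    left: np.ndarray
    right: np.ndarray
    up: np.ndarray
    down: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.left.shape

    def as_planes(self) -> np.ndarray:
        """(H, W, 4) integer dump (left, right, up, down) for debugging."""
        return np.stack([self.left, self.right, self.up, self.down], axis=2)


def _color_diff(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """D_C: max per-channel absolute difference."""
    return np.abs(a - b).max(axis=2)


def build_arms(image: np.ndarray, params: AggregationParams) -> CrossArms:
    """Grow the four arms of every pixel.

    A candidate at distance ``l`` (1-indexed) extends the arm iff
    D_C(anchor, candidate) < tau1, D_C(candidate, previous) < tau1,
    l < L1, and additionally D_C(anchor, candidate) < tau2 once l > L2.
    All comparisons are strict; arms never cross the image border.
    """
    rgb = to_rgb(image)
    height, width = rgb.shape[:2]
    arms: dict[str, np.ndarray] = {}
    for name, (dx, dy) in _DIRS.items():
        arm = np.zeros((height, width), dtype=np.int32)
        alive = np.ones((height, width), dtype=bool)
        prev = rgb
        for l in range(1, params.L1):
            # candidate pixel at offset l*(dy, dx); out-of-image kills the run
            cand = np.full_like(rgb, np.nan)
            sy, sx = l * dy, l * dx
            src_r = slice(max(sy, 0), height + min(sy, 0))
            src_c = slice(max(sx, 0), width + min(sx, 0))
            dst_r = slice(max(-sy, 0), height + min(-sy, 0))
            dst_c = slice(max(-sx, 0), width + min(-sx, 0))
            cand[dst_r, dst_c] = rgb[src_r, src_c]
            inside = ~np.isnan(cand[:, :, 0])
            d_anchor = _color_diff(cand, rgb)
            d_prev = _color_diff(cand, prev)
            with np.errstate(invalid="ignore"):
                ok = (d_anchor < params.tau1) & (d_prev < params.tau1)
                if l > params.L2:
                    ok &= d_anchor < params.tau2
            alive &= inside & ok
            arm[alive] = l
            if not alive.any():
                break
            prev = cand
        arms[name] = arm
    return CrossArms(**arms)


def support_region(
    arms: CrossArms, p: tuple[int, int], horizontal_first: bool = False
) -> set[tuple[int, int]]:
    """Enumerate the support region of pixel ``p = (row, col)``.

    Vertical-first (default): union over q on p's vertical arm of q's
    horizontal arm; ``horizontal_first`` transposes the construction.
    Always contains p.
    """
    height, width = arms.shape
    row, col = p
    if not (0 <= row < height and 0 <= col < width):
        raise ValueError(f"pixel {p} outside image bounds {arms.shape}")
    region: set[tuple[int, int]] = set()
    if horizontal_first:
        for c in range(col - int(arms.left[row, col]), col + int(arms.right[row, col]) + 1):
            for r in range(row - int(arms.up[row, c]), row + int(arms.down[row, c]) + 1):
                region.add((r, c))
    else:
        for r in range(row - int(arms.up[row, col]), row + int(arms.down[row, col]) + 1):
            for c in range(col - int(arms.left[r, col]), col + int(arms.right[r, col]) + 1):
                region.add((r, c))
    return region


def _interval_sums(
    slice2d: np.ndarray, lo_ext: np.ndarray, hi_ext: np.ndarray, axis: int
) -> tuple[np.ndarray, np.ndarray]:
    """Sum and count of ``slice2d`` over per-pixel index intervals along axis.

    ``lo_ext``/``hi_ext`` are non-negative extents: the interval at index i
    is [i - lo_ext, i + hi_ext] (assumed inside the array).
    """
    if axis == 0:
        s, lo, hi = slice2d.T, lo_ext.T, hi_ext.T
    else:
        s, lo, hi = slice2d, lo_ext, hi_ext
    n_rows, n_cols = s.shape
    ps = np.zeros((n_rows, n_cols + 1), dtype=np.float64)
    np.cumsum(s, axis=1, out=ps[:, 1:])
    idx = np.arange(n_cols)[None, :]
    hi_idx = idx + hi + 1
    lo_idx = idx - lo
    sums = np.take_along_axis(ps, hi_idx, axis=1) - np.take_along_axis(ps, lo_idx, axis=1)
    counts = (hi + lo + 1).astype(np.float64)
    if axis == 0:
        return sums.T, counts.T
    return sums, counts


def _min_shifted(left_arm: np.ndarray, right_arm: np.ndarray, d: int) -> np.ndarray:
    """Element-wise min of the left-view arm at x and right-view arm at x-d."""
    shifted = np.zeros_like(right_arm)
    if d == 0:
        shifted = right_arm
    else:
        shifted[:, d:] = right_arm[:, :-d]
    return np.minimum(left_arm, shifted)


def _aggregate_once(
    values: np.ndarray,
    arms_left: CrossArms,
    arms_right: CrossArms,
    d_min: int,
    vertical_first: bool,
) -> np.ndarray:
    height, width, n_d = values.shape
    out = np.empty_like(values)
    for i in range(n_d):
        d = d_min + i
        slice2d = values[:, :, i]
        if d >= width:
            out[:, :, i] = slice2d
            continue
        # joint arms: min of left-view arms at x and right-view arms at x-d
        eff = {
            name: _min_shifted(getattr(arms_left, name), getattr(arms_right, name), d)
            for name in _DIRS
        }
        if vertical_first:
            # region = union over rows r on the joint vertical arm of the
            # joint horizontal arm of (x, r): horizontal pass first
            hsum, hcnt = _interval_sums(slice2d, eff["left"], eff["right"], axis=1)
            vsum, _ = _interval_sums(hsum, eff["up"], eff["down"], axis=0)
            vcnt, _ = _interval_sums(hcnt, eff["up"], eff["down"], axis=0)
        else:
            vsum0, vcnt0 = _interval_sums(slice2d, eff["up"], eff["down"], axis=0)
            vsum, _ = _interval_sums(vsum0, eff["left"], eff["right"], axis=1)
            vcnt, _ = _interval_sums(vcnt0, eff["left"], eff["right"], axis=1)
        agg = vsum / vcnt
        if d > 0:
            agg[:, :d] = slice2d[:, :d]  # no right correspondent: passthrough
        out[:, :, i] = agg
    return out


def aggregate(
    volume: CostVolume,
    arms_left: CrossArms,
    arms_right: CrossArms,
    params: AggregationParams,
) -> CostVolume:
    """Aggregate the cost volume over joint adaptive support regions.

    Runs ``params.iterations`` passes, alternating the region construction
    orientation per ``params.orientation_schedule``.  Pixels with no right
    correspondent (x < d) keep their input cost.
    """
    if arms_left.shape != volume.values.shape[:2] or arms_right.shape != volume.values.shape[:2]:
        raise ValueError("arm dimensions do not match the cost volume")
    values = volume.values
    for it in range(params.iterations):
        vertical_first = params.orientation(it) == "vertical_first"
        values = _aggregate_once(values, arms_left, arms_right, volume.d_min, vertical_first)
    return CostVolume(
        values=values, d_min=volume.d_min, d_max=volume.d_max, sentinel=volume.sentinel
    )
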