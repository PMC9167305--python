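"""Synthetic stereo scenes and point clouds with exact ground truth.

Scenes are random-dot stereograms over a piecewise-constant disparity map:
raised rectangles/disks painted over a constant base disparity.  Integer
disparities and nearest-column warping keep the ground truth exact (no
resampling blur), and the occlusion mask follows from a forward-warp
visibility test: a left pixel is occluded iff another left pixel with
strictly larger disparity claims its right-image column.

Shape clouds sample the upward-visible surface of a solid (stereo sees the
top) plus the surrounding base plane, with known analytic volume; they feed
the volume pipeline without any reconstruction.

Texture intensities are drawn in [10, 200) so that the gain/bias
photometric distortions exercised by the tests remain strictly increasing
maps after 8-bit rounding (no clipping, no collisions for gain >= 1), which
is what makes the Census bit strings provably invariant to them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "SceneShape",
    "GroundTruthScene",
    "ShapeSpec",
    "generate_disparity_scene",
    "render_stereo_pair",
    "generate_shape_cloud",
]

_TEX_LO, _TEX_HI = 10, 200  # texture intensity range, leaves gain/bias headroom


@dataclass(frozen=True)
class SceneShape:
    """A raised region: axis-aligned rectangle or disk with a disparity offset.

    Rectangles are (x0, y0, width, height); disks are (cx, cy, radius),
    all in pixels.  ``offset`` adds to the base disparity inside the shape.
    """

    kind: str  # "rect" | "disk"
    offset: int
    x0: int = 0
    y0: int = 0
    width: int = 0
    height: int = 0
    cx: int = 0
    cy: int = 0
    radius: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("rect", "disk"):
            raise ValueError(f"unknown scene shape kind {self.kind!r}")
        if self.offset < 0:
            raise ValueError("disparity offset must be >= 0")


@dataclass
class GroundTruthScene:
    """Synthetic scene: exact disparity, occlusion mask, shape description."""

    width: int
    height: int
    disparity_gt: np.ndarray  # (H, W) float64, integer-valued
    occlusion_mask: np.ndarray  # (H, W) bool, True = not visible in right image
    shape_list: tuple[SceneShape, ...] = ()
    base_disparity: int = 0

    @property
    def d_max_used(self) -> int:
        return int(self.disparity_gt.max())


def _paint_shapes(
    width: int, height: int, shapes: list[SceneShape], base_disparity: int
) -> np.ndarray:
    disp = np.full((height, width), float(base_disparity))
    yy, xx = np.mgrid[0:height, 0:width]
    for i, s in enumerate(shapes):
        if s.kind == "rect":
            if not (
                0 <= s.x0 and 0 <= s.y0 and s.width > 0 and s.height > 0
                and s.x0 + s.width <= width and s.y0 + s.height <= height
            ):
                raise ValueError(f"shape {i} (rect) lies outside the {width}x{height} image")
            mask = (xx >= s.x0) & (xx < s.x0 + s.width) & (yy >= s.y0) & (yy < s.y0 + s.height)
        else:
            if not (
                s.radius > 0 and s.cx - s.radius >= 0 and s.cy - s.radius >= 0
                and s.cx + s.radius < width and s.cy + s.radius < height
            ):
                raise ValueError(f"shape {i} (disk) lies outside the {width}x{height} image")
            mask = (xx - s.cx) ** 2 + (yy - s.cy) ** 2 <= s.radius**2
        disp[mask] = base_disparity + s.offset
    return disp


def _occlusion_from_disparity(disp: np.ndarray) -> np.ndarray:
    """Forward-warp visibility: occluded iff a larger disparity wins the column."""
    height, width = disp.shape
    occ = np.zeros((height, width), dtype=bool)
    d = disp.astype(np.int64)
    for r in range(height):
        best = np.full(width, -1, dtype=np.int64)  # per right column: max disparity
        cols = np.arange(width) - d[r]
        inside = cols >= 0
        np.maximum.at(best, cols[inside], d[r][inside])
        occ[r, inside] = d[r][inside] < best[cols[inside]]
    return occ


def generate_disparity_scene(
    width: int,
    height: int,
    shapes: list[SceneShape] | tuple[SceneShape, ...] = (),
    base_disparity: int = 0,
    seed: int = 0,
) -> GroundTruthScene:
    """Piecewise-constant ground-truth disparity scene with occlusion mask."""
    if width < 16 or height < 16:
        raise ValueError("scene must be at least 16x16 pixels")
    if base_disparity < 0:
        raise ValueError("base disparity must be >= 0")
    shapes = tuple(shapes)
    disp = _paint_shapes(width, height, list(shapes), base_disparity)
    occ = _occlusion_from_disparity(disp)
    return GroundTruthScene(
        width=width,
        height=height,
        disparity_gt=disp,
        occlusion_mask=occ,
        shape_list=shapes,
        base_disparity=base_disparity,
    )


def _random_texture(
    height: int, width: int, texture_density: float, rng: np.random.Generator
) -> np.ndarray:
    """Random-dot RGB texture (independent channels), smoothed once (3x3 box).

    Independent channels triple the discriminative information available to
    the SD cost and the color-difference arm rules.  Channel values are
    integers in a clip-free range, so a per-channel monotone photometric
    map (gain >= 1 plus bias) stays strictly increasing per channel after
    8-bit rounding and per-channel Census bit strings are exactly
    invariant to it.
    """
    img = np.full((height, width, 3), float((_TEX_LO + _TEX_HI) // 2))
    dots = rng.random((height, width)) < texture_density
    img[dots] = rng.integers(_TEX_LO, _TEX_HI, size=(int(dots.sum()), 3))
    for ch in range(3):
        img[:, :, ch] = ndimage.uniform_filter(img[:, :, ch], size=3, mode="nearest")
    return np.round(img).astype(np.uint8)


def render_stereo_pair(
    scene: GroundTruthScene,
    texture_density: float = 0.9,
    gain: float = 1.0,
    bias: float = 0.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Render an 8-bit RGB stereo pair consistent with the scene's disparity.

    The right image is the forward warp of the left (right column =
    left column - d, max-disparity winner per column), with fresh texture in
    unclaimed (disoccluded) regions; gain/bias and Gaussian noise apply to
    the right image only.  Identical seeds give bit-identical pairs.
    """
    if not (0 < texture_density <= 1):
        raise ValueError("texture_density must be in (0, 1]")
    if scene.d_max_used >= scene.width:
        raise ValueError("scene disparity exceeds the image width")
    rng = np.random.default_rng(seed)
    left = _random_texture(scene.height, scene.width, texture_density, rng)
    fill = _random_texture(scene.height, scene.width, texture_density, rng)

    d = scene.disparity_gt.astype(np.int64)
    right = fill.copy()
    for r in range(scene.height):
        cols = np.arange(scene.width) - d[r]
        inside = cols >= 0
        # paint in increasing disparity order so the largest-d pixel wins
        order = np.argsort(d[r][inside], kind="stable")
        src = np.where(inside)[0][order]
        right[r, cols[src]] = left[r, src]

    out = right.astype(np.float64) * gain + bias
    if noise_sigma > 0:
        out = out + rng.normal(0.0, noise_sigma, size=out.shape)
    right = np.clip(np.round(out), 0, 255).astype(np.uint8)
    return left, right


@dataclass(frozen=True)
class ShapeSpec:
    """A solid standing on the base plane, with closed-form volume.

    kinds: ``plane`` (no raised material), ``cuboid`` (width x depth x
    height mm) and ``cylinder`` (radius, height mm; axis normal to the
    base).  ``pose`` optionally applies a rigid transform (R, t) to the
    sampled points.
    """

    kind: str
    width: float = 0.0
    depth: float = 0.0
    height: float = 0.0
    radius: float = 0.0
    pose: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("plane", "cuboid", "cylinder"):
            raise ValueError(f"unknown shape kind {self.kind!r}")
        dims = {
            "plane": (self.width, self.depth),
            "cuboid": (self.width, self.depth, self.height),
            "cylinder": (self.radius, self.height),
        }[self.kind]
        if any(v <= 0 for v in dims):
            raise ValueError(f"all {self.kind} dimensions must be > 0")

    @property
    def analytic_volume(self) -> float:
        """Closed-form volume in mm^3 (0 for a bare plane)."""
        if self.kind == "plane":
            return 0.0
        if self.kind == "cuboid":
            return self.width * self.depth * self.height
        return float(np.pi) * self.radius**2 * self.height


def _stratified_xy(
    x0: float, x1: float, y0: float, y1: float, density: float, rng: np.random.Generator
) -> np.ndarray:
    """Stratified-uniform samples over a rectangle at ~``density`` points/mm^2.

    One point uniform within each grid cell: even coverage without the
    grid-phase bias of a plain lattice (a lattice aligned with a footprint
    edge would bias the skirt volume systematically).
    """
    step = 1.0 / np.sqrt(density)
    nx = max(int(np.ceil((x1 - x0) / step)), 1)
    ny = max(int(np.ceil((y1 - y0) / step)), 1)
    gx = x0 + (x1 - x0) * (np.arange(nx) + 0.5) / nx
    gy = y0 + (y1 - y0) * (np.arange(ny) + 0.5) / ny
    xx, yy = np.meshgrid(gx, gy)
    jitter = rng.random((ny, nx, 2)) - 0.5
    xx = xx + jitter[:, :, 0] * (x1 - x0) / nx
    yy = yy + jitter[:, :, 1] * (y1 - y0) / ny
    return np.column_stack([xx.ravel(), yy.ravel()])


def generate_shape_cloud(
    spec: ShapeSpec,
    points_per_mm2: float = 50.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
    base_margin: float = 5.0,
) -> tuple["PointCloud", float]:
    """Sample the shape's exposed top surface plus the surrounding base plane.

    Returns ``(cloud, analytic_volume)``.  Points are jittered-grid samples
    at ``points_per_mm2`` density, perturbed by isotropic Gaussian noise of
    scale ``noise_sigma`` mm.  The base plane extends ``base_margin`` mm
    beyond the footprint on every side.
    """
    from .reconstruction import PointCloud  # local import avoids a cycle

    if points_per_mm2 <= 0:
        raise ValueError("density must be > 0")
    rng = np.random.default_rng(seed)
    if spec.kind == "plane":
        half_w, half_d = spec.width / 2, spec.depth / 2
        xy = _stratified_xy(-half_w, half_w, -half_d, half_d, points_per_mm2, rng)
        pts = np.column_stack([xy, np.zeros(len(xy))])
    elif spec.kind == "cuboid":
        half_w, half_d = spec.width / 2, spec.depth / 2
        m = base_margin
        xy = _stratified_xy(
            -half_w - m, half_w + m, -half_d - m, half_d + m, points_per_mm2, rng
        )
        inside = (np.abs(xy[:, 0]) <= half_w) & (np.abs(xy[:, 1]) <= half_d)
        z = np.where(inside, spec.height, 0.0)
        pts = np.column_stack([xy, z])
    else:  # cylinder, axis normal to the base
        r = spec.radius
        m = base_margin
        xy = _stratified_xy(-r - m, r + m, -r - m, r + m, points_per_mm2, rng)
        inside = xy[:, 0] ** 2 + xy[:, 1] ** 2 <= r**2
        z = np.where(inside, spec.height, 0.0)
        pts = np.column_stack([xy, z])
    if noise_sigma > 0:
        pts = pts + rng.normal(0.0, noise_sigma, size=pts.shape)
    if spec.pose is not None:
        rot, trans = spec.pose
        pts = pts @ np.asarray(rot, dtype=np.float64).T + np.asarray(trans, dtype=np.float64)
    return PointCloud(points=pts), spec.analytic_volume
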