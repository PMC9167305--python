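"""Metric 3D reconstruction from a calibrated disparity map.

For a rectified pair with baseline B (mm), pixel focal lengths f_x, f_y and
principal point (u0, v0), a left pixel (u, v) with disparity d maps to

    X = B (u - u0) / d,   Y = B f_x (v - v0) / (d f_y),   Z = B f_x / d.

The empty-container background cloud is removed by nearest-neighbor
distance: a scene point survives iff its nearest background point is
farther than ``eps`` (exact coordinate equality is meaningless for
reconstructed floats).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .disparity_pipeline import DisparityMap

__all__ = [
    "CameraParams",
    "PointCloud",
    "DEFAULT_CAMERA",
    "disparity_to_depth",
    "disparity_to_cloud",
    "project_points",
    "cloud_subtract",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CameraParams:
    """Stereo calibration: baseline and left-camera intrinsics.

    ``baseline_mm`` is the magnitude of the dominant translation component
    between the cameras; focal lengths are in pixels.  ``focal_mm`` and
    ``pixel_width_mm`` are optional metric intrinsics kept for the
    metric-disparity relation d_pixels = d_metric / pixel_width.
    """

    baseline_mm: float
    focal_px_x: float
    focal_px_y: float
    principal_point_px: tuple[float, float]  # (u0, v0)
    focal_mm: float | None = None
    pixel_width_mm: float | None = None

    def __post_init__(self) -> None:
        if self.baseline_mm <= 0:
            raise ValueError("baseline must be > 0")
        if self.focal_px_x <= 0 or self.focal_px_y <= 0:
            raise ValueError("focal lengths must be > 0")

    @classmethod
    def from_calibration(cls, calib: dict) -> "CameraParams":
        """Build from a calibration dict (intrinsic matrices + translation).

        Expected keys: ``left_intrinsics`` (3x3 row-major) and
        ``translation`` (3-vector, mm); the baseline is the magnitude of the
        dominant translation component, with the left camera as the origin.
        """
        K = np.asarray(calib["left_intrinsics"], dtype=np.float64)
        if K.shape != (3, 3):
            raise ValueError("left_intrinsics must be a 3x3 matrix")
        t = np.asarray(calib["translation"], dtype=np.float64).ravel()
        baseline = float(np.max(np.abs(t)))
        return cls(
            baseline_mm=baseline,
            focal_px_x=float(K[0, 0]),
            focal_px_y=float(K[1, 1]),
            principal_point_px=(float(K[0, 2]), float(K[1, 2])),
        )


#: Example calibration of a real bench rig (Zhang calibration output).
DEFAULT_CAMERA = CameraParams(
    baseline_mm=61.6635,
    focal_px_x=807.35,
    focal_px_y=806.75,
    principal_point_px=(363.86, 240.07),
)


@dataclass
class PointCloud:
    """Points in mm, optional per-point 8-bit RGB colors."""

    points: np.ndarray  # (N, 3) float64
    colors: np.ndarray | None = None  # (N, 3) uint8

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        if self.colors is not None:
            self.colors = np.asarray(self.colors, dtype=np.uint8).reshape(-1, 3)
            if len(self.colors) != len(self.points):
                raise ValueError("colors and points length differ")
        if not np.isfinite(self.points).all():
            raise ValueError("point cloud contains non-finite coordinates")

    def __len__(self) -> int:
        return len(self.points)


def disparity_to_depth(d, cam: CameraParams):
    """Depth Z = B f_x / d (mm); monotone decreasing in d, requires d > 0."""
    d = np.asarray(d, dtype=np.float64)
    if np.any(d <= 0):
        raise ValueError("disparity must be > 0 for depth conversion")
    out = cam.baseline_mm * cam.focal_px_x / d
    return out if out.ndim else float(out)


def disparity_to_cloud(
    disp: DisparityMap, cam: CameraParams, image: np.ndarray | None = None
) -> PointCloud:
    """Reconstruct one 3D point per valid pixel of a left-referenced map.

    Invalid or non-positive disparities are skipped (counted in the log).
    ``image`` optionally supplies per-point colors.
    """
    if disp.reference != "left":
        raise ValueError("reconstruction expects a left-referenced disparity map")
    u0, v0 = cam.principal_point_px
    height, width = disp.shape
    vv, uu = np.mgrid[0:height, 0:width].astype(np.float64)
    d = disp.values
    with np.errstate(invalid="ignore"):
        keep = np.isfinite(d) & (d > 0)
    n_skipped = int((~keep).sum())
    if n_skipped:
        log.info("disparity_to_cloud: skipped %d invalid/non-positive pixels", n_skipped)
    dk = d[keep]
    X = cam.baseline_mm * (uu[keep] - u0) / dk
    Y = cam.baseline_mm * cam.focal_px_x * (vv[keep] - v0) / (dk * cam.focal_px_y)
    Z = cam.baseline_mm * cam.focal_px_x / dk
    colors = None
    if image is not None:
        arr = np.asarray(image)
        if arr.ndim == 2:
            arr = np.repeat(arr[:, :, None], 3, axis=2)
        colors = arr[keep].astype(np.uint8)
    return PointCloud(points=np.column_stack([X, Y, Z]), colors=colors)


def project_points(points: np.ndarray, cam: CameraParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Forward pinhole projection to (u, v, d); inverse of the reconstruction.

    u = u0 + X f_x / Z,  v = v0 + Y f_y / Z,  d = B f_x / Z; requires Z > 0.
    """
    pts = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    X, Y, Z = pts[:, 0], pts[:, 1], pts[:, 2]
    if np.any(Z <= 0):
        raise ValueError("points must have Z > 0 in the camera frame")
    u0, v0 = cam.principal_point_px
    u = u0 + X * cam.focal_px_x / Z
    v = v0 + Y * cam.focal_px_y / Z
    d = cam.baseline_mm * cam.focal_px_x / Z
    return u, v, d


def cloud_subtract(scene: PointCloud, background: PointCloud, eps: float = 1.0) -> PointCloud:
    """Remove scene points within ``eps`` mm of any background point."""
    if eps < 0:
        raise ValueError("eps must be >= 0")
    if len(scene) == 0:
        return PointCloud(points=np.empty((0, 3)))
    if len(background) == 0:
        return PointCloud(
            points=scene.points.copy(),
            colors=None if scene.colors is None else scene.colors.copy(),
        )
    dist, _ = cKDTree(background.points).query(scene.points, k=1)
    keep = dist > eps
    log.info(
        "cloud_subtract: kept %d of %d points (eps=%.3g mm)", int(keep.sum()), len(scene), eps
    )
    return PointCloud(
        points=scene.points[keep],
        colors=None if scene.colors is None else scene.colors[keep],
    )
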