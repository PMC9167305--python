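"""Point-cloud denoising and Delaunay-projection volume estimation.

The cloud is denoised with a normal-based bilateral filter: each point
moves along its estimated normal by the weighted mean of its neighbors'
normal offsets,

    P_i' = P_i + alpha n_i,
    alpha = sum_j Wc(|P_j - P_i|) Ws(|<n_i, P_j - P_i>|) <n_i, P_j - P_i>
            / sum_j Wc(.) Ws(.),

with Gaussian weights Wc (spatial smoothing, scale sigma_c) and Ws
(feature retention, scale sigma_s) over the k nearest neighbors.

For the volume, points are expressed in a base-plane frame (h = height
above a least-squares background plane), their (x, y) projections are
Delaunay-triangulated, and the solid between each triangular surface patch
and its planar projection is accumulated.  That per-triangle solid — a
prism plus two tetrahedra in the classical decomposition — has volume
projected_area * mean(vertex heights), the form used here (the identity is
asserted in the tests).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay, QhullError, cKDTree

from .reconstruction import PointCloud, cloud_subtract

__all__ = [
    "FilterParams",
    "PlaneFrame",
    "TriangulatedSurface",
    "VolumeReport",
    "estimate_normals",
    "bilateral_filter",
    "fit_base_plane",
    "triangulate_projection",
    "composite_volume",
    "compute_volume",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterParams:
    """Bilateral-filter configuration.

    ``sigma_c`` (mm) controls spatial smoothing and ``sigma_s`` (mm) feature
    retention; when left ``None`` they default to the median nearest-
    neighbor distance and twice that value, adapting to sampling density.
    """

    k_neighbors: int = 15
    sigma_c: float | None = None
    sigma_s: float | None = None
    iterations: int = 1

    def __post_init__(self) -> None:
        if self.k_neighbors < 3:
            raise ValueError("k_neighbors must be >= 3")
        if self.sigma_c is not None and self.sigma_c <= 0:
            raise ValueError("sigma_c must be > 0")
        if self.sigma_s is not None and self.sigma_s <= 0:
            raise ValueError("sigma_s must be > 0")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


def _neighbor_indices(points: np.ndarray, k: int) -> np.ndarray:
    """(N, k) indices of the k nearest neighbors of each point (self excluded)."""
    n = len(points)
    if k + 1 > n:
        raise ValueError(f"k={k} neighbors requested but the cloud has only {n} points")
    _, idx = cKDTree(points).query(points, k=k + 1)
    return idx[:, 1:]


def estimate_normals(
    cloud: PointCloud, k: int = 15, degenerate_rtol: float = 1e-9
) -> tuple[np.ndarray, np.ndarray]:
    """Per-point unit normals from local PCA over the k nearest neighbors.

    The normal is the eigenvector of the smallest covariance eigenvalue,
    oriented toward the origin (camera center) where that is defined and
    otherwise flipped to have a non-positive z component.  Returns
    ``(normals, ok)``; ``ok`` is False for degenerate (near-collinear)
    neighborhoods, whose points should pass through unfiltered.
    """
    pts = cloud.points
    nbr = _neighbor_indices(pts, k)
    group = np.concatenate([pts[:, None, :], pts[nbr]], axis=1)  # (N, k+1, 3)
    centered = group - group.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", centered, centered) / group.shape[1]
    eigval, eigvec = np.linalg.eigh(cov)  # ascending eigenvalues
    normals = eigvec[:, :, 0]
    # collinear neighborhood: the two smallest eigenvalues both vanish
    ok = eigval[:, 1] > degenerate_rtol * np.maximum(eigval[:, 2], 1e-300)
    toward = np.einsum("ni,ni->n", normals, pts)
    flip = np.where(np.abs(toward) > 1e-12, toward > 0, normals[:, 2] > 0)
    normals[flip] *= -1.0
    if (~ok).any():
        log.info("estimate_normals: %d degenerate neighborhoods flagged", int((~ok).sum()))
    return normals, ok


def _default_sigmas(points: np.ndarray, nbr: np.ndarray, params: FilterParams) -> tuple[float, float]:
    nn_dist = np.linalg.norm(points[nbr[:, 0]] - points, axis=1)
    med = float(np.median(nn_dist))
    med = med if med > 0 else 1.0
    sigma_c = params.sigma_c if params.sigma_c is not None else med
    sigma_s = params.sigma_s if params.sigma_s is not None else 2.0 * med
    return sigma_c, sigma_s


def bilateral_filter(
    cloud: PointCloud,
    params: FilterParams | None = None,
    normals: np.ndarray | None = None,
) -> PointCloud:
    """Normal-based bilateral denoising; points move only along their normal.

    Normals are (re-)estimated from the current positions at each
    iteration unless supplied for the first pass.  Points with degenerate
    neighborhoods or zero total weight are left unchanged.
    """
    params = params or FilterParams()
    pts = cloud.points.copy()
    for it in range(params.iterations):
        pc = PointCloud(points=pts, colors=None)
        if normals is not None and it == 0:
            n = np.asarray(normals, dtype=np.float64)
            if n.shape != pts.shape:
                raise ValueError("normals shape must match the cloud")
            ok = np.ones(len(pts), dtype=bool)
        else:
            n, ok = estimate_normals(pc, k=params.k_neighbors)
        nbr = _neighbor_indices(pts, params.k_neighbors)
        sigma_c, sigma_s = _default_sigmas(pts, nbr, params)
        dvec = pts[nbr] - pts[:, None, :]  # (N, k, 3)
        dist2 = np.einsum("nkj,nkj->nk", dvec, dvec)
        t = np.einsum("nkj,nj->nk", dvec, n)  # normal offsets of neighbors
        w = np.exp(-dist2 / (2.0 * sigma_c**2)) * np.exp(-(t**2) / (2.0 * sigma_s**2))
        wsum = w.sum(axis=1)
        alpha = np.zeros(len(pts))
        nz = wsum > 0
        alpha[nz] = (w * t).sum(axis=1)[nz] / wsum[nz]
        alpha[~ok] = 0.0
        pts = pts + alpha[:, None] * n
    return PointCloud(points=pts, colors=cloud.colors)


@dataclass
class PlaneFrame:
    """Rigid transform to a base-plane frame (plane at h = 0, material h > 0)."""

    rotation: np.ndarray  # (3, 3): rows are the frame axes (x, y, normal)
    origin: np.ndarray  # (3,)

    def to_frame(self, points: np.ndarray) -> np.ndarray:
        """Map camera/world points to (x, y, h) with h the height above the plane."""
        return (np.asarray(points, dtype=np.float64) - self.origin) @ self.rotation.T

    def from_frame(self, points_xyh: np.ndarray) -> np.ndarray:
        return np.asarray(points_xyh, dtype=np.float64) @ self.rotation + self.origin


def _lstsq_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares plane: returns (centroid, unit normal)."""
    centroid = points.mean(axis=0)
    centered = points - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if len(points) < 3 or s[1] <= 1e-12 * max(s[0], 1e-300):
        raise ValueError("plane fit requires >= 3 non-collinear points")
    return centroid, vt[2]


def _robust_plane(points: np.ndarray, n_trials: int = 200) -> tuple[np.ndarray, np.ndarray]:
    """Dominant plane by least-median-of-squares over seeded point triples.

    A plain total-least-squares fit fails when the raised material's height
    variance exceeds the base's lateral variance (the smallest principal
    axis then lies *in* the base plane); minimizing the median absolute
    residual instead locks onto the majority plane.  Deterministic: the
    triple sampling uses a fixed seed.
    """
    n = len(points)
    if n < 3:
        raise ValueError("plane fit requires >= 3 non-collinear points")
    rng = np.random.default_rng(12345)
    best_score = np.inf
    best: tuple[np.ndarray, np.ndarray] | None = None
    for _ in range(n_trials):
        idx = rng.choice(n, size=3, replace=False)
        a, b, c = points[idx]
        normal = np.cross(b - a, c - a)
        norm = np.linalg.norm(normal)
        if norm < 1e-12:
            continue
        normal = normal / norm
        score = float(np.median(np.abs((points - a) @ normal)))
        if score < best_score:
            best_score = score
            best = (a, normal)
    if best is None:
        raise ValueError("plane fit requires >= 3 non-collinear points")
    anchor, normal = best
    # refit by least squares on the majority band around the best plane
    resid = np.abs((points - anchor) @ normal)
    scale = max(best_score, 1e-9 * (np.ptp(points, axis=0).max() + 1e-300))
    inliers = resid <= 2.5 * scale
    if inliers.sum() >= 3:
        try:
            return _lstsq_plane(points[inliers])
        except ValueError:
            pass
    return anchor, normal


def fit_base_plane(
    cloud: PointCloud,
    background: PointCloud | None = None,
    band_fraction: float = 0.3,
) -> PlaneFrame:
    """Fit the base (background) plane and return the transform to its frame.

    With a ``background`` cloud the plane is the least-squares fit through
    it.  Otherwise the plane is fit through all points and refit through
    the lowest ``band_fraction`` height band, so raised material does not
    tilt the base estimate.  Heights are oriented so the cloud's material
    lies on the positive side.
    """
    ref = background.points if background is not None else cloud.points
    if background is not None:
        centroid, normal = _lstsq_plane(ref)
    else:
        centroid, normal = _robust_plane(ref)
    if background is None:
        h = (cloud.points - centroid) @ normal
        if np.mean(h) < 0:
            normal, h = -normal, -h
        band = h <= np.quantile(h, band_fraction)
        if band.sum() >= 3:
            try:
                centroid, normal = _lstsq_plane(cloud.points[band])
            except ValueError:
                pass  # degenerate band: keep the global fit
    h_all = (cloud.points - centroid) @ normal
    if np.mean(h_all) < 0:
        normal = -normal
    # deterministic in-plane axes: project the world axis least aligned
    # with the normal
    pick = int(np.argmin(np.abs(normal)))
    e = np.zeros(3)
    e[pick] = 1.0
    x_axis = e - normal * (e @ normal)
    x_axis /= np.linalg.norm(x_axis)
    y_axis = np.cross(normal, x_axis)
    rotation = np.stack([x_axis, y_axis, normal])
    return PlaneFrame(rotation=rotation, origin=np.asarray(centroid, dtype=np.float64))


@dataclass
class TriangulatedSurface:
    """Surface points (x, y, h) in the plane frame plus Delaunay triangles."""

    points: np.ndarray  # (N, 3) with h in column 2
    triangles: np.ndarray  # (M, 3) int indices
    n_duplicates: int = 0

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)


def triangulate_projection(points_xyh: np.ndarray) -> TriangulatedSurface:
    """Delaunay-triangulate the (x, y) projections of plane-frame points.

    Exactly coincident projections are deduplicated keeping the maximum
    height (the upper surface wins); all-collinear projections raise.
    """
    pts = np.asarray(points_xyh, dtype=np.float64).reshape(-1, 3)
    if len(pts) < 3:
        raise ValueError("triangulation requires >= 3 points")
    # dedup exact (x, y) duplicates, keep max height
    order = np.lexsort((-pts[:, 2], pts[:, 1], pts[:, 0]))
    spts = pts[order]
    keep = np.ones(len(spts), dtype=bool)
    keep[1:] = np.any(spts[1:, :2] != spts[:-1, :2], axis=1)
    n_dup = int((~keep).sum())
    if n_dup:
        log.info("triangulate_projection: %d duplicate projections dropped", n_dup)
    upts = spts[keep]
    try:
        tri = Delaunay(upts[:, :2])
    except QhullError as exc:
        raise ValueError(f"degenerate projections cannot be triangulated: {exc}") from exc
    simplices = tri.simplices
    # drop zero-area simplices qhull may emit for cocircular inputs
    a = upts[simplices[:, 1], :2] - upts[simplices[:, 0], :2]
    b = upts[simplices[:, 2], :2] - upts[simplices[:, 0], :2]
    area2 = np.abs(a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0])
    simplices = simplices[area2 > 0]
    if len(simplices) == 0:
        raise ValueError("all projected points are collinear")
    return TriangulatedSurface(points=upts, triangles=simplices, n_duplicates=n_dup)


def composite_volume(surface: TriangulatedSurface) -> float:
    """Total volume between the surface patches and their projections.

    Per triangle: projected area times the mean of the three vertex
    heights (clamped at zero), identical to the prism-plus-two-tetrahedra
    decomposition of the patch solid.
    """
    if surface.n_triangles == 0:
        log.warning("composite_volume: empty triangulation, volume 0")
        return 0.0
    p = surface.points
    t = surface.triangles
    a = p[t[:, 1], :2] - p[t[:, 0], :2]
    b = p[t[:, 2], :2] - p[t[:, 0], :2]
    areas = 0.5 * np.abs(a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0])
    heights = np.maximum(p[:, 2][t], 0.0).mean(axis=1)
    return float((areas * heights).sum())


@dataclass
class VolumeReport:
    """Volume plus per-stage bookkeeping for auditing gap/skirt effects."""

    volume_mm3: float
    n_points_input: int
    n_points_after_subtract: int
    n_points_triangulated: int
    n_triangles: int
    n_clamped: int
    n_duplicates: int

    def to_dict(self) -> dict:
        return {
            "volume_mm3": float(f"{self.volume_mm3:.6g}"),
            "n_points_input": self.n_points_input,
            "n_points_after_subtract": self.n_points_after_subtract,
            "n_points_triangulated": self.n_points_triangulated,
            "n_triangles": self.n_triangles,
            "n_clamped": self.n_clamped,
            "n_duplicates": self.n_duplicates,
        }


def compute_volume(
    cloud: PointCloud,
    filter_params: FilterParams | None = None,
    background: PointCloud | None = None,
    eps: float = 1.0,
) -> VolumeReport:
    """Full volume pipeline: subtract, denoise, fit plane, triangulate, sum.

    ``background`` (the empty-container cloud) is both subtracted from the
    scene and used as the base-plane reference; without it the plane comes
    from the cloud's own lowest height band.  Points below the fitted plane
    are reconstruction noise: clamped to h = 0 and counted.
    """
    if len(cloud) == 0:
        raise ValueError("cannot compute the volume of an empty cloud")
    n_input = len(cloud)
    work = cloud
    if background is not None:
        work = cloud_subtract(cloud, background, eps=eps)
    n_sub = len(work)
    if n_sub == 0:
        log.warning("compute_volume: no points left after background subtraction")
        return VolumeReport(0.0, n_input, 0, 0, 0, 0, 0)
    if n_sub >= (filter_params.k_neighbors if filter_params else FilterParams().k_neighbors) + 1:
        work = bilateral_filter(work, filter_params)
    frame = fit_base_plane(work, background=background)
    xyh = frame.to_frame(work.points)
    n_clamped = int((xyh[:, 2] < 0).sum())
    xyh[:, 2] = np.maximum(xyh[:, 2], 0.0)
    if n_sub < 3:
        log.warning("compute_volume: fewer than 3 points, volume 0")
        return VolumeReport(0.0, n_input, n_sub, n_sub, 0, n_clamped, 0)
    surface = triangulate_projection(xyh)
    volume = composite_volume(surface)
    report = VolumeReport(
        volume_mm3=volume,
        n_points_input=n_input,
        n_points_after_subtract=n_sub,
        n_points_triangulated=len(surface.points),
        n_triangles=surface.n_triangles,
        n_clamped=n_clamped,
        n_duplicates=surface.n_duplicates,
    )
    log.info("compute_volume: %s", report.to_dict())
    return report
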