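"""Readers and writers for every on-disk format the pipeline touches.

Images: 8-bit PNG and PGM (both binary P5 and ascii P2 dialects) via
Pillow.  Disparity maps: Middlebury PFM (float, bottom-up row order, scale
sign encodes endianness, infinity marks invalid pixels); a 16-bit PNG
export with an explicit scale factor is provided for convenience.  Point
clouds: ascii PLY (written with double precision for exact roundtrips,
read via trimesh) and whitespace XYZ.  Calibration: YAML in the
intrinsics/rotation/translation table layout.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import trimesh
import yaml
from PIL import Image

from .disparity_pipeline import DisparityMap
from .reconstruction import PointCloud

__all__ = [
    "read_image",
    "write_image",
    "read_pfm",
    "write_pfm",
    "write_disparity_png16",
    "read_ply",
    "write_ply",
    "read_xyz",
    "write_xyz",
    "read_calibration",
    "write_calibration",
]


# -- 8-bit images -----------------------------------------------------------

def read_image(path) -> np.ndarray:
    """Read an 8-bit grayscale or RGB image (PNG, PGM P2/P5, PPM)."""
    path = Path(path)
    try:
        img = Image.open(path)
        img.load()
    except Exception as exc:
        raise ValueError(f"cannot read image {path}: {exc}") from exc
    if img.mode in ("I", "I;16", "I;16B", "I;16L", "F"):
        raise ValueError(f"{path}: 16-bit/float images need an explicit scale (use PFM)")
    if img.mode == "L":
        return np.asarray(img, dtype=np.uint8)
    if img.mode in ("RGB", "RGBA", "P", "LA"):
        return np.asarray(img.convert("RGB"), dtype=np.uint8)
    raise ValueError(f"{path}: unsupported image mode {img.mode}")


def write_image(path, image: np.ndarray) -> None:
    """Write an 8-bit grayscale or RGB image; format from the extension."""
    path = Path(path)
    arr = np.asarray(image)
    if arr.dtype != np.uint8:
        raise ValueError("write_image expects uint8 data")
    if arr.ndim == 3 and path.suffix.lower() == ".pgm":
        raise ValueError("PGM stores grayscale only; convert or use PNG")
    Image.fromarray(arr).save(path)


# -- PFM disparity maps -----------------------------------------------------

def read_pfm(path) -> DisparityMap:
    """Read a Middlebury PFM file into a left-referenced disparity map."""
    path = Path(path)
    with open(path, "rb") as f:
        header = f.readline().strip()
        if header == b"Pf":
            channels = 1
        elif header == b"PF":
            raise ValueError(f"{path}: color PFM is not a disparity map")
        else:
            raise ValueError(f"{path}: malformed PFM header {header!r}")
        dims = f.readline().split()
        if len(dims) != 2:
            raise ValueError(f"{path}: malformed PFM dimensions line")
        width, height = int(dims[0]), int(dims[1])
        scale = float(f.readline().strip())
        if scale == 0:
            raise ValueError(f"{path}: PFM scale must be nonzero")
        endian = "<" if scale < 0 else ">"
        count = width * height * channels
        raw = f.read(count * 4)
        if len(raw) != count * 4:
            raise ValueError(f"{path}: truncated PFM payload")
    data = np.frombuffer(raw, dtype=endian + "f4").astype(np.float64)
    values = data.reshape(height, width)[::-1]  # PFM rows are bottom-up
    return DisparityMap(values=values.copy(), reference="left")


def write_pfm(path, disp: DisparityMap) -> None:
    """Write a disparity map as little-endian PFM; invalid pixels as +inf."""
    path = Path(path)
    values = np.where(disp.valid_mask(), disp.values, np.inf).astype("<f4")
    height, width = values.shape
    with open(path, "wb") as f:
        f.write(b"Pf\n")
        f.write(f"{width} {height}\n".encode())
        f.write(b"-1.0\n")
        f.write(values[::-1].tobytes())


def write_disparity_png16(path, disp: DisparityMap, scale: float) -> None:
    """16-bit PNG export: stored value = round(disparity * scale), invalid = 0."""
    if scale <= 0:
        raise ValueError("scale must be > 0")
    values = np.where(disp.valid_mask(), disp.values * scale, 0.0)
    if values.max() > 65535:
        raise ValueError("scaled disparity exceeds the 16-bit range")
    arr = np.round(values).astype(np.uint16)
    Image.fromarray(arr).save(Path(path))


# -- point clouds -----------------------------------------------------------

def write_ply(path, cloud: PointCloud) -> None:
    """Write an ascii PLY 1.0 point cloud (double precision, deterministic)."""
    path = Path(path)
    with open(path, "w", newline="\n") as f:
        f.write("ply\nformat ascii 1.0\n")
        f.write(f"element vertex {len(cloud)}\n")
        f.write("property double x\nproperty double y\nproperty double z\n")
        if cloud.colors is not None:
            f.write("property uchar red\nproperty uchar green\nproperty uchar blue\n")
        f.write("end_header\n")
        if cloud.colors is None:
            for x, y, z in cloud.points:
                f.write(f"{x:.17g} {y:.17g} {z:.17g}\n")
        else:
            for (x, y, z), (r, g, b) in zip(cloud.points, cloud.colors):
                f.write(f"{x:.17g} {y:.17g} {z:.17g} {r} {g} {b}\n")


def read_ply(path) -> PointCloud:
    """Read a PLY point cloud (ascii or binary) via trimesh."""
    path = Path(path)
    try:
        obj = trimesh.load(str(path), process=False)
    except Exception as exc:
        raise ValueError(f"cannot read PLY {path}: {exc}") from exc
    points = np.asarray(obj.vertices, dtype=np.float64)
    colors = None
    try:
        c = np.asarray(obj.colors)
        if c.size and len(c) == len(points):
            colors = c[:, :3].astype(np.uint8)
    except Exception:
        colors = None
    return PointCloud(points=points, colors=colors)


def write_xyz(path, cloud: PointCloud) -> None:
    """Write whitespace-separated x y z text."""
    np.savetxt(Path(path), cloud.points, fmt="%.17g")


def read_xyz(path) -> PointCloud:
    """Read whitespace-separated x y z text."""
    pts = np.loadtxt(Path(path), dtype=np.float64)
    return PointCloud(points=pts.reshape(-1, 3))


# -- calibration ------------------------------------------------------------

def read_calibration(path) -> dict:
    """Read a YAML calibration file in the table layout.

    Required: ``left_intrinsics`` (3x3) and ``translation`` (3-vector);
    ``right_intrinsics``, distortion vectors and ``rotation`` are stored
    for completeness (distortion is not applied downstream).
    """
    path = Path(path)
    with open(path) as f:
        data = yaml.safe_load(f)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: calibration file must be a YAML mapping")
    for key in ("left_intrinsics", "translation"):
        if key not in data:
            raise ValueError(f"{path}: missing calibration key {key!r}")
    return data


def write_calibration(path, calib: dict) -> None:
    with open(Path(path), "w") as f:
        yaml.safe_dump(calib, f, sort_keys=True)
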