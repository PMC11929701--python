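"""Tracked-sweep 3D reconstruction of vessel point clouds.

Each ultrasound frame is a 2D raster whose image plane is embedded at z = 0 in
the probe frame; the frame's pose maps image-plane millimetre coordinates to
the world.  Reconstruction maps every retained vessel-mask pixel centre through
its frame pose and pools the results into one world-space cloud, which is then
voxel-downsampled and given PCA surface normals for feature extraction.

Conventions: pixels are 0-based ``(u, v) = (column, row)``; pixel (0, 0) has
its centre at the probe-frame origin; units are millimetres throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .geometry import RigidTransform

_NORMAL_TOL = 1e-6


@dataclass(frozen=True)
class UltrasoundFrame:
    """A posed 2D ultrasound image.

    Attributes
    ----------
    image : (H, W) float array, intensities in [0, 1] (uint8 inputs are
        normalized by callers that load PNGs).
    spacing : (sx, sy) mm/px for the u (column) and v (row) directions.
    pose : rigid map from probe-frame mm coordinates (u*sx, v*sy, 0) to world.
    index : frame number within its sweep.
    """

    image: np.ndarray
    spacing: tuple
    pose: RigidTransform
    index: int = 0

    def __post_init__(self):
        img = np.asarray(self.image)
        if img.ndim != 2:
            raise ValueError("frame image must be 2D")
        sx, sy = self.spacing
        if sx <= 0 or sy <= 0:
            raise ValueError("pixel spacing must be positive")
        object.__setattr__(self, "image", img)
        object.__setattr__(self, "spacing", (float(sx), float(sy)))

    @property
    def shape(self) -> tuple:
        return self.image.shape


@dataclass
class VesselPointCloud:
    """N x 3 point cloud (mm) with optional unit normals and a provenance tag."""

    points: np.ndarray
    normals: Optional[np.ndarray] = None
    tag: str = ""

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.points = pts
        if self.normals is not None:
            nrm = np.asarray(self.normals, dtype=float).reshape(-1, 3)
            if nrm.shape != pts.shape:
                raise ValueError("normals must be one per point")
            lengths = np.linalg.norm(nrm, axis=1)
            if pts.shape[0] and np.any(np.abs(lengths - 1.0) > _NORMAL_TOL):
                raise ValueError("normals must be unit length")
            self.normals = nrm

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def has_normals(self) -> bool:
        return self.normals is not None

    def transformed(self, transform: RigidTransform) -> "VesselPointCloud":
        normals = (transform.apply_vectors(self.normals)
                   if self.normals is not None else None)
        return VesselPointCloud(transform.apply(self.points), normals, self.tag)

    def subset(self, indices) -> "VesselPointCloud":
        idx = np.asarray(indices)
        normals = self.normals[idx] if self.normals is not None else None
        return VesselPointCloud(self.points[idx], normals, self.tag)


def pixel_to_world(frame: UltrasoundFrame, pixel) -> np.ndarray:
    """World position (mm) of a pixel centre ``(u, v) = (column, row)``."""
    u, v = pixel
    h, w = frame.shape
    if not (0 <= u < w and 0 <= v < h):
        raise IndexError(f"pixel {pixel} outside raster {frame.shape}")
    sx, sy = frame.spacing
    return frame.pose.apply(np.array([u * sx, v * sy, 0.0]))


def pixels_to_world(frame: UltrasoundFrame, uv: np.ndarray) -> np.ndarray:
    """Vectorized ``pixel_to_world`` for an (N, 2) array of (u, v) pixels."""
    uv = np.asarray(uv, dtype=float)
    sx, sy = frame.spacing
    plane = np.column_stack([uv[:, 0] * sx, uv[:, 1] * sy,
                             np.zeros(len(uv))])
    return frame.pose.apply(plane)


def reconstruct_cloud(frames: Sequence[UltrasoundFrame],
                      masks: Sequence[np.ndarray],
                      stride: int = 1) -> VesselPointCloud:
    """Pool world-mapped vessel-mask pixel centres over a sweep.

    ``stride`` subsamples the pixel grid (keep pixels whose row and column are
    both multiples of ``stride``); the returned point count equals the number
    of retained mask pixels summed over frames.
    """
    if len(frames) != len(masks):
        raise ValueError(f"{len(frames)} frames but {len(masks)} masks")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    chunks = []
    for frame, mask in zip(frames, masks):
        mask = np.asarray(mask)
        if mask.shape != frame.shape:
            raise ValueError(
                f"mask shape {mask.shape} != frame shape {frame.shape}")
        kept = np.zeros_like(mask, dtype=bool)
        kept[::stride, ::stride] = mask[::stride, ::stride] > 0
        vv, uu = np.nonzero(kept)
        if len(uu):
            chunks.append(pixels_to_world(frame, np.column_stack([uu, vv])))
    points = np.vstack(chunks) if chunks else np.empty((0, 3))
    return VesselPointCloud(points, tag="US")


def voxel_downsample(cloud: VesselPointCloud, voxel: float) -> VesselPointCloud:
    """Replace all points in each occupied voxel by their centroid.

    Output order is lexicographic in voxel index, so the result is a pure
    function of the input set.  Normals, when present, are averaged and
    renormalized (degenerate averages fall back to the first member's normal).
    """
    if voxel <= 0:
        raise ValueError("voxel size must be positive")
    if len(cloud) == 0:
        return VesselPointCloud(np.empty((0, 3)), tag=cloud.tag)
    keys = np.floor(cloud.points / voxel).astype(np.int64)
    order = np.lexsort((keys[:, 2], keys[:, 1], keys[:, 0]))
    keys_sorted = keys[order]
    boundaries = np.r_[0, 1 + np.nonzero(np.any(np.diff(keys_sorted, axis=0) != 0,
                                                axis=1))[0], len(keys_sorted)]
    pts = cloud.points[order]
    centroids = np.add.reduceat(pts, boundaries[:-1], axis=0)
    counts = np.diff(boundaries)[:, None]
    centroids = centroids / counts
    normals = None
    if cloud.normals is not None:
        nrm = cloud.normals[order]
        mean_n = np.add.reduceat(nrm, boundaries[:-1], axis=0) / counts
        lengths = np.linalg.norm(mean_n, axis=1, keepdims=True)
        bad = lengths[:, 0] < 1e-9
        mean_n[bad] = nrm[boundaries[:-1]][bad]
        lengths = np.linalg.norm(mean_n, axis=1, keepdims=True)
        normals = mean_n / lengths
    return VesselPointCloud(centroids, normals, cloud.tag)


def estimate_normals(cloud: VesselPointCloud, k: int = 30) -> VesselPointCloud:
    """PCA surface normals from the k nearest neighbours of each point.

    The normal is the eigenvector of the local covariance with the smallest
    eigenvalue, signed to point away from the neighbourhood centroid (outward
    for tubular samplings, whose local centroid lies toward the axis).
    """
    n = len(cloud)
    if k < 3:
        raise ValueError("k must be >= 3")
    if n < k:
        raise ValueError(f"need at least k={k} points, got {n}")
    tree = cKDTree(cloud.points)
    _, idx = tree.query(cloud.points, k=k)
    neigh = cloud.points[idx]                       # (n, k, 3)
    centroids = neigh.mean(axis=1)                  # (n, 3)
    centered = neigh - centroids[:, None, :]
    cov = np.einsum("nki,nkj->nij", centered, centered) / k
    _, vecs = np.linalg.eigh(cov)                   # ascending eigenvalues
    normals = vecs[:, :, 0]
    outward = cloud.points - centroids
    flip = np.einsum("ni,ni->n", normals, outward) < 0
    normals[flip] *= -1.0
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    return VesselPointCloud(cloud.points.copy(), normals, cloud.tag)
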