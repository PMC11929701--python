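"""Synthetic vessel phantom: trees, tracked sweeps, CT clouds, tumor targets.

This module stands in for the patient, the robot-held ultrasound probe, and
the preoperative CT segmentation.  It generates

* a branching tree of straight cylindrical vessel segments,
* surface point samplings of that tree (with analytic outward normals),
* a simulated tracked ultrasound sweep (intensity frames with hypoechoic
  vessels on a speckled background, plus ground-truth masks),
* a CT-side point cloud of the same tree under a hidden rigid transform plus
  a mild smooth deformation, and
* tumor targets fixed relative to the vessels,

all as pure functions of their seeds, so every downstream accuracy number has
an exact ground truth.  Units are millimetres; the world frame is
right-handed with the root vessel growing along +z.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .geometry import RigidTransform, random_rigid_transform
from .reconstruct import UltrasoundFrame, VesselPointCloud

# Intensity model for rendered frames: vessels hypoechoic (dark) on a brighter
# speckled background, separable under a 0.5 confidence threshold even at the
# extremes of the multiplicative speckle.
_VESSEL_INTENSITY = 0.15
_BACKGROUND_INTENSITY = 0.8
_SPECKLE_RANGE = (0.75, 1.25)


def _orthonormal_basis(direction: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Deterministic (e1, e2) completing ``direction`` to a right-handed frame."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    helper = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    return e1, e2


@dataclass
class VesselTree:
    """Straight cylindrical vessel segments forming a connected tree.

    ``starts[i]`` coincides with a point on the parent segment (its end, in
    generated trees); radii are strictly positive and never exceed the
    parent's radius.
    """

    starts: np.ndarray          # (n, 3)
    ends: np.ndarray            # (n, 3)
    radii: np.ndarray           # (n,)
    parents: np.ndarray         # (n,) int, -1 for the root
    root: int = 0

    def __post_init__(self):
        self.starts = np.asarray(self.starts, dtype=float).reshape(-1, 3)
        self.ends = np.asarray(self.ends, dtype=float).reshape(-1, 3)
        self.radii = np.asarray(self.radii, dtype=float).reshape(-1)
        self.parents = np.asarray(self.parents, dtype=int).reshape(-1)
        n = len(self.radii)
        if not (self.starts.shape[0] == self.ends.shape[0] == n == self.parents.shape[0]):
            raise ValueError("inconsistent segment arrays")
        if np.any(self.radii <= 0):
            raise ValueError("segment radii must be strictly positive")

    @property
    def n_segments(self) -> int:
        return len(self.radii)

    @property
    def directions(self) -> np.ndarray:
        d = self.ends - self.starts
        return d / np.linalg.norm(d, axis=1, keepdims=True)

    @property
    def lengths(self) -> np.ndarray:
        return np.linalg.norm(self.ends - self.starts, axis=1)

    def surface_area(self) -> float:
        """Total lateral (cylinder side) area, mm^2."""
        return float(np.sum(2.0 * np.pi * self.radii * self.lengths))

    def junctions(self) -> np.ndarray:
        """(J, 3) world positions of bifurcations (ends that spawn children)."""
        has_child = np.unique(self.parents[self.parents >= 0])
        return self.ends[has_child]

    def bounds(self, margin: float = 0.0) -> Tuple[np.ndarray, np.ndarray]:
        pad = self.radii.max() + margin if self.n_segments else margin
        lo = np.minimum(self.starts.min(axis=0), self.ends.min(axis=0)) - pad
        hi = np.maximum(self.starts.max(axis=0), self.ends.max(axis=0)) + pad
        return lo, hi

    def distance_to_centerline(self, points: np.ndarray) -> np.ndarray:
        """Distance from each point to the nearest segment axis (clamped)."""
        return self._segment_distances(points).min(axis=1)

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        """Negative inside some tube, positive outside; zero on the surface."""
        d = self._segment_distances(points) - self.radii[None, :]
        return d.min(axis=1)

    def _segment_distances(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float).reshape(-1, 3)
        n = self.n_segments
        out = np.empty((p.shape[0], n))
        for i in range(n):
            a, b = self.starts[i], self.ends[i]
            ab = b - a
            denom = float(ab @ ab)
            t = np.clip((p - a) @ ab / denom, 0.0, 1.0)
            closest = a + t[:, None] * ab
            out[:, i] = np.linalg.norm(p - closest, axis=1)
        return out


def make_vessel_tree(seed: int,
                     depth: int = 3,
                     root_radius: float = 3.0,
                     branch_angle_range: Tuple[float, float] = (20.0, 45.0),
                     root_length: float = 30.0,
                     radius_decay: float = 0.75,
                     length_decay: float = 0.72) -> VesselTree:
    """Random full binary vessel tree of straight cylinders.

    The root grows along +z; each generation halves into two children whose
    radii and lengths decay by fixed factors and whose directions deviate from
    the parent by an angle drawn uniformly from ``branch_angle_range``
    (degrees), at roughly opposite azimuths.
    """
    if root_radius <= 0:
        raise ValueError("root_radius must be positive")
    if depth < 0:
        raise ValueError("depth must be >= 0")
    lo, hi = branch_angle_range
    if not (0.0 <= lo <= hi):
        raise ValueError("invalid branch_angle_range")
    rng = np.random.default_rng(seed)
    starts = [np.zeros(3)]
    ends = [np.array([0.0, 0.0, root_length])]
    radii = [float(root_radius)]
    parents = [-1]
    frontier = [(0, np.array([0.0, 0.0, 1.0]), root_length, root_radius)]
    for _ in range(depth):
        next_frontier = []
        for idx, direction, length, radius in frontier:
            child_len = length * length_decay
            child_rad = radius * radius_decay
            azimuth0 = rng.uniform(0.0, 2.0 * np.pi)
            e1, e2 = _orthonormal_basis(direction)
            for j in range(2):
                theta = np.radians(rng.uniform(lo, hi))
                phi = azimuth0 + j * np.pi + rng.normal(0.0, 0.15)
                child_dir = (np.cos(theta) * direction
                             + np.sin(theta) * (np.cos(phi) * e1 + np.sin(phi) * e2))
                child_dir /= np.linalg.norm(child_dir)
                start = ends[idx]
                starts.append(start.copy())
                ends.append(start + child_len * child_dir)
                radii.append(child_rad)
                parents.append(idx)
                next_frontier.append((len(radii) - 1, child_dir, child_len, child_rad))
        frontier = next_frontier
    return VesselTree(np.array(starts), np.array(ends), np.array(radii),
                      np.array(parents))


def sample_tree_surface(tree: VesselTree, density: float,
                        seed: int = 0) -> VesselPointCloud:
    """Poisson sampling of the tube surfaces at ``density`` points per mm^2.

    Each segment draws from its own seed substream, so a segment's sample does
    not depend on how many other segments exist (sampling is additive over
    segments).  Points lie exactly on the cylinder surface; normals are the
    analytic outward radial directions.
    """
    if density <= 0:
        raise ValueError("density must be positive")
    pts, nrms = [], []
    dirs = tree.directions if tree.n_segments else None
    for i in range(tree.n_segments):
        rng = np.random.default_rng([int(seed), i])
        radius = tree.radii[i]
        length = tree.lengths[i]
        n = rng.poisson(density * 2.0 * np.pi * radius * length)
        if n == 0:
            continue
        t = rng.uniform(0.0, length, n)
        phi = rng.uniform(0.0, 2.0 * np.pi, n)
        e1, e2 = _orthonormal_basis(dirs[i])
        radial = np.cos(phi)[:, None] * e1 + np.sin(phi)[:, None] * e2
        pts.append(tree.starts[i] + t[:, None] * dirs[i] + radius * radial)
        nrms.append(radial)
    if not pts:
        return VesselPointCloud(np.empty((0, 3)), None, tag="CT")
    return VesselPointCloud(np.vstack(pts), np.vstack(nrms), tag="CT")


def jitter_along_normals(cloud: VesselPointCloud, sigma: float,
                         rng: np.random.Generator) -> VesselPointCloud:
    """Gaussian surface-localization noise, directed along each point's normal."""
    if not cloud.has_normals:
        raise ValueError("cloud has no normals to jitter along")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0 or len(cloud) == 0:
        return VesselPointCloud(cloud.points.copy(), cloud.normals, cloud.tag)
    offsets = rng.normal(0.0, sigma, len(cloud))[:, None] * cloud.normals
    return VesselPointCloud(cloud.points + offsets, cloud.normals, cloud.tag)


@dataclass(frozen=True)
class DeformationField:
    """Smooth, bounded displacement field: breathing-residual nuisance term.

    The displacement is the sum of three mutually orthogonal sinusoidal
    components whose amplitudes sum in quadrature to ``amplitude``, so the
    per-point displacement magnitude never exceeds ``amplitude`` and the field
    is band-limited at ``wavelength``.  ``amplitude == 0`` is the identity.
    """

    amplitude: float
    wavelength: float = 80.0
    seed: int = 0

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")

    def _components(self):
        rng = np.random.default_rng(self.seed)
        # random orthonormal triad of displacement directions
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 2] *= -1.0
        wave_dirs = rng.normal(size=(3, 3))
        wave_dirs /= np.linalg.norm(wave_dirs, axis=1, keepdims=True)
        phases = rng.uniform(0.0, 2.0 * np.pi, 3)
        return q.T, wave_dirs, phases

    def displacement(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float).reshape(-1, 3)
        if self.amplitude == 0.0:
            return np.zeros_like(p)
        axes, wave_dirs, phases = self._components()
        scale = self.amplitude / np.sqrt(3.0)
        disp = np.zeros_like(p)
        for i in range(3):
            phase = 2.0 * np.pi * (p @ wave_dirs[i]) / self.wavelength + phases[i]
            disp += scale * np.sin(phase)[:, None] * axes[i]
        return disp


def apply_deformation(cloud: VesselPointCloud,
                      field: DeformationField) -> VesselPointCloud:
    """Displace every point by the field (normals carried over unchanged)."""
    if field.amplitude == 0.0:
        return VesselPointCloud(cloud.points.copy(), cloud.normals, cloud.tag)
    return VesselPointCloud(cloud.points + field.displacement(cloud.points),
                            cloud.normals, cloud.tag)


def make_sweep_path(tree: VesselTree,
                    n_frames: int = 60,
                    pixel_spacing: float = 0.2,
                    margin: float = 4.0) -> Tuple[List[RigidTransform], Tuple[int, int]]:
    """Parallel transverse image planes covering the tree, swept along +z.

    Returns the list of frame poses (image u -> world x, v -> world y, plane
    normal +z) and the image shape needed to cover the tree's lateral extent
    with ``margin`` mm on each side.
    """
    if n_frames < 1:
        raise ValueError("need at least one frame")
    lo, hi = tree.bounds(margin)
    width = int(np.ceil((hi[0] - lo[0]) / pixel_spacing)) + 1
    height = int(np.ceil((hi[1] - lo[1]) / pixel_spacing)) + 1
    z_positions = np.linspace(lo[2], hi[2], n_frames)
    poses = [RigidTransform.from_rotation_translation(
        np.eye(3), np.array([lo[0], lo[1], z])) for z in z_positions]
    return poses, (height, width)


def simulate_sweep(tree: VesselTree,
                   probe_path: Sequence[RigidTransform],
                   image_shape: Tuple[int, int],
                   pixel_spacing: float = 0.2,
                   noise_sigma: float = 0.0,
                   seed: int = 0) -> Tuple[List[UltrasoundFrame], List[np.ndarray]]:
    """Render a tracked sweep: intensity frames plus ground-truth vessel masks.

    A pixel is vessel-labelled iff its world-mapped centre lies inside some
    tube, with the tube boundary jittered by Gaussian noise of scale
    ``noise_sigma`` (mm, applied to the signed distance).  Vessels render
    hypoechoic on a brighter background with multiplicative speckle.
    """
    if pixel_spacing <= 0:
        raise ValueError("pixel_spacing must be positive")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    h, w = image_shape
    uu, vv = np.meshgrid(np.arange(w), np.arange(h))
    plane = np.column_stack([uu.ravel() * pixel_spacing,
                             vv.ravel() * pixel_spacing,
                             np.zeros(h * w)])
    frames, masks = [], []
    for i, pose in enumerate(probe_path):
        world = pose.apply(plane)
        sd = tree.signed_distance(world)
        if noise_sigma > 0:
            # jitter only near the boundary; far pixels cannot flip sign
            near = np.abs(sd) < max(6.0 * noise_sigma, 1e-6)
            sd = sd.copy()
            sd[near] += rng.normal(0.0, noise_sigma, int(near.sum()))
        mask = (sd <= 0.0).reshape(h, w)
        speckle = rng.uniform(*_SPECKLE_RANGE, size=(h, w))
        image = np.where(mask, _VESSEL_INTENSITY, _BACKGROUND_INTENSITY) * speckle
        np.clip(image, 0.0, 1.0, out=image)
        frames.append(UltrasoundFrame(image, (pixel_spacing, pixel_spacing),
                                      pose, index=i))
        masks.append(mask.astype(np.uint8))
    return frames, masks


def _draw_targets(tree: VesselTree, n_targets: int, max_distance: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Tumor targets fixed relative to the vessels, each within
    ``max_distance`` mm of some segment centerline."""
    targets = np.empty((n_targets, 3))
    dirs = tree.directions
    for i in range(n_targets):
        seg = int(rng.integers(0, tree.n_segments))
        t = rng.uniform(0.2, 0.8) * tree.lengths[seg]
        on_axis = tree.starts[seg] + t * dirs[seg]
        e1, e2 = _orthonormal_basis(dirs[seg])
        phi = rng.uniform(0.0, 2.0 * np.pi)
        # keep a safety margin inside the stated proximity bound
        dist = rng.uniform(tree.radii[seg] + 2.0, 0.8 * max_distance)
        targets[i] = on_axis + dist * (np.cos(phi) * e1 + np.sin(phi) * e2)
    return targets


@dataclass
class PhantomCase:
    """Complete synthetic case with ground truth.

    ``world_to_ct`` is the hidden rigid transform: the CT cloud is the
    (optionally deformed) vessel surface sampling mapped through it, plus
    surface jitter.  The ultrasound frames image the *undeformed* tree in the
    world ("current patient") frame.  Targets are stored both in CT space (as
    a plan would provide them) and at their true world positions.
    """

    tree: VesselTree
    world_to_ct: RigidTransform
    deformation: DeformationField
    ct_cloud: VesselPointCloud
    frames: List[UltrasoundFrame]
    masks: List[np.ndarray]
    targets_ct: np.ndarray
    targets_world: np.ndarray
    seed: int
    params: dict = field(default_factory=dict)

    @property
    def ct_to_world(self) -> RigidTransform:
        """The transform registration should recover."""
        return self.world_to_ct.inverse()


def make_phantom_case(seed: int,
                      tree_params: Optional[dict] = None,
                      transform_params: Optional[dict] = None,
                      deformation_amplitude: float = 1.0,
                      deformation_wavelength: float = 80.0,
                      noise_sigma: float = 0.2,
                      n_targets: int = 4,
                      max_target_distance: float = 30.0,
                      surface_density: float = 2.0,
                      n_frames: int = 60,
                      pixel_spacing: float = 0.2) -> PhantomCase:
    """Build one full phantom case from a single seed.

    Defaults emulate the phantom study conditions: a depth-3 tree, four tumor
    targets within 30 mm of a vessel, a hidden rigid transform of up to 15
    degrees / 30 mm, deformation amplitude 1 mm, and a ~60-frame transverse
    sweep at 0.2 mm/px with boundary noise ``noise_sigma``.
    """
    tree_params = dict(tree_params or {})
    transform_params = dict(transform_params or {})
    max_rot = transform_params.pop("max_rotation_deg", 15.0)
    max_trans = transform_params.pop("max_translation_mm", 30.0)
    if transform_params:
        raise ValueError(f"unknown transform_params: {sorted(transform_params)}")
    rng = np.random.default_rng(seed)
    tree = make_vessel_tree(seed=int(rng.integers(2 ** 31)), **tree_params)
    world_to_ct = random_rigid_transform(rng, max_rot, max_trans)
    deformation = DeformationField(deformation_amplitude, deformation_wavelength,
                                   seed=int(rng.integers(2 ** 31)))

    surface = sample_tree_surface(tree, surface_density,
                                  seed=int(rng.integers(2 ** 31)))
    deformed = apply_deformation(surface, deformation)
    ct_cloud = jitter_along_normals(deformed.transformed(world_to_ct),
                                    noise_sigma, rng)
    ct_cloud.tag = "CT"

    targets_world = _draw_targets(tree, n_targets, max_target_distance, rng)
    targets_ct = world_to_ct.apply(
        targets_world + deformation.displacement(targets_world))

    poses, image_shape = make_sweep_path(tree, n_frames, pixel_spacing)
    frames, masks = simulate_sweep(tree, poses, image_shape, pixel_spacing,
                                   noise_sigma, seed=int(rng.integers(2 ** 31)))
    params = dict(tree_params=tree_params, max_rotation_deg=max_rot,
                  max_translation_mm=max_trans,
                  deformation_amplitude=deformation_amplitude,
                  deformation_wavelength=deformation_wavelength,
                  noise_sigma=noise_sigma, n_targets=n_targets,
                  max_target_distance=max_target_distance,
                  surface_density=surface_density, n_frames=n_frames,
                  pixel_spacing=pixel_spacing)
    return PhantomCase(tree, world_to_ct, deformation, ct_cloud, frames, masks,
                       targets_ct, targets_world, seed, params)


def tree_to_volume(tree: VesselTree, spacing: float = 1.0,
                   margin: float = 5.0):
    """Rasterize the tree into a contrast-CT-like volume (vessels bright).

    Returns a ``target_fuse.CTVolume``; used by the fusion demo and CLI.
    """
    from .target_fuse import CTVolume

    lo, hi = tree.bounds(margin)
    shape = np.maximum(np.ceil((hi - lo) / spacing).astype(int) + 1, 2)
    xs = lo[0] + spacing * np.arange(shape[0])
    ys = lo[1] + spacing * np.arange(shape[1])
    zs = lo[2] + spacing * np.arange(shape[2])
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    inside = tree.signed_distance(pts) <= 0.0
    data = np.where(inside, 300.0, 50.0).reshape(shape)
    return CTVolume(data, np.full(3, float(spacing)), lo.copy())
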