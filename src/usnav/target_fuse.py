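"""Target localization, puncture-plan geometry, and CT/US slice fusion.

After registration the CT-space puncture target is mapped into the current
patient (ultrasound world) frame; the plan's needle angle and depth are
checked against the guide mechanism's envelope (angle 10-50 degrees from the
skin plane, depth 0-100 mm); and the CT volume is resampled on the current
ultrasound image plane — one trilinear CT sample per ultrasound pixel — for
fused display.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple, Union

import numpy as np
from scipy import ndimage

from .geometry import RigidTransform
from .reconstruct import UltrasoundFrame, pixels_to_world
from .register import RegistrationResult

#: puncture guide mechanism envelope
ANGLE_RANGE_DEG = (10.0, 50.0)
DEPTH_RANGE_MM = (0.0, 100.0)


@dataclass
class CTVolume:
    """Axis-aligned scalar voxel grid; voxel (i, j, k) sits at
    ``origin + (i*dx, j*dy, k*dz)`` in world millimetres."""

    data: np.ndarray             # (nx, ny, nz)
    spacing: np.ndarray          # (3,) mm
    origin: np.ndarray           # (3,) mm

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3D")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be positive per axis")

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Continuous voxel indices of world points."""
        p = np.asarray(points, dtype=float).reshape(-1, 3)
        return (p - self.origin) / self.spacing


@dataclass
class TrajectoryPlan:
    """Needle path from skin entry to target, with derived angle and depth."""

    entry: np.ndarray            # (3,) mm, world
    target: np.ndarray           # (3,) mm, world
    angle_deg: float             # needle axis vs skin plane; 90 = perpendicular
    depth_mm: float


@dataclass
class PlanVerdict:
    valid: bool
    reasons: List[str]


@dataclass
class FusedSlice:
    """CT resampled on the ultrasound plane plus an alpha-blended overlay."""

    ct: np.ndarray               # (H, W), volume units, fill outside
    overlay: np.ndarray          # (H, W), blended display raster in [0, 1]


def _as_transform(registration: Union[RegistrationResult, RigidTransform]) -> RigidTransform:
    if isinstance(registration, RegistrationResult):
        return registration.transform
    return registration


def localize_target(registration: Union[RegistrationResult, RigidTransform],
                    ct_target: np.ndarray) -> np.ndarray:
    """Map a CT-space target through the recovered CT -> world transform."""
    return _as_transform(registration).apply(np.asarray(ct_target, dtype=float))


def target_localization_error(predicted: np.ndarray, truth: np.ndarray) -> float:
    """Euclidean distance (mm) between predicted and true target positions."""
    return float(np.linalg.norm(np.asarray(predicted, dtype=float)
                                - np.asarray(truth, dtype=float)))


def plan_geometry(entry: np.ndarray, target: np.ndarray,
                  skin_normal: np.ndarray) -> TrajectoryPlan:
    """Derive needle depth and entry angle from the planned path.

    Depth is the entry-to-target distance; the angle is measured between the
    needle axis and the skin (probe-face) plane, so 90 degrees is a
    perpendicular entry and 0 degrees lies in the plane.
    """
    entry = np.asarray(entry, dtype=float).reshape(3)
    target = np.asarray(target, dtype=float).reshape(3)
    normal = np.asarray(skin_normal, dtype=float).reshape(3)
    if abs(np.linalg.norm(normal) - 1.0) > 1e-6:
        raise ValueError("skin_normal must be unit length")
    depth = float(np.linalg.norm(target - entry))
    if depth == 0.0:
        raise ValueError("entry and target coincide")
    direction = (target - entry) / depth
    angle = float(np.degrees(np.arcsin(
        np.clip(abs(direction @ normal), 0.0, 1.0))))
    return TrajectoryPlan(entry, target, angle, depth)


def validate_plan(plan: TrajectoryPlan,
                  angle_range: Tuple[float, float] = ANGLE_RANGE_DEG,
                  depth_range: Tuple[float, float] = DEPTH_RANGE_MM) -> PlanVerdict:
    """Check the plan against the puncture guide mechanism envelope."""
    reasons = []
    if plan.angle_deg < angle_range[0]:
        reasons.append(f"angle {plan.angle_deg:.1f} deg below minimum {angle_range[0]:g} deg")
    if plan.angle_deg > angle_range[1]:
        reasons.append(f"angle {plan.angle_deg:.1f} deg above maximum {angle_range[1]:g} deg")
    if plan.depth_mm < depth_range[0]:
        reasons.append(f"depth {plan.depth_mm:.1f} mm below minimum {depth_range[0]:g} mm")
    if plan.depth_mm > depth_range[1]:
        reasons.append(f"depth {plan.depth_mm:.1f} mm above maximum {depth_range[1]:g} mm")
    return PlanVerdict(not reasons, reasons)


def fuse_slice(volume: CTVolume,
               frame: UltrasoundFrame,
               registration: Union[RegistrationResult, RigidTransform],
               fill: float = 0.0,
               alpha: float = 0.5) -> FusedSlice:
    """Resample the CT volume on the ultrasound image plane and blend.

    Every ultrasound pixel centre is mapped to world, pulled back into CT
    space through the inverse registration, and trilinearly interpolated;
    pixels whose CT-space position leaves the voxel grid receive ``fill``
    exactly.  The resampled slice therefore has the ultrasound frame's shape
    and spacing — the CT is rescaled to the ultrasound image's proportions by
    construction.
    """
    transform = _as_transform(registration)
    h, w = frame.shape
    uu, vv = np.meshgrid(np.arange(w), np.arange(h))
    world = pixels_to_world(frame, np.column_stack([uu.ravel(), vv.ravel()]))
    ct_pts = transform.inverse().apply(world)
    idx = volume.world_to_index(ct_pts)
    upper = np.asarray(volume.data.shape) - 1
    inside = np.all((idx >= 0.0) & (idx <= upper), axis=1)
    values = np.full(h * w, float(fill))
    if inside.any():
        values[inside] = ndimage.map_coordinates(
            volume.data, idx[inside].T, order=1, mode="nearest")
    ct = values.reshape(h, w)

    us = np.asarray(frame.image, dtype=float)
    if us.size and us.max() > 1.0:
        us = us / 255.0
    lo, hi = float(volume.data.min()), float(volume.data.max())
    ct_norm = (ct - lo) / (hi - lo) if hi > lo else np.zeros_like(ct)
    overlay = np.clip(alpha * ct_norm + (1.0 - alpha) * us, 0.0, 1.0)
    return FusedSlice(ct, overlay)
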