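"""File-format plumbing: ASCII PLY point clouds, pose CSVs, transform and
plan JSON, mask PNGs, NIfTI volumes, YAML configs, and phantom case export.

All formats round-trip losslessly through this module (PLY floats are written
with full double precision).
"""

from __future__ import annotations

import json
import os
from pathlib import Path
from typing import List, Optional, Tuple

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .geometry import RigidTransform
from .phantom import PhantomCase
from .reconstruct import UltrasoundFrame, VesselPointCloud
from .register import RegistrationResult
from .target_fuse import CTVolume

# ---------------------------------------------------------------------------
# PLY point clouds (ASCII, x/y/z with optional nx/ny/nz)


def write_ply(path, cloud: VesselPointCloud) -> None:
    path = Path(path)
    n = len(cloud)
    props = ["property double x", "property double y", "property double z"]
    if cloud.has_normals:
        props += ["property double nx", "property double ny", "property double nz"]
    header = "\n".join(["ply", "format ascii 1.0",
                        f"comment usnav point cloud tag={cloud.tag or 'none'}",
                        f"element vertex {n}", *props, "end_header"])
    data = (np.hstack([cloud.points, cloud.normals])
            if cloud.has_normals else cloud.points)
    with open(path, "w") as fh:
        fh.write(header + "\n")
        np.savetxt(fh, data, fmt="%.17g")


def read_ply(path) -> VesselPointCloud:
    path = Path(path)
    with open(path) as fh:
        line = fh.readline().strip()
        if line != "ply":
            raise ValueError(f"{path} is not a PLY file")
        fmt = fh.readline().strip()
        if not fmt.startswith("format ascii"):
            raise ValueError("only ASCII PLY is supported")
        n = None
        names: List[str] = []
        tag = ""
        for line in fh:
            line = line.strip()
            if line.startswith("comment"):
                if "tag=" in line:
                    tag = line.split("tag=")[-1]
                    tag = "" if tag == "none" else tag
            elif line.startswith("element vertex"):
                n = int(line.split()[-1])
            elif line.startswith("element"):
                raise ValueError("only vertex elements are supported")
            elif line.startswith("property"):
                names.append(line.split()[-1])
            elif line == "end_header":
                break
        if n is None:
            raise ValueError("missing vertex element")
        data = np.loadtxt(fh, ndmin=2) if n else np.empty((0, len(names)))
    if data.shape != (n, len(names)):
        raise ValueError("PLY body does not match header")
    cols = {name: data[:, i] for i, name in enumerate(names)}
    points = np.column_stack([cols["x"], cols["y"], cols["z"]])
    normals = None
    if {"nx", "ny", "nz"} <= set(names):
        normals = np.column_stack([cols["nx"], cols["ny"], cols["nz"]])
    return VesselPointCloud(points, normals, tag)


# ---------------------------------------------------------------------------
# Poses CSV: frame_id plus the 12 row-major entries of the top 3 matrix rows


_POSE_COLUMNS = ["frame_id"] + [f"m{r}{c}" for r in range(3) for c in range(4)]


def write_poses_csv(path, poses: List[RigidTransform]) -> None:
    rows = []
    for i, pose in enumerate(poses):
        rows.append([i] + [float(x) for x in pose.matrix[:3].ravel()])
    df = pd.DataFrame(rows, columns=_POSE_COLUMNS)
    df.to_csv(path, index=False, float_format="%.17g")


def read_poses_csv(path) -> List[RigidTransform]:
    df = pd.read_csv(path)
    missing = set(_POSE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"poses CSV missing columns: {sorted(missing)}")
    poses = []
    for _, row in df.sort_values("frame_id").iterrows():
        m = np.eye(4)
        m[:3] = np.array([row[c] for c in _POSE_COLUMNS[1:]]).reshape(3, 4)
        poses.append(RigidTransform(m))
    return poses


# ---------------------------------------------------------------------------
# Transforms, plans, registration results (JSON)


def save_transform(path, transform: RigidTransform) -> None:
    with open(path, "w") as fh:
        json.dump({"matrix": transform.to_flat()}, fh, indent=1)


def load_transform(path) -> RigidTransform:
    with open(path) as fh:
        payload = json.load(fh)
    return RigidTransform.from_flat(payload["matrix"])


def save_registration_result(path, result: RegistrationResult) -> None:
    payload = {
        "matrix": result.transform.to_flat(),
        "rmsa_mm": result.rmsa,
        "iterations": result.iterations,
        "converged": result.converged,
        "correspondences": [[s, t, d] for s, t, d in result.correspondences],
        "rmsa_history_mm": list(result.history),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_plan(path) -> dict:
    with open(path) as fh:
        plan = json.load(fh)
    for key in ("entry", "target", "skin_normal"):
        if key not in plan:
            raise ValueError(f"plan JSON missing '{key}'")
        plan[key] = np.asarray(plan[key], dtype=float)
    return plan


# ---------------------------------------------------------------------------
# Masks and frames (8-bit PNG: 0 background, 255 vessel)


def write_mask_png(path, mask: np.ndarray) -> None:
    iio.imwrite(path, (np.asarray(mask) > 0).astype(np.uint8) * 255)


def read_mask_png(path) -> np.ndarray:
    img = np.asarray(iio.imread(path))
    if img.ndim == 3:
        img = img[..., 0]
    return (img > 127).astype(np.uint8)


def write_image_png(path, image: np.ndarray) -> None:
    img = np.asarray(image, dtype=float)
    iio.imwrite(path, np.clip(img * 255.0, 0, 255).astype(np.uint8))


def read_image_png(path) -> np.ndarray:
    img = np.asarray(iio.imread(path))
    if img.ndim == 3:
        img = img[..., 0]
    return img.astype(float) / 255.0


# ---------------------------------------------------------------------------
# NIfTI volumes (axis-aligned only)


def load_nifti_volume(path) -> CTVolume:
    import nibabel as nib

    img = nib.load(str(path))
    affine = img.affine
    rot = affine[:3, :3]
    if not np.allclose(rot, np.diag(np.diag(rot)), atol=1e-6):
        raise ValueError("only axis-aligned NIfTI volumes are supported")
    spacing = np.diag(rot).copy()
    origin = affine[:3, 3].copy()
    data = np.asarray(img.dataobj, dtype=float)
    # fold negative-direction axes into a positive-spacing grid
    for ax in range(3):
        if spacing[ax] < 0:
            data = np.flip(data, axis=ax)
            origin[ax] = origin[ax] + spacing[ax] * (data.shape[ax] - 1)
            spacing[ax] = -spacing[ax]
    return CTVolume(data, spacing, origin)


def save_nifti_volume(path, volume: CTVolume) -> None:
    import nibabel as nib

    affine = np.eye(4)
    affine[:3, :3] = np.diag(volume.spacing)
    affine[:3, 3] = volume.origin
    nib.save(nib.Nifti1Image(volume.data.astype(np.float32), affine), str(path))


# ---------------------------------------------------------------------------
# Config


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


# ---------------------------------------------------------------------------
# Phantom case export / import


def export_case(case: PhantomCase, directory) -> None:
    """Write a case as ct_cloud.ply, frames/, masks/, ground_truth.json."""
    directory = Path(directory)
    (directory / "frames").mkdir(parents=True, exist_ok=True)
    (directory / "masks").mkdir(parents=True, exist_ok=True)
    write_ply(directory / "ct_cloud.ply", case.ct_cloud)
    write_poses_csv(directory / "frames" / "poses.csv",
                    [f.pose for f in case.frames])
    for frame, mask in zip(case.frames, case.masks):
        write_image_png(directory / "frames" / f"frame_{frame.index:04d}.png",
                        frame.image)
        write_mask_png(directory / "masks" / f"frame_{frame.index:04d}.png", mask)
    truth = {
        "seed": case.seed,
        "world_to_ct": case.world_to_ct.to_flat(),
        "ct_to_world": case.ct_to_world.to_flat(),
        "targets_ct": case.targets_ct.tolist(),
        "targets_world": case.targets_world.tolist(),
        "deformation": {"amplitude": case.deformation.amplitude,
                        "wavelength": case.deformation.wavelength,
                        "seed": case.deformation.seed},
        "pixel_spacing": case.params.get("pixel_spacing"),
        "params": case.params,
    }
    with open(directory / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)


def load_case_frames(directory,
                     pixel_spacing: Optional[float] = None
                     ) -> Tuple[List[UltrasoundFrame], List[np.ndarray]]:
    """Re-read an exported case's frames and masks."""
    directory = Path(directory)
    if pixel_spacing is None:
        with open(directory / "ground_truth.json") as fh:
            pixel_spacing = json.load(fh)["pixel_spacing"]
    poses = read_poses_csv(directory / "frames" / "poses.csv")
    frames, masks = [], []
    for i, pose in enumerate(poses):
        image = read_image_png(directory / "frames" / f"frame_{i:04d}.png")
        frames.append(UltrasoundFrame(image, (pixel_spacing, pixel_spacing),
                                      pose, index=i))
        mask_path = directory / "masks" / f"frame_{i:04d}.png"
        if mask_path.exists():
            masks.append(read_mask_png(mask_path))
    return frames, masks
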