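"""Rigid transforms in millimetre world coordinates.

Every pose, every registration unknown, and the hidden phantom transform are
4x4 homogeneous rigid maps.  The class validates orthonormality strictly so a
non-rigid matrix is rejected at construction, not three modules later.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

_ORTHO_TOL = 1e-9


class RigidTransform:
    """A proper rigid map ``p -> R p + t`` stored as a 4x4 homogeneous matrix.

    Invariants enforced at construction: ``R^T R = I`` and ``det(R) = +1``
    within 1e-9, last row exactly ``(0, 0, 0, 1)``.
    """

    __slots__ = ("matrix",)

    def __init__(self, matrix: np.ndarray):
        m = np.asarray(matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError(f"expected a 4x4 matrix, got shape {m.shape}")
        R = m[:3, :3]
        if not np.allclose(R.T @ R, np.eye(3), atol=_ORTHO_TOL):
            raise ValueError("rotation block is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > _ORTHO_TOL:
            raise ValueError("rotation block is not proper (det != +1)")
        if not np.array_equal(m[3], [0.0, 0.0, 0.0, 1.0]):
            m = m.copy()
            if not np.allclose(m[3], [0.0, 0.0, 0.0, 1.0], atol=_ORTHO_TOL):
                raise ValueError("last row must be (0, 0, 0, 1)")
            m[3] = (0.0, 0.0, 0.0, 1.0)
        m.setflags(write=False)
        self.matrix = m

    # -- constructors -----------------------------------------------------
    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(4))

    @classmethod
    def from_rotation_translation(cls, rotation: np.ndarray,
                                  translation: np.ndarray) -> "RigidTransform":
        m = np.eye(4)
        m[:3, :3] = np.asarray(rotation, dtype=float)
        m[:3, 3] = np.asarray(translation, dtype=float)
        return cls(m)

    @classmethod
    def from_rotvec_translation(cls, rotvec: np.ndarray,
                                translation: np.ndarray) -> "RigidTransform":
        """Axis-angle (radians, axis*angle vector) plus translation."""
        R = Rotation.from_rotvec(np.asarray(rotvec, dtype=float)).as_matrix()
        return cls.from_rotation_translation(R, translation)

    # -- accessors --------------------------------------------------------
    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation, degrees."""
        return float(np.degrees(np.linalg.norm(
            Rotation.from_matrix(self.rotation).as_rotvec())))

    # -- algebra ----------------------------------------------------------
    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map an (..., 3) array of points."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def apply_vectors(self, vectors: np.ndarray) -> np.ndarray:
        """Rotate direction vectors (no translation) — e.g. surface normals."""
        return np.asarray(vectors, dtype=float) @ self.rotation.T

    def inverse(self) -> "RigidTransform":
        R = self.rotation
        return RigidTransform.from_rotation_translation(R.T, -R.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``self @ other``: apply ``other`` first, then ``self``."""
        m = self.matrix @ other.matrix
        # renormalize to keep the 1e-9 invariant through long products
        U, _, Vt = np.linalg.svd(m[:3, :3])
        R = U @ Vt
        if np.linalg.det(R) < 0:
            R = U @ np.diag([1.0, 1.0, -1.0]) @ Vt
        return RigidTransform.from_rotation_translation(R, m[:3, 3])

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def __repr__(self) -> str:
        return f"RigidTransform(angle={self.rotation_angle_deg():.3f} deg, t={self.translation})"

    # -- serialization ----------------------------------------------------
    def to_flat(self) -> list:
        """16 row-major entries (JSON interchange form)."""
        return [float(x) for x in self.matrix.ravel()]

    @classmethod
    def from_flat(cls, values) -> "RigidTransform":
        arr = np.asarray(list(values), dtype=float)
        if arr.size != 16:
            raise ValueError("expected 16 row-major matrix entries")
        return cls(arr.reshape(4, 4))


def random_rigid_transform(rng: np.random.Generator,
                           max_rotation_deg: float = 15.0,
                           max_translation_mm: float = 30.0) -> RigidTransform:
    """Uniform random axis, rotation angle U(0, max), translation in a ball."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.radians(rng.uniform(0.0, max_rotation_deg))
    # uniform in the ball of radius max_translation_mm
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    radius = max_translation_mm * rng.uniform(0.0, 1.0) ** (1.0 / 3.0)
    return RigidTransform.from_rotvec_translation(axis * angle, direction * radius)


def rotation_error_deg(a: RigidTransform, b: RigidTransform) -> float:
    """Angle of the relative rotation between two transforms, degrees."""
    rel = a.rotation @ b.rotation.T
    return float(np.degrees(np.linalg.norm(Rotation.from_matrix(rel).as_rotvec())))


def translation_error_mm(a: RigidTransform, b: RigidTransform) -> float:
    return float(np.linalg.norm(a.translation - b.translation))
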