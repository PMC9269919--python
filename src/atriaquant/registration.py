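"""Landmark-based rigid registration between imaging time points.

The transform mapping moving to fixed landmarks minimises the sum of squared
differences over corresponding points.  The closed-form minimiser is used:
centroid alignment followed by the orthogonal-Procrustes (Kabsch/SVD)
rotation with determinant correction, so reflections are excluded.
Correspondence is strictly by landmark label, never by file order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import (
    GeometryError,
    ImageVolume,
    LabelMap,
    LandmarkSet,
    ValidationError,
)


@dataclass
class RigidTransform:
    """Rigid map ``p -> rotation @ p + translation`` in physical mm."""

    rotation: np.ndarray
    translation: np.ndarray
    rmse_mm: float = 0.0
    fixed_role: str = "fixed"
    moving_role: str = "moving"

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if self.rotation.shape != (3, 3):
            raise ValidationError("rotation must be 3x3")
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(3), atol=1e-9):
            raise ValidationError("rotation must be orthonormal (RᵀR = I)")
        if not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-9):
            raise ValidationError("rotation must be proper (det = +1)")
        if self.rmse_mm < 0:
            raise ValidationError("rmse_mm must be >= 0")

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points @ self.rotation.T + self.translation

    def apply_to_landmarks(self, lms: LandmarkSet, role: str | None = None) -> LandmarkSet:
        coords = self.apply(lms.as_array())
        return LandmarkSet.from_arrays(lms.labels, coords, role=role or lms.role)

    def inverse(self) -> "RigidTransform":
        r_inv = self.rotation.T
        return RigidTransform(
            r_inv,
            -r_inv @ self.translation,
            rmse_mm=self.rmse_mm,
            fixed_role=self.moving_role,
            moving_role=self.fixed_role,
        )

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def to_dict(self) -> dict:
        return {
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
            "rmse_mm": float(self.rmse_mm),
            "fixed_role": self.fixed_role,
            "moving_role": self.moving_role,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(
            np.array(d["rotation"]),
            np.array(d["translation"]),
            rmse_mm=d.get("rmse_mm", 0.0),
            fixed_role=d.get("fixed_role", "fixed"),
            moving_role=d.get("moving_role", "moving"),
        )

    @classmethod
    def from_json(cls, path) -> "RigidTransform":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def rotation_about_z(angle_deg: float) -> np.ndarray:
    """Proper rotation about the z (slice) axis."""
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def fit_rigid_landmarks(moving: LandmarkSet, fixed: LandmarkSet) -> RigidTransform:
    """Least-squares rigid fit mapping moving landmarks onto fixed ones.

    Requires the same labels in both sets and at least 3 non-collinear
    points; raises :class:`GeometryError` on degenerate configurations.
    """
    if set(moving.labels) != set(fixed.labels):
        only_m = sorted(set(moving.labels) - set(fixed.labels))
        only_f = sorted(set(fixed.labels) - set(moving.labels))
        raise ValidationError(
            f"landmark label mismatch (moving-only {only_m}, fixed-only {only_f})"
        )
    labels = sorted(moving.labels)
    if len(labels) < 3:
        raise GeometryError(f"rigid fit needs >= 3 landmarks, got {len(labels)}")
    p = moving.as_array(labels)  # moving
    q = fixed.as_array(labels)  # fixed
    cm, cf = p.mean(axis=0), q.mean(axis=0)
    pc, qc = p - cm, q - cf
    # collinearity: centered moving cloud must span a plane
    sv = np.linalg.svd(pc, compute_uv=False)
    if sv[1] <= 1e-9 * max(sv[0], 1.0):
        raise GeometryError("landmarks are collinear: rotation is not identifiable")
    h = pc.T @ qc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = cf - rot @ cm
    residuals = q - (p @ rot.T + trans)
    rmse = float(np.sqrt(np.mean(np.sum(residuals**2, axis=1))))
    return RigidTransform(
        rot, trans, rmse_mm=rmse, fixed_role=fixed.role, moving_role=moving.role
    )


def apply_rigid_to_volume(
    vol: ImageVolume | LabelMap, transform: RigidTransform
) -> ImageVolume | LabelMap:
    """Resample a volume under a rigid transform, on its own grid.

    Intensities use trilinear interpolation; label maps use nearest
    neighbour (so outputs stay in {0, 1}).  Voxels mapped from outside the
    field of view become 0.
    """
    is_label = isinstance(vol, LabelMap)
    data = vol.mask.astype(np.uint8) if is_label else vol.data
    spacing = np.asarray(vol.spacing, dtype=float)
    origin = np.asarray(vol.origin, dtype=float)
    # Output voxel index -> physical y -> input physical x = Rᵀ(y - t)
    # -> input index.  Composed affine: idx_in = M idx_out + off.
    r_inv = transform.rotation.T
    s = np.diag(spacing)
    s_inv = np.diag(1.0 / spacing)
    matrix = s_inv @ r_inv @ s
    offset = s_inv @ (r_inv @ (origin - transform.translation) - origin)
    out = ndimage.affine_transform(
        data.astype(float),
        matrix=matrix,
        offset=offset,
        order=0 if is_label else 1,
        mode="constant",
        cval=0.0,
    )
    if is_label:
        return LabelMap(out > 0.5, vol.region, vol.spacing, vol.origin)
    return ImageVolume(out, vol.spacing, vol.origin)
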