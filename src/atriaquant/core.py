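"""Core in-memory containers for the quantification pipeline.

The package works on a fixed grid model: a 3D scalar intensity array indexed
``data[i, j, k]`` where axes 0-1 are in-plane and axis 2 (``k``) enumerates
axial slices.  Physical position of a voxel center is
``origin + spacing * (i, j, k)`` (axis-aligned grids only; oblique direction
matrices are rejected at I/O time).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Default voxel geometry (mm) of the 3D IR-FLASH acquisitions: in-plane
#: resolution 0.625 mm, slice thickness 0.975 mm.
DEFAULT_SPACING: tuple[float, float, float] = (0.625, 0.625, 0.975)


class AtriaQuantError(Exception):
    """Base class for package errors."""


class ValidationError(AtriaQuantError, ValueError):
    """Invalid argument or inconsistent inputs."""


class FormatError(AtriaQuantError, ValueError):
    """Unreadable or unsupported file content."""


class GeometryError(AtriaQuantError, ValueError):
    """Impossible or degenerate geometry."""


class NormalizationError(AtriaQuantError, ValueError):
    """Blood-pool normalization is undefined (empty pool, zero mean)."""


class NoEnhancementError(AtriaQuantError, ValueError):
    """No voxel exceeds the fibrosis threshold anywhere in the wall."""


def _as_triple(x, name: str) -> tuple[float, float, float]:
    t = tuple(float(v) for v in x)
    if len(t) != 3:
        raise ValidationError(f"{name} must have 3 components, got {len(t)}")
    if not all(np.isfinite(t)):
        raise ValidationError(f"{name} must be finite, got {t}")
    return t


@dataclass
class ImageVolume:
    """3D scalar intensity grid with voxel spacing and origin in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValidationError(
                f"volume data must be 3D, got {self.data.ndim}D"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("volume intensities must be finite")
        self.spacing = _as_triple(self.spacing, "spacing")
        if any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be positive, got {self.spacing}")
        self.origin = _as_triple(self.origin, "origin")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    @property
    def n_slices(self) -> int:
        """Number of axial slices (extent along axis 2)."""
        return self.data.shape[2]


# Region semantics a label map can carry.
REGIONS = ("blood_pool", "dilated", "wall", "fibrosis", "exclusion", "generic")


@dataclass
class LabelMap:
    """Boolean 3D mask congruent with an :class:`ImageVolume` grid."""

    mask: np.ndarray
    region: str = "generic"
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask)
        if self.mask.ndim != 3:
            raise ValidationError(f"mask must be 3D, got {self.mask.ndim}D")
        if self.mask.dtype != bool:
            vals = np.unique(self.mask)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValidationError(
                    "mask values must be boolean or {0,1}"
                )
            self.mask = self.mask.astype(bool)
        if self.region not in REGIONS:
            raise ValidationError(
                f"unknown region {self.region!r}; expected one of {REGIONS}"
            )
        self.spacing = _as_triple(self.spacing, "spacing")
        if any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be positive, got {self.spacing}")
        self.origin = _as_triple(self.origin, "origin")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    @property
    def volume_mm3(self) -> float:
        return self.voxel_count * self.voxel_volume_mm3

    def with_region(self, region: str) -> "LabelMap":
        return LabelMap(self.mask, region, self.spacing, self.origin)


def require_congruent(*grids) -> None:
    """Raise :class:`ValidationError` unless all grids share one shape."""
    shapes = {g.shape for g in grids}
    if len(shapes) > 1:
        raise ValidationError(f"incongruent grid shapes: {sorted(shapes)}")


@dataclass
class Landmark:
    label: str
    position: np.ndarray  # (3,) physical mm

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValidationError("landmark position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValidationError(
                f"landmark {self.label!r} has non-finite coordinates"
            )


@dataclass
class LandmarkSet:
    """Ordered, uniquely labelled 3D points in physical space (mm).

    ``role`` tags which side of a registration the set plays: the post-pacing
    image provides the *fixed* landmarks, baseline / in-situ the *moving* ones.
    """

    landmarks: list[Landmark] = field(default_factory=list)
    role: str = "fixed"

    def __post_init__(self) -> None:
        if self.role not in ("fixed", "moving"):
            raise ValidationError(f"role must be fixed|moving, got {self.role!r}")
        labels = [lm.label for lm in self.landmarks]
        if len(set(labels)) != len(labels):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise ValidationError(f"duplicate landmark labels: {dup}")

    def __len__(self) -> int:
        return len(self.landmarks)

    def __iter__(self):
        return iter(self.landmarks)

    @property
    def labels(self) -> list[str]:
        return [lm.label for lm in self.landmarks]

    def as_array(self, label_order: list[str] | None = None) -> np.ndarray:
        """Return an (n, 3) coordinate array, optionally in a given label order."""
        if label_order is None:
            return np.array([lm.position for lm in self.landmarks], dtype=float)
        by_label = {lm.label: lm.position for lm in self.landmarks}
        missing = [l for l in label_order if l not in by_label]
        if missing:
            raise ValidationError(f"landmarks missing labels: {missing}")
        return np.array([by_label[l] for l in label_order], dtype=float)

    @classmethod
    def from_arrays(
        cls, labels: list[str], coords: np.ndarray, role: str = "fixed"
    ) -> "LandmarkSet":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(labels), 3):
            raise ValidationError("coords must be (n_labels, 3)")
        return cls([Landmark(l, c) for l, c in zip(labels, coords)], role=role)
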