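"""LA myocardial wall extraction from a blood-pool chamber mask.

The wall shell is derived morphologically: each axial slice of the chamber
mask is dilated in-plane by a Euclidean disk, the chamber is subtracted
(Boolean remove), and an optional exclusion mask erases non-myocardial
regions (valves, septum) that in the original workflow were removed by hand.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import LabelMap, ValidationError, require_congruent

DEFAULT_DILATION_RADIUS = 4


def disk_footprint(radius: int) -> np.ndarray:
    """2D Euclidean disk: lattice points with i² + j² ≤ radius²."""
    r = int(radius)
    ii, jj = np.mgrid[-r : r + 1, -r : r + 1]
    return (ii * ii + jj * jj) <= r * r


def axial_dilate(chamber: LabelMap, radius: int = DEFAULT_DILATION_RADIUS) -> LabelMap:
    """Dilate each axial slice independently by a Euclidean disk.

    No growth occurs across slices (the k index), mirroring an in-plane
    "4-pixel dilation in the axial plane".  ``radius`` is in pixels;
    in-plane anisotropy is ignored.
    """
    if int(radius) != radius or radius < 1:
        raise ValidationError(f"dilation radius must be an integer >= 1, got {radius}")
    footprint = disk_footprint(int(radius))
    out = np.zeros_like(chamber.mask)
    for k in range(chamber.mask.shape[2]):
        sl = chamber.mask[:, :, k]
        if sl.any():
            out[:, :, k] = ndimage.binary_dilation(sl, structure=footprint)
    return LabelMap(out, "dilated", chamber.spacing, chamber.origin)


def boolean_remove(dilated: LabelMap, chamber: LabelMap) -> LabelMap:
    """Set difference ``dilated \\ chamber``."""
    require_congruent(dilated, chamber)
    return LabelMap(
        dilated.mask & ~chamber.mask, "wall", dilated.spacing, dilated.origin
    )


@dataclass
class WallSegmentationResult:
    dilated: LabelMap
    wall: LabelMap
    excluded_voxel_count: int


def extract_wall(
    chamber: LabelMap,
    exclusion: LabelMap | None = None,
    radius: int = DEFAULT_DILATION_RADIUS,
) -> WallSegmentationResult:
    """Chamber → dilate → subtract chamber → apply exclusion mask.

    Raises on an empty chamber (no wall is derivable) and records how many
    preliminary wall voxels the exclusion mask removed.
    """
    if not chamber.mask.any():
        raise ValidationError("empty chamber mask: no wall derivable")
    dilated = axial_dilate(chamber, radius)
    wall = boolean_remove(dilated, chamber)
    excluded = 0
    if exclusion is not None:
        require_congruent(wall, exclusion)
        excluded = int((wall.mask & exclusion.mask).sum())
        wall = LabelMap(
            wall.mask & ~exclusion.mask, "wall", wall.spacing, wall.origin
        )
    return WallSegmentationResult(dilated=dilated, wall=wall, excluded_voxel_count=excluded)
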