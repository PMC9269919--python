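"""Reading and writing volumes, label maps and landmark tables.

NRRD is the canonical on-disk dialect (matching the study's deposited image
files); NIfTI-1 (``.nii`` / ``.nii.gz``) is supported for interoperability.
SimpleITK backs both formats.  Landmark tables are plain CSV with a
``label,x,y,z`` header; 3D Slicer FCSV comment lines (``#``) are tolerated
and skipped.

Grids are axis-aligned only: a header whose direction matrix is not the
identity is rejected, keeping the physical mapping
``position = origin + spacing * index`` unambiguous.
"""

from __future__ import annotations

import csv
import gzip
import warnings
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .core import (
    DEFAULT_SPACING,
    FormatError,
    ImageVolume,
    LabelMap,
    Landmark,
    LandmarkSet,
    ValidationError,
)

_NRRD_SPACING_FIELDS = ("spacings", "space directions", "axis mins", "thicknesses")


def _nrrd_header_fields(path: Path) -> set[str]:
    """Field names present in an NRRD plain-text header.

    The NRRD header is ASCII lines up to the first blank line; fields are
    ``name: value``.  Used only to detect whether spacing information exists
    at all (the reader itself defaults absent spacing to 1.0, which would
    silently mask missing geometry).
    """
    opener = gzip.open if path.suffix == ".gz" else open
    fields: set[str] = set()
    try:
        with opener(path, "rb") as fh:
            for raw in fh:
                line = raw.decode("ascii", errors="replace").rstrip("\r\n")
                if line == "":
                    break
                if line.startswith("#"):
                    continue
                if ":" in line:
                    fields.add(line.split(":", 1)[0].strip().lower())
    except OSError as exc:  # pragma: no cover - unreadable file
        raise FormatError(f"cannot read NRRD header of {path}: {exc}") from exc
    return fields


def _is_nrrd(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nrrd") or name.endswith(".nhdr")


def read_volume(path, format_hint: str | None = None) -> ImageVolume:
    """Read a scalar NRRD or NIfTI volume into an :class:`ImageVolume`.

    A NRRD header carrying no spacing information falls back to the default
    acquisition geometry ``(0.625, 0.625, 0.975)`` mm with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        img = sitk.ReadImage(str(path))
    except Exception as exc:
        raise FormatError(f"unreadable volume {path}: {exc}") from exc
    if img.GetDimension() != 3:
        raise FormatError(
            f"{path}: expected a 3D scalar volume, got {img.GetDimension()}D"
        )
    if img.GetNumberOfComponentsPerPixel() != 1:
        raise FormatError(f"{path}: vector voxels are unsupported")
    direction = np.asarray(img.GetDirection(), dtype=float).reshape(3, 3)
    if not np.allclose(direction, np.eye(3), atol=1e-6):
        raise FormatError(
            f"{path}: non-identity direction matrix is unsupported "
            "(axis-aligned grids only)"
        )
    # SimpleITK arrays are [k, j, i]; the package convention is data[i, j, k].
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    spacing = tuple(float(s) for s in img.GetSpacing())
    origin = tuple(float(o) for o in img.GetOrigin())
    if _is_nrrd(path):
        fields = _nrrd_header_fields(path)
        if not (fields & set(_NRRD_SPACING_FIELDS)):
            warnings.warn(
                f"{path.name}: NRRD header has no spacing fields; "
                f"assuming default geometry {DEFAULT_SPACING} mm",
                stacklevel=2,
            )
            spacing = DEFAULT_SPACING
    return ImageVolume(data=data, spacing=spacing, origin=origin)


def read_label_map(path, region: str = "generic") -> LabelMap:
    """Read a volume and interpret nonzero voxels as a mask."""
    vol = read_volume(path)
    return LabelMap(vol.data != 0, region=region, spacing=vol.spacing, origin=vol.origin)


def write_volume(vol: ImageVolume | LabelMap, path) -> Path:
    """Write an :class:`ImageVolume` or :class:`LabelMap` to NRRD or NIfTI.

    Format follows the extension (``.nrrd``/``.nhdr`` → NRRD, ``.nii``/
    ``.nii.gz`` → NIfTI).  Label maps are written as 8-bit {0, 1}.
    """
    path = Path(path)
    if isinstance(vol, LabelMap):
        data = vol.mask.astype(np.uint8)
    else:
        data = vol.data
    img = sitk.GetImageFromArray(np.ascontiguousarray(data.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in vol.spacing))
    img.SetOrigin(tuple(float(o) for o in vol.origin))
    try:
        sitk.WriteImage(img, str(path))
    except Exception as exc:
        raise OSError(f"cannot write {path}: {exc}") from exc
    return path


def read_landmarks(path, role: str = "fixed") -> LandmarkSet:
    """Read a ``label,x,y,z`` CSV (FCSV ``#`` comments skipped) as landmarks."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    landmarks: list[Landmark] = []
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh) if r and not r[0].lstrip().startswith("#")]
    if not rows:
        raise FormatError(f"{path}: no landmark rows")
    header = [c.strip().lower() for c in rows[0]]
    if "label" in header:
        try:
            idx = [header.index(c) for c in ("label", "x", "y", "z")]
        except ValueError as exc:
            raise FormatError(
                f"{path}: header must contain label,x,y,z columns"
            ) from exc
        rows = rows[1:]
    else:
        idx = [0, 1, 2, 3]
    for row in rows:
        if len(row) < 4:
            raise FormatError(f"{path}: landmark row too short: {row}")
        label = row[idx[0]].strip()
        try:
            coords = [float(row[i]) for i in idx[1:]]
        except ValueError as exc:
            raise FormatError(
                f"{path}: non-numeric coordinate in row {row}"
            ) from exc
        landmarks.append(Landmark(label, np.array(coords)))
    try:
        return LandmarkSet(landmarks, role=role)
    except ValidationError:
        raise


def write_landmarks(lms: LandmarkSet, path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["label", "x", "y", "z"])
        for lm in lms:
            writer.writerow([lm.label, *(f"{v:.9g}" for v in lm.position)])
    return path
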