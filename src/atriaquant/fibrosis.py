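"""Image-intensity-ratio fibrosis quantification.

Wall intensities are normalized voxelwise by the mean blood-pool intensity,

    NI(x) = I(x) / mu_BP,

and a voxel is classified as fibrotic when its normalized intensity strictly
exceeds the threshold

    T_fib = mu_NI + k * sigma_NI        (k = 2 by default),

where mu_NI and sigma_NI are the mean and sample standard deviation of the
normalized intensities over the wall.  Percent myocardial fibrosis (%MF) is
reported volumetrically (fibrotic share of the whole wall volume) and
slice-wise (fibrotic share of the wall area in the single axial slice that
contains the most fibrotic voxels).  Quantification by this normalization is
valid only for in-vivo time points; post-mortem (in-situ) acquisitions are
rejected because stagnant contrast in the blood pool invalidates the
reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    ImageVolume,
    LabelMap,
    NoEnhancementError,
    NormalizationError,
    ValidationError,
    require_congruent,
)

DEFAULT_SD_MULTIPLIER = 2.0

TIMEPOINTS = ("baseline", "post_pacing", "in_situ")


@dataclass
class BloodPoolStats:
    mu_bp: float
    voxel_count: int


@dataclass
class NormalizedWall:
    """Normalized intensities over the wall voxels.

    ``values`` holds NI at the wall voxels in C order of the mask; ``wall``
    retains the spatial footprint for slice-wise measurements.
    """

    values: np.ndarray
    wall: LabelMap
    mu_ni: float
    sigma_ni: float

    @property
    def n_voxels(self) -> int:
        return len(self.values)

    def ni_volume(self) -> np.ndarray:
        """NI mapped back onto the 3D grid (zero outside the wall)."""
        vol = np.zeros(self.wall.shape, dtype=float)
        vol[self.wall.mask] = self.values
        return vol


@dataclass
class FibrosisMeasurement:
    """Per-acquisition quantification record."""

    t_fib: float
    k_sd: float
    mu_bp: float
    mu_ni: float
    sigma_ni: float
    mf_voxels: int
    wall_voxels: int
    mf_volume_mm3: float
    wall_volume_mm3: float
    percent_mf_volumetric: float
    percent_mf_slicewise: float | None = None
    max_slice_index: int | None = None
    slice_tie: bool = False
    timepoint: str = "baseline"

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class ProgressionRecord:
    """Signed %MF change (percentage points), post minus baseline."""

    animal_id: str
    v_b: float
    v_p: float

    @property
    def d_abs(self) -> float:
        return d_abs(self.v_b, self.v_p)


def iir_normalize(
    image: ImageVolume, blood_pool: LabelMap, wall: LabelMap
) -> tuple[BloodPoolStats, NormalizedWall]:
    """Normalize wall intensities by the mean blood-pool intensity."""
    require_congruent(image, blood_pool, wall)
    n_bp = blood_pool.voxel_count
    if n_bp == 0:
        raise NormalizationError("empty blood-pool mask")
    mu_bp = float(image.data[blood_pool.mask].mean())
    if mu_bp <= 0:
        raise NormalizationError(f"non-positive blood-pool mean ({mu_bp})")
    ni = image.data[wall.mask] / mu_bp
    if ni.size == 0:
        raise NormalizationError("empty wall mask")
    mu_ni = float(ni.mean())
    sigma_ni = float(ni.std(ddof=1)) if ni.size > 1 else 0.0
    return (
        BloodPoolStats(mu_bp=mu_bp, voxel_count=n_bp),
        NormalizedWall(values=ni, wall=wall, mu_ni=mu_ni, sigma_ni=sigma_ni),
    )


def fibrosis_threshold(nw: NormalizedWall, k_sd: float = DEFAULT_SD_MULTIPLIER) -> float:
    """T_fib = mu_NI + k * sigma_NI (sample SD; k configurable, default 2)."""
    if nw.n_voxels < 2:
        raise ValidationError(
            "threshold undefined: need >= 2 wall voxels for an SD"
        )
    return nw.mu_ni + k_sd * nw.sigma_ni


def percent_mf_volumetric(
    nw: NormalizedWall,
    t_fib: float,
    voxel_volume_mm3: float | None = None,
) -> tuple[int, float, float, float]:
    """Volumetric fibrosis load of the wall.

    Returns ``(mf_voxels, mf_volume_mm3, wall_volume_mm3, percent_mf)``.
    Classification is strict: a voxel is fibrotic iff NI > t_fib.
    """
    if nw.n_voxels == 0:
        raise ValidationError("empty wall: %MF undefined")
    if voxel_volume_mm3 is None:
        voxel_volume_mm3 = nw.wall.voxel_volume_mm3
    fibrotic = nw.values > t_fib
    mf_voxels = int(fibrotic.sum())
    mf_volume = mf_voxels * voxel_volume_mm3
    wall_volume = nw.n_voxels * voxel_volume_mm3
    return mf_voxels, mf_volume, wall_volume, 100.0 * mf_voxels / nw.n_voxels


def percent_mf_slicewise(
    nw: NormalizedWall, t_fib: float
) -> tuple[int, float, bool]:
    """Fibrotic share of the wall area in the most-enhanced axial slice.

    The slice is the argmax over k of the fibrotic-voxel count; ties break
    to the lowest k (flagged in the returned tuple).  Raises
    :class:`NoEnhancementError` when no voxel anywhere exceeds the
    threshold — a distinct outcome from a 0% volumetric measurement.

    Returns ``(slice_index, percent_area, tie_flag)``.
    """
    fib_vol = np.zeros(nw.wall.shape, dtype=bool)
    fib_vol[nw.wall.mask] = nw.values > t_fib
    fib_per_slice = fib_vol.sum(axis=(0, 1))
    if fib_per_slice.sum() == 0:
        raise NoEnhancementError("no fibrotic voxel in any slice")
    k = int(np.argmax(fib_per_slice))
    tie = int((fib_per_slice == fib_per_slice[k]).sum()) > 1
    wall_in_slice = int(nw.wall.mask[:, :, k].sum())
    return k, 100.0 * float(fib_per_slice[k]) / wall_in_slice, tie


def measure_fibrosis(
    image: ImageVolume,
    blood_pool: LabelMap,
    wall: LabelMap,
    k_sd: float = DEFAULT_SD_MULTIPLIER,
    timepoint: str = "baseline",
    allow_in_situ: bool = False,
) -> FibrosisMeasurement:
    """Full single-acquisition quantification: normalize, threshold, %MF.

    In-situ (post-mortem) acquisitions are rejected unless explicitly
    overridden, since blood-pool normalization is invalid there.
    """
    if timepoint not in TIMEPOINTS:
        raise ValidationError(f"unknown timepoint {timepoint!r}")
    if timepoint == "in_situ" and not allow_in_situ:
        raise ValidationError(
            "in-situ acquisitions are excluded from IIR %MF quantification "
            "(blood-pool reference invalid post mortem)"
        )
    bp, nw = iir_normalize(image, blood_pool, wall)
    t_fib = fibrosis_threshold(nw, k_sd)
    mf_voxels, mf_volume, wall_volume, pct_vol = percent_mf_volumetric(nw, t_fib)
    try:
        k, pct_slice, tie = percent_mf_slicewise(nw, t_fib)
    except NoEnhancementError:
        k, pct_slice, tie = None, None, False
    return FibrosisMeasurement(
        t_fib=t_fib,
        k_sd=k_sd,
        mu_bp=bp.mu_bp,
        mu_ni=nw.mu_ni,
        sigma_ni=nw.sigma_ni,
        mf_voxels=mf_voxels,
        wall_voxels=nw.n_voxels,
        mf_volume_mm3=mf_volume,
        wall_volume_mm3=wall_volume,
        percent_mf_volumetric=pct_vol,
        percent_mf_slicewise=pct_slice,
        max_slice_index=k,
        slice_tie=tie,
        timepoint=timepoint,
    )


def d_abs(v_b: float, v_p: float) -> float:
    """Signed %MF change, post minus baseline (sign is kept)."""
    if not (np.isfinite(v_b) and np.isfinite(v_p)):
        raise ValidationError("%MF values must be finite")
    return v_p - v_b


@dataclass
class GroupSummary:
    n: int
    mean: float
    sd: float | None  # sample SD (n-1); None when n < 2
    median: float
    iqr: float  # Q3 - Q1, linear-interpolation quantiles

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def group_summary(values) -> GroupSummary:
    """Mean ± sample SD and median ± IQR of a group of measurements."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValidationError("group_summary of an empty list")
    if not np.all(np.isfinite(arr)):
        raise ValidationError("group values must be finite")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else None
    q1, q3 = np.percentile(arr, [25, 75])
    return GroupSummary(
        n=int(arr.size),
        mean=float(arr.mean()),
        sd=sd,
        median=float(np.median(arr)),
        iqr=float(q3 - q1),
    )
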