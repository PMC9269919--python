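"""Synthetic LGE-CMR phantom studies with known ground truth.

The phantom emulates the features the quantification pipeline actually
consumes: a bright ellipsoidal blood-pool chamber, a thin myocardial wall
shell around it containing healthy and enhancing (fibrotic) voxel classes at
a controllable fraction, Rician magnitude noise, paired baseline /
post-pacing time points with a specified fibrosis increment, 13 labelled
landmarks under a known rigid transform, and two-class trichrome slide
images.  It makes no claim to cardiac anatomy: chambers are ellipsoids and
landmarks are surrogate points on the surrounding "vasculature" sphere.

The wall ground truth is constructed as an in-plane (axial 2D disk) shell of
the chamber, i.e. exactly the shape a matched morphological dilation radius
recovers, so segmentation accuracy and quantification accuracy can be tested
separately.

Wall voxel intensities carry Gaussian tissue heterogeneity around their
class mean (``tissue_sigma``), emulating the continuous intensity spread
that partial-volume averaging and biological variation give real LGE walls;
without it, %MF would be a deterministic voxel count and repeated
acquisitions of the same animal would agree exactly, which real data never
do.  The blood pool is homogeneous (noise only).

Stream order of the per-call random generator: fibrosis patch seeds and
growth order first, then the wall tissue-heterogeneity field, then the two
Gaussian noise fields (real, imaginary).  Identical seeds give bit-identical
phantoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import (
    DEFAULT_SPACING,
    GeometryError,
    ImageVolume,
    LabelMap,
    LandmarkSet,
    ValidationError,
)
from .registration import RigidTransform, rotation_about_z
from .segmentation import axial_dilate, boolean_remove

#: Surrogates for the 13 anatomical fiducials used in the study.
LANDMARK_LABELS = (
    "ascending aorta",
    "descending aorta",
    "aortic arch",
    "left pulmonary artery",
    "right pulmonary artery",
    "left superior pulmonary vein",
    "left inferior pulmonary vein",
    "right superior pulmonary vein",
    "right inferior pulmonary vein",
    "LA septum",
    "LA appendage",
    "left anterior descending artery",
    "aortic valve",
)


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic LGE-CMR acquisition.

    Intensity means default to (blood 600, healthy wall 360, fibrotic wall
    840), i.e. noise-free normalized intensities 0.6 and 1.4 bracketing the
    plausible fibrosis-threshold range.  Wall thickness is in voxels (the
    atrial wall spans only a few voxels at this resolution).
    """

    grid_shape: tuple[int, int, int] = (48, 48, 32)
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    chamber_semi_axes_mm: tuple[float, float, float] = (10.0, 8.0, 9.0)
    wall_thickness: int = 3
    fibrosis_fraction: float = 0.10
    intensity_means: tuple[float, float, float] = (600.0, 360.0, 840.0)
    tissue_sigma: float = 90.0
    noise_sigma: float = 10.0
    n_fibrosis_patches: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.intensity_means[0] <= 0:
            raise ValidationError("blood-pool intensity mean must be > 0")
        if self.wall_thickness < 1:
            raise ValidationError("wall_thickness must be >= 1 voxel")
        if not (0.0 <= self.fibrosis_fraction < 1.0):
            raise ValidationError(
                f"fibrosis_fraction must be in [0, 1), got {self.fibrosis_fraction}"
            )
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")
        if self.tissue_sigma < 0:
            raise ValidationError("tissue_sigma must be >= 0")


@dataclass
class GroundTruth:
    """Noise-free class assignments and metadata of a generated phantom."""

    blood_pool_mask: LabelMap
    wall_mask: LabelMap
    fibrosis_mask: LabelMap
    true_percent_mf: float
    landmarks: LandmarkSet
    applied_transform: RigidTransform | None = None


_NEIGHBORS6 = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
)


def _grow_patches(
    wall: np.ndarray, target: int, n_patches: int, rng: np.random.Generator
) -> np.ndarray:
    """Grow ~n_patches contiguous fibrotic patches on the wall shell.

    Multi-source randomized breadth-first growth over 6-connected wall
    voxels until exactly ``target`` voxels are marked.
    """
    fib = np.zeros_like(wall)
    if target <= 0:
        return fib
    wall_idx = np.argwhere(wall)
    queued = np.zeros_like(wall)
    n_seeds = max(1, min(n_patches, target, len(wall_idx)))
    seed_rows = rng.choice(len(wall_idx), size=n_seeds, replace=False)
    frontier = [tuple(wall_idx[r]) for r in seed_rows]
    for v in frontier:
        queued[v] = True
    shape = wall.shape
    selected = 0
    while selected < target:
        if not frontier:
            # disconnected remainder: reseed on an untouched wall voxel
            remaining = np.argwhere(wall & ~queued)
            v = tuple(remaining[rng.integers(len(remaining))])
            queued[v] = True
            frontier.append(v)
        i = int(rng.integers(len(frontier)))
        frontier[i], frontier[-1] = frontier[-1], frontier[i]
        v = frontier.pop()
        fib[v] = True
        selected += 1
        for d in _NEIGHBORS6:
            w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
            if (
                0 <= w[0] < shape[0]
                and 0 <= w[1] < shape[1]
                and 0 <= w[2] < shape[2]
                and wall[w]
                and not queued[w]
            ):
                queued[w] = True
                frontier.append(w)
    return fib


def _surface_landmarks(
    center: np.ndarray, semi_axes: np.ndarray, scale: float = 1.6
) -> LandmarkSet:
    """13 deterministic surrogate fiducials on a scaled chamber surface."""
    n = len(LANDMARK_LABELS)
    k = np.arange(n)
    # golden-spiral directions: distinct, well spread, deterministic
    phi = np.arccos(1 - 2 * (k + 0.5) / n)
    theta = np.pi * (1 + 5**0.5) * k
    dirs = np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)],
        axis=1,
    )
    coords = center + scale * semi_axes * dirs
    return LandmarkSet.from_arrays(list(LANDMARK_LABELS), coords, role="fixed")


def rician_noise(
    signal: np.ndarray, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """Magnitude-MRI noise model: |(signal + g₁) + i·g₂|, g ~ N(0, σ)."""
    if sigma == 0:
        return signal.copy()
    g1 = rng.normal(0.0, sigma, signal.shape)
    g2 = rng.normal(0.0, sigma, signal.shape)
    return np.hypot(signal + g1, g2)


def generate_la_phantom(spec: PhantomSpec) -> tuple[ImageVolume, GroundTruth]:
    """Generate one phantom acquisition plus its ground truth."""
    shape = tuple(int(n) for n in spec.grid_shape)
    spacing = np.asarray(spec.spacing, dtype=float)
    semi = np.asarray(spec.chamber_semi_axes_mm, dtype=float)
    # chamber must fit with room for the wall shell plus one voxel margin
    half_extent_mm = spacing * (np.asarray(shape) - 1) / 2.0
    margin_mm = (spec.wall_thickness + 1) * spacing
    if np.any(semi + margin_mm > half_extent_mm):
        raise GeometryError(
            f"chamber semi-axes {tuple(semi)} mm + wall margin do not fit in "
            f"grid {shape} at spacing {tuple(spacing)} mm"
        )
    center = spacing * (np.asarray(shape) - 1) / 2.0
    ii, jj, kk = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij")
    pos = np.stack([ii, jj, kk], axis=-1) * spacing
    rel = (pos - center) / semi
    chamber = np.sum(rel * rel, axis=-1) <= 1.0

    pool = LabelMap(chamber, "blood_pool", tuple(spacing), (0.0, 0.0, 0.0))
    dilated = axial_dilate(pool, spec.wall_thickness)
    wall = boolean_remove(dilated, pool)

    rng = np.random.default_rng(spec.seed)
    n_wall = wall.voxel_count
    target = int(round(spec.fibrosis_fraction * n_wall))
    fib_mask = _grow_patches(wall.mask, target, spec.n_fibrosis_patches, rng)
    fib = LabelMap(fib_mask, "fibrosis", tuple(spacing), (0.0, 0.0, 0.0))

    mu_blood, mu_healthy, mu_fibrotic = spec.intensity_means
    signal = np.zeros(shape, dtype=float)
    signal[chamber] = mu_blood
    signal[wall.mask & ~fib_mask] = mu_healthy
    signal[fib_mask] = mu_fibrotic
    if spec.tissue_sigma > 0:
        signal[wall.mask] = np.maximum(
            signal[wall.mask] + rng.normal(0.0, spec.tissue_sigma, n_wall), 0.0
        )
    data = rician_noise(signal, spec.noise_sigma, rng)

    truth = GroundTruth(
        blood_pool_mask=pool,
        wall_mask=wall,
        fibrosis_mask=fib,
        true_percent_mf=100.0 * fib.voxel_count / n_wall,
        landmarks=_surface_landmarks(center, semi),
    )
    return ImageVolume(data, tuple(spacing), (0.0, 0.0, 0.0)), truth


def generate_paired_study(
    spec_baseline: PhantomSpec,
    delta_f: float,
    rigid_jitter: tuple[float, float] = (0.0, 0.0),
    seed: int | None = None,
) -> tuple[
    tuple[ImageVolume, GroundTruth], tuple[ImageVolume, GroundTruth]
]:
    """Baseline / post-pacing phantom pair with a known fibrosis increment.

    The post time point has fibrosis fraction ``f_baseline + delta_f`` and
    its landmarks are moved by a known rigid transform (rotation by
    ``rigid_jitter[0]`` degrees about the slice axis through the phantom
    center, plus a translation of ``rigid_jitter[1]`` mm along the grid
    diagonal), recorded in ``GroundTruth.applied_transform`` as the
    baseline-to-post (moving-to-fixed) map.

    ``seed`` overrides ``spec_baseline.seed``; the post phantom uses
    ``seed + 1`` so the two noise realizations are independent.
    """
    f_post = spec_baseline.fibrosis_fraction + delta_f
    if not (0.0 <= f_post < 1.0):
        raise ValidationError(
            f"post-pacing fibrosis fraction {f_post} out of [0, 1)"
        )
    base_seed = spec_baseline.seed if seed is None else int(seed)
    spec_b = replace(spec_baseline, seed=base_seed)
    spec_p = replace(spec_baseline, fibrosis_fraction=f_post, seed=base_seed + 1)
    baseline = generate_la_phantom(spec_b)
    post = generate_la_phantom(spec_p)

    angle_deg, shift_mm = rigid_jitter
    center = np.asarray(spec_b.spacing) * (np.asarray(spec_b.grid_shape) - 1) / 2.0
    rot = rotation_about_z(angle_deg)
    shift = shift_mm * np.ones(3) / np.sqrt(3.0)
    translation = center - rot @ center + shift
    transform = RigidTransform(
        rot, translation, fixed_role="fixed", moving_role="moving"
    )
    post_img, post_truth = post
    post_truth.landmarks = transform.apply_to_landmarks(
        baseline[1].landmarks, role="fixed"
    )
    post_truth.applied_transform = transform
    base_img, base_truth = baseline
    base_truth.landmarks = LandmarkSet.from_arrays(
        base_truth.landmarks.labels, base_truth.landmarks.as_array(), role="moving"
    )
    return (base_img, base_truth), (post_img, post_truth)


_NEIGHBORS4 = ((1, 0), (-1, 0), (0, 1), (0, -1))


def generate_trichrome_image(
    width: int,
    height: int,
    fibrosis_fraction: float,
    background_fraction: float = 0.3,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Synthetic two-class trichrome slide with known fibrosis fraction.

    Tissue occupies a central ellipse covering roughly
    ``1 - background_fraction`` of the image; within tissue, contiguous
    blue-hue (collagen) blobs cover exactly
    ``round(f * n_tissue)`` pixels and the rest is red-hue (myocyte) tissue;
    the background is near-white.  Returns the (height, width, 3) uint8 image
    and the realized fibrosis fraction.
    """
    if not (0.0 <= fibrosis_fraction <= 1.0):
        raise ValidationError("fibrosis_fraction must be in [0, 1]")
    if not (0.0 <= background_fraction < 1.0):
        raise ValidationError("background_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:height, 0:width]
    cy, cx = (height - 1) / 2.0, (width - 1) / 2.0
    target_tissue = (1.0 - background_fraction) * width * height
    scale = min(0.98, np.sqrt(target_tissue / (np.pi * (height / 2) * (width / 2))))
    ry, rx = scale * height / 2.0, scale * width / 2.0
    tissue = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
    n_tissue = int(tissue.sum())
    if n_tissue == 0:
        raise ValidationError("image too small: no tissue pixels")
    n_blue = int(round(fibrosis_fraction * n_tissue))

    blue = np.zeros_like(tissue)
    if n_blue > 0:
        tissue_idx = np.argwhere(tissue)
        queued = np.zeros_like(tissue)
        n_seeds = max(1, min(4, n_blue))
        seeds = rng.choice(len(tissue_idx), size=n_seeds, replace=False)
        frontier = [tuple(tissue_idx[s]) for s in seeds]
        for v in frontier:
            queued[v] = True
        selected = 0
        while selected < n_blue:
            if not frontier:
                remaining = np.argwhere(tissue & ~queued)
                v = tuple(remaining[rng.integers(len(remaining))])
                queued[v] = True
                frontier.append(v)
            i = int(rng.integers(len(frontier)))
            frontier[i], frontier[-1] = frontier[-1], frontier[i]
            v = frontier.pop()
            blue[v] = True
            selected += 1
            for dy, dx in _NEIGHBORS4:
                w = (v[0] + dy, v[1] + dx)
                if (
                    0 <= w[0] < height
                    and 0 <= w[1] < width
                    and tissue[w]
                    and not queued[w]
                ):
                    queued[w] = True
                    frontier.append(w)

    img = np.empty((height, width, 3), dtype=np.int16)
    img[...] = (246, 244, 246)  # near-white background
    img[tissue & ~blue] = (190, 35, 55)  # red/magenta myocyte hue
    img[blue] = (45, 65, 190)  # blue collagen hue
    jitter = rng.integers(-5, 6, size=img.shape, dtype=np.int16)
    img = np.clip(img + jitter, 0, 255).astype(np.uint8)
    return img, n_blue / n_tissue
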