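"""Image-quality and observer-variability metrics.

Covers NEMA-4 SNR (one signal ROI, four background ROIs, Rayleigh
correction), Dice similarity, boundary F1 / precision / recall under a
distance tolerance, relative volume error, and the variance-component
reliability metrics

    ICC = (1 + sigma2_w / sigma2_b)^-1
    R   = (1 + sigma2_w / (k * sigma2_b))^-1,

where sigma2_w is the mean within-condition sample variance, sigma2_b the
sample variance of condition means, and k the number of operators.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import ndimage

from .core import ImageVolume, LabelMap, ValidationError, require_congruent

RAYLEIGH_FACTOR = 0.66


@dataclass
class SnrResult:
    signal_mean: float
    noise_sd_avg: float
    rayleigh_factor: float
    snr: float


def nema4_snr(
    image: ImageVolume,
    signal_roi: LabelMap,
    noise_rois: list[LabelMap],
    factor: float = RAYLEIGH_FACTOR,
) -> SnrResult:
    """SNR = factor * mean(signal ROI) / mean of the four noise-ROI SDs."""
    if len(noise_rois) != 4:
        raise ValidationError(f"exactly 4 noise ROIs required, got {len(noise_rois)}")
    require_congruent(image, signal_roi, *noise_rois)
    if signal_roi.voxel_count == 0:
        raise ValidationError("empty signal ROI")
    combined = np.zeros(image.shape, dtype=int)
    for roi in noise_rois:
        if roi.voxel_count == 0:
            raise ValidationError("empty noise ROI")
        combined += roi.mask
    if combined.max() > 1:
        raise ValidationError("noise ROIs must be disjoint")
    sds = [float(image.data[roi.mask].std(ddof=1)) for roi in noise_rois]
    noise_sd_avg = float(np.mean(sds))
    if noise_sd_avg <= 0:
        raise ValidationError("degenerate noise: zero background SD")
    signal_mean = float(image.data[signal_roi.mask].mean())
    return SnrResult(
        signal_mean=signal_mean,
        noise_sd_avg=noise_sd_avg,
        rayleigh_factor=factor,
        snr=factor * signal_mean / noise_sd_avg,
    )


def dice(a: LabelMap, b: LabelMap) -> float:
    """Dice similarity in percent: 100 * 2|A∩B| / (|A| + |B|).

    Both empty → 100 (perfect agreement on nothing); exactly one empty → 0.
    """
    require_congruent(a, b)
    na, nb = a.voxel_count, b.voxel_count
    if na == 0 and nb == 0:
        return 100.0
    inter = int((a.mask & b.mask).sum())
    return 100.0 * 2.0 * inter / (na + nb)


def pairwise_mean_dice(masks: list[LabelMap]) -> tuple[float, float]:
    """Mean ± SD of Dice over all unordered pairs of ≥2 masks."""
    if len(masks) < 2:
        raise ValidationError("need >= 2 masks for pairwise Dice")
    scores = [dice(a, b) for a, b in combinations(masks, 2)]
    sd = float(np.std(scores, ddof=1)) if len(scores) > 1 else 0.0
    return float(np.mean(scores)), sd


def boundary_voxels(mask: LabelMap) -> np.ndarray:
    """Mask voxels with at least one non-mask 6-neighbour (outside counts)."""
    struct = ndimage.generate_binary_structure(3, 1)
    interior = ndimage.binary_erosion(mask.mask, structure=struct, border_value=0)
    return mask.mask & ~interior


def boundary_scores(
    candidate: LabelMap, reference: LabelMap, tolerance: float = 2.0
) -> tuple[float, float, float]:
    """Boundary F1, precision, recall (%) under a Euclidean voxel tolerance.

    Precision is the fraction of candidate-boundary voxels lying within
    ``tolerance`` voxels of the reference boundary; recall is symmetric; F1
    is their harmonic mean.  Both boundaries empty → all 100; exactly one
    empty → all 0.
    """
    require_congruent(candidate, reference)
    if tolerance < 0:
        raise ValidationError("tolerance must be >= 0")
    cb = boundary_voxels(candidate)
    rb = boundary_voxels(reference)
    if not cb.any() and not rb.any():
        return 100.0, 100.0, 100.0
    if not cb.any() or not rb.any():
        return 0.0, 0.0, 0.0
    dist_to_ref = ndimage.distance_transform_edt(~rb)
    dist_to_cand = ndimage.distance_transform_edt(~cb)
    precision = 100.0 * float((dist_to_ref[cb] <= tolerance).mean())
    recall = 100.0 * float((dist_to_cand[rb] <= tolerance).mean())
    f1 = (
        0.0
        if precision + recall == 0
        else 2.0 * precision * recall / (precision + recall)
    )
    return f1, precision, recall


def relative_volume_error(candidate: LabelMap, reference: LabelMap) -> float:
    """Signed (|candidate| - |reference|) / |reference|."""
    require_congruent(candidate, reference)
    if reference.voxel_count == 0:
        raise ValidationError("empty reference mask: RVE undefined")
    return (candidate.voxel_count - reference.voxel_count) / reference.voxel_count


def _reliability(sigma2_w: float, sigma2_b: float, k: int) -> float:
    """(1 + sigma2_w / (k * sigma2_b))^-1; k = 1 gives the ICC formula."""
    return 1.0 / (1.0 + sigma2_w / (k * sigma2_b))


def variance_components(groups) -> tuple[float, float]:
    """(sigma2_w, sigma2_b): mean within-group sample variance and sample
    variance of group means, for a sequence of value sequences."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValidationError("need >= 2 conditions")
    if any(len(g) < 2 for g in groups):
        raise ValidationError("need >= 2 repeats per condition")
    sigma2_w = float(np.mean([g.var(ddof=1) for g in groups]))
    means = np.array([g.mean() for g in groups])
    sigma2_b = float(means.var(ddof=1))
    return sigma2_w, sigma2_b


def icc_intra(measurements) -> tuple[float, float, float]:
    """Intra-operator intraclass correlation over repeated measurements.

    ``measurements`` is per-condition sequences of one operator's repeats
    (e.g. three segmentation attempts per animal/time point).  Returns
    ``(icc, sigma2_w, sigma2_b)``.
    """
    sigma2_w, sigma2_b = variance_components(measurements)
    if sigma2_b == 0:
        raise ValidationError(
            "no between-condition spread (sigma2_b = 0): ICC undefined"
        )
    return _reliability(sigma2_w, sigma2_b, 1), sigma2_w, sigma2_b


def inter_rater_r(measurements) -> tuple[float, int]:
    """Inter-rater reliability over k operators' repeated measurements.

    ``measurements`` is per-condition sequences of per-operator repeat
    sequences, shape-like (n_conditions, k_operators, n_repeats).  Variance
    components are pooled: sigma2_w over every (condition, operator) cell,
    sigma2_b over condition means pooled across operators.  Returns
    ``(r, k)``.
    """
    conditions = [[np.asarray(op, dtype=float) for op in cond] for cond in measurements]
    if len(conditions) < 2:
        raise ValidationError("need >= 2 conditions")
    ks = {len(cond) for cond in conditions}
    if len(ks) != 1:
        raise ValidationError("all conditions need the same number of operators")
    k = ks.pop()
    if k < 2:
        raise ValidationError(f"inter-rater R needs >= 2 operators, got {k}")
    cells = [op for cond in conditions for op in cond]
    if any(len(c) < 2 for c in cells):
        raise ValidationError("need >= 2 repeats per operator and condition")
    sigma2_w = float(np.mean([c.var(ddof=1) for c in cells]))
    cond_means = np.array([np.concatenate(cond).mean() for cond in conditions])
    sigma2_b = float(cond_means.var(ddof=1))
    if sigma2_b == 0:
        raise ValidationError("no between-condition spread (sigma2_b = 0)")
    return _reliability(sigma2_w, sigma2_b, k), k
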