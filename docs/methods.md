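# Methods

This note documents the models, conventions, and numerical choices behind
`atriaquant`, and what its synthetic-data tests do and do not demonstrate
about real LGE-CMR data.

## Grid model and I/O

Volumes are 3D scalar grids indexed `data[i, j, k]`, axes 0–1 in-plane and
axis 2 the axial slice index; a voxel center sits at
`origin + spacing ⊙ (i, j, k)` in mm. Only axis-aligned grids are accepted:
a non-identity direction matrix in an NRRD/NIfTI header is rejected rather
than silently resampled, because landmark-based registration operates on
fiducial tables, not on image resampling chains, and an unambiguous
index↔physical mapping keeps every downstream measurement auditable.
Landmark coordinates are treated as an abstract consistent physical frame;
no RAS/LPS convention is imposed, only that fixed and moving tables share
one frame.

When an NRRD header carries no spacing information the reader falls back to
the acquisition geometry used throughout: 0.625 × 0.625 mm in-plane,
0.975 mm slice thickness, with a warning. SimpleITK backs both dialects.

## Wall extraction

The LA wall is derived from a manually segmented blood-pool chamber mask by
(1) dilating every axial slice independently with a 2D Euclidean disk of
radius *r* pixels (default 4), (2) subtracting the chamber (Boolean
remove), and (3) erasing an optional exclusion mask that stands in for the
interactive removal of valves and septal tissue. "Radius-*r* disk" means
the lattice points with i² + j² ≤ r² (49 pixels at r = 4); the alternative
reading — r iterations of a small structuring element — is not used, but
the dilation routine accepts any radius so either convention can be
emulated. Dilation is strictly in-plane: no growth crosses slices, and
in-plane anisotropy is ignored because the radius is specified in pixels.

## Fibrosis quantification

Normalized intensity is `NI(x) = I(x)/μ_BP` with μ_BP the mean intensity of
the same acquisition's blood-pool mask. The threshold is
`T_fib = μ_NI + k·σ_NI` over wall voxels; k defaults to 2 and is a config
key, as is the slice-tie rule. Numerical conventions, all of which matter
at small samples:

- σ_NI is the **sample** SD (n−1), consistent with every other SD the
  package reports.
- Classification is **strict** (`NI > T_fib`); a voxel exactly at the
  threshold is healthy.
- Slice-wise %MF uses the axial slice with the **highest fibrotic voxel
  count**; ties break to the lowest slice index and are flagged. A wall
  with no suprathreshold voxel anywhere raises a distinct "no enhancement"
  error rather than reporting a 0% slice, since the slice choice would be
  meaningless.
- `D_abs = V_post − V_baseline` keeps its sign.
- Group summaries report mean ± sample SD and median ± IQR, with IQR =
  Q3 − Q1 under linear-interpolation quantiles. Other hinge definitions
  exist and give different numbers on 5-element groups; the definition here
  is fixed and documented rather than matched to any particular published
  rounding.
- Post-mortem (in-situ) acquisitions are rejected by the quantifier (an
  explicit override exists): without circulation, pooled contrast
  invalidates the blood-pool reference. They may still contribute to
  registration and SNR QC.

Two structural properties follow from the quotient form and are pinned by
tests: %MF is invariant under global intensity scaling (bit-identical for
power-of-two factors, to 1 ulp otherwise — binary floating point makes
other factors inexact at the last bit), and it is **not** invariant under
additive offsets. A third property bounds the estimator itself: on a binary
wall (healthy NI = a, fibrotic NI = b > a, fraction f fibrotic),
T_fib < b ⟺ f + 2√(f(1−f)) < 1 ⟺ f < 0.2, so measured %MF equals 100f
exactly below f = 0.2 and collapses to 0 above it — the mean+2SD rule
cannot see fibrosis burdens above one fifth of the wall. On a fibrosis-free
Gaussian wall the expected %MF is 100·Φ(−2) ≈ 2.28%, the method's intrinsic
false-positive floor.

## Exact tests

The Wilcoxon signed-rank and Mann-Whitney U tests are exact at every sample
size: the null distributions (all 2ⁿ sign assignments; all C(n₁+n₂, n₁)
group assignments) are computed by subset-sum dynamic programming over
doubled midranks in integer arithmetic, which is identical to full
enumeration at polynomial cost. Two-sided p = min(1, 2·min(lower tail,
upper tail)), tails inclusive of the observed statistic. Zero differences
are dropped before ranking (their count is reported); ties get midranks and
set a flag. A normal-approximation p is available behind a `method` flag as
a cross-check only. The enumeration oracles in the test suite are
independent brute-force implementations.

## Registration

The rigid transform minimizing the sum of squared differences between
labelled fixed and moving landmarks is computed in closed form: centroid
alignment plus the SVD (Kabsch) rotation with determinant correction, so
reflections are excluded. Correspondence is by label, never file order;
fewer than 3 landmarks or a collinear configuration is a degeneracy error.
Volume resampling under a transform uses trilinear interpolation for
intensities and nearest neighbour for label maps. No overlap metric is ever
computed between masks from different time points — anatomy genuinely moves
and deforms between sessions, so such numbers would quantify posture, not
segmentation or fibrosis agreement — and the report layer contains none.

## Variability and QC metrics

Dice is reported on a 0–100 scale (both-empty = 100, one-empty = 0);
repeated-segmentation agreement is the mean ± SD over all unordered attempt
pairs. Boundary precision/recall/F1 extract boundary voxels (mask voxels
with a non-mask 6-neighbour; the grid edge counts as background), measure
Euclidean distances in voxel units, and use a default tolerance of 2
voxels. ICC and R combine variance components as
ICC = (1 + σ²_w/σ²_b)⁻¹ and R = (1 + σ²_w/(k·σ²_b))⁻¹; the estimators are
a declared choice: σ²_w is the mean within-condition (or within
condition-and-operator, pooled) sample variance and σ²_b the sample
variance of condition means. R at k = 1 collapses to ICC. NEMA-4 SNR is
`0.66 · mean(signal ROI) / mean(SD of 4 background ROIs)`; the 0.66
Rayleigh factor converts magnitude-background SD to Gaussian-equivalent
noise. The pipeline places its four background boxes in grid corners
automatically.

## Histology

Trichrome slides are classified in HSV space: background is saturation
< 0.15 or value > 0.95 (near-white); remaining tissue pixels are collagen
(fibrosis) when hue ∈ [90°, 270°) and myocyte tissue otherwise; percent
fibrosis is computed over tissue pixels only. The thresholds are fixed,
configurable defaults pinned by ground-truth recovery tests on synthetic
slides (±1 point across f = 0…0.9 at 512²); no per-sample threshold
optimization is attempted. Classification is invariant to hue-preserving
brightness changes within these cutoffs. Per-animal histology is the mean
over available slices; group statistics reuse the same summary definitions
as the imaging tables.

## Synthetic phantoms: what they emulate, and what they don't

The generator produces an ellipsoidal blood pool at mean intensity 600, a
wall shell of 2–4 voxel thickness whose healthy/fibrotic class means are
360/840 (noise-free NI 0.6/1.4, straddling plausible thresholds), fibrotic
voxels grown as contiguous surface patches by seeded region growing (so
enhancement is blob-like, not salt-and-pepper), Gaussian tissue
heterogeneity within the wall (default SD 90, i.e. NI class SD 0.15),
Rician magnitude noise `|(s + g₁) + i·g₂|` (default σ 10), 13 labelled
surrogate fiducials on a scaled chamber surface, and paired time points in
which the post acquisition carries a specified fibrosis increment and a
known rigid transform on its landmarks. Ground truth (masks, exact %MF,
transform) is recorded noise-free.

The wall ground truth is itself built as the in-plane disk shell of the
chamber, so a matched dilation radius recovers it exactly; this keeps
"does segmentation match" and "does quantification recover the injected
fraction" as separate questions. Tissue heterogeneity is what gives
repeated phantom acquisitions distinct %MF values — with purely binary
classes the measurement would be a deterministic count, all paired
differences would vanish, and the control-group test would be undefined, a
degeneracy real cohorts never show.

Default cohort conditions: 9 experimental + 3 control animals, baseline
fibrosis fraction 0.05, experimental increment +0.02 (two percentage
points, the order of the reported progression), grid 48×48×32 at the
acquisition spacing, chamber semi-axes (10, 8, 9) mm, wall thickness 3
voxels. A 12-animal study runs in well under a second, so repeatability
claims are made over 20 independently seeded runs.

The phantoms deliberately do **not** model cardiac anatomy, motion or
arrhythmia artifacts, coil sensitivity, inversion-time contrast behaviour,
partial-volume mixtures at mask borders, or manual-segmentation error.
Passing tests therefore demonstrate the correctness of the computations and
the internal consistency of the pipeline under known ground truth — not
that the mean+2SD threshold is biologically optimal, nor the accuracy
achievable on clinical images, where observer variability dominates.

## Known limitations

- The mean+2SD estimator saturates at f ≥ 0.2 on near-binary walls (see
  above) and carries a ≈2.3% false-positive floor on enhancement-free
  walls; both are properties of the method, reproduced and tested, not
  corrected.
- Measured progression on noisy phantoms is mildly attenuated relative to
  the injected increment (threshold misclassification acts at both time
  points); the noise-free recovery is exact to voxel quantization.
- Oblique acquisitions require prior resampling elsewhere; the package
  refuses them.
- Exact tests at very large n are computationally fine (DP is polynomial)
  but the package targets small-cohort inference; no asymptotic machinery
  beyond the cross-check flag is provided.
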