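# atriaquant

Quantification of left-atrial (LA) myocardial fibrosis from 3D
late-gadolinium-enhanced cardiac MR (LGE-CMR), built for longitudinal
studies that track fibrosis progression between imaging time points — e.g.
a paced-animal model imaged before and after sustained rapid ventricular
pacing — with histological (Masson's trichrome) validation.

## What it computes

Fibrotic myocardium retains gadolinium and appears bright on LGE-CMR, but
raw intensities are not comparable across scans. The package normalizes
every LA wall voxel by the mean blood-pool intensity (the *image intensity
ratio*),

    NI(x) = I(x) / μ_BP,

and classifies a wall voxel as fibrotic when its normalized intensity
strictly exceeds

    T_fib = μ_NI + k · σ_NI        (k = 2 by default),

with μ_NI and σ_NI the mean and sample SD of NI over the wall. From this it
reports:

- **%MF (volumetric)** — fibrotic share of the whole LA wall volume, and
  **%MF (slice-wise)** — fibrotic share of the wall area in the single axial
  slice containing the most fibrotic voxels (the natural comparator for
  single-slice histology);
- **D_abs = V_post − V_baseline** — the signed per-animal progression in
  percentage points;
- group tables (mean ± SD, median ± IQR) and **exact** small-sample
  nonparametric inference: the Wilcoxon signed-rank test on paired %MF
  within groups and the Mann-Whitney U test between groups, both by full
  enumeration of the discrete null;
- the LA wall itself, derived morphologically from a blood-pool chamber
  mask (per-slice disk dilation, Boolean subtraction, optional exclusion
  mask for non-myocardial tissue);
- landmark-based rigid registration between time points (closed-form
  SSD-minimizing fit over 13 labelled fiducials), for rendering volumes in
  a common space — deliberately *without* cross-time-point overlap metrics;
- QC and observer-variability metrics: NEMA-4 SNR with Rayleigh correction,
  Dice, boundary F1/precision/recall, relative volume error, and the
  variance-component reliability metrics ICC = (1 + σ²_w/σ²_b)⁻¹ and
  R = (1 + σ²_w/(k·σ²_b))⁻¹;
- trichrome histology quantification: blue (collagen) vs red (myocyte)
  pixel classification in HSV space, per-animal and group summaries.

A synthetic phantom generator (`atriaquant.phantom`) produces paired
baseline/post studies, landmark sets under a known rigid transform, and
trichrome slides — all with exact ground truth — so the entire pipeline is
testable without clinical data. See `docs/methods.md` for the model and its
limits.

## Worked example

```python
from atriaquant import run_synthetic_study

report = run_synthetic_study(
    n_experimental=9, n_control=3,   # cohort size
    f_baseline=0.05, delta_f=0.02,   # 5% baseline fibrosis, +2 points if paced
    seed=1,
)
exp = report.group_tables["volumetric"]["experimental"]
print(f"experimental %MF: {exp['baseline']['mean']:.2f} -> "
      f"{exp['post_pacing']['mean']:.2f}, mean D_abs {exp['d_abs']['mean']:.2f}")
print("paired Wilcoxon p (experimental):",
      report.tests["wilcoxon_volumetric_experimental"]["p_two_sided"])
print("paired Wilcoxon p (control):    ",
      report.tests["wilcoxon_volumetric_control"]["p_two_sided"])
print("Mann-Whitney p (post, exp vs ctl):",
      report.tests["mann_whitney_post_volumetric"]["p_two_sided"])
```

prints

```
experimental %MF: 4.90 -> 6.51, mean D_abs 1.62
paired Wilcoxon p (experimental): 0.00390625
paired Wilcoxon p (control):     0.25
Mann-Whitney p (post, exp vs ctl): 0.00909090909090909
```

The paced group's measured fibrosis rises by ≈1.6 points (the injected 2
points, attenuated slightly by threshold misclassification in the noisy
wall), the paired test flags it at the smallest p attainable for n = 9
(2/512), the control group shows no change, and the between-group test at
the post time point reaches 2/220 ≈ 0.009 under complete separation.

The same pipeline runs from the shell over a cohort directory:

```
atriaquant synth --animals 12 --controls 3 --seed 1 --out cohort/
atriaquant run --config cohort/manifest.json --out results/
```

producing `report.json`, group tables (`table_volumetric.csv`,
`table_slicewise.csv`), `per_animal.csv`, `qc_snr.csv` and a `run.log` with
input hashes.

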