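# Methods

## The two-compartment partition

The core computation treats every voxel in the measured lung region as a
mixture of exactly two materials: air, imaged at `nCT_air` HU, and lung
tissue (parenchyma including capillary blood), imaged at `nCT_tissue` HU.
Volume conservation and linearity of the CT number in component fractions
give the region-level partition

```
vCT_tissue = vCT_total * (nCT_total - nCT_air) / (nCT_tissue - nCT_air)
vCT_air    = vCT_total - vCT_tissue
```

Assumptions worth stating explicitly:

* **Linearity.** CT numbers mix linearly with volume fractions.  This is a
  good approximation at fixed kVp over the -1000..+100 HU range but ignores
  beam hardening and kernel nonlinearity.
* **Two compartments.** Bone, calcification and contrast are excluded by
  the extraction protocol's final window; blood and parenchyma are not
  separated (they jointly form "tissue", as in physiological methods).
* **Region-level evaluation.** The partition is evaluated on the region
  mean, which is exactly equivalent to integrating a voxelwise linear
  fraction map when no voxel falls outside the calibration gamut.
  `voxelwise_fraction_map` provides the voxel-resolved view (clipped to
  [0, 1]); the region path is primary and performs no clipping.

### Calibration constants

| constant | classical | measured-air | unit | rationale |
|---|---|---|---|---|
| `nCT_tissue` | 0 | **39.5** | HU | mean CT number of atelectatic (airless) lung at 120 kVp; atelectasis is the closest in-vivo surrogate for pure tissue |
| `nCT_air` | -1000 | **per-scan trachea ROI** (default -980.9) | HU | scatter raises imaged air above the nominal -1000 HU; the trachea ROI measures air as the scanner actually renders it |

Out-of-gamut region means (outside `[nCT_air, nCT_tissue]`) are returned
with a QC flag rather than clipped: silent clipping would hide acquisition
problems and break volume conservation.  An explicit `clip_gamut` option
clips the fraction and lets the air compartment absorb the residual.

## Lung-field extraction

The measurement region is constructed in stages (all operators classical
and deterministic):

1. **Whole lung (a).** Voxels ≤ `lung_threshold_hu` (default -320 HU),
   connected components labelled (6- or 26-connectivity, default 26),
   components touching the volume border discarded (exterior air), the up
   to two largest kept and hole-filled (vessels stay inside).
2. **Airway/vessel removal (b).** The airway is the near-air
   (≤ -900 HU) component grown from a tracheal seed — the highest-z
   near-air voxel in the central third of the in-plane field, excluding
   border-connected air, ties broken toward the in-plane centre.  A missing
   seed is a logged warning, not an error.  Vessels are intra-lung
   components ≥ `vessel_threshold_hu` (default -500 HU) of at least
   `min_vessel_voxels` voxels.
3. **Surface shell (c).** Dilation minus erosion of (a) with a metric-aware
   Euclidean ball of radius `shell_thickness_mm` (default 3 mm), built from
   the voxel spacing, so the band has the same physical width on
   anisotropic grids.
4. **Core (d) and add-back (e).** d = b − c removes the boundary band where
   partial-volume voxels blend lung with chest wall, diaphragm, heart and
   fat; e restores only the shell voxels inside the lung-field window
   (-1000..-500 HU, inclusive) — true lung at the surface returns, soft
   tissue (≈ +40 HU) and fat (≈ -100 HU) stay out.
5. **Final statistics (f).** d and e are each restricted to the final
   window (-1000..+100 HU, inclusive; removes noise outliers) and pooled by
   exact "mean × volume" weighting.  The final region is an accounting
   construct: it is never rendered as an image.

The defaults (-320 HU lung threshold, -500 HU vessel threshold, 3 mm
shell, 26-connectivity) follow standard lung-densitometry practice; the
clinical workstations that perform these steps do not disclose their
internals, so every threshold is configuration, not a fidelity claim.
Identical input and configuration yield bit-identical masks.

ROI membership everywhere is centre-in-disc: a voxel belongs to a circular
ROI when its in-plane centre (at `index * spacing` mm) lies within the
disc.  This is simple, reproducible and matches clinical ROI tools to first
order; area-weighted membership would change means by well under the
measurement noise at the default 10–25 mm ROI diameters.

## Air-calibration validation (dilution model)

Inspiration is modelled as adding pure air to the expiratory lung, exactly
like diluting a solution:

```
n_theory = (ExpnCT_total * ExpvCT_total + nCT_air * (InsvCT_total - ExpvCT_total)) / InsvCT_total
```

The absolute difference between `n_theory` and the measured inspiratory
mean scores a candidate `nCT_air`; the prediction is affine in `nCT_air`
with slope `(V_ins - V_exp)/V_ins > 0`, so the error has a unique zero and
a wrong candidate incurs error `|Δair| * (V_ins - V_exp)/V_ins`.
Candidates (nominal -1000 HU, trachea air measured on expiration, on
inspiration) are compared with the two-sided Wilcoxon signed-rank test
(exact for n ≤ 25 with no zero differences, normal approximation
otherwise); the winner is the minimum-mean-error candidate.

## Repeatability

For two paired scans on different days, "variation" between any two of the
four tissue volumes is their absolute difference as a percentage of the
largest of the four (the largest value is "set to 100 %").  This single
definition reproduces both the min/max-variation summaries and the
designated same-phase between-day entries; because the normalisation is
ambiguous in the clinical literature, both the all-six-pairs and the
cross-day-pairs-only min/max are reported.  Metrics are invariant to
uniform rescaling of the four values.

## Normative models

The six published regressions (tissue volume on height and on total lung
volume; pooled, male, female) are shipped as frozen constants with their
reported Spearman correlations, and are never refitted — `fit_linear` (OLS)
exists for synthetic cohorts but returns new objects.  Cohort analysis uses
Spearman rank correlation with the conventional strength bands (> 0.7
strong, 0.4–0.7 moderate, 0.2–0.4 weak, ≤ 0.2 absent).  BSA is consumed as
an input covariate; the synthetic cohort generator fills it with the
Du Bois formula, but no normative claim depends on that choice.

## The phantom generator

### What it emulates

* two ellipsoidal lungs in a soft-tissue elliptic-cylinder body (+40 HU)
  with a 6 mm subcutaneous fat ring (-100 HU);
* parenchyma rendered voxelwise from a known uniform tissue fraction
  (default 0.13, a normal inspiratory value): HU = f·39.5 + (1-f)·air;
* imaged air at -980 HU by default (nominal -1000 plus a +20 HU scatter
  offset applied to all air-containing structures);
* three z-aligned vessels per lung (+40 HU, 4 mm radius) strictly inside
  the parenchyma, and a mediastinal tracheal air cylinder (8 mm radius)
  ending below the grid top so it never merges with exterior air;
* a one-voxel partial-volume rim blending parenchyma 50/50 with the chest
  wall, giving the shell/add-back logic realistic work;
* optional additive Gaussian noise; everything is a pure function of the
  spec (seed included).

Paired states: the inspiratory lung axes are scaled by
`inspiration_scale^(1/3)` (default 1.6, matching normal paired-scan volume
ratios) and the tissue fraction diluted by the realised parenchyma-volume
ratio, so ground-truth tissue volume is conserved *exactly* and the
interior mean obeys the dilution formula identically; discretisation enters
only through the voxelised geometry (< 0.5 HU at default resolution).

The cohort generator samples sex-specific heights/weights (normal
distributions at typical adult screening values), maps height to target
tissue volume through the shipped pooled model with lognormal scatter
(σ = 0.13, chosen to land the height–tissue Spearman correlation near the
published ≈ 0.65), draws a per-subject tissue fraction
(0.13 ± 0.012), and rescales the whole scene uniformly so the rendered
parenchyma volume realises the implied total lung volume.

### What it does not emulate

No projection/reconstruction physics, kernels, dose or beam hardening;
scatter is a single HU offset; the airway is one cylinder, not a tree; the
fraction field is uniform rather than gravity-dependent; lobes, fissures
and the diaphragm are absent.  Passing tests therefore demonstrate that the
algorithms are *correct on their stated model* — exact accounting, correct
thresholding/morphology/region-growing, correct formula evaluation — not
that segmentation is robust to real anatomical variation.

### Problem sizes

Default phantoms are 72×120×120 voxels at 2.5 mm (the `small` variant
48×84×84 at 3.5 mm for cohort work) — deliberately coarser than clinical
512² × 1 mm scans so a full generate–extract–partition cycle takes well
under a second and whole simulated cohorts run in seconds.  Consequently
phantom lung volumes sit below typical adult values; all validation
properties (recovery error, dilution consistency, correlation structure)
are scale-free.

## Numerical choices

* HU window bounds are inclusive at both ends, so the -1000 HU floor and
  every stated bound are retained.
* All lattices are (z, y, x), 0-based; NIfTI affines are consumed only for
  voxel spacing (statistics are orientation-independent); volumes in ml
  from the spacing product, assuming contiguous reconstructed slices.
* Pooled statistics are exact volume-weighted sums; the partition/pooling
  identity holds to 1e-9 relative in tests (float64 round-off only).
* Empty regions raise explicit errors; NaNs are never returned silently.
* `tissue_fraction` at zero total volume is defined as 0 (avoids 0/0).
* Reports print mean HU to 0.1 HU and volumes to 0.1 ml.

## Known limitations

* The extraction thresholds are conventions, not fitted to any scanner;
  real scans with severe emphysema (parenchyma near -950 HU) would need a
  lower airway threshold to avoid region-growing into lung.
* The tissue calibration 39.5 HU is specific to 120 kVp acquisitions;
  atelectasis includes large vessels and may differ from healthy
  parenchyma.
* The dilution validation assumes capillary blood volume is constant across
  the breathing cycle.
* The per-voxel fraction map clips to [0, 1]; region-level results are
  reported unclipped with a gamut flag instead.
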