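# Methods

This note documents the models, algorithms, parameter defaults, and design
choices behind `fibroquant`, and what the synthetic phantoms do and do not
establish about real data.

## MRI lesion volumetry

### Pipeline

Given a 3D lung stack (slice axis first) and per-slice binary lung-border
masks, `segment_lung_injury` runs four stages:

1. **Gaussian lowpass.** Each slice is convolved with an isotropic 2D
   Gaussian (reflect boundary). Default `sigma_px = 1.0`. Filtering is 2D
   per slice because the acquisitions are strongly anisotropic (e.g.
   1.4 mm slices vs 0.156 mm in-plane for the mouse preset); 3D smoothing
   would mix anatomically distant tissue across thick slices.
2. **Adaptive Lloyd–Max quantization** into `n_classes = 4` grey-level
   classes (below).
3. **Highest-class extraction** inside the border mask. In batch mode
   (default) every top-class voxel inside the border is kept — the border
   masks fully replace the interactive seeding of a region grower. With
   explicit seed voxels, only in-plane connected components (8-neighbor
   default, 4-neighbor optional) containing a seed are kept. Growing is 2D
   per slice, consistent with per-slice borders.
4. **Volumetry.** Per-slice areas (pixel count × pixel area) are summed
   and multiplied by the slice thickness; 1 mm³ = 1 µL.

All parameters, the fitted quantizer, and per-slice areas are recorded in
the result; serialization is deterministic (sorted-key JSON), so reruns on
identical inputs are bit-identical.

### Lloyd–Max quantizer

The k-level minimum-MSE scalar quantizer alternates the centroid condition
(each level is the mean of its class) and the nearest-neighbor condition
(each threshold is the midpoint of adjacent levels) until the maximum
level change falls below `tol = 1e-6 ×` intensity range or 200 iterations.
Ties at a threshold go to the lower class. An empty class is reseeded at
the midpoint of its interval; if a class is still empty at convergence, or
fewer than k distinct values exist, the input is rejected as a degenerate
histogram.

**Initialization.** Plain alternation is only locally convergent: started
from equal-mass quantiles it stalls in local minima on a majority of
random multi-modal histograms (measured against an exhaustive-search
oracle). The default `init="optimal"` therefore solves the 1D
optimal-partition problem *exactly* by dynamic programming over the
distinct-value histogram (binned to at most `max_bins = 2048` mass-
preserving bins when finer) and lets the alternation polish the result on
the full data. Because an optimal 1D partition already satisfies both
optimality conditions, the polish converges immediately on discrete data;
on binned continuous data it adapts the DP solution to the unbinned
sample. `init="quantile"` (classical equal-mass start) and explicit level
vectors remain available.

**Fit domain.** The quantizer is fitted once per 3D stack on the filtered
voxels *inside the lung border* (`fit_within_border = True` by default).
An adaptive quantizer should adapt to the intensity distribution of the
tissue it is meant to classify: when extra-thoracic chest-wall tissue
dominates the histogram, the optimal partition spends classes on it, the
upper-mid class centroid moves to chest-wall intensities, and the top
threshold lands well above the lesion edge midpoint — systematically
eroding the blurred margins of lesions (up to −30% volume on heavily
lesioned phantoms). Fitting inside the border keeps the top threshold
near the parenchyma-to-lesion midpoint and removes this bias. Whole-stack
(`fit_within_border = False`) and per-slice (`per_slice_fit = True`)
fitting are retained as configuration options; cross-slice class
consistency is preserved in both default and whole-stack modes because a
single model labels all slices.

### Error characteristics

With additive noise at one fifth of the lesion–parenchyma contrast and
the default σ = 1 filter, seeded mouse-preset phantoms with lesion loads
of 5–150 µL are recovered with a median |relative error| of ≈5% and a
maximum of ≈12%; vessel-only baselines are recovered within ≈6%
(`scripts/acceptance.py` recomputes these). The residual bias is a slight
undercount from partial-volume voxels at blurred lesion margins: the
rasterized truth counts every voxel whose centre lies in the lesion,
whereas the class boundary sits near the blurred edge midpoint. The bias
grows as lesion radius shrinks toward the filter width.

## Synthetic phantoms

`generate_lung_phantom` builds a piecewise-constant scene: dark air
(default intensity 2) outside an elliptical body, chest-wall tissue (60)
inside it, an elliptical dark lung field (20) per slice, bright vessel
tubes running through the slices, and bright lesion blobs (both 100 by
default), plus additive zero-clipped Gaussian noise. With zero noise the
scene has exactly four intensity populations even when vessels and
lesions share an intensity, so a 4-class quantizer isolates the bright
population exactly — the basis of the exact noise-free contract tests.
Truth volumes are exact rasterized voxel counts times the voxel volume;
lesion and vessel voxel sets are disjoint by construction (lesions take
precedence). Default intensities are free parameters chosen for
qualitative UTE-like contrast, not measured values. Vessels default to
two hilar tubes (radii 2.5 and 2.0 px) so that baseline phantoms yield a
nonzero vessel volume, as real baseline lungs do. Lesion placement
supports `dispersed` (homogeneous, oropharyngeal-aspiration-like) and
`central` (peri-airway, intranasal-like) patterns.

The noise model is Gaussian, not Rician: the pipeline under test is
intensity-class-based and insensitive to the noise tail shape at the
contrasts studied; Rician noise is a possible extension. Other real-data
features the phantoms do **not** emulate: radial-acquisition streaking,
motion artifacts, intensity inhomogeneity, partial-volume anatomy at
lobe boundaries, and longitudinal registration error. Passing recovery
tests therefore demonstrates correctness of the quantification chain
under controlled contrast, not robustness to all in-vivo confounds.

Histology phantoms place an exact number of stain-coloured pixels
(`round(fraction × lung pixels)`) in seeded patches without
anti-aliasing, so recovery tests are exact to rounding. CT-table phantoms
shift treated-group target CTs by −log₂(fold) cycles with constant
housekeeping expectation. Cohort phantoms draw (MRI, readouts) per animal
from a single-factor Gaussian model, giving corr(MRI, readout_j) = R_j
exactly in expectation (and exactly at |R| = 1); a full correlation
matrix may be supplied instead and is validated for positive
semi-definiteness.

## Histomorphometry

Stain extraction uses explicit per-channel bounds in RGB or HSV; the
shipped default is an HSV window (hue ∈ [0.88, 1.0], saturation ≥ 0.25,
value ≥ 0.15) for picrosirius red under bright field. Threshold values
are a configuration choice recorded with the output, not a measured
constant. When no lung mask is supplied, the analyzed surface is the
non-background area, background meaning all channels ≥ 240 (near-white
airspace/glass) — whether airspace should count as lung surface is
configurable because conventions differ between laboratories. Any number
of slides per animal is averaged (the count is reported); the picrosirius
factor divides each animal mean by the saline-group mean, making the
saline mean factor exactly 1 and the measure invariant to any global
rescaling of percentages.

## Expression analysis

Technical replicates are averaged on the CT scale before ΔCT, matching
the averaged-CT convention; undetermined or non-positive CT wells are
excluded with a logged warning rather than imputed. The control-group
mean ΔCT is the reference, so the geometric mean of control folds is
exactly 1. Amplification-efficiency correction and multi-reference-gene
normalization are out of scope.

## Statistics

Pearson p-values are two-sided and t-based (t = R√((n−2)/(1−R²)), n−2
df). Correlation reports use pairwise-complete deletion and expose n per
pair, because readouts are routinely measured on subsets of a cohort
(e.g. histology on half the animals). One-way ANOVA is fixed-effects;
pairwise comparisons are pooled-variance t-tests with Bonferroni
adjustment (raw p × number of comparisons, capped at 1), so adjusted
p ≥ raw p always. p-values below 1e−15 are labelled "< 1e-15" rather
than printed as 0. Baseline subtraction reports negative differences
unclipped. Repeated-measures ANOVA for longitudinal time courses is out
of scope.

## Numerical and convention choices

- Slice axis 0, in-plane (row, col), 0-based indexing everywhere.
- Intensities pass through readers unrescaled; the quantizer is adaptive,
  so absolute scale is irrelevant and silent rescaling would break
  reproducibility.
- Quantization tie at a threshold → lower class; region-growing
  connectivity default 8-neighbor in-plane. Both are arbitrary but fixed
  so results are bit-reproducible.
- Problem sizes in the test and acceptance runs (20 phantoms, 100 oracle
  histograms, 200 cohort seeds, 512² slides) were chosen as the smallest
  sizes at which the Monte-Carlo summaries are stable to well within the
  asserted tolerances.

## Known limitations

- The volumetric pipeline reports *total high-intensity signal*, which
  includes vessels; isolating injury requires per-animal baseline
  subtraction (provided in the statistics layer), not vessel
  segmentation.
- Very small lesions (radius approaching the filter σ) are
  systematically undercounted by partial-volume erosion.
- The histology module assumes bright-field colour thresholds;
  polarized-light birefringence analysis and stain deconvolution are not
  implemented.
- Lung borders are inputs; no automatic lung segmentation is attempted.
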