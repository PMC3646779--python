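# fibroquant

Quantification toolkit for preclinical bleomycin-induced lung fibrosis
studies. Experimental fibrosis in mice and rats is followed *in vivo* by
ultrashort-echo-time (UTE) MRI — healthy lung parenchyma is dark, vessels
and fibrotic injury are bright — and confirmed post mortem by
picrosirius-red collagen histology, hydroxyproline content, and qRT-PCR of
fibrosis-associated genes. `fibroquant` implements the complete
quantification chain for such studies as a tested, reproducible library
with a thin command-line interface, plus a synthetic phantom generator
with exact ground truth for validating every stage.

## What it computes

**MRI lesion volumetry** (`fibroquant.mri_seg`). Each slice of a 3D lung
stack is lowpass-filtered with a 2D Gaussian kernel; the filtered
intensities are quantized into k = 4 grey-level classes by an adaptive
Lloyd–Max (minimum-MSE) scalar quantizer with levels ℓ₁<ℓ₂<ℓ₃<ℓ₄ and
thresholds tᵢ satisfying the two optimality conditions

    tᵢ = (ℓᵢ + ℓᵢ₊₁)/2          (nearest-level / midpoint condition)
    ℓᵢ = E[v | tᵢ₋₁ < v ≤ tᵢ]   (centroid condition)

The highest class is extracted inside per-slice lung-border masks (the
automated equivalent of an interactively seeded region grower constrained
by manually drawn borders), per-slice areas are converted with the
acquisition geometry (pixel area = (FOV/matrix)²), and the total
high-intensity-signal volume is

    V [µL] = ( Σ_slices area_mm² ) × slice thickness_mm.

Shipped geometry presets: `mouse47t` (192×192, FOV 3.0×3.0 cm, 1.4 mm
slices, 10 slices; voxel = 0.0341796875 µL) and `rat47t` (192×192,
FOV 6.0×6.0 cm, 2.0 mm slices, 18 slices; voxel = 0.1953125 µL).

**Histomorphometry** (`fibroquant.histo_quant`). Picrosirius-red-stained
area is extracted by explicit colour thresholds, expressed as percent of
the lung surface analyzed, averaged over an animal's slides, and reported
as the *picrosirius factor* — the animal mean divided by the saline-group
mean (saline mean factor ≡ 1).

**Relative expression** (`fibroquant.expression`). The 2^−ΔΔCT method:
ΔCT = CT(gene) − CT(housekeeping) per sample (replicates averaged on the
CT scale), ΔΔCT = ΔCT − mean control-group ΔCT, fold = 2^−ΔΔCT.

**Cross-readout statistics** (`fibroquant.stats_report`). Pearson
correlations of MRI volume against each post-mortem readout with
pairwise-complete n reported per pair, one-way ANOVA with
Bonferroni-adjusted pairwise t-tests, and per-animal baseline subtraction
of longitudinal MRI volumes (baseline signal contains vessels).

**Phantoms** (`fibroquant.phantom`). Seeded generators for UTE-like lung
stacks (dark parenchyma, bright vessels and lesions, exact rasterized
volumes), stained slides with exact stained-pixel counts, CT tables with
programmed folds, and jointly Gaussian animal cohorts with programmed
correlations.

## Worked example

```python
import fibroquant as fq

g = fq.get_preset("mouse47t")
spec = fq.PhantomSpec(geometry=g,
                      vessels=fq.default_vessels(g),
                      lesions=fq.dispersed_lesions(g, 60.0, seed=7),
                      noise_sigma=16.0, seed=7)
stack, border, truth = fq.generate_lung_phantom(spec)
result = fq.segment_lung_injury(stack, border)
print(f"ground-truth signal volume: "
      f"{truth.lesion_volume_ul + truth.vessel_volume_ul:.2f} uL "
      f"(lesions {truth.lesion_volume_ul:.2f} + "
      f"vessels {truth.vessel_volume_ul:.2f})")
print(f"segmented signal volume:    {result.total_volume_ul:.2f} uL")
print("quantizer levels:", [round(l, 1) for l in result.quantizer.levels])
```

prints

```
ground-truth signal volume: 68.74 uL (lesions 57.46 + vessels 11.28)
segmented signal volume:    66.00 uL
quantizer levels: [17.5, 23.8, 34.4, 88.1]
```

The phantom carries ~57 µL of lesions plus ~11 µL of vessels at 5×-noise
contrast; the pipeline recovers the combined high-intensity volume within
4%. The four fitted levels track the parenchyma (≈18–24), intermediate
partial-volume intensities (≈34), and the bright vessel/lesion population
(≈88). A correlated 32-animal cohort then reproduces a Table-1-style
report:

```python
cohort = fq.generate_cohort(32, correlation=0.9, seed=7,
                            readouts=["picrosirius_factor",
                                      "hydroxyproline_ug"])
print(fq.correlation_report(cohort).to_string(index=False))
```

```
           readout  n        r            p  p_label
picrosirius_factor 32 0.874241 6.302087e-11  6.3e-11
 hydroxyproline_ug 32 0.864582 1.787978e-10 1.79e-10
```

The same operations are available from the shell:

```sh
fibroquant simulate --preset mouse47t --lesion-volume-ul 60 --seed 7 --out ph/
fibroquant segment-mri --stack ph/stack.nii.gz --mask ph/mask --out result.json
fibroquant ddct --ct ct.csv --housekeeping HPRT --control-group Saline --out folds.csv
fibroquant correlate --cohort cohort.csv --out table.csv
```

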