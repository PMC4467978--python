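# ctneoquant

Quantitative analysis of stained neo-tissue in contrast-enhanced
nanofocus CT (CE-nanoCT) scans of tissue-engineering constructs.

## The problem

Neo-tissue — cells plus the extracellular matrix they deposit in vitro —
attenuates X-rays barely more than the culture medium around it, so it is
invisible in absorption-mode CT. Soaking a construct in an X-ray-opaque
contrast agent (an equilibrium agent such as an ioxaglate solution, or
phosphotungstic acid, which binds connective-tissue components) makes the
tissue visible, but the staining conditions now determine whether the scan
is *quantifiable*: too little contrast and the tissue cannot be separated
from scaffold-induced streaks and beam-hardening bias; a binding stain can
also physically shrink the tissue it is supposed to measure.

`ctneoquant` implements the read-outs needed to screen staining conditions
and to run the resulting morphometry, for researchers doing scaffold-based
tissue engineering with desktop micro/nanoCT:

1. **Normalized image contrast.** Along a line profile crossing background,
   neo-tissue and scaffold in one transaxial slice, with plateau means
   (transition values excluded), the contrast is

   ```
   normalized contrast = B / (A + B)
   ```

   where `A` is the scaffold-to-tissue and `B` the tissue-to-background
   mean greyscale difference; `A + B` is the full dynamic range, so the
   statistic is invariant to affine greyscale rescaling.

2. **Dataset quality.** Each transaxial slice is segmented with per-slice
   multi-level Otsu thresholding (maximizing the between-class variance
   `sum_k w_k (mu_k − mu)^2`), the tissue classes are binarized, and a
   voxelwise differential overlay against the reference (stained) tissue
   mask scores each slice's mismatched area. Slices with a mismatch below
   1% of the slice surface are attributed to background noise and excluded;
   the quality read-out is the fraction of flagged slices. The number of
   Otsu levels per contrast agent is chosen as the fewest levels within one
   standard error of the minimal mismatched-slice fraction.

3. **Tissue integrity.** After rigid 3D registration of the two stain
   conditions of the same construct, the binarized tissue is cleaned
   (scaffold dilated by 2 voxels and subtracted; speckles under 200 voxels
   removed; 2-voxel closing) and the degree of stain-induced shrinkage is

   ```
   degree of shrinkage = (SA_first − SA_second) / SA_first
   ```

   from cross-sectional areas on three analysis slices distributed over the
   construct height. Local tissue thickness (largest inscribed disc/sphere)
   is computed per slice and in 3D.

4. **Design of experiments.** Staining time, concentration and neo-tissue
   volume are screened with a 9-run, 3-level, 3-factor fractional factorial
   design (a Graeco-Latin square, orthogonal in every factor pair). Main
   effects come from OLS on coded levels; the standardized effect
   `|coefficient| / SE` is ranked in a Pareto chart against the two-sided
   t critical value at p = 0.05.

Because no scan data of this kind is publicly deposited, the package ships
a first-class synthetic-data module: cylindrical constructs with a strut
lattice, a neo-tissue shell of controllable (sub-voxel) thickness,
partial-volume blur, noise, streak rays and radial bias, plus an
erosion-based shrinkage transform — all with ground-truth masks, so every
stage is testable end to end.

## Worked example

Run the full synthetic staining study — 9 conditions × 3 replicates, three
read-outs per condition, effects per read-out:

```python
from ctneoquant.phantom import PhantomSpec
from ctneoquant.pipeline import RunConfig, run_staining_evaluation

cfg = RunConfig(seed=5, base_phantom=PhantomSpec(
    shape=(48, 48, 48), psf_sigma_vox=0.5, noise_sigma=3.0,
    streak_amplitude=45.0, bias_amplitude=10.0))
report = run_staining_evaluation(cfg)
print(report.table.groupby("concentration_pct")[
    ["normalized_contrast", "mismatched_slice_fraction",
     "degree_of_shrinkage"]].mean().round(3))
for row in report.pareto["normalized_contrast"]:
    print(f"{row['factor']:>20s}  |t| = {row['standardized_effect']:6.2f}  "
          f"significant: {row['significant']}")
```

prints

```
                   normalized_contrast  mismatched_slice_fraction  degree_of_shrinkage
concentration_pct
20                               0.211                      0.993                0.130
40                               0.358                      0.248                0.227
60                               0.504                      0.118                0.325

   concentration_pct  |t| =  26.74  significant: True
   neo_tissue_volume  |t| =   0.62  significant: False
   staining_time_min  |t| =   0.29  significant: False
```

Reading the numbers: contrast rises with concentration (0.21 → 0.50: at the
highest concentration the stained tissue sits halfway between background
and scaffold greyscale); the mismatched-slice fraction collapses from 99%
to 12% as the tissue separates from the streak artifacts; and the shrinkage
induced by the binding stain grows with concentration. In the Pareto
ranking only concentration crosses the p = 0.05 reference line (|t| = 2.07
at 23 residual degrees of freedom) — staining time has no effect, matching
how the conditions were wired into the generator.

The same stages are available from the shell:

```bash
ctneoquant phantom  --config spec.yaml --out ph/
ctneoquant segment  --stack ph/volume.tif --levels 3 --out neo.tif
ctneoquant quality  --reference ph/neo_mask.tif --binarized neo.tif
ctneoquant morph    --neo neo.tif --scaffold ph/scaffold_mask.tif --out clean.tif
ctneoquant contrast --stack ph/volume.tif --line "16,23.5,9,23.5,26"
ctneoquant run-all  --seed 5 --out study/
```

The `contrast` call on the phantom above prints `"normalized_contrast":
0.5075…` — the generating greyscale means (20/120/220) give exactly 0.5,
recovered here through blur and noise.

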