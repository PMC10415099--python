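# adcseg

Automated delineation of acute ischemic stroke lesions on diffusion-weighted
MRI (DWI) by apparent-diffusion-coefficient (ADC) thresholding, together with
the analysis battery needed to characterize how well fixed ADC thresholds
work: voxelwise ROC threshold discovery, Dice overlap, Bland–Altman
volumetric agreement, and standardized-coefficient regression of performance
on lesion and tissue factors. A seeded synthetic diffusion-phantom generator
makes the whole pipeline testable end to end without patient data.

## Who this is for

Stroke-imaging researchers who want a transparent, fully scripted
counterpart to the ADC-threshold segmentation used in commercial DWI
software (fixed band ADC ≤ 620 × 10⁻⁶ mm²/s), and who need to quantify when
and why such thresholds succeed or fail — rather than a clinical tool.
Inputs are co-registered, brain-extracted NIfTI volumes: a b0 image, a
trace image (b = 1000 s/mm²), an ADC map in 10⁻⁶ mm²/s, and a brain mask on
one common grid (registration and brain extraction happen upstream).

## The algorithm

For each case the segmentation pipeline computes

1. **ratio image** `trace / ADC` inside the brain — infarcts are
   trace-hyperintense and ADC-hypointense, so the ratio amplifies contrast;
2. **slice normalization** — every axial slice is divided by its in-brain
   mean, making values comparable across slices and subjects;
3. **Gaussian smoothing** with an isotropic 5-voxel (FWHM) kernel;
4. **mirror subtraction** `max(0, I − flip(I))` about the mid-sagittal
   plane — symmetric background cancels, unilateral pathology survives;
5. **intensity threshold** at 0.75 on the processed image, followed by one
   iteration of 6-connected dilation, restricted to the brain (the
   *primary mask*);
6. **ADC band gate**: keep voxels with 200 ≤ ADC ≤ 620 × 10⁻⁶ mm²/s;
7. **trace-percentile cleanup**: drop voxels whose trace intensity falls
   below the 95th percentile of the parenchymal trace distribution.

Threshold discovery treats `ADC ≤ t` as the classifier, sweeps t over an
integer grid (default 0…1500 × 10⁻⁶ mm²/s), and selects the operating point
by the Youden index J = sensitivity + specificity − 1, per subject and
pooled over a cohort (counts summed before rates). Agreement between
automated and reference volumes is summarized by the Bland–Altman bias and
±1.96 SD limits and by Pearson correlation; standardized-coefficient OLS
relates Dice and Youden performance to lesion volume, lesion ADC and
parenchymal ADC.

## Worked example

```python
from adcseg import PhantomSpec, generate_case, delineate, dice, lesion_summary, roc_sweep
from adcseg.segmentation import SegmentationConfig, parenchyma_mask
from adcseg.volume_io import BinaryMask

case = generate_case(PhantomSpec(seed=1))          # 2 mm phantom, ~5 mL lesion
result = delineate(case.b0, case.trace, case.adc, case.brain_mask)
print(f"truth lesion volume:      {case.truth_lesion.volume_ml:.2f} mL")
print(f"automated lesion volume:  {result.lesion_mask.volume_ml:.2f} mL")
print(f"Dice overlap:             {dice(result.lesion_mask, case.truth_lesion):.3f}")
s = lesion_summary(result.lesion_mask, case.adc)
print(f"automated median ADC:     {s.median_adc:.0f} x 1e-6 mm^2/s")

parenchyma = parenchyma_mask(case.adc, case.brain_mask, SegmentationConfig())
truth = BinaryMask(case.truth_lesion.data & parenchyma.data, case.truth_lesion.spacing)
roc = roc_sweep(case.adc, truth, parenchyma)
print(f"optimal ADC threshold:    {roc.optimal_threshold:.0f} x 1e-6 mm^2/s "
      f"(Youden {roc.optimal_youden:.3f}, AUC {roc.auc:.3f})")
```

prints

```
truth lesion volume:      4.81 mL
automated lesion volume:  4.24 mL
Dice overlap:             0.937
automated median ADC:     494 x 1e-6 mm^2/s
optimal ADC threshold:    667 x 1e-6 mm^2/s (Youden 0.999, AUC 1.000)
```

The automated mask recovers most of the ~5 mL lesion (Dice 0.94); its
median ADC sits below the 620 gate by construction, and the per-subject
optimal threshold lands between the lesion (≈500) and parenchyma (≈850)
ADC distributions, near their equal-density point. On this clean phantom
the separation is nearly perfect (AUC ≈ 1); real patient data, with partial
volume, artifacts and heterogeneous lesions, separates far less cleanly.

## Command line

```bash
adcseg simulate --n 20 --seed 1 --out cohort/              # phantom cohort + manifest
adcseg delineate --b0 b0.nii.gz --trace trace.nii.gz \
       --adc adc.nii.gz --brain-mask brain.nii.gz --out lesion.nii.gz
adcseg roc --adc adc.nii.gz --truth truth.nii.gz \
       --parenchyma parenchyma.nii.gz --out roc.csv        # + roc.json summary
adcseg roc-pool case*_roc.csv --out pooled.json
adcseg evaluate --pred lesion.nii.gz --truth truth.nii.gz --adc adc.nii.gz
adcseg cohort-stats --cases run/cases.csv --out stats/
adcseg run-all --out run/ --seed 1                         # everything end to end
```

`run-all` accepts a TOML config mirroring every pipeline tunable, records
the resolved config in its output directory, and is deterministic under a
fixed seed (reruns are byte-identical).

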