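"""Automated ADC-threshold delineation of acute DWI stroke lesions.

The algorithm enhances lesion contrast by dividing the trace image by the
ADC map, normalizes each axial slice by its in-brain mean, smooths with an
isotropic Gaussian, and suppresses symmetric background by subtracting the
left-right mirrored image. Thresholding the processed image at a fixed
intensity, dilating, and gating to the fixed acute-infarct ADC band
200-620 x 1e-6 mm^2/s yields the lesion mask; scattered trace-hypointense
voxels are removed with a parenchymal trace-percentile cutoff.

All inputs must already be brain-extracted and co-registered on one grid
with the mid-sagittal plane aligned to the configured mirror axis (e.g.
images in a standard 2 mm space, or phantoms from :mod:`adcseg.phantom`).
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume_io import (
    ADC_UNITS,
    INTENSITY,
    BinaryMask,
    ImageVolume,
    check_same_grid,
)

log = logging.getLogger(__name__)

#: FWHM of a unit-variance Gaussian: 2 sqrt(2 ln 2)
_FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))

#: face-adjacent (6-connected) structuring element
_STRUCT6 = ndimage.generate_binary_structure(3, 1)


@dataclass
class SegmentationConfig:
    """Tunables of the delineation pipeline.

    Attributes
    ----------
    smoothing_fwhm_vox
        Full width at half maximum of the isotropic Gaussian, in voxels.
    intensity_threshold
        Lower cut (inclusive) on the mirror-subtracted processed image.
    dilation_iterations
        Iterations of 6-connected binary dilation of the thresholded mask,
        restricted to the brain.
    adc_lower, adc_upper
        Inclusive acute-infarct ADC band in 1e-6 mm^2/s.
    trace_percentile
        Percentile of the parenchymal trace distribution; mask voxels with
        trace strictly below it are discarded.
    csf_adc_cutoff
        ADC (1e-6 mm^2/s) above which a brain voxel is treated as CSF when
        building the parenchyma mask.
    mirror_axis
        Array axis of the left-right direction (mirror plane).
    slice_axis
        Array axis perpendicular to the (axial) normalization slices,
        i.e. the inferior-superior direction.
    percentile_population
        Population over which the trace percentile is computed:
        ``"parenchyma"`` (default) or ``"mask"`` (the candidate mask itself).
    """

    smoothing_fwhm_vox: float = 5.0
    intensity_threshold: float = 0.75
    dilation_iterations: int = 1
    adc_lower: float = 200.0
    adc_upper: float = 620.0
    trace_percentile: float = 95.0
    csf_adc_cutoff: float = 2000.0
    mirror_axis: int = 0
    slice_axis: int = 2
    percentile_population: str = "parenchyma"

    def __post_init__(self) -> None:
        if not 0 <= self.adc_lower < self.adc_upper:
            raise ValueError(
                f"require 0 <= adc_lower < adc_upper, got [{self.adc_lower}, {self.adc_upper}]"
            )
        if not 0 <= self.trace_percentile < 100:
            raise ValueError(f"trace_percentile must be in [0, 100), got {self.trace_percentile}")
        if self.dilation_iterations < 0:
            raise ValueError("dilation_iterations must be >= 0")
        if self.smoothing_fwhm_vox <= 0:
            raise ValueError("smoothing_fwhm_vox must be > 0")
        if self.percentile_population not in ("parenchyma", "mask"):
            raise ValueError(
                f"percentile_population must be 'parenchyma' or 'mask', got {self.percentile_population!r}"
            )


@dataclass
class SegmentationResult:
    """Output of :func:`delineate`.

    ``stage_log`` records the surviving voxel count after each mask-forming
    stage, in pipeline order.
    """

    lesion_mask: BinaryMask
    primary_mask: BinaryMask
    processed_image: ImageVolume
    stage_log: list[tuple[str, int]]


def ratio_image(trace: ImageVolume, adc: ImageVolume, brain: BinaryMask) -> ImageVolume:
    """trace / ADC inside the brain; 0 where ADC <= 0 or outside the brain.

    Acute infarcts are trace-hyperintense and ADC-hypointense, so the ratio
    amplifies lesion-to-background contrast.
    """
    check_same_grid(trace, adc, brain)
    if not brain.data.any():
        raise ValueError("brain mask is empty")
    out = np.zeros(trace.shape, dtype=np.float64)
    valid = brain.data & (adc.data > 0)
    out[valid] = trace.data[valid] / adc.data[valid]
    return ImageVolume(out, trace.spacing, INTENSITY)


def slice_normalize(img: ImageVolume, brain: BinaryMask, slice_axis: int = 2) -> ImageVolume:
    """Divide every in-brain voxel by the in-brain mean of its slice.

    Slices are taken perpendicular to ``slice_axis``. Slices without brain
    voxels (or with zero mean) are left at 0.
    """
    check_same_grid(img, brain)
    out = np.zeros_like(img.data)
    n = img.shape[slice_axis]
    for k in range(n):
        sl = [slice(None)] * 3
        sl[slice_axis] = k
        sl = tuple(sl)
        m = brain.data[sl]
        if not m.any():
            continue
        mean = img.data[sl][m].mean()
        if mean == 0:
            continue
        plane = np.zeros_like(img.data[sl])
        plane[m] = img.data[sl][m] / mean
        out[sl] = plane
    return ImageVolume(out, img.spacing, img.units)


def gaussian_smooth(img: ImageVolume, fwhm_vox: float) -> ImageVolume:
    """Isotropic Gaussian smoothing with sigma = fwhm / (2 sqrt(2 ln 2)) voxels.

    Constant-zero boundary handling; the kernel is truncated at 6 sigma so
    repeated smoothing composes to numerical precision.
    """
    if fwhm_vox <= 0:
        raise ValueError("fwhm_vox must be > 0")
    sigma = fwhm_vox / _FWHM_PER_SIGMA
    out = ndimage.gaussian_filter(img.data, sigma=sigma, mode="constant", cval=0.0, truncate=6.0)
    return ImageVolume(out, img.spacing, img.units)


def mirror_subtract(img: ImageVolume, mirror_axis: int = 0) -> ImageVolume:
    """max(0, img - flip(img, mirror_axis)).

    Mirror-symmetric structure cancels exactly; unilateral hyperintensity
    survives on its own side. Negative differences are clipped because only
    ipsilateral hyperintensity is meaningful for infarct detection.
    """
    flipped = np.flip(img.data, axis=mirror_axis)
    return ImageVolume(np.maximum(img.data - flipped, 0.0), img.spacing, img.units)


def primary_mask(
    processed: ImageVolume, brain: BinaryMask, config: SegmentationConfig
) -> BinaryMask:
    """Threshold the processed image (inclusive), dilate, intersect with brain."""
    check_same_grid(processed, brain)
    mask = processed.data >= config.intensity_threshold
    if config.dilation_iterations > 0:
        mask = ndimage.binary_dilation(
            mask, structure=_STRUCT6, iterations=config.dilation_iterations
        )
    return BinaryMask(mask & brain.data, processed.spacing)


def adc_gate(mask: BinaryMask, adc: ImageVolume, config: SegmentationConfig) -> BinaryMask:
    """Keep mask voxels with adc_lower <= ADC <= adc_upper (both inclusive)."""
    check_same_grid(mask, adc)
    keep = (adc.data >= config.adc_lower) & (adc.data <= config.adc_upper)
    return BinaryMask(mask.data & keep, mask.spacing)


def trace_percentile_cleanup(
    mask: BinaryMask,
    trace: ImageVolume,
    brain_parenchyma: BinaryMask,
    config: SegmentationConfig,
) -> BinaryMask:
    """Drop mask voxels whose trace is strictly below the parenchymal percentile.

    The cutoff is the ``trace_percentile``-th percentile (linear
    interpolation between order statistics) of trace intensities over
    ``brain_parenchyma``. This removes scattered trace-hypointense voxels
    that pass the ADC gate without being lesion.
    """
    check_same_grid(mask, trace, brain_parenchyma)
    if not brain_parenchyma.data.any():
        raise ValueError("percentile reference population is empty")
    cutoff = float(np.percentile(trace.data[brain_parenchyma.data], config.trace_percentile))
    keep = trace.data >= cutoff
    return BinaryMask(mask.data & keep, mask.spacing)


def parenchyma_mask(
    adc: ImageVolume, brain: BinaryMask, config: SegmentationConfig
) -> BinaryMask:
    """Brain voxels with ADC below the CSF cutoff.

    An ADC rule stands in for tissue segmentation: free water diffuses at
    roughly 3000 x 1e-6 mm^2/s, far above parenchyma, so a cutoff near
    2000 excludes CSF robustly.
    """
    check_same_grid(adc, brain)
    out = BinaryMask(brain.data & (adc.data < config.csf_adc_cutoff), adc.spacing)
    if not out.data.any():
        warnings.warn("parenchyma mask is empty (csf_adc_cutoff too low?)", stacklevel=2)
    return out


def delineate(
    b0: ImageVolume,
    trace: ImageVolume,
    adc: ImageVolume,
    brain: BinaryMask,
    config: SegmentationConfig | None = None,
) -> SegmentationResult:
    """Run the full delineation pipeline on one case.

    Stages: ratio image -> slice normalization -> Gaussian smoothing ->
    mirror subtraction -> intensity threshold + dilation (primary mask) ->
    ADC band gate -> trace percentile cleanup. The final mask may be empty
    (no infarct detected). ``b0`` is accepted and grid-checked for
    interface completeness; the processing itself uses only trace and ADC.
    """
    if config is None:
        config = SegmentationConfig()
    check_same_grid(b0, trace, adc, brain)

    ratio = ratio_image(trace, adc, brain)
    normalized = slice_normalize(ratio, brain, config.slice_axis)
    smoothed = gaussian_smooth(normalized, config.smoothing_fwhm_vox)
    processed = mirror_subtract(smoothed, config.mirror_axis)

    stage_log: list[tuple[str, int]] = []
    thresholded = processed.data >= config.intensity_threshold
    stage_log.append(("threshold", int(thresholded.sum())))

    primary = primary_mask(processed, brain, config)
    stage_log.append(("primary_mask", primary.voxel_count))

    gated = adc_gate(primary, adc, config)
    stage_log.append(("adc_gate", gated.voxel_count))

    parenchyma = parenchyma_mask(adc, brain, config)
    population = parenchyma if config.percentile_population == "parenchyma" else gated
    if population.data.any():
        final = trace_percentile_cleanup(gated, trace, population, config)
    else:
        warnings.warn("skipping trace cleanup: empty percentile population", stacklevel=2)
        final = gated
    stage_log.append(("trace_cleanup", final.voxel_count))

    log.info("delineation stages: %s", stage_log)
    return SegmentationResult(
        lesion_mask=final,
        primary_mask=primary,
        processed_image=processed,
        stage_log=stage_log,
    )
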