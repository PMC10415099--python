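"""NIfTI image/mask containers and grid bookkeeping.

All volumes in one analysis live on a single co-registered grid (the
upstream pipeline registers everything to a common 2 mm space before this
package sees it); grid compatibility is checked, resampling is out of scope.
ADC maps are carried in units of 10^-6 mm^2/s throughout.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

log = logging.getLogger(__name__)

#: units tag for diffusion-weighted / b0 intensity images (arbitrary units)
INTENSITY = "intensity"
#: units tag for ADC maps in 10^-6 mm^2/s
ADC_UNITS = "adc_1e-6_mm2_per_s"

_VALID_UNITS = (INTENSITY, ADC_UNITS)


class GridMismatchError(ValueError):
    """Two volumes/masks do not share shape and voxel spacing."""


class VolumeFormatError(ValueError):
    """A file on disk is not a readable 3-D scalar volume."""


@dataclass
class ImageVolume:
    """A 3-D scalar lattice with voxel spacing and a units tag.

    Parameters
    ----------
    data
        3-D float array.
    spacing
        Voxel edge lengths in mm, one per axis; all strictly positive.
    units
        Either ``"intensity"`` (b0/trace, arbitrary units) or
        ``"adc_1e-6_mm2_per_s"`` (ADC map). ADC-tagged volumes must be
        finite and non-negative.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    units: str = INTENSITY

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise VolumeFormatError(
                f"expected 3-D data, got {self.data.ndim}-D"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive lengths, got {self.spacing}")
        if self.units not in _VALID_UNITS:
            raise ValueError(f"unknown units tag {self.units!r}")
        if np.isnan(self.data).any():
            raise ValueError("volume contains NaN; load through load_volume")
        if self.units == ADC_UNITS:
            if not np.isfinite(self.data).all() or (self.data < 0).any():
                raise ValueError("ADC volume must be finite and non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class BinaryMask:
    """A 3-D boolean lattice on the same grid as the volumes it annotates."""

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise VolumeFormatError(f"expected 3-D mask, got {self.data.ndim}-D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive lengths, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    @property
    def volume_ml(self) -> float:
        return mask_volume_ml(self)


def check_same_grid(*objs: ImageVolume | BinaryMask) -> None:
    """Raise :class:`GridMismatchError` unless all arguments share shape and spacing."""
    if not objs:
        return
    ref = objs[0]
    for other in objs[1:]:
        if other.shape != ref.shape:
            raise GridMismatchError(f"shape mismatch: {ref.shape} vs {other.shape}")
        if not np.allclose(other.spacing, ref.spacing, rtol=0, atol=1e-6):
            raise GridMismatchError(
                f"spacing mismatch: {ref.spacing} vs {other.spacing}"
            )


def _read_nifti(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise VolumeFormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj).astype(np.float64)
    # 4-D files with a singleton trailing dimension are common exports
    while data.ndim == 4 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise VolumeFormatError(
            f"{path}: expected a 3-D volume, got shape {data.shape}"
        )
    zooms = img.header.get_zooms()[:3]
    return data, tuple(float(z) for z in zooms)


def load_volume(path, expected_units: str = INTENSITY) -> ImageVolume:
    """Load a 3-D NIfTI volume.

    NaN voxels (typical at brain-extraction borders of derived maps) are
    replaced by 0 and counted in the log. When ``expected_units`` is the ADC
    tag and the 99th percentile of positive voxels is below 10, the file is
    assumed to store mm^2/s and is rescaled by 1e6 (the two dialects differ
    by six orders of magnitude, so any cutoff between ~1 and ~100 is safe).
    Negative ADC voxels are clipped to 0.
    """
    if expected_units not in _VALID_UNITS:
        raise ValueError(f"unknown units tag {expected_units!r}")
    data, spacing = _read_nifti(path)
    n_nan = int(np.isnan(data).sum())
    if n_nan:
        log.warning("%s: replaced %d NaN voxels with 0", path, n_nan)
        data = np.nan_to_num(data, nan=0.0)
    if expected_units == ADC_UNITS:
        positive = data[data > 0]
        if positive.size and np.percentile(positive, 99) < 10:
            log.info("%s: ADC stored in mm^2/s, rescaling by 1e6", path)
            data = data * 1e6
        n_neg = int((data < 0).sum())
        if n_neg:
            log.warning("%s: clipped %d negative ADC voxels to 0", path, n_neg)
            data = np.maximum(data, 0.0)
    return ImageVolume(data=data, spacing=spacing, units=expected_units)


def load_mask(path) -> BinaryMask:
    """Load a binary mask (any nonzero voxel is True)."""
    data, spacing = _read_nifti(path)
    data = np.nan_to_num(data, nan=0.0)
    return BinaryMask(data=data != 0, spacing=spacing)


def _affine(spacing: tuple[float, float, float]) -> np.ndarray:
    return np.diag(list(spacing) + [1.0])


def save_volume(volume: ImageVolume, path) -> None:
    """Write a volume as NIfTI-1 (float64, diagonal affine from spacing)."""
    img = nib.Nifti1Image(volume.data.astype(np.float64), _affine(volume.spacing))
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def save_mask(mask: BinaryMask, path) -> None:
    """Write a mask as NIfTI-1 uint8 with values {0, 1}."""
    img = nib.Nifti1Image(mask.data.astype(np.uint8), _affine(mask.spacing))
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


def mask_volume_ml(mask: BinaryMask) -> float:
    """Mask volume in millilitres: voxel count x voxel volume (mm^3) / 1000."""
    return mask.voxel_count * float(np.prod(mask.spacing)) / 1000.0
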