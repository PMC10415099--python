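"""Synthetic diffusion-MRI phantoms with ground-truth stroke lesions.

The phantom emulates the statistical structure the delineation algorithm
relies on, not anatomy: an ellipsoidal brain that is mirror-symmetric about
the mid-sagittal plane, symmetric ventricle-like CSF blobs, and a single
(optionally multi-focal) ischemic lesion in one hemisphere whose ADC sits
well below parenchymal ADC. The diffusion signal follows the
mono-exponential decay law

    trace = b0 * exp(-b * ADC * 1e-6)

with b in s/mm^2 and ADC in 1e-6 mm^2/s, plus additive Gaussian noise on b0
and trace. Background ADC texture is drawn on one hemisphere and mirrored,
so with ``noise_sd = 0`` everything outside the lesion is exactly symmetric
under a flip of the left-right axis (axis 0); the mirror plane sits exactly
between the two central voxel columns for even grids.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .volume_io import ADC_UNITS, INTENSITY, BinaryMask, ImageVolume


class PhantomSpecError(ValueError):
    """Phantom geometry or parameters are inconsistent."""


@dataclass
class PhantomSpec:
    """Everything needed to generate one phantom case deterministically.

    ADC parameters are in 1e-6 mm^2/s. Defaults describe a moderately noisy
    acute-stroke case: lesion ADC ~ N(500, 60), parenchyma ~ N(850, 60),
    free-water CSF near 3000, b = 1000 s/mm^2 on a 2 mm isotropic grid.
    ``lesion_radii_vox = None`` produces a lesion-free (fully symmetric)
    phantom.
    """

    grid_shape: tuple[int, int, int] = (64, 76, 64)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    s0_mean: float = 1000.0
    parenchyma_adc_mean: float = 850.0
    parenchyma_adc_sd: float = 60.0
    lesion_adc_mean: float = 500.0
    lesion_adc_sd: float = 60.0
    csf_adc_mean: float = 3000.0
    lesion_center_vox: tuple[float, float, float] | None = None
    lesion_radii_vox: tuple[float, float, float] | None = (5.0, 5.8, 5.0)
    b_value: float = 1000.0
    noise_sd: float = 20.0
    seed: int = 0
    #: number of lesion foci; >1 splits the lesion into scattered blobs
    n_foci: int = 1
    #: brain ellipsoid semi-axes in voxels; None -> 0.42 * grid_shape
    brain_radii_vox: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if any(int(n) <= 0 for n in self.grid_shape):
            raise PhantomSpecError(f"grid_shape must be positive, got {self.grid_shape}")
        if any(s <= 0 for s in self.spacing_mm):
            raise PhantomSpecError(f"spacing_mm must be positive, got {self.spacing_mm}")
        if self.lesion_radii_vox is not None:
            if not (self.lesion_adc_mean < self.parenchyma_adc_mean < self.csf_adc_mean):
                raise PhantomSpecError(
                    "require lesion_adc_mean < parenchyma_adc_mean < csf_adc_mean, got "
                    f"{self.lesion_adc_mean}, {self.parenchyma_adc_mean}, {self.csf_adc_mean}"
                )
        if self.n_foci < 1:
            raise PhantomSpecError("n_foci must be >= 1")

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing_mm)) / 1000.0

    def brain_semiaxes(self) -> np.ndarray:
        if self.brain_radii_vox is not None:
            return np.asarray(self.brain_radii_vox, dtype=float)
        return 0.42 * np.asarray(self.grid_shape, dtype=float)

    def grid_center(self) -> np.ndarray:
        # (N-1)/2 on every axis: invariant under np.flip on any axis
        return (np.asarray(self.grid_shape, dtype=float) - 1.0) / 2.0


@dataclass
class PhantomCase:
    """One generated case: images, masks and the spec that produced them."""

    b0: ImageVolume
    trace: ImageVolume
    adc: ImageVolume
    brain_mask: BinaryMask
    truth_lesion: BinaryMask
    spec: PhantomSpec


def _ellipsoid_mask(shape, center, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    r = np.zeros(shape, dtype=float)
    for g, c, a in zip(grids, center, radii):
        r = r + ((g - c) / a) ** 2
    return r <= 1.0


def _mirror_symmetric_normal(rng: np.random.Generator, shape) -> np.ndarray:
    """Standard-normal field exactly symmetric under np.flip along axis 0."""
    n0 = shape[0]
    half = (n0 + 1) // 2
    draw = rng.standard_normal((half,) + tuple(shape[1:]))
    out = np.empty(shape, dtype=float)
    out[:half] = draw
    out[n0 - half:] = draw[::-1]
    return out


def _csf_mask(spec: PhantomSpec) -> np.ndarray:
    """Two ventricle-like ellipsoids mirrored about the mid-sagittal plane."""
    c = spec.grid_center()
    br = spec.brain_semiaxes()
    radii = (0.12 * br[0], 0.33 * br[1], 0.18 * br[2])
    offset = np.array([0.24 * br[0], 0.0, 0.08 * br[2]])
    left = _ellipsoid_mask(spec.grid_shape, c - offset * [1, 0, 0] + offset * [0, 1, 1], radii)
    right = _ellipsoid_mask(spec.grid_shape, c + offset, radii)
    return left | right


def _lesion_mask(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Lesion compartment: one ellipsoid, or n_foci scattered blobs."""
    shape = spec.grid_shape
    c = spec.grid_center()
    br = spec.brain_semiaxes()
    if spec.lesion_center_vox is not None:
        center = np.asarray(spec.lesion_center_vox, dtype=float)
    else:
        center = c + np.array([0.5 * br[0], 0.1 * br[1], 0.05 * br[2]])
    radii = np.asarray(spec.lesion_radii_vox, dtype=float)
    if spec.n_foci == 1:
        return _ellipsoid_mask(shape, center, radii)
    # split total volume across foci scattered around the main centre
    focus_radii = radii / spec.n_foci ** (1 / 3)
    mask = np.zeros(shape, dtype=bool)
    for _ in range(spec.n_foci):
        jitter = rng.uniform(-1.0, 1.0, size=3) * radii * 1.5
        mask |= _ellipsoid_mask(shape, center + jitter, focus_radii)
    return mask


def generate_case(spec: PhantomSpec) -> PhantomCase:
    """Generate one phantom case; identical spec + seed gives identical output."""
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(n) for n in spec.grid_shape)
    spacing = tuple(float(s) for s in spec.spacing_mm)

    brain = _ellipsoid_mask(shape, spec.grid_center(), spec.brain_semiaxes())
    csf = _csf_mask(spec) & brain

    # symmetric ADC texture: one field drawn on a hemisphere and mirrored
    texture = _mirror_symmetric_normal(rng, shape)
    adc = spec.parenchyma_adc_mean + spec.parenchyma_adc_sd * texture
    adc[csf] = spec.csf_adc_mean + spec.parenchyma_adc_sd * texture[csf]

    if spec.lesion_radii_vox is not None:
        lesion = _lesion_mask(spec, rng) & brain
        interior = ndimage.binary_erosion(
            brain, structure=ndimage.generate_binary_structure(3, 1)
        )
        if not lesion.any():
            raise PhantomSpecError("lesion ellipsoid contains no voxels")
        if (lesion & ~interior).any():
            raise PhantomSpecError("lesion ellipsoid must lie strictly inside the brain")
        adc[lesion] = spec.lesion_adc_mean + spec.lesion_adc_sd * rng.standard_normal(
            int(lesion.sum())
        )
    else:
        lesion = np.zeros(shape, dtype=bool)

    adc = np.where(brain, np.maximum(adc, 0.0), 0.0)

    b0_clean = np.where(brain, spec.s0_mean, 0.0)
    trace_clean = b0_clean * np.exp(-spec.b_value * adc * 1e-6)

    b0 = np.maximum(b0_clean + rng.normal(0.0, spec.noise_sd, shape) * brain, 0.0)
    trace = np.maximum(trace_clean + rng.normal(0.0, spec.noise_sd, shape) * brain, 0.0)

    return PhantomCase(
        b0=ImageVolume(b0, spacing, INTENSITY),
        trace=ImageVolume(trace, spacing, INTENSITY),
        adc=ImageVolume(adc, spacing, ADC_UNITS),
        brain_mask=BinaryMask(brain, spacing),
        truth_lesion=BinaryMask(lesion, spacing),
        spec=spec,
    )


def _solve_lesion_radii(
    spec: PhantomSpec, center: np.ndarray, target_ml: float
) -> tuple[float, float, float]:
    """Radii (fixed 1 : 1.15 : 1 proportions) whose voxelised ellipsoid volume
    is as close as possible to ``target_ml`` (bisection on the scale)."""
    proportions = np.array([1.0, 1.15, 1.0])
    vox_ml = spec.voxel_volume_ml
    target_vox = target_ml / vox_ml

    def count(scale: float) -> int:
        return int(_ellipsoid_mask(spec.grid_shape, center, proportions * scale).sum())

    s0 = (target_vox / (4.0 / 3.0 * math.pi * np.prod(proportions))) ** (1 / 3)
    lo, hi = 0.4 * s0, 2.0 * s0
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if count(mid) < target_vox:
            lo = mid
        else:
            hi = mid
    # pick the bracket end whose count is nearest the target
    best = min((lo, hi), key=lambda s: abs(count(s) - target_vox))
    return tuple(proportions * best)


def generate_cohort(
    base_spec: PhantomSpec,
    n: int,
    lesion_volume_range_ml: tuple[float, float] = (1.0, 30.0),
    adc_jitter: float = 25.0,
    seed: int = 0,
) -> list[PhantomCase]:
    """Generate ``n`` cases with log-uniform lesion volumes and jittered ADC means.

    Per-case seeds are spawned deterministically from ``seed``; lesion
    centres are placed at a random lateral offset in a random hemisphere,
    shrunk toward the centre until the lesion fits strictly inside the
    brain. ``adc_jitter`` is the SD (1e-6 mm^2/s) of between-subject shifts
    applied to the lesion and parenchyma ADC means.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = lesion_volume_range_ml
    if not (0 < lo <= hi):
        raise PhantomSpecError(
            f"invalid lesion volume range {lesion_volume_range_ml}"
        )
    child_seqs = np.random.SeedSequence(seed).spawn(n)
    cases = []
    for seq in child_seqs:
        case_seed = int(seq.generate_state(1)[0] % (2**31))
        rng = np.random.default_rng(seq)
        target_ml = math.exp(rng.uniform(math.log(lo), math.log(hi)))

        c = base_spec.grid_center()
        br = base_spec.brain_semiaxes()
        side = rng.choice([-1.0, 1.0])
        offset = np.array(
            [
                side * rng.uniform(0.35, 0.55) * br[0],
                rng.uniform(-0.15, 0.15) * br[1],
                rng.uniform(-0.15, 0.15) * br[2],
            ]
        )
        lesion_mean = base_spec.lesion_adc_mean + rng.normal(0.0, adc_jitter)
        paren_mean = base_spec.parenchyma_adc_mean + rng.normal(0.0, adc_jitter)

        spec = None
        for _ in range(25):
            center = c + offset
            radii = _solve_lesion_radii(base_spec, center, target_ml)
            candidate = replace(
                base_spec,
                lesion_center_vox=tuple(center),
                lesion_radii_vox=radii,
                lesion_adc_mean=lesion_mean,
                parenchyma_adc_mean=paren_mean,
                seed=case_seed,
            )
            try:
                cases.append(generate_case(candidate))
                spec = candidate
                break
            except PhantomSpecError:
                offset = offset * 0.85  # pull toward the brain centre and retry
        if spec is None:
            raise PhantomSpecError(
                f"could not place a {target_ml:.2f} mL lesion inside the brain"
            )
    return cases
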