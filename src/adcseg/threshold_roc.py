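"""Voxelwise ROC analysis for optimal ADC thresholds.

The classifier is "infarct if ADC <= t". For each threshold on an ascending
grid, true/false positives are counted against a reference lesion mask
within a search region (whole-brain parenchyma, or a dilated neighbourhood
of the lesion), and the operating threshold is chosen by maximizing the
Youden index J = sensitivity + specificity - 1 (ties broken toward the
lowest threshold). Per-subject count tables can be pooled by summing counts
on a shared grid before recomputing rates.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume_io import BinaryMask, ImageVolume, check_same_grid

log = logging.getLogger(__name__)

_STRUCT6 = ndimage.generate_binary_structure(3, 1)

COUNT_COLUMNS = ["threshold", "TP", "FP", "FN", "TN"]


def default_threshold_grid(
    lower: float = 0.0, upper: float = 1500.0, step: float = 1.0
) -> np.ndarray:
    """Default ADC threshold grid: 0..1500 x 1e-6 mm^2/s in unit steps."""
    return np.arange(lower, upper + 0.5 * step, step, dtype=np.float64)


@dataclass
class ROCResult:
    """A threshold sweep with per-threshold rates and the Youden optimum."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    youden: np.ndarray
    optimal_threshold: float
    optimal_youden: float
    optimal_sensitivity: float
    optimal_specificity: float
    auc: float
    counts: pd.DataFrame
    n_positive: int
    n_negative: int

    def to_dataframe(self) -> pd.DataFrame:
        """Per-threshold table: counts plus sensitivity/specificity/Youden."""
        df = self.counts.copy()
        df["sensitivity"] = self.sensitivity
        df["specificity"] = self.specificity
        df["youden"] = self.youden
        return df

    def summary(self) -> dict:
        return {
            "optimal_threshold": self.optimal_threshold,
            "optimal_youden": self.optimal_youden,
            "optimal_sensitivity": self.optimal_sensitivity,
            "optimal_specificity": self.optimal_specificity,
            "auc": self.auc,
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
        }


def _validate_thresholds(thresholds: np.ndarray) -> np.ndarray:
    t = np.asarray(thresholds, dtype=np.float64)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("thresholds must be a non-empty 1-D array")
    if not (np.diff(t) > 0).all():
        raise ValueError("thresholds must be strictly ascending")
    return t


def _result_from_counts(
    thresholds: np.ndarray, tp: np.ndarray, fp: np.ndarray, fn: np.ndarray, tn: np.ndarray
) -> ROCResult:
    n_pos = int(tp[0] + fn[0])
    n_neg = int(fp[0] + tn[0])
    sens = tp / n_pos
    spec = tn / n_neg
    youden = sens + spec - 1.0
    best = int(np.argmax(youden))  # first maximum -> lowest threshold on ties
    fpr = np.concatenate([[0.0], 1.0 - spec, [1.0]])
    tpr = np.concatenate([[0.0], sens, [1.0]])
    auc = float(np.trapezoid(tpr, fpr))
    counts = pd.DataFrame(
        {
            "threshold": thresholds,
            "TP": tp.astype(np.int64),
            "FP": fp.astype(np.int64),
            "FN": fn.astype(np.int64),
            "TN": tn.astype(np.int64),
        }
    )
    return ROCResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        youden=youden,
        optimal_threshold=float(thresholds[best]),
        optimal_youden=float(youden[best]),
        optimal_sensitivity=float(sens[best]),
        optimal_specificity=float(spec[best]),
        auc=auc,
        counts=counts,
        n_positive=n_pos,
        n_negative=n_neg,
    )


def roc_sweep(
    adc: ImageVolume,
    truth: BinaryMask,
    search_region: BinaryMask,
    thresholds: np.ndarray | None = None,
) -> ROCResult:
    """Sweep ADC thresholds within a search region against a reference lesion.

    ``truth`` must be a nonempty subset of ``search_region``; the negative
    class is the search region minus the truth. Counts at threshold t
    classify voxels with ADC <= t as positive.
    """
    check_same_grid(adc, truth, search_region)
    if thresholds is None:
        thresholds = default_threshold_grid()
    thresholds = _validate_thresholds(thresholds)
    if not truth.data.any():
        raise ValueError("reference lesion is empty: ROC undefined")
    if not search_region.data.any():
        raise ValueError("search region is empty")
    if (truth.data & ~search_region.data).any():
        raise ValueError("truth mask must be contained in the search region")

    pos_vals = np.sort(adc.data[truth.data])
    neg_vals = np.sort(adc.data[search_region.data & ~truth.data])
    if neg_vals.size == 0:
        raise ValueError("search region contains no negative voxels")

    tp = np.searchsorted(pos_vals, thresholds, side="right").astype(np.float64)
    fp = np.searchsorted(neg_vals, thresholds, side="right").astype(np.float64)
    fn = pos_vals.size - tp
    tn = neg_vals.size - fp
    return _result_from_counts(thresholds, tp, fp, fn, tn)


def dilated_search_region(
    truth: BinaryMask, brain_parenchyma: BinaryMask, iterations: int
) -> BinaryMask:
    """Dilate the lesion (6-connected) and intersect with the parenchyma.

    Narrows the ROC comparison to the lesion's vicinity. The fraction of
    parenchyma excluded by the narrowing is logged; see
    :func:`parenchyma_excluded_fraction`.
    """
    check_same_grid(truth, brain_parenchyma)
    if not truth.data.any():
        raise ValueError("truth mask is empty")
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if iterations == 0:
        dilated = truth.data
    else:
        dilated = ndimage.binary_dilation(truth.data, structure=_STRUCT6, iterations=iterations)
    region = BinaryMask(dilated & brain_parenchyma.data, truth.spacing)
    log.info(
        "dilated search region excludes %.1f%% of parenchyma",
        100.0 * parenchyma_excluded_fraction(region, brain_parenchyma),
    )
    return region


def parenchyma_excluded_fraction(region: BinaryMask, brain_parenchyma: BinaryMask) -> float:
    """Fraction of parenchyma voxels excluded by a narrowed search region."""
    n_par = brain_parenchyma.voxel_count
    if n_par == 0:
        raise ValueError("parenchyma mask is empty")
    n_in = int((region.data & brain_parenchyma.data).sum())
    return 1.0 - n_in / n_par


def pooled_roc(
    results: list[ROCResult] | list[pd.DataFrame],
    thresholds: np.ndarray | None = None,
) -> ROCResult:
    """Pool per-subject count tables (sum TP/FP/FN/TN) on a shared grid.

    Accepts :class:`ROCResult` objects or count DataFrames with columns
    ``threshold, TP, FP, FN, TN``; every subject must have been evaluated
    on the identical threshold grid.
    """
    if not results:
        raise ValueError("no results to pool")
    tables = [r.counts if isinstance(r, ROCResult) else r for r in results]
    ref = np.asarray(tables[0]["threshold"], dtype=np.float64)
    if thresholds is not None:
        thresholds = _validate_thresholds(thresholds)
        if ref.size != thresholds.size or not np.array_equal(ref, thresholds):
            raise ValueError("count tables do not match the requested threshold grid")
    for t in tables[1:]:
        other = np.asarray(t["threshold"], dtype=np.float64)
        if other.size != ref.size or not np.array_equal(other, ref):
            raise ValueError("all subjects must share one threshold grid")
    tp = sum(np.asarray(t["TP"], dtype=np.float64) for t in tables)
    fp = sum(np.asarray(t["FP"], dtype=np.float64) for t in tables)
    fn = sum(np.asarray(t["FN"], dtype=np.float64) for t in tables)
    tn = sum(np.asarray(t["TN"], dtype=np.float64) for t in tables)
    return _result_from_counts(ref, tp, fp, fn, tn)
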