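"""Agreement and performance statistics for lesion delineations.

Dice overlap, per-lesion summaries, Bland-Altman volumetric agreement with
Pearson correlation, and ordinary least squares with standardized
coefficients for relating segmentation performance (Dice, Youden) to
patient/lesion factors.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .volume_io import BinaryMask, ImageVolume, check_same_grid, mask_volume_ml


def dice(pred: BinaryMask, truth: BinaryMask) -> float:
    """Dice coefficient 2 TP / (2 TP + FP + FN) between two binary masks.

    Two empty masks agree perfectly on absence and return 1.0 (with a
    warning, since the value is a convention).
    """
    check_same_grid(pred, truth)
    tp = int((pred.data & truth.data).sum())
    fp = int((pred.data & ~truth.data).sum())
    fn = int((truth.data & ~pred.data).sum())
    if tp + fp + fn == 0:
        warnings.warn("both masks empty: Dice defined as 1.0", stacklevel=2)
        return 1.0
    return 2.0 * tp / (2.0 * tp + fp + fn)


class LesionSummary(NamedTuple):
    volume_ml: float
    mean_adc: float
    median_adc: float


def lesion_summary(mask: BinaryMask, adc: ImageVolume) -> LesionSummary:
    """Volume (mL) and mean/median ADC over a lesion mask.

    An empty mask yields volume 0 and NaN ADC summaries (with a warning).
    """
    check_same_grid(mask, adc)
    if not mask.data.any():
        warnings.warn("empty mask: ADC summaries undefined", stacklevel=2)
        return LesionSummary(0.0, float("nan"), float("nan"))
    vals = adc.data[mask.data]
    return LesionSummary(
        volume_ml=mask_volume_ml(mask),
        mean_adc=float(vals.mean()),
        median_adc=float(np.median(vals)),
    )


@dataclass
class AgreementStats:
    """Bland-Altman agreement between two volume series.

    Differences are oriented a - b (first argument minus second), so with
    (reference, automated) the bias is reference-minus-automated. Limits of
    agreement are bias +/- 1.96 sample SD (n-1 denominator). The linear fit
    regresses the first series on the second.
    """

    bias: float
    loa_low: float
    loa_high: float
    pearson_r: float
    slope: float
    intercept: float
    adj_r2: float
    n: int


def bland_altman(volumes_a: Sequence[float], volumes_b: Sequence[float]) -> AgreementStats:
    """Agreement statistics between paired volume measurements (mL)."""
    a = np.asarray(volumes_a, dtype=np.float64)
    b = np.asarray(volumes_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("volume lists must be 1-D and of equal length")
    if a.size < 2:
        # two pairs are enough for the closed-form bias/limits, though the
        # limits are then a formality rather than a useful agreement interval
        raise ValueError("need at least 2 paired volumes")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    if np.allclose(a, a[0]) or np.allclose(b, b[0]):
        r = float("nan")
    else:
        r = float(np.corrcoef(a, b)[0, 1])
    fit = sm.OLS(a, sm.add_constant(b)).fit()
    # adjusted R^2 needs a residual degree of freedom
    adj_r2 = float(fit.rsquared_adj) if a.size > 2 else float("nan")
    return AgreementStats(
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        pearson_r=r,
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        adj_r2=adj_r2,
        n=int(a.size),
    )


@dataclass
class RegressionReport:
    """Standardized-coefficient OLS fit of a performance score on predictors.

    ``coefficients`` is indexed by predictor name with columns
    ``beta, ci_low, ci_high, p_value`` (95% Wald intervals, two-sided
    t-tests). Response and predictors are z-scored before fitting, so betas
    are standardized effect sizes.
    """

    response_name: str
    coefficients: pd.DataFrame
    adj_r2: float
    n: int
    n_dropped: int

    def summary(self) -> str:
        lines = [
            f"standardized OLS: {self.response_name} ~ "
            + " + ".join(self.coefficients.index),
            f"n = {self.n} (dropped {self.n_dropped} incomplete cases), "
            f"adj R^2 = {self.adj_r2:.3f}",
            self.coefficients.to_string(float_format=lambda x: f"{x: .3f}"),
        ]
        return "\n".join(lines)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot z-score a constant column")
    return (x - x.mean()) / sd


def standardized_regression(
    response: Sequence[float],
    predictors: Mapping[str, Sequence[float]] | pd.DataFrame,
    response_name: str = "response",
) -> RegressionReport:
    """OLS of a z-scored response on z-scored predictors.

    Cases with any missing value are dropped and counted. Near-collinear
    predictors (design condition number > 1e8) raise an error naming the
    most-correlated pair.
    """
    X = pd.DataFrame(predictors).astype(np.float64)
    y = pd.Series(np.asarray(response, dtype=np.float64), index=X.index, name=response_name)
    if X.shape[1] == 0:
        raise ValueError("no predictors given")
    complete = ~(X.isna().any(axis=1) | y.isna())
    n_dropped = int((~complete).sum())
    X, y = X.loc[complete], y.loc[complete]
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 observations, got n={n}, p={p}")

    Xz = X.apply(lambda col: _zscore(col.to_numpy()), axis=0)
    yz = _zscore(y.to_numpy())

    cond = np.linalg.cond(Xz.to_numpy())
    if cond > 1e8:
        corr = Xz.corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(int(np.argmax(corr)), corr.shape)
        raise ValueError(
            f"collinear predictors (condition number {cond:.2g}): "
            f"{Xz.columns[i]!r} vs {Xz.columns[j]!r}"
        )

    fit = sm.OLS(yz, sm.add_constant(Xz)).fit()
    ci = fit.conf_int(alpha=0.05)
    coef = pd.DataFrame(
        {
            "beta": fit.params,
            "ci_low": ci[0],
            "ci_high": ci[1],
            "p_value": fit.pvalues,
        }
    ).drop(index="const")
    return RegressionReport(
        response_name=response_name,
        coefficients=coef,
        adj_r2=float(fit.rsquared_adj),
        n=int(n),
        n_dropped=n_dropped,
    )
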