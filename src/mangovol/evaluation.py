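"""Regression metrics and the diagnostic battery.

Metric conventions
------------------
* R^2 = 1 - SS_res / SS_tot about the truth mean (may be negative).
* MAPE = (100/n) * sum |y_i - yhat_i| / (y_i + eps) with eps = 1e-6.  The
  denominator is ``y_i + eps``, not ``|y_i| + eps`` — volumes are positive,
  and the epsilon only guards exact zeros.  For negative truths this
  differs from the absolute-value convention used elsewhere.
* RMSE = sqrt(mean squared error), same units as the target (cm^3).
* Bias = mean(yhat - y): negative means systematic underestimation.
* Bland-Altman differences use the same sign (yhat - y); limits of
  agreement are bias +/- 1.96 * SD(d).

Diagnostics wrap scipy.stats: the paired t-test compares per-sample
absolute errors of two models, and Levene's test (classic mean centering;
median centering available) compares residual variances.  p-values are
reported at full precision — threshold annotations belong in reports, not
in test logic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import stats

from .exceptions import DegenerateCaseError, ParameterError

__all__ = [
    "EvalConfig",
    "EvalReport",
    "SevenNumberSummary",
    "r_squared",
    "mape",
    "rmse",
    "mean_bias",
    "abs_pct_error_stats",
    "evaluate",
    "paired_t_abs_errors",
    "levene_residual_variance",
    "bland_altman",
    "BlandAltman",
]


@dataclass(frozen=True)
class EvalConfig:
    epsilon: float = 1e-6  # MAPE division guard
    loa_multiplier: float = 1.96  # Bland-Altman 95% limits of agreement

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ParameterError("epsilon must be positive")


class SevenNumberSummary(NamedTuple):
    mean: float
    sd: float
    min: float
    q1: float
    median: float
    q3: float
    max: float


class BlandAltman(NamedTuple):
    bias: float
    loa_low: float
    loa_high: float


def _pair(truth, pred, min_n=1):
    y = np.asarray(truth, float).ravel()
    yhat = np.asarray(pred, float).ravel()
    if y.shape != yhat.shape:
        raise ParameterError("truth and prediction must have equal length")
    if len(y) < min_n:
        raise ParameterError(f"need at least {min_n} samples")
    return y, yhat


def r_squared(truth, pred) -> float:
    y, yhat = _pair(truth, pred, min_n=2)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise DegenerateCaseError("R^2 undefined: truth values are all identical")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot


def mape(truth, pred, config: EvalConfig | None = None) -> float:
    """Mean absolute percentage error (%), eps-guarded denominator y + eps."""
    config = config or EvalConfig()
    y, yhat = _pair(truth, pred)
    return 100.0 * float(np.mean(np.abs(y - yhat) / (y + config.epsilon)))


def rmse(truth, pred) -> float:
    y, yhat = _pair(truth, pred)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def mean_bias(truth, pred) -> float:
    """mean(pred - truth); negative = systematic underestimation."""
    y, yhat = _pair(truth, pred)
    return float(np.mean(yhat - y))


def abs_pct_error_stats(truth, pred, config: EvalConfig | None = None) -> SevenNumberSummary:
    """Boxplot statistics of the per-sample absolute percentage errors."""
    config = config or EvalConfig()
    y, yhat = _pair(truth, pred)
    e = 100.0 * np.abs(y - yhat) / (y + config.epsilon)
    return SevenNumberSummary(
        mean=float(e.mean()),
        sd=float(e.std(ddof=1)) if len(e) > 1 else 0.0,
        min=float(e.min()),
        q1=float(np.quantile(e, 0.25)),
        median=float(np.quantile(e, 0.5)),
        q3=float(np.quantile(e, 0.75)),
        max=float(e.max()),
    )


@dataclass(frozen=True)
class EvalReport:
    """Full evaluation of one model on one test set.

    ``residuals`` follow the truth-minus-prediction sign convention used
    in residual analysis; ``bias`` uses prediction-minus-truth.
    ``rmse >= |bias|`` always (Jensen).
    """

    n: int
    r2: float
    mape: float
    rmse: float
    bias: float
    abs_pct_error_stats: SevenNumberSummary
    residuals: np.ndarray = field(repr=False)
    n_negative_pred: int = 0


def evaluate(truth, pred, config: EvalConfig | None = None) -> EvalReport:
    config = config or EvalConfig()
    y, yhat = _pair(truth, pred, min_n=2)
    return EvalReport(
        n=len(y),
        r2=r_squared(y, yhat),
        mape=mape(y, yhat, config),
        rmse=rmse(y, yhat),
        bias=mean_bias(y, yhat),
        abs_pct_error_stats=abs_pct_error_stats(y, yhat, config),
        residuals=y - yhat,
        n_negative_pred=int(np.sum(yhat < 0)),
    )


def paired_t_abs_errors(errors_a, errors_b) -> tuple[float, float]:
    """Paired t-test on per-sample absolute errors of two models.

    Inputs are the (signed or absolute) error vectors of the two models,
    paired by sample; absolute values are taken before differencing.
    Returns (t statistic, two-sided p) with n-1 degrees of freedom.
    """
    a, b = _pair(errors_a, errors_b, min_n=3)
    d = np.abs(a) - np.abs(b)
    if np.std(d, ddof=1) == 0:
        if np.all(d == 0):  # identical magnitudes: no difference at all
            return 0.0, 1.0
        raise DegenerateCaseError("zero-variance nonzero paired differences")
    res = stats.ttest_rel(np.abs(a), np.abs(b))
    return float(res.statistic), float(res.pvalue)


def levene_residual_variance(res_a, res_b, center: str = "mean") -> tuple[float, float]:
    """Levene's W for equality of residual variances (classic mean centering).

    ``center='median'`` switches to the Brown-Forsythe variant.  Raises on
    degenerate inputs where every absolute deviation is identical (e.g.
    two constant vectors), where the F denominator vanishes.
    """
    a = np.asarray(res_a, float).ravel()
    b = np.asarray(res_b, float).ravel()
    if len(a) < 2 or len(b) < 2:
        raise ParameterError("need >= 2 residuals per group")
    if center not in ("mean", "median"):
        raise ParameterError("center must be 'mean' or 'median'")
    loc = np.mean if center == "mean" else np.median
    z = np.concatenate([np.abs(a - loc(a)), np.abs(b - loc(b))])
    if np.allclose(z, z[0]):
        raise DegenerateCaseError("Levene undefined: all absolute deviations identical")
    res = stats.levene(a, b, center=center)
    return float(res.statistic), float(res.pvalue)


def bland_altman(truth, pred, config: EvalConfig | None = None) -> BlandAltman:
    """Agreement analysis: bias and limits of agreement of d = pred - truth."""
    config = config or EvalConfig()
    y, yhat = _pair(truth, pred, min_n=2)
    d = yhat - y
    bias = float(d.mean())
    half = config.loa_multiplier * float(d.std(ddof=1))
    return BlandAltman(bias=bias, loa_low=bias - half, loa_high=bias + half)
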