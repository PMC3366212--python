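"""Validation statistics for uric-acid prediction models.

Residuals follow the convention e = predicted - observed, so a model whose
mean prediction falls below the laboratory mean has negative BIAS.  The
three headline error measures are

* BIAS = Σe_i / N                       (systematic error)
* SE   = sqrt(Σ(e_i - BIAS)² / (N-1))   (spread about the bias)
* RMSE = sqrt(Σe_i² / N)                (total error)

which satisfy RMSE² = BIAS² + SE²·(N-1)/N.  R² is the squared Pearson
correlation between laboratory and calculated values.  Agreement between
methods is summarised Bland-Altman style (mean difference ± 1.96 SD), and
models are compared by a paired two-sided t-test on absolute residuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .calibrate import LinearModel, NegativePredictionWarning, apply_model
from .errors import InvalidInputError
from .spectra import SpectraDataset

__all__ = [
    "EvalReport",
    "BlandAltmanSummary",
    "error_metrics",
    "r_squared",
    "evaluate_model",
    "bland_altman",
    "compare_models",
    "predict_dataset",
]


@dataclass(frozen=True)
class EvalReport:
    """Table-style evaluation summary for one model on one split."""

    model_name: str
    split: str
    n: int
    mean_pred: float
    sd_pred: float
    r_squared: float
    bias: float
    se: float
    rmse: float


@dataclass(frozen=True)
class BlandAltmanSummary:
    """Mean difference and 1.96-SD limits of agreement."""

    mean_difference: float
    sd_difference: float
    lower_limit: float
    upper_limit: float


def error_metrics(residuals) -> tuple[float, float, float]:
    """(BIAS, SE, RMSE) of a signed residual vector (predicted - observed)."""
    e = np.asarray(residuals, dtype=float)
    if e.ndim != 1 or e.size == 0:
        raise InvalidInputError("residual vector must be 1-D and non-empty")
    n = e.size
    if n < 2:
        raise InvalidInputError("SE needs N >= 2 (denominator N-1)")
    bias = float(np.sum(e) / n)
    se = float(np.sqrt(np.sum((e - bias) ** 2) / (n - 1)))
    rmse = float(np.sqrt(np.sum(e**2) / n))
    return bias, se, rmse


def r_squared(observed, predicted) -> float:
    """Squared Pearson correlation between observed and predicted values."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise InvalidInputError("observed and predicted must be equal-length 1-D")
    if obs.size < 3:
        raise InvalidInputError("need at least 3 pairs for a correlation")
    if np.ptp(obs) == 0 or np.ptp(pred) == 0:
        raise InvalidInputError("correlation undefined for a constant vector")
    r = np.corrcoef(obs, pred)[0, 1]
    return float(r**2)


def predict_dataset(
    model: LinearModel, dataset: SpectraDataset, split: str | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """(observed, predicted) arrays for the records of one split."""
    records = dataset.records if split is None else dataset.split_records(split)
    if not records:
        raise InvalidInputError(f"no records in split {split!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", NegativePredictionWarning)
        predicted = np.array([apply_model(model, r.spectrum) for r in records])
    observed = np.array([r.ua_umol_l for r in records])
    return observed, predicted


def evaluate_model(
    model: LinearModel, dataset: SpectraDataset, split: str
) -> EvalReport:
    """Populate an :class:`EvalReport` for one model on one dataset split."""
    observed, predicted = predict_dataset(model, dataset, split)
    residuals = predicted - observed
    bias, se, rmse = error_metrics(residuals)
    return EvalReport(
        model_name=model.name,
        split=split,
        n=observed.size,
        mean_pred=float(np.mean(predicted)),
        sd_pred=float(np.std(predicted, ddof=1)) if observed.size > 1 else 0.0,
        r_squared=r_squared(observed, predicted),
        bias=bias,
        se=se,
        rmse=rmse,
    )


def bland_altman(observed, predicted) -> BlandAltmanSummary:
    """Limits-of-agreement summary of predicted - observed differences."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise InvalidInputError("observed and predicted must be equal-length 1-D")
    if obs.size < 2:
        raise InvalidInputError("need at least 2 pairs")
    diff = pred - obs
    mean = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    return BlandAltmanSummary(
        mean_difference=mean,
        sd_difference=sd,
        lower_limit=mean - 1.96 * sd,
        upper_limit=mean + 1.96 * sd,
    )


def compare_models(
    residuals_a, residuals_b, alpha: float = 0.05
) -> tuple[float, float, bool]:
    """Paired two-sided t-test on absolute residuals of two models.

    Returns ``(t_statistic, p_value, significant)`` with ``significant``
    meaning p < alpha (strict).
    """
    a = np.abs(np.asarray(residuals_a, dtype=float))
    b = np.abs(np.asarray(residuals_b, dtype=float))
    if a.shape != b.shape or a.ndim != 1:
        raise InvalidInputError("residual vectors must be equal-length 1-D pairs")
    if a.size < 3:
        raise InvalidInputError("need at least 3 paired residuals")
    if np.allclose(a - b, 0):
        return 0.0, 1.0, False
    res = stats.ttest_rel(a, b)
    t, p = float(res.statistic), float(res.pvalue)
    return t, p, bool(p < alpha)
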