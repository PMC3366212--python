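"""Multi-wavelength linear calibration of uric-acid concentration.

Models have the form ``Y = a + b1*x1 + ... + bk*xk`` where Y is uric-acid
concentration in µmol/L and each x_i is the spectrum value (absorbance, AU,
or first derivative, AU/nm) at one selected wavelength.  Coefficients are
fitted by ordinary least squares on the calibration split; wavelengths are
chosen by forward stepwise selection over the full 190-380 nm grid, adding
at each step the wavelength that most reduces calibration RMSE and stopping
when a paired t-test on absolute residuals no longer shows improvement, or
when the step cap is reached.

Six published models (three on original absorbance at 294/312/266 nm, three
on first-derivative spectra at 300/270/222 nm) ship as packaged JSON
fixtures and can be applied directly via :func:`published_model`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy import stats

from .errors import (
    CollinearityError,
    GridError,
    InvalidInputError,
    InvalidParameterError,
    KindMismatchError,
)
from .spectra import (
    CALIBRATION,
    SIGNAL_KINDS,
    SampleRecord,
    SpectraDataset,
    Spectrum,
)

#: Condition-number cap: candidate wavelengths whose addition pushes the
#: design matrix beyond this are skipped (smooth spectra make neighbouring
#: wavelengths nearly collinear).
CONDITION_LIMIT = 1e10

STOP_MAX_STEPS = "max_steps"
STOP_NO_IMPROVEMENT = "no_significant_improvement"


class NegativePredictionWarning(UserWarning):
    """A model produced a physically impossible negative concentration."""


@dataclass(frozen=True)
class LinearModel:
    """Intercept plus (wavelength, coefficient) terms of one signal kind."""

    intercept: float
    terms: tuple[tuple[float, float], ...]
    signal_kind: str
    name: str = ""
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if self.signal_kind not in SIGNAL_KINDS:
            raise KindMismatchError(
                f"signal_kind must be one of {SIGNAL_KINDS}, got {self.signal_kind!r}"
            )
        if len(self.terms) < 1:
            raise InvalidParameterError("model must have at least one term")
        wls = [wl for wl, _ in self.terms]
        if len(set(wls)) != len(wls):
            raise InvalidParameterError(f"duplicate wavelengths in model: {wls}")
        for wl in wls:
            if not 190 <= wl <= 380:
                raise InvalidParameterError(
                    f"wavelength {wl} nm outside the 190-380 nm range"
                )

    @property
    def wavelengths(self) -> tuple[float, ...]:
        return tuple(wl for wl, _ in self.terms)

    @property
    def coefficients(self) -> tuple[float, ...]:
        return tuple(b for _, b in self.terms)


@dataclass(frozen=True)
class StepRecord:
    """One step of the forward-stepwise trace."""

    step: int
    wavelength_nm: float
    model: LinearModel
    rmse_cal: float
    p_value_vs_previous: float | None
    skipped_collinear: tuple[float, ...] = ()


@dataclass(frozen=True)
class FitResult:
    """Final stepwise model plus the per-step trace and stopping reason."""

    model: LinearModel
    steps: tuple[StepRecord, ...]
    stopping_reason: str


def _records(dataset) -> list[SampleRecord]:
    if isinstance(dataset, SpectraDataset):
        return dataset.split_records(CALIBRATION)
    return list(dataset)


def _design(records: list[SampleRecord], wavelengths, signal_kind):
    """(X with intercept column, y) for the given wavelengths."""
    if not records:
        raise InvalidInputError("calibration set is empty")
    for r in records:
        if r.spectrum.signal_kind != signal_kind:
            raise KindMismatchError(
                f"record {r.sample_id!r} has signal kind "
                f"{r.spectrum.signal_kind!r}, model expects {signal_kind!r}"
            )
    grid = records[0].spectrum.wavelengths_nm
    idx = []
    for wl in wavelengths:
        pos = np.nonzero(np.isclose(grid, wl))[0]
        if pos.size == 0:
            raise GridError(f"wavelength {wl} nm not on spectrum grid")
        idx.append(int(pos[0]))
    X = np.column_stack(
        [np.ones(len(records))]
        + [np.array([r.spectrum.values[i] for r in records]) for i in idx]
    )
    y = np.array([r.ua_umol_l for r in records])
    return X, y


def fit_mlr(dataset, wavelengths, signal_kind: str,
            name: str = "fitted") -> LinearModel:
    """Ordinary-least-squares fit of uric acid on fixed wavelengths.

    Uric-acid concentration is the dependent variable; spectrum values at
    the given wavelengths are the regressors.  Raises
    :class:`CollinearityError` if the design matrix is rank deficient.
    """
    wavelengths = list(wavelengths)
    records = _records(dataset)
    if len(records) < len(wavelengths) + 2:
        raise InvalidInputError(
            f"need >= {len(wavelengths) + 2} records for "
            f"{len(wavelengths)} wavelengths, got {len(records)}"
        )
    X, y = _design(records, wavelengths, signal_kind)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise CollinearityError(wavelengths)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    terms = tuple(
        (float(wl), float(b)) for wl, b in zip(wavelengths, beta[1:])
    )
    return LinearModel(
        intercept=float(beta[0]),
        terms=terms,
        signal_kind=signal_kind,
        name=name,
        provenance={"fitted": True, "n_records": len(records)},
    )


def apply_model(model: LinearModel, spectrum: Spectrum) -> float:
    """Evaluate the model on one spectrum: Y = a + Σ b_i·x(λ_i).

    Negative predictions are returned as-is (no clipping) with a
    :class:`NegativePredictionWarning`.
    """
    if spectrum.signal_kind != model.signal_kind:
        raise KindMismatchError(
            f"{model.signal_kind!r} model applied to a "
            f"{spectrum.signal_kind!r} spectrum"
        )
    y = model.intercept
    for wl, b in model.terms:
        y += b * spectrum.value_at(wl)
    if y < 0:
        warnings.warn(
            f"model {model.name or '<unnamed>'} predicted negative "
            f"concentration {y:.2f} µmol/L",
            NegativePredictionWarning,
            stacklevel=2,
        )
    return float(y)


def _rmse(X: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = X @ beta - y
    return float(np.sqrt(np.mean(resid**2))), resid


def forward_stepwise(
    dataset,
    signal_kind: str,
    max_steps: int = 3,
    alpha: float = 0.05,
    candidate_wavelengths=None,
) -> FitResult:
    """Forward stepwise wavelength selection on the calibration split.

    At each step the candidate wavelength minimising calibration RMSE is
    added (ties broken toward the lower wavelength; candidates that push
    the design-matrix condition number beyond ``CONDITION_LIMIT`` are
    skipped).  Selection continues while the step count is below
    ``max_steps`` and a paired two-sided t-test on absolute residuals
    (current vs previous model) rejects at ``alpha``.
    """
    records = _records(dataset)
    if not records:
        raise InvalidInputError("calibration set is empty")
    if max_steps < 1:
        raise InvalidParameterError("max_steps must be >= 1")
    grid = records[0].spectrum.wavelengths_nm
    candidates = (
        [float(w) for w in grid]
        if candidate_wavelengths is None
        else [float(w) for w in candidate_wavelengths]
    )
    y = np.array([r.ua_umol_l for r in records])
    # value matrix indexed by candidate for speed: one column per grid point
    values = np.array([r.spectrum.values for r in records])
    grid_index = {float(w): i for i, w in enumerate(grid)}
    for r in records:
        if r.spectrum.signal_kind != signal_kind:
            raise KindMismatchError(
                f"record {r.sample_id!r} has signal kind "
                f"{r.spectrum.signal_kind!r}, expected {signal_kind!r}"
            )

    selected: list[float] = []
    steps: list[StepRecord] = []
    prev_abs_resid: np.ndarray | None = None
    stopping_reason = STOP_MAX_STEPS
    ones = np.ones(len(records))

    for step in range(1, max_steps + 1):
        best: tuple[float, float, np.ndarray] | None = None  # (rmse, wl, resid)
        skipped: list[float] = []
        base_cols = [ones] + [values[:, grid_index[w]] for w in selected]
        for wl in candidates:
            if wl in selected:
                continue
            X = np.column_stack(base_cols + [values[:, grid_index[wl]]])
            if np.linalg.cond(X) > CONDITION_LIMIT:
                skipped.append(wl)
                continue
            rmse, resid = _rmse(X, y)
            if best is None or rmse < best[0]:
                best = (rmse, wl, resid)
        if best is None:
            stopping_reason = STOP_NO_IMPROVEMENT
            break
        rmse, wl, resid = best
        abs_resid = np.abs(resid)
        p_value: float | None = None
        if prev_abs_resid is not None:
            diff = abs_resid - prev_abs_resid
            if np.allclose(diff, 0):
                p_value = 1.0
            else:
                p_value = float(stats.ttest_rel(abs_resid, prev_abs_resid).pvalue)
            if not p_value < alpha:
                stopping_reason = STOP_NO_IMPROVEMENT
                break
        trial = selected + [wl]
        model = fit_mlr(records, trial, signal_kind,
                        name=f"stepwise_{len(trial)}WL")
        steps.append(
            StepRecord(
                step=step,
                wavelength_nm=wl,
                model=model,
                rmse_cal=rmse,
                p_value_vs_previous=p_value,
                skipped_collinear=tuple(skipped),
            )
        )
        selected = trial
        prev_abs_resid = abs_resid

    if not steps:
        raise InvalidInputError("stepwise selection could not add any wavelength")
    return FitResult(
        model=steps[-1].model,
        steps=tuple(steps),
        stopping_reason=stopping_reason,
    )


# --- published model registry ------------------------------------------------

PUBLISHED_MODEL_NAMES = (
    "UVa_1WL",
    "UVa_2WL",
    "UVa_3WL",
    "UVd_1WL",
    "UVd_2WL",
    "UVd_3WL",
)


def _model_from_dict(payload: dict) -> LinearModel:
    if payload.get("signal_kind") not in SIGNAL_KINDS:
        raise KindMismatchError(
            f"unknown signal_kind {payload.get('signal_kind')!r} in model payload"
        )
    terms = tuple(
        (float(t["wavelength_nm"]), float(t["coefficient"]))
        for t in payload["terms"]
    )
    return LinearModel(
        intercept=float(payload["intercept"]),
        terms=terms,
        signal_kind=payload["signal_kind"],
        name=payload.get("name", ""),
        provenance=payload.get("provenance", {}),
    )


def published_model(name: str) -> LinearModel:
    """Load one of the six published models from the packaged registry."""
    if name not in PUBLISHED_MODEL_NAMES:
        raise InvalidInputError(
            f"unknown model {name!r}; valid names: {', '.join(PUBLISHED_MODEL_NAMES)}"
        )
    ref = resources.files("dialyspec").joinpath(f"models/{name}.json")
    payload = json.loads(ref.read_text(encoding="utf-8"))
    return _model_from_dict(payload)
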