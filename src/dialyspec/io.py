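"""File formats: wide spectra CSV, model JSON, and YAML run configs.

The spectra table is wide — one row per sample, wavelengths encoded in the
header (``A190``...``A380`` for absorbance, ``D190``...``D380`` for
first-derivative tables) — matching the regression design-matrix view.
CSV is UTF-8, comma-separated, decimal point.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibrate import LinearModel, _model_from_dict
from .errors import InvalidInputError, KindMismatchError, SchemaError
from .simulate import SimConfig
from .spectra import (
    ABSORBANCE,
    CALIBRATION,
    DERIVATIVE,
    VALIDATION,
    SampleRecord,
    SpectraDataset,
    Spectrum,
)

META_COLUMNS = [
    "sample_id",
    "session_id",
    "time_min",
    "split",
    "ua_lab_umol_l",
    "signal_kind",
]

_SPLIT_TO_CSV = {CALIBRATION: "cal", VALIDATION: "val"}
_SPLIT_FROM_CSV = {"cal": CALIBRATION, "val": VALIDATION}
_KIND_PREFIX = {ABSORBANCE: "A", DERIVATIVE: "D"}


def _wavelength_columns(kind: str, grid: np.ndarray) -> list[str]:
    prefix = _KIND_PREFIX[kind]
    return [f"{prefix}{int(w)}" for w in grid]


def write_spectra_csv(dataset: SpectraDataset, path) -> None:
    """Write a dataset to the wide spectra CSV format."""
    if not dataset.records:
        raise InvalidInputError("cannot write an empty dataset")
    kind = dataset.signal_kind
    grid = dataset.records[0].spectrum.wavelengths_nm
    cols = _wavelength_columns(kind, grid)
    rows = []
    for r in dataset.records:
        row = {
            "sample_id": r.sample_id,
            "session_id": r.spectrum.session_id,
            "time_min": r.spectrum.time_min,
            "split": _SPLIT_TO_CSV[r.split],
            "ua_lab_umol_l": r.ua_umol_l,
            "signal_kind": kind,
        }
        row.update(dict(zip(cols, r.spectrum.values)))
        rows.append(row)
    frame = pd.DataFrame(rows, columns=META_COLUMNS + cols)
    frame.to_csv(path, index=False, encoding="utf-8")


def read_spectra_csv(path, signal_kind: str | None = None) -> SpectraDataset:
    """Read a wide spectra CSV with strict header validation.

    ``signal_kind``, if given, must match the table's declared kind;
    feeding a derivative table where absorbance is required raises
    :class:`KindMismatchError`.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, encoding="utf-8")
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise SchemaError(f"cannot parse {path}: {exc}") from exc
    for col in META_COLUMNS:
        if col not in frame.columns:
            raise SchemaError(f"missing metadata column {col!r}")
    kinds = set(frame["signal_kind"].astype(str))
    if len(kinds) != 1:
        raise SchemaError(f"table mixes signal kinds: {sorted(kinds)}")
    table_kind = kinds.pop()
    if table_kind not in _KIND_PREFIX:
        raise SchemaError(f"unknown signal_kind value {table_kind!r}")
    if signal_kind is not None and signal_kind != table_kind:
        raise KindMismatchError(
            f"requested {signal_kind!r} but table holds {table_kind!r} spectra"
        )
    grid = np.arange(190, 381, dtype=float)
    expected = _wavelength_columns(table_kind, grid)
    data_cols = [c for c in frame.columns if c not in META_COLUMNS]
    if data_cols != expected:
        missing = [c for c in expected if c not in data_cols]
        if missing:
            raise SchemaError(f"missing/misordered wavelength column {missing[0]!r}")
        raise SchemaError(
            "wavelength columns must be contiguous 190-380 nm in order"
        )
    if frame["sample_id"].duplicated().any():
        dup = frame.loc[frame["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise SchemaError(f"duplicate sample_id {dup!r}")
    values = frame[expected].to_numpy()
    try:
        values = values.astype(float)
    except (TypeError, ValueError):
        for i, row in enumerate(values):
            for col, v in zip(expected, row):
                try:
                    float(v)
                except (TypeError, ValueError):
                    raise SchemaError(
                        f"non-numeric cell at row {i}, column {col!r}: {v!r}"
                    ) from None
        raise
    records = []
    for i, row in frame.iterrows():
        split = _SPLIT_FROM_CSV.get(str(row["split"]))
        if split is None:
            raise SchemaError(
                f"unknown split {row['split']!r} at row {i} (expected cal/val)"
            )
        spec = Spectrum(
            wavelengths_nm=grid,
            values=values[i],
            signal_kind=table_kind,
            session_id=str(row["session_id"]),
            time_min=float(row["time_min"]),
        )
        records.append(
            SampleRecord(
                spectrum=spec,
                ua_umol_l=float(row["ua_lab_umol_l"]),
                split=split,
                sample_id=str(row["sample_id"]),
            )
        )
    return SpectraDataset(records, {"source": str(path)})


def write_model_json(model: LinearModel, path) -> None:
    payload = {
        "name": model.name,
        "signal_kind": model.signal_kind,
        "intercept": model.intercept,
        "terms": [
            {"wavelength_nm": wl, "coefficient": b} for wl, b in model.terms
        ],
        "provenance": model.provenance,
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n", encoding="utf-8")


def read_model_json(path) -> LinearModel:
    try:
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise SchemaError(f"malformed model JSON {path}: {exc}") from exc
    try:
        return _model_from_dict(payload)
    except (KeyError, TypeError, ValueError) as exc:
        if isinstance(exc, KindMismatchError):
            raise
        raise SchemaError(f"invalid model schema in {path}: {exc}") from exc


def config_hash(params: dict) -> str:
    """Short content hash of a resolved parameter dict (for log lines)."""
    blob = json.dumps(params, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def save_sim_config(config: SimConfig, path) -> None:
    payload = {
        "n_sessions": config.n_sessions,
        "cal_count": config.cal_count,
        "noise_sd_au": config.noise_sd_au,
        "baseline_drift_sd": config.baseline_drift_sd,
        "path_length_cm": config.path_length_cm,
        "ua_range_umol_l": list(config.ua_range_umol_l),
        "sampling_times_min": list(config.sampling_times_min),
        "seed": config.seed,
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True), encoding="utf-8")


def load_sim_config(path) -> SimConfig:
    payload = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if not isinstance(payload, dict):
        raise SchemaError(f"config file {path} does not hold a mapping")
    kwargs = dict(payload)
    if "ua_range_umol_l" in kwargs:
        kwargs["ua_range_umol_l"] = tuple(kwargs["ua_range_umol_l"])
    if "sampling_times_min" in kwargs:
        kwargs["sampling_times_min"] = tuple(kwargs["sampling_times_min"])
    try:
        return SimConfig(**kwargs)
    except TypeError as exc:
        raise SchemaError(f"invalid config key in {path}: {exc}") from exc
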