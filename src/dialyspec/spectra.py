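"""Core in-memory containers: spectra, samples, and datasets.

A :class:`Spectrum` is one blank-referenced trace on the standard
190-380 nm grid (1 nm steps, 191 points).  Absorbance spectra carry AU,
first-derivative spectra AU/nm.  A :class:`SampleRecord` pairs a spectrum
with the uric-acid concentration of the same dialysate sample and a
calibration/validation split label assigned at the session level.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

from .errors import GridError, InvalidInputError, KindMismatchError

#: Standard acquisition grid: 190-380 nm inclusive, 1 nm steps (191 points).
WAVELENGTH_GRID = np.arange(190, 381, dtype=float)

ABSORBANCE = "absorbance"
DERIVATIVE = "derivative"
SIGNAL_KINDS = (ABSORBANCE, DERIVATIVE)

CALIBRATION = "calibration"
VALIDATION = "validation"
SPLITS = (CALIBRATION, VALIDATION)


def validate_grid(wavelengths: np.ndarray) -> None:
    """Check that a wavelength grid is contiguous and strictly increasing."""
    w = np.asarray(wavelengths, dtype=float)
    if w.ndim != 1 or w.size < 2:
        raise GridError("wavelength grid must be a 1-D array of >= 2 points")
    steps = np.diff(w)
    if not np.all(steps > 0):
        raise GridError("wavelength grid must be strictly increasing")
    if not np.allclose(steps, steps[0]):
        raise GridError("wavelength grid must be uniformly spaced")


@dataclass(frozen=True)
class Spectrum:
    """One trace on a uniform wavelength grid with session/time metadata.

    Parameters
    ----------
    wavelengths_nm : array of float
        Uniform, strictly increasing grid in nm.
    values : array of float
        AU for ``signal_kind="absorbance"``, AU/nm for ``"derivative"``.
    signal_kind : str
        ``"absorbance"`` or ``"derivative"``.
    session_id : str
        Dialysis session the sample belongs to.
    time_min : float
        Sampling time in minutes after session start.
    edge_mask : array of bool or None
        True where a filter handled the point with a one-sided fit.
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray
    signal_kind: str = ABSORBANCE
    session_id: str = ""
    time_min: float = 0.0
    edge_mask: np.ndarray | None = None

    def __post_init__(self):
        w = np.asarray(self.wavelengths_nm, dtype=float)
        v = np.asarray(self.values, dtype=float)
        validate_grid(w)
        if v.shape != w.shape:
            raise InvalidInputError(
                f"values length {v.size} does not match grid length {w.size}"
            )
        if self.signal_kind not in SIGNAL_KINDS:
            raise KindMismatchError(
                f"signal_kind must be one of {SIGNAL_KINDS}, got {self.signal_kind!r}"
            )
        object.__setattr__(self, "wavelengths_nm", w)
        object.__setattr__(self, "values", v)

    @property
    def spacing_nm(self) -> float:
        return float(self.wavelengths_nm[1] - self.wavelengths_nm[0])

    def value_at(self, wavelength_nm: float) -> float:
        """Value at an exact grid wavelength; raises GridError if absent."""
        idx = np.nonzero(np.isclose(self.wavelengths_nm, wavelength_nm))[0]
        if idx.size == 0:
            raise GridError(f"wavelength {wavelength_nm} nm not on spectrum grid")
        return float(self.values[idx[0]])

    def with_values(self, values, signal_kind=None, edge_mask=None) -> "Spectrum":
        return replace(
            self,
            values=np.asarray(values, dtype=float),
            signal_kind=signal_kind or self.signal_kind,
            edge_mask=edge_mask,
        )


@dataclass(frozen=True)
class SampleRecord:
    """A spectrum paired with the sample's uric-acid concentration (µmol/L)."""

    spectrum: Spectrum
    ua_umol_l: float
    split: str
    sample_id: str

    def __post_init__(self):
        if self.split not in SPLITS:
            raise InvalidInputError(
                f"split must be one of {SPLITS}, got {self.split!r}"
            )


@dataclass
class SpectraDataset:
    """A collection of sample records with provenance metadata.

    The calibration/validation split is assigned per dialysis session:
    every record of a session carries the same label.
    """

    records: list[SampleRecord]
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SampleRecord]:
        return iter(self.records)

    @property
    def signal_kind(self) -> str:
        kinds = {r.spectrum.signal_kind for r in self.records}
        if len(kinds) != 1:
            raise KindMismatchError(f"dataset mixes signal kinds: {sorted(kinds)}")
        return kinds.pop()

    def split_records(self, split: str) -> list[SampleRecord]:
        if split not in SPLITS:
            raise InvalidInputError(f"unknown split {split!r}")
        return [r for r in self.records if r.split == split]

    def session_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.spectrum.session_id, None)
        return list(seen)

    def design_matrix(
        self, wavelengths: Sequence[float], split: str | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Regression view: (X, y) with one column per requested wavelength."""
        recs = self.records if split is None else self.split_records(split)
        if not recs:
            raise InvalidInputError(f"no records in split {split!r}")
        grid = recs[0].spectrum.wavelengths_nm
        idx = []
        for wl in wavelengths:
            pos = np.nonzero(np.isclose(grid, wl))[0]
            if pos.size == 0:
                raise GridError(f"wavelength {wl} nm not on dataset grid")
            idx.append(pos[0])
        X = np.array([[r.spectrum.values[i] for i in idx] for r in recs])
        y = np.array([r.ua_umol_l for r in recs])
        return X, y

    def map_spectra(self, fn) -> "SpectraDataset":
        """Apply ``fn(Spectrum) -> Spectrum`` to every record."""
        new = [
            SampleRecord(fn(r.spectrum), r.ua_umol_l, r.split, r.sample_id)
            for r in self.records
        ]
        return SpectraDataset(new, dict(self.meta))
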