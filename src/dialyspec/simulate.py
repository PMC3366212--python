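"""Synthetic spent-dialysate UV spectra with intradialytic washout kinetics.

The simulator builds blank-referenced absorbance spectra as Beer-Lambert
mixtures of a small chromophore library.  Each chromophore's extinction
trace is a sum of Gaussian bands; concentrations in spent dialysate decline
mono-exponentially over the session as solutes are cleared from blood.
The default library places the uric-acid chromophore's absorbance maximum
near 294 nm with a trough near 265 nm, and makes uric acid the dominant
absorber in the 280-310 nm window, while two interfering chromophores
(a strong short-wavelength absorber and a weak broad one) keep
single-wavelength estimation imperfect.

Spectra are relative to pure (pre-session) dialysate, so the solvent
contributes nothing; noise is i.i.d. additive Gaussian on absorbance plus
an optional per-spectrum constant baseline offset emulating an imperfect
blank reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError, InvalidParameterError
from .spectra import (
    ABSORBANCE,
    CALIBRATION,
    VALIDATION,
    WAVELENGTH_GRID,
    SampleRecord,
    SpectraDataset,
    Spectrum,
    validate_grid,
)

#: Default sampling schedule (minutes after session start).
DEFAULT_SAMPLING_TIMES = (10.0, 60.0, 120.0, 180.0, 240.0)

#: Default range for randomized initial uric-acid concentration, µmol/L.
DEFAULT_UA_RANGE = (30.0, 160.0)


@dataclass(frozen=True)
class Chromophore:
    """A UV chromophore parameterized as a sum of Gaussian extinction bands.

    ``bands`` is a list of ``(center_nm, width_nm, amplitude)`` tuples where
    amplitude is the peak molar extinction in AU per (µmol/L)·cm and width
    is the Gaussian sigma in nm.  ``baseline`` is a flat non-negative
    extinction floor.
    """

    name: str
    bands: tuple[tuple[float, float, float], ...]
    baseline: float = 0.0

    def __post_init__(self):
        for center, width, amplitude in self.bands:
            if width <= 0:
                raise InvalidParameterError(
                    f"chromophore {self.name!r}: band width must be > 0, got {width}"
                )
            if amplitude < 0:
                raise InvalidParameterError(
                    f"chromophore {self.name!r}: band amplitude must be >= 0"
                )
        if self.baseline < 0:
            raise InvalidParameterError(
                f"chromophore {self.name!r}: baseline must be >= 0"
            )


@dataclass(frozen=True)
class SessionProfile:
    """Initial concentrations and washout rates for one dialysis session."""

    session_id: str
    initial_concentrations: dict[str, float]
    decay_rate_per_min: dict[str, float]
    sampling_times_min: tuple[float, ...] = DEFAULT_SAMPLING_TIMES

    def __post_init__(self):
        for name, c0 in self.initial_concentrations.items():
            if c0 < 0:
                raise InvalidParameterError(
                    f"initial concentration of {name!r} must be >= 0, got {c0}"
                )
        for name, k in self.decay_rate_per_min.items():
            if k < 0:
                raise InvalidParameterError(
                    f"decay rate of {name!r} must be >= 0, got {k}"
                )
        t = np.asarray(self.sampling_times_min, dtype=float)
        if t.size == 0 or np.any(np.diff(t) <= 0):
            raise InvalidParameterError("sampling times must be strictly increasing")


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters for a full multi-session dataset."""

    n_sessions: int = 188
    cal_count: int = 75
    noise_sd_au: float = 0.005
    baseline_drift_sd: float = 0.01
    path_length_cm: float = 1.0
    ua_range_umol_l: tuple[float, float] = DEFAULT_UA_RANGE
    sampling_times_min: tuple[float, ...] = DEFAULT_SAMPLING_TIMES
    seed: int = 0
    wavelength_grid: np.ndarray = field(
        default_factory=lambda: WAVELENGTH_GRID.copy(), compare=False, repr=False
    )

    def __post_init__(self):
        validate_grid(self.wavelength_grid)
        if self.path_length_cm <= 0:
            raise InvalidParameterError("path length must be > 0")
        if self.noise_sd_au < 0 or self.baseline_drift_sd < 0:
            raise InvalidParameterError("noise levels must be >= 0")
        if self.n_sessions < 1:
            raise InvalidParameterError("n_sessions must be >= 1")
        if not (0 < self.cal_count < self.n_sessions):
            raise InvalidInputError(
                f"cal_count must satisfy 0 < cal_count < n_sessions "
                f"({self.cal_count} vs {self.n_sessions})"
            )


UA_NAME = "uric_acid"


def default_library() -> list[Chromophore]:
    """Chromophore library shipped as the simulator default.

    * ``uric_acid`` — two bands (~235 and ~294 nm) giving the characteristic
      294 nm maximum and 265 nm trough; peak extinction at 294 nm close to
      uric acid's molar absorptivity (~12.6e3 L/(mol·cm)).
    * ``uv_low`` — strong absorber below 260 nm (small UV-absorbing uremic
      solutes pooled into one species).
    * ``broad`` — weak, broad mid-UV absorber overlapping the uric-acid
      window, so no single wavelength is a perfect uric-acid probe.
    """
    return [
        Chromophore(
            UA_NAME,
            bands=((235.0, 14.0, 0.0105), (294.0, 15.0, 0.0126)),
        ),
        Chromophore("uv_low", bands=((225.0, 16.0, 0.009),)),
        Chromophore("broad", bands=((275.0, 50.0, 0.0018),)),
    ]


#: Default washout rates per chromophore (1/min); uric acid clears fastest.
DEFAULT_DECAY_RATES = {UA_NAME: 0.005, "uv_low": 0.006, "broad": 0.003}

#: Default ranges for randomized initial interferent concentrations (µmol/L).
DEFAULT_INTERFERENT_RANGES = {"uv_low": (50.0, 250.0), "broad": (20.0, 120.0)}


def band_extinction(chromophore: Chromophore, grid: np.ndarray) -> np.ndarray:
    """Extinction trace of a chromophore on a wavelength grid.

    Returns AU per (µmol/L)·cm at each grid wavelength: the sum of the
    chromophore's Gaussian bands plus its flat baseline.
    """
    validate_grid(grid)
    w = np.asarray(grid, dtype=float)
    trace = np.full(w.shape, chromophore.baseline, dtype=float)
    for center, width, amplitude in chromophore.bands:
        if width <= 0:
            raise InvalidParameterError(f"band width must be > 0, got {width}")
        trace += amplitude * np.exp(-0.5 * ((w - center) / width) ** 2)
    return trace


def _library_map(library: list[Chromophore]) -> dict[str, Chromophore]:
    return {c.name: c for c in library}


def noiseless_absorbance(
    concentrations: dict[str, float],
    library: list[Chromophore],
    grid: np.ndarray,
    path_length_cm: float = 1.0,
) -> np.ndarray:
    """Beer-Lambert mixture absorbance A(λ) = Σ ε_j(λ)·c_j·l."""
    lib = _library_map(library)
    total = np.zeros(np.asarray(grid).shape, dtype=float)
    for name, conc in concentrations.items():
        if name not in lib:
            raise InvalidInputError(f"chromophore {name!r} not in library")
        total += band_extinction(lib[name], grid) * conc * path_length_cm
    return total


def simulate_session(
    profile: SessionProfile,
    library: list[Chromophore],
    config: SimConfig,
    rng: np.random.Generator,
    split: str = CALIBRATION,
) -> list[SampleRecord]:
    """Simulate all samples of one session.

    At sampling time t each chromophore's dialysate concentration is
    c(t) = c0·exp(-k·t); the spectrum is the Beer-Lambert mixture plus
    i.i.d. Gaussian noise and an optional per-spectrum baseline offset.
    The record stores the true uric-acid concentration at t.
    """
    lib = _library_map(library)
    missing = set(profile.initial_concentrations) - set(lib)
    if missing:
        raise InvalidInputError(
            f"profile references chromophores not in library: {sorted(missing)}"
        )
    grid = config.wavelength_grid
    extinctions = {
        name: band_extinction(lib[name], grid)
        for name in profile.initial_concentrations
    }
    records = []
    for t in profile.sampling_times_min:
        spectrum_values = np.zeros(grid.shape)
        ua_true = 0.0
        for name, c0 in profile.initial_concentrations.items():
            k = profile.decay_rate_per_min.get(name, 0.0)
            c_t = c0 * np.exp(-k * t)
            spectrum_values += extinctions[name] * c_t * config.path_length_cm
            if name == UA_NAME:
                ua_true = c_t
        if config.baseline_drift_sd > 0:
            spectrum_values = spectrum_values + rng.normal(
                0.0, config.baseline_drift_sd
            )
        if config.noise_sd_au > 0:
            spectrum_values = spectrum_values + rng.normal(
                0.0, config.noise_sd_au, size=grid.shape
            )
        spec = Spectrum(
            wavelengths_nm=grid,
            values=spectrum_values,
            signal_kind=ABSORBANCE,
            session_id=profile.session_id,
            time_min=float(t),
        )
        records.append(
            SampleRecord(
                spectrum=spec,
                ua_umol_l=float(ua_true),
                split=split,
                sample_id=f"{profile.session_id}_t{int(t)}",
            )
        )
    return records


def random_profile(
    session_id: str,
    config: SimConfig,
    rng: np.random.Generator,
    interferent_ranges: dict[str, tuple[float, float]] | None = None,
    decay_rates: dict[str, float] | None = None,
) -> SessionProfile:
    """Draw one session profile with randomized initial concentrations."""
    ranges = dict(DEFAULT_INTERFERENT_RANGES if interferent_ranges is None
                  else interferent_ranges)
    rates = dict(DEFAULT_DECAY_RATES if decay_rates is None else decay_rates)
    lo, hi = config.ua_range_umol_l
    concs = {UA_NAME: float(rng.uniform(lo, hi))}
    for name, (a, b) in ranges.items():
        concs[name] = float(rng.uniform(a, b))
    return SessionProfile(
        session_id=session_id,
        initial_concentrations=concs,
        decay_rate_per_min=rates,
        sampling_times_min=config.sampling_times_min,
    )


def simulate_dataset(
    config: SimConfig,
    library: list[Chromophore] | None = None,
    profile_generator=None,
) -> SpectraDataset:
    """Simulate a full dataset with a session-level calibration split.

    ``cal_count`` sessions are assigned (at random, seeded) to the
    calibration split; all samples of one session share its label.
    ``profile_generator(session_id, config, rng) -> SessionProfile`` may be
    supplied to override the default randomized profiles.
    """
    library = default_library() if library is None else library
    gen = random_profile if profile_generator is None else profile_generator
    rng = np.random.default_rng(config.seed)
    cal_sessions = set(
        rng.choice(config.n_sessions, size=config.cal_count, replace=False).tolist()
    )
    records: list[SampleRecord] = []
    for i in range(config.n_sessions):
        session_id = f"s{i:04d}"
        split = CALIBRATION if i in cal_sessions else VALIDATION
        profile = gen(session_id, config, rng)
        records.extend(simulate_session(profile, library, config, rng, split))
    meta = {
        "seed": config.seed,
        "n_sessions": config.n_sessions,
        "cal_count": config.cal_count,
        "noise_sd_au": config.noise_sd_au,
        "baseline_drift_sd": config.baseline_drift_sd,
        "path_length_cm": config.path_length_cm,
    }
    return SpectraDataset(records, meta)


def ua_share(
    concentrations: dict[str, float],
    library: list[Chromophore],
    grid: np.ndarray = WAVELENGTH_GRID,
    window: tuple[float, float] = (280.0, 310.0),
) -> float:
    """Uric acid's average share of total noiseless absorbance in a window.

    Computed as UA-only absorbance divided by total mixture absorbance,
    averaged over grid wavelengths inside ``window``.
    """
    total = noiseless_absorbance(concentrations, library, grid)
    ua_only = noiseless_absorbance(
        {UA_NAME: concentrations.get(UA_NAME, 0.0)}, library, grid
    )
    w = np.asarray(grid, dtype=float)
    mask = (w >= window[0]) & (w <= window[1])
    if not np.any(total[mask] > 0):
        raise InvalidInputError("total absorbance is zero in the requested window")
    return float(np.mean(ua_only[mask] / total[mask]))
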