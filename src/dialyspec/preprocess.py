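"""Savitzky-Golay smoothing and derivative filtering of spectra.

The filter is implemented from its defining least-squares problem: inside a
sliding window of odd length, a polynomial of the requested order is fitted
to the samples, and the filtered value is the fitted polynomial's value (or
``deriv``-th derivative) at the window centre.  Because the fit is linear in
the data, the interior of the output is a fixed convolution whose weights
come from the normal equations; they are computed here directly rather than
taken from a table or a library routine.

Derivatives are normalised per nm (weights carry a ``deriv!/spacing^deriv``
factor), so a first-derivative spectrum has physical units AU/nm regardless
of the grid spacing.  Edge points — the first and last ``(window-1)/2``
samples — are handled by refitting the same local polynomial one-sidedly on
the first/last full window and evaluating it at the edge position; no data
are fabricated by padding, and edge points are flagged in the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import factorial

import numpy as np

from .errors import InvalidInputError, InvalidParameterError
from .spectra import ABSORBANCE, DERIVATIVE, Spectrum


def _validate_params(window: int, polyorder: int, deriv: int, spacing_nm: float):
    if window < 3 or window % 2 == 0:
        raise InvalidParameterError(f"window must be odd and >= 3, got {window}")
    if not 0 <= polyorder < window:
        raise InvalidParameterError(
            f"polyorder must satisfy 0 <= polyorder < window, got {polyorder}"
        )
    if not 0 <= deriv <= polyorder:
        raise InvalidParameterError(
            f"deriv must satisfy 0 <= deriv <= polyorder, got {deriv}"
        )
    if spacing_nm <= 0:
        raise InvalidParameterError(f"spacing must be > 0, got {spacing_nm}")


def _lsq_weights(offsets: np.ndarray, polyorder: int, deriv: int,
                 spacing_nm: float) -> np.ndarray:
    """Weights of the least-squares polynomial's deriv-th derivative at 0.

    ``offsets`` are sample positions in grid steps relative to the
    evaluation point.  Row ``deriv`` of the pseudo-inverse of the Vandermonde
    matrix gives the fitted polynomial coefficient of z^deriv as a linear
    map of the data; the derivative at z = 0 is deriv! times it.
    """
    A = np.vander(offsets.astype(float), polyorder + 1, increasing=True)
    pinv = np.linalg.pinv(A)
    return pinv[deriv] * factorial(deriv) / spacing_nm**deriv


def sg_coefficients(window: int, polyorder: int, deriv: int = 0,
                    spacing_nm: float = 1.0) -> np.ndarray:
    """Savitzky-Golay convolution weights for the window centre."""
    _validate_params(window, polyorder, deriv, spacing_nm)
    half = (window - 1) // 2
    offsets = np.arange(-half, half + 1)
    return _lsq_weights(offsets, polyorder, deriv, spacing_nm)


@dataclass(frozen=True)
class SGFilter:
    """A Savitzky-Golay window/order/derivative specification.

    The default (9-point window, quadratic, ``deriv=0``) is the classic
    smoothing convolute; ``deriv=1`` yields the per-nm first derivative.
    """

    window: int = 9
    polyorder: int = 2
    deriv: int = 0
    spacing_nm: float = 1.0
    weights: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        object.__setattr__(
            self,
            "weights",
            sg_coefficients(self.window, self.polyorder, self.deriv,
                            self.spacing_nm),
        )

    @property
    def half(self) -> int:
        return (self.window - 1) // 2


def sg_apply(spectrum: Spectrum, filt: SGFilter) -> Spectrum:
    """Apply a Savitzky-Golay filter to a spectrum.

    Interior points are the centred convolution with ``filt.weights``;
    the first/last ``(window-1)/2`` points are one-sided refits of the same
    local polynomial on the first/last full window, flagged in
    ``edge_mask``.  Output ``signal_kind`` is ``"derivative"`` when
    ``deriv >= 1``.
    """
    n = spectrum.values.size
    if n < filt.window:
        raise InvalidInputError(
            f"spectrum has {n} points, shorter than window {filt.window}"
        )
    if not np.isclose(spectrum.spacing_nm, filt.spacing_nm):
        raise InvalidInputError(
            f"grid spacing {spectrum.spacing_nm} nm does not match filter "
            f"spacing {filt.spacing_nm} nm"
        )
    if spectrum.signal_kind != ABSORBANCE and filt.deriv >= 1:
        raise InvalidInputError(
            "derivative filtering expects an absorbance spectrum"
        )
    y = spectrum.values
    half = filt.half
    out = np.empty(n)
    # interior: centred convolution
    for i in range(half, n - half):
        out[i] = filt.weights @ y[i - half : i + half + 1]
    # edges: one-sided refit of the local polynomial, no padding
    window_idx = np.arange(filt.window)
    for i in range(half):
        w = _lsq_weights(window_idx - i, filt.polyorder, filt.deriv,
                         filt.spacing_nm)
        out[i] = w @ y[: filt.window]
    for i in range(n - half, n):
        start = n - filt.window
        w = _lsq_weights(window_idx - (i - start), filt.polyorder, filt.deriv,
                         filt.spacing_nm)
        out[i] = w @ y[start:]
    edge_mask = np.zeros(n, dtype=bool)
    edge_mask[:half] = True
    edge_mask[n - half :] = True
    kind = DERIVATIVE if filt.deriv >= 1 else spectrum.signal_kind
    return spectrum.with_values(out, signal_kind=kind, edge_mask=edge_mask)
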