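"""Spectral preprocessing: Savitzky-Golay smoothing and the optional
reflectance -> absorbance transform.

Interior points use the standard centered S-G convolution (local polynomial
least squares).  Edge points are refit on the truncated one-sided window —
the first/last ``window // 2`` points each get their own least-squares
polynomial over the grid points actually available; no reflection padding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .errors import ConfigurationError, DataError
from .spectra import SpectraSet


@dataclass(frozen=True)
class SGParams:
    """Savitzky-Golay parameters: full window point count and polynomial degree."""

    window: int = 11
    polyorder: int = 2

    def validate(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ConfigurationError("window must be odd and >= 3")
        if not 0 <= self.polyorder < self.window:
            raise ConfigurationError("polyorder must satisfy 0 <= polyorder < window")


def _edge_hat(positions: np.ndarray, at: int, polyorder: int) -> np.ndarray:
    """Row vector h with fitted_value(at) = data @ h for a poly LSQ on positions."""
    a = np.vander(positions.astype(float), polyorder + 1, increasing=True)
    row = np.vander(np.array([float(at)]), polyorder + 1, increasing=True)
    return (row @ np.linalg.pinv(a)).ravel()


def savitzky_golay_smooth(spectra: SpectraSet, params: SGParams = SGParams()) -> SpectraSet:
    """Smooth every spectrum; grid, nitrogen and metadata pass through."""
    params.validate()
    p = spectra.n_wavelengths
    if params.window > p:
        raise ConfigurationError(f"window {params.window} exceeds {p} spectral points")

    r = spectra.reflectance
    half = params.window // 2
    # interior: centered convolution (mode irrelevant away from edges)
    out = savgol_filter(r, params.window, params.polyorder, axis=1, mode="interp")
    # edges: truncated one-sided refit
    for k in range(half):
        left = np.arange(0, k + half + 1)
        out[:, k] = r[:, left] @ _edge_hat(left, k, params.polyorder)
        right = np.arange(p - 1 - k - half, p)
        out[:, p - 1 - k] = r[:, right] @ _edge_hat(right, p - 1 - k, params.polyorder)
    return spectra.with_reflectance(out)


def reflectance_to_absorbance(spectra: SpectraSet) -> SpectraSet:
    """Apparent absorbance log10(1/R); requires strictly positive reflectance."""
    r = spectra.reflectance
    if np.any(r <= 0):
        raise DataError("reflectance must be strictly positive for absorbance")
    return spectra.with_reflectance(np.log10(1.0 / r))


def absorbance_to_reflectance(spectra: SpectraSet) -> SpectraSet:
    """Inverse of :func:`reflectance_to_absorbance`."""
    return spectra.with_reflectance(np.power(10.0, -spectra.reflectance))
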