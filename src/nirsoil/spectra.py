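"""The SpectraSet container: wavelength grid, reflectance matrix, targets, metadata.

A SpectraSet is the X/y of every downstream model: ``reflectance`` is the
n x P matrix of diffuse-reflectance values on a shared wavelength grid and
``nitrogen`` the per-sample nitrogen content in g/kg.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError

#: default spectral grid: 400 points spanning 900-1700 nm
WL_MIN = 900.0
WL_MAX = 1700.0
N_POINTS = 400

_META_COLS = ["sample_id", "soil_type", "treatment", "nitrogen_g_kg"]


@dataclass
class SpectraSet:
    """Immutable-by-convention bundle of spectra and per-sample metadata."""

    wavelengths: np.ndarray  # (P,) nm, strictly increasing
    reflectance: np.ndarray  # (n, P)
    nitrogen: np.ndarray  # (n,) g/kg
    soil_type: np.ndarray  # (n,) labels
    treatment: np.ndarray  # (n,) labels
    sample_id: np.ndarray  # (n,) unique labels

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.atleast_2d(np.asarray(self.reflectance, dtype=float))
        self.nitrogen = np.asarray(self.nitrogen, dtype=float)
        self.soil_type = np.asarray(self.soil_type, dtype=object)
        self.treatment = np.asarray(self.treatment, dtype=object)
        self.sample_id = np.asarray(self.sample_id, dtype=object)

        n, p = self.reflectance.shape
        if self.wavelengths.ndim != 1 or self.wavelengths.size != p:
            raise DataError(f"wavelength grid length {self.wavelengths.size} != {p} columns")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise DataError("wavelengths must be strictly increasing")
        for name in ("nitrogen", "soil_type", "treatment", "sample_id"):
            if getattr(self, name).shape != (n,):
                raise DataError(f"{name} must have length {n}")
        if not np.all(np.isfinite(self.reflectance)):
            raise DataError("reflectance contains non-finite values")
        if not np.all(np.isfinite(self.nitrogen)) or np.any(self.nitrogen < 0):
            raise DataError("nitrogen must be finite and non-negative")
        if len(set(self.sample_id)) != n:
            raise DataError("sample_id values must be unique")

    # ------------------------------------------------------------------ shape
    @property
    def n_samples(self) -> int:
        return self.reflectance.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.reflectance.shape[1]

    def band_index(self, nm: float) -> int:
        """Index of the grid point nearest to ``nm``."""
        return int(np.argmin(np.abs(self.wavelengths - nm)))

    # ------------------------------------------------------------ derivations
    def with_reflectance(self, reflectance: np.ndarray) -> "SpectraSet":
        """Copy with the spectral matrix replaced (same grid and metadata)."""
        return _dc_replace(self, reflectance=np.asarray(reflectance, dtype=float))

    def subset(self, idx) -> "SpectraSet":
        idx = np.asarray(idx, dtype=int)
        return SpectraSet(
            wavelengths=self.wavelengths,
            reflectance=self.reflectance[idx],
            nitrogen=self.nitrogen[idx],
            soil_type=self.soil_type[idx],
            treatment=self.treatment[idx],
            sample_id=self.sample_id[idx],
        )

    # -------------------------------------------------------------------- I/O
    def to_csv(self, path: str | Path) -> None:
        """Write the wide CSV layout.

        Header is ``sample_id,soil_type,treatment,nitrogen_g_kg,R_<wl>,...``
        with wavelengths printed to 2 decimals.  Reflectance values are
        written at full precision so the matrix round-trips bitwise.
        """
        cols = {
            "sample_id": self.sample_id,
            "soil_type": self.soil_type,
            "treatment": self.treatment,
            "nitrogen_g_kg": self.nitrogen,
        }
        df = pd.DataFrame(cols)
        spec = pd.DataFrame(
            self.reflectance, columns=[f"R_{w:.2f}" for w in self.wavelengths]
        )
        pd.concat([df, spec], axis=1).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpectraSet":
        """Read the wide CSV layout written by :meth:`to_csv`.

        The header stores wavelengths rounded to 2 decimals; for a uniform
        grid the exact values are rebuilt as ``linspace(first, last, P)`` so
        a write/read round trip reproduces the generator grid bitwise.
        """
        df = pd.read_csv(path, float_precision="round_trip")
        spec_cols = [c for c in df.columns if c.startswith("R_")]
        if not spec_cols:
            raise DataError("no reflectance columns (R_<wavelength>) found")
        wl_printed = np.array([float(c[2:]) for c in spec_cols])
        steps = np.diff(wl_printed)
        if wl_printed.size > 2 and np.allclose(steps, steps[0], atol=0.02):
            wl = np.linspace(wl_printed[0], wl_printed[-1], wl_printed.size)
        else:
            wl = wl_printed
        return cls(
            wavelengths=wl,
            reflectance=df[spec_cols].to_numpy(dtype=float),
            nitrogen=df["nitrogen_g_kg"].to_numpy(dtype=float),
            soil_type=df["soil_type"].to_numpy(dtype=object),
            treatment=df["treatment"].to_numpy(dtype=object),
            sample_id=df["sample_id"].astype(str).to_numpy(dtype=object),
        )


def concat(sets: list[SpectraSet]) -> SpectraSet:
    """Stack SpectraSets sharing one wavelength grid."""
    if not sets:
        raise DataError("nothing to concatenate")
    wl = sets[0].wavelengths
    for s in sets[1:]:
        if not np.array_equal(s.wavelengths, wl):
            raise DataError("wavelength grids differ")
    return SpectraSet(
        wavelengths=wl,
        reflectance=np.vstack([s.reflectance for s in sets]),
        nitrogen=np.concatenate([s.nitrogen for s in sets]),
        soil_type=np.concatenate([s.soil_type for s in sets]),
        treatment=np.concatenate([s.treatment for s in sets]),
        sample_id=np.concatenate([s.sample_id for s in sets]),
    )
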