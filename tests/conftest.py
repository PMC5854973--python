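"""Shared fixtures and helpers."""

from __future__ import annotations

import numpy as np
import pytest

from nirsoil import SoilProfile, SpectraSet


def make_spectra(
    n: int = 8,
    p: int = 12,
    seed: int = 0,
    nitrogen: np.ndarray | None = None,
    reflectance: np.ndarray | None = None,
) -> SpectraSet:
    """Small ad-hoc SpectraSet on a uniform toy grid."""
    rng = np.random.default_rng(seed)
    if reflectance is None:
        reflectance = 0.5 + 0.1 * rng.standard_normal((n, p))
    reflectance = np.atleast_2d(np.asarray(reflectance, dtype=float))
    n, p = reflectance.shape
    if nitrogen is None:
        nitrogen = rng.uniform(0.1, 2.0, size=n)
    return SpectraSet(
        wavelengths=np.linspace(900.0, 1700.0, p),
        reflectance=reflectance,
        nitrogen=np.asarray(nitrogen, dtype=float),
        soil_type=np.full(n, "black", dtype=object),
        treatment=np.full(n, "50C", dtype=object),
        sample_id=np.array([f"s{i:03d}" for i in range(n)], dtype=object),
    )


def noiseless_profile(
    sensitivity: float = 0.1,
    n_gradients: int = 11,
    replicates: int = 16,
    soil: str = "loess",
    treatment: str = "50C",
) -> SoilProfile:
    """Single nitrogen band, no static bands, no water band, no noise."""
    return SoilProfile(
        soil_name=soil,
        treatment=treatment,
        baseline_level=0.6,
        baseline_slope=-2e-5,
        bands=(),
        nitrogen_band=(1160.0, 25.0, sensitivity),
        water_band=(1385.0, 45.0, 0.0),
        scatter_sd=0.0,
        noise_sd=0.0,
        nitrogen_min=0.09,
        nitrogen_max=0.93,
        n_gradients=n_gradients,
        replicates=replicates,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
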