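"""Synthetic soil spectra generator.

No public soil NIR dataset accompanies the analysis this package supports, so
models are exercised on simulated diffuse-reflectance spectra with the same
statistical structure: three soil archetypes (black, loess, calcium), four
drying treatments (25C placement; 50C, 80C, 95C drying), a broad water O-H
feature near 1385 nm whose amplitude grows as drying gets milder, and one
nitrogen-sensitive absorption band per soil (black ~1470 nm, loess ~1160 nm,
calcium ~1145 nm).

The generative model for one sample with nitrogen content N (g/kg) is

    R(w) = s * [ b0 + b1*(w - 900)
                 - sum_static depth * G(w; c, width)
                 - sens * N * G(w; c_N, width_N)
                 - amp * G(w; c_w, width_w) ]  + eps(w)

where G is a unit-height Gaussian, s is a per-sample multiplicative
log-normal scatter factor (sd of log = scatter_sd) and eps is i.i.d.
Gaussian noise per grid point.  Reflectance is floored at CLIP_FLOOR.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import ConfigurationError
from .spectra import N_POINTS, WL_MAX, WL_MIN, SpectraSet

SOILS = ("black", "loess", "calcium")
TREATMENTS = ("25C", "50C", "80C", "95C")

#: reflectance never drops below this after clipping
CLIP_FLOOR = 1e-4

#: default stochastic scales; 25C profiles get 3x noise and 2x scatter to
#: reflect the degraded measurement conditions of undried soil (a modeling
#: choice, not a measured constant)
DEFAULT_SCATTER_SD = 0.01
DEFAULT_NOISE_SD = 0.002
AMBIENT_NOISE_FACTOR = 3.0
AMBIENT_SCATTER_FACTOR = 2.0


@dataclass(frozen=True)
class SoilProfile:
    """Generative parameters for one soil archetype under one treatment."""

    soil_name: str
    treatment: str
    baseline_level: float  # unitless reflectance in (0, 1)
    baseline_slope: float  # reflectance per nm
    bands: tuple[tuple[float, float, float], ...]  # (center nm, width nm, depth)
    nitrogen_band: tuple[float, float, float]  # (center nm, width nm, sensitivity per g/kg)
    water_band: tuple[float, float, float]  # (center nm, width nm, amplitude)
    scatter_sd: float = DEFAULT_SCATTER_SD
    noise_sd: float = DEFAULT_NOISE_SD
    nitrogen_min: float = 0.0
    nitrogen_max: float = 1.0
    n_gradients: int = 11
    replicates: int = 16

    def validate(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ConfigurationError(f"unknown treatment {self.treatment!r}")
        if not 0.0 < self.baseline_level < 1.0:
            raise ConfigurationError("baseline_level must lie in (0, 1)")
        for c, w, d in self.bands:
            if w <= 0 or d < 0:
                raise ConfigurationError("static bands need width > 0 and depth >= 0")
        for name, (c, w, a) in (
            ("nitrogen_band", self.nitrogen_band),
            ("water_band", self.water_band),
        ):
            if w <= 0 or a < 0:
                raise ConfigurationError(f"{name} needs width > 0 and amplitude >= 0")
        if self.scatter_sd < 0 or self.noise_sd < 0:
            raise ConfigurationError("scatter_sd and noise_sd must be >= 0")
        if not self.nitrogen_min < self.nitrogen_max:
            raise ConfigurationError("nitrogen_min must be < nitrogen_max")
        if self.nitrogen_min < 0:
            raise ConfigurationError("nitrogen must be >= 0")
        if self.n_gradients < 2:
            raise ConfigurationError("n_gradients must be >= 2")
        if self.replicates < 1:
            raise ConfigurationError("replicates must be >= 1")


def _gauss(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    """Unit-height Gaussian line shape."""
    return np.exp(-0.5 * ((wl - center) / width) ** 2)


def clean_reflectance(profile: SoilProfile, wl: np.ndarray, nitrogen: np.ndarray) -> np.ndarray:
    """Deterministic part of the generative model, one row per sample."""
    base = profile.baseline_level + profile.baseline_slope * (wl - WL_MIN)
    for c, w, d in profile.bands:
        base = base - d * _gauss(wl, c, w)
    c_w, w_w, amp = profile.water_band
    base = base - amp * _gauss(wl, c_w, w_w)
    c_n, w_n, sens = profile.nitrogen_band
    return base[None, :] - np.outer(nitrogen, sens * _gauss(wl, c_n, w_n))


def nitrogen_levels(profile: SoilProfile) -> np.ndarray:
    """The n_gradients equally spaced nitrogen values, min to max inclusive."""
    return np.linspace(profile.nitrogen_min, profile.nitrogen_max, profile.n_gradients)


def generate_soil_spectra(
    profile: SoilProfile, seed: int, n_points: int = N_POINTS
) -> SpectraSet:
    """Draw one synthetic soil/treatment cell.

    Returns ``n_gradients * replicates`` samples on the uniform
    ``[WL_MIN, WL_MAX]`` grid.  The RNG is consumed in a fixed order
    (scatter first, then noise) so equal (profile, seed) pairs reproduce
    the output bitwise.
    """
    profile.validate()
    rng = np.random.default_rng(seed)
    wl = np.linspace(WL_MIN, WL_MAX, n_points)

    levels = nitrogen_levels(profile)
    nitrogen = np.repeat(levels, profile.replicates)
    n = nitrogen.size

    clean = clean_reflectance(profile, wl, nitrogen)
    scatter = np.exp(rng.normal(0.0, profile.scatter_sd, size=n)) if profile.scatter_sd > 0 else np.ones(n)
    noise = rng.normal(0.0, profile.noise_sd, size=(n, n_points)) if profile.noise_sd > 0 else 0.0
    refl = np.maximum(scatter[:, None] * clean + noise, CLIP_FLOOR)

    sample_id = np.array(
        [
            f"{profile.soil_name}-{profile.treatment}-g{g:02d}-r{r:02d}"
            for g in range(profile.n_gradients)
            for r in range(profile.replicates)
        ],
        dtype=object,
    )
    return SpectraSet(
        wavelengths=wl,
        reflectance=refl,
        nitrogen=nitrogen,
        soil_type=np.full(n, profile.soil_name, dtype=object),
        treatment=np.full(n, profile.treatment, dtype=object),
        sample_id=sample_id,
    )


# --------------------------------------------------------------------------
# Default profile registry
# --------------------------------------------------------------------------

# per-soil nitrogen ranges (g/kg)
_N_RANGES = {"black": (0.46, 2.15), "loess": (0.09, 0.93), "calcium": (0.32, 1.17)}

# nitrogen-sensitive band per soil: (center nm, width nm, sensitivity per g/kg)
_N_BANDS = {
    "black": (1470.0, 30.0, 0.05),
    "loess": (1160.0, 25.0, 0.10),
    "calcium": (1145.0, 25.0, 0.09),
}

# water O-H amplitude at 1385 nm per soil x treatment; strictly decreasing
# with drying temperature (residual moisture), black soil wettest at 25C
_WATER_AMP = {
    "black": {"25C": 0.30, "50C": 0.10, "80C": 0.05, "95C": 0.04},
    "loess": {"25C": 0.12, "50C": 0.06, "80C": 0.035, "95C": 0.03},
    "calcium": {"25C": 0.15, "50C": 0.07, "80C": 0.04, "95C": 0.035},
}
_WATER_WIDTH = 45.0

_BASELINES = {"black": 0.40, "loess": 0.65, "calcium": 0.60}
_SLOPES = {"black": -2e-5, "loess": -3e-5, "calcium": -2.5e-5}

# soil-specific static absorption features (center nm, width nm, depth)
_STATIC_BANDS = {
    "black": ((1200.0, 60.0, 0.05), (1600.0, 80.0, 0.04)),
    "loess": ((1000.0, 50.0, 0.03), (1600.0, 70.0, 0.03)),
    "calcium": ((1300.0, 60.0, 0.03), (1620.0, 70.0, 0.04)),
}


def default_profiles(
    scatter_sd: float = DEFAULT_SCATTER_SD,
    noise_sd: float = DEFAULT_NOISE_SD,
    n_gradients: int = 11,
    replicates: int = 16,
) -> list[SoilProfile]:
    """The 12 built-in profiles: 3 soils x 4 treatments.

    25C profiles get ``AMBIENT_NOISE_FACTOR`` x noise_sd and
    ``AMBIENT_SCATTER_FACTOR`` x scatter_sd on top of the soil's water-band
    amplitude being largest at 25C.
    """
    profiles = []
    for soil in SOILS:
        n_min, n_max = _N_RANGES[soil]
        for treatment in TREATMENTS:
            ambient = treatment == "25C"
            profiles.append(
                SoilProfile(
                    soil_name=soil,
                    treatment=treatment,
                    baseline_level=_BASELINES[soil],
                    baseline_slope=_SLOPES[soil],
                    bands=_STATIC_BANDS[soil],
                    nitrogen_band=_N_BANDS[soil],
                    water_band=(1385.0, _WATER_WIDTH, _WATER_AMP[soil][treatment]),
                    scatter_sd=scatter_sd * (AMBIENT_SCATTER_FACTOR if ambient else 1.0),
                    noise_sd=noise_sd * (AMBIENT_NOISE_FACTOR if ambient else 1.0),
                    nitrogen_min=n_min,
                    nitrogen_max=n_max,
                    n_gradients=n_gradients,
                    replicates=replicates,
                )
            )
    return profiles


def get_profile(soil: str, treatment: str, **kwargs) -> SoilProfile:
    """Look up one default profile by soil and treatment labels."""
    for p in default_profiles(**kwargs):
        if p.soil_name == soil and p.treatment == treatment:
            return p
    raise ConfigurationError(f"no default profile for soil={soil!r} treatment={treatment!r}")
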