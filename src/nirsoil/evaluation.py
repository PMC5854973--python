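"""Model-quality metrics: R, RMSE, RPD and the RPD interpretation bands."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InfiniteRPDError, UndefinedCorrelationError, ZeroSDError
from .models import CalibrationModel, predict
from .spectra import SpectraSet
from .split import SplitResult

RPD_AGRICULTURE = 3.0
RPD_GOOD = 2.0
RPD_INTERMEDIATE = 1.4


def pearson_r(y: np.ndarray, yhat: np.ndarray) -> float:
    """Pearson product-moment correlation between reference and prediction."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.ptp(y) == 0 or np.ptp(yhat) == 0:
        raise UndefinedCorrelationError("correlation undefined for a constant vector")
    return float(np.corrcoef(y, yhat)[0, 1])


def rmse(y: np.ndarray, yhat: np.ndarray) -> float:
    """Root mean square error, in the units of y (g/kg here)."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.size < 1:
        raise ValueError("need two equal-length non-empty vectors")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def rpd(y_val: np.ndarray, rmsep: float) -> float:
    """Residual predictive deviation: SD(y_val) / RMSEP, SD with n-1 denominator."""
    y_val = np.asarray(y_val, dtype=float)
    if y_val.size < 2:
        raise ValueError("need at least 2 validation reference values")
    sd = float(np.std(y_val, ddof=1))
    if sd == 0.0:
        raise ZeroSDError("validation reference values are constant")
    if rmsep == 0.0:
        raise InfiniteRPDError("RMSEP is zero; RPD is infinite")
    if rmsep < 0.0:
        raise ValueError("rmsep must be >= 0")
    return sd / rmsep


def rpd_category(value: float) -> str:
    """RPD interpretation band.

    >= 3 agriculture-grade; (2, 3) good; (1.4, 2] intermediate... boundaries
    1.4 and 2.0 fall to the lower band, 3.0 counts as agriculture-grade.
    """
    if value <= 0:
        raise ValueError("RPD must be positive")
    if value >= RPD_AGRICULTURE:
        return "agriculture-grade"
    if value > RPD_GOOD:
        return "good"
    if value > RPD_INTERMEDIATE:
        return "intermediate"
    return "poor"


@dataclass
class EvaluationReport:
    """Metrics for one soil x treatment x algorithm cell."""

    soil_type: str
    treatment: str
    algorithm: str
    n_cal: int
    n_val: int
    r_c: float
    rmsec: float
    r_p: float
    rmsep: float
    rpd: float
    rpd_category: str
    flags: list[str] = field(default_factory=list)

    def to_row(self) -> dict:
        return {
            "soil_type": self.soil_type,
            "treatment": self.treatment,
            "algorithm": self.algorithm,
            "N1": self.n_cal,
            "R_c": self.r_c,
            "RMSEC": self.rmsec,
            "N2": self.n_val,
            "R_p": self.r_p,
            "RMSEP": self.rmsep,
            "RPD": self.rpd,
            "RPD_category": self.rpd_category,
            "flags": ";".join(self.flags),
        }


def evaluate_model(
    model: CalibrationModel, spectra: SpectraSet, split: SplitResult
) -> EvaluationReport:
    """Score a fitted model on the calibration and validation partitions.

    Degenerate cases are surfaced as flags rather than hard errors: a
    constant prediction vector yields ``R = nan`` with an
    ``undefined-correlation`` flag, and ``RMSEP = 0`` yields ``RPD = inf``
    with an ``infinite-rpd`` flag.
    """
    flags: list[str] = []
    cal, val = split.calibration_idx, split.validation_idx
    y_cal, y_val = spectra.nitrogen[cal], spectra.nitrogen[val]
    yhat_cal = predict(model, spectra.reflectance[cal])
    yhat_val = predict(model, spectra.reflectance[val])

    def _safe_r(y, yhat, label):
        try:
            return pearson_r(y, yhat)
        except UndefinedCorrelationError:
            flags.append(f"undefined-correlation-{label}")
            return float("nan")

    r_c = _safe_r(y_cal, yhat_cal, "cal")
    r_p = _safe_r(y_val, yhat_val, "val")
    rmsec = rmse(y_cal, yhat_cal)
    rmsep = rmse(y_val, yhat_val)

    try:
        rpd_value = rpd(y_val, rmsep)
        category = rpd_category(rpd_value)
    except InfiniteRPDError:
        flags.append("infinite-rpd")
        rpd_value = float("inf")
        category = "agriculture-grade"
    except ZeroSDError:
        flags.append("zero-sd")
        rpd_value = float("nan")
        category = "undefined"

    return EvaluationReport(
        soil_type=str(spectra.soil_type[cal[0]]),
        treatment=str(spectra.treatment[cal[0]]),
        algorithm=model.kind,
        n_cal=len(cal),
        n_val=len(val),
        r_c=r_c,
        rmsec=rmsec,
        r_p=r_p,
        rmsep=rmsep,
        rpd=rpd_value,
        rpd_category=category,
        flags=flags,
    )
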