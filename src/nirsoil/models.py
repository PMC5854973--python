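"""Calibration routes: PLS (NIPALS, RMSECV-selected components), SPA-MLR and
CARS-PLS.

All fits are linear in the spectra; a fitted :class:`CalibrationModel`
predicts ``yhat = intercept + X[:, selected_idx] @ coefficients`` on the
full-width spectral matrix.

PLS is PLS1 via NIPALS on column-centered X and centered y — no variance
scaling, since reflectance columns share units.  The latent-variable count
is the RMSECV argmin over a deterministic contiguous-block K-fold on the
calibration set, ties resolved toward fewer components.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import DimensionalityError, FitError, SelectionError

_TOL = 1e-12


# ---------------------------------------------------------------------------
# Model containers
# ---------------------------------------------------------------------------

@dataclass
class CalibrationModel:
    """A fitted affine predictor over a subset of wavelengths."""

    kind: str  # PLS | SPA-MLR | CARS-PLS | MLR
    selected_idx: np.ndarray  # wavelength indices into the training grid
    coefficients: np.ndarray  # one per selected wavelength
    intercept: float
    n_features: int  # P of the training grid
    n_components: Optional[int] = None  # latent variables (absent for MLR)
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.selected_idx = np.asarray(self.selected_idx, dtype=int)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.selected_idx.size == 0:
            raise FitError("model must select at least one wavelength")
        if len(set(self.selected_idx.tolist())) != self.selected_idx.size:
            raise FitError("selected_idx must be unique")
        if self.selected_idx.min() < 0 or self.selected_idx.max() >= self.n_features:
            raise FitError("selected_idx out of range")
        if self.coefficients.shape != self.selected_idx.shape:
            raise FitError("coefficients must align with selected_idx")
        if self.n_components is not None and self.n_components < 1:
            raise FitError("n_components must be >= 1 when present")

    def to_dict(self, wavelengths: np.ndarray | None = None) -> dict:
        d = {
            "kind": self.kind,
            "selected_idx": self.selected_idx.tolist(),
            "coefficients": self.coefficients.tolist(),
            "intercept": float(self.intercept),
            "n_features": int(self.n_features),
            "n_components": self.n_components,
            "training_meta": _jsonable(self.training_meta),
        }
        if wavelengths is not None:
            d["selected_nm"] = [float(wavelengths[i]) for i in self.selected_idx]
        return d

    def to_json(self, path: str | Path, wavelengths: np.ndarray | None = None) -> None:
        Path(path).write_text(json.dumps(self.to_dict(wavelengths), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationModel":
        d = json.loads(Path(path).read_text())
        return cls(
            kind=d["kind"],
            selected_idx=np.asarray(d["selected_idx"], dtype=int),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            intercept=float(d["intercept"]),
            n_features=int(d["n_features"]),
            n_components=d.get("n_components"),
            training_meta=d.get("training_meta", {}),
        )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


@dataclass
class CVResult:
    """RMSECV over a grid of latent-variable counts."""

    component_grid: np.ndarray
    rmsecv: np.ndarray
    chosen: int

    def __post_init__(self) -> None:
        self.component_grid = np.asarray(self.component_grid, dtype=int)
        self.rmsecv = np.asarray(self.rmsecv, dtype=float)
        if np.any(~np.isfinite(self.rmsecv)) or np.any(self.rmsecv < 0):
            raise FitError("RMSECV values must be finite and >= 0")


@dataclass
class CarsIteration:
    """One CARS Monte Carlo iteration record."""

    retained_count: int
    sampled_rows: np.ndarray
    rmsecv: float
    subset_idx: np.ndarray


@dataclass
class SelectionTrace:
    """Full CARS history; ``chosen_iteration`` attains minimal RMSECV."""

    iterations: list[CarsIteration]
    chosen_iteration: int

    @property
    def rmsecv_path(self) -> np.ndarray:
        return np.array([it.rmsecv for it in self.iterations])

    @property
    def retained_counts(self) -> np.ndarray:
        return np.array([it.retained_count for it in self.iterations])


def predict(model: CalibrationModel, X: np.ndarray) -> np.ndarray:
    """Apply a fitted model to a full-width spectral matrix."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"X has {X.shape[1]} columns, model was trained on {model.n_features}"
        )
    return model.intercept + X[:, model.selected_idx] @ model.coefficients


# ---------------------------------------------------------------------------
# MLR
# ---------------------------------------------------------------------------

def fit_mlr(X: np.ndarray, y: np.ndarray, kind: str = "MLR") -> CalibrationModel:
    """Ordinary least squares with intercept; minimal-norm under rank deficiency.

    Requires strictly more samples than regressors (n > k).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if n <= k:
        raise DimensionalityError(f"MLR needs n > k, got n={n}, k={k}")
    design = np.column_stack([np.ones(n), X])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return CalibrationModel(
        kind=kind,
        selected_idx=np.arange(k),
        coefficients=beta[1:],
        intercept=float(beta[0]),
        n_features=k,
    )


# ---------------------------------------------------------------------------
# PLS1 (NIPALS)
# ---------------------------------------------------------------------------

def _pls_coef_paths(
    X: np.ndarray, y: np.ndarray, max_components: int
) -> list[tuple[np.ndarray, float]]:
    """NIPALS PLS1 coefficient path.

    Returns one (coefficients, intercept) pair per latent-variable count
    1..A_eff, where A_eff <= max_components shrinks if the residual
    collapses (rank exhausted).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    xbar = X.mean(axis=0)
    ybar = y.mean()
    Xc = X - xbar
    yc = y - ybar
    scale = float(np.linalg.norm(Xc.T @ yc))
    if scale <= _TOL:
        return []

    W, P, q = [], [], []
    for _ in range(max_components):
        w = Xc.T @ yc
        nw = float(np.linalg.norm(w))
        if nw <= _TOL * max(1.0, scale):
            break
        w = w / nw
        t = Xc @ w
        tt = float(t @ t)
        if tt <= _TOL:
            break
        p = (Xc.T @ t) / tt
        qa = float(yc @ t) / tt
        Xc = Xc - np.outer(t, p)
        yc = yc - qa * t
        W.append(w)
        P.append(p)
        q.append(qa)

    paths: list[tuple[np.ndarray, float]] = []
    for a in range(1, len(W) + 1):
        Wa = np.column_stack(W[:a])
        Pa = np.column_stack(P[:a])
        qa = np.asarray(q[:a])
        coef = Wa @ np.linalg.solve(Pa.T @ Wa, qa)
        paths.append((coef, float(ybar - xbar @ coef)))
    return paths


def pls_rmsecv(
    X: np.ndarray, y: np.ndarray, max_components: int, folds: int
) -> np.ndarray:
    """RMSECV per latent-variable count 1..max_components.

    Folds are deterministic contiguous index blocks.  When a training fold
    cannot support ``a`` components the largest achievable count stands in.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    if folds < 2 or folds > n:
        raise ValueError(f"folds must lie in [2, n]; got {folds} for n={n}")
    sq = np.zeros(max_components)
    for test_idx in np.array_split(np.arange(n), folds):
        mask = np.ones(n, dtype=bool)
        mask[test_idx] = False
        paths = _pls_coef_paths(X[mask], y[mask], max_components)
        if not paths:
            raise FitError("degenerate training fold (no usable component)")
        for a in range(max_components):
            coef, b0 = paths[min(a, len(paths) - 1)]
            resid = y[test_idx] - (X[test_idx] @ coef + b0)
            sq[a] += float(resid @ resid)
    return np.sqrt(sq / n)


def fit_pls(
    X: np.ndarray,
    y: np.ndarray,
    max_components: int = 10,
    folds: int = 10,
    seed: int = 0,
) -> tuple[CalibrationModel, CVResult]:
    """Fit PLS1 with the RMSECV-minimizing latent-variable count.

    ``seed`` is recorded for provenance; fold assignment is deterministic
    (contiguous blocks) so it does not influence the fit.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if np.allclose(X, X[0:1], atol=0.0):
        raise FitError("X has zero variance in every column")
    a_max = int(min(max_components, n - 1, k))
    if a_max < 1:
        raise FitError("cannot extract any latent variable")
    rmsecv = pls_rmsecv(X, y, a_max, folds)
    chosen = int(np.argmin(rmsecv)) + 1  # argmin first occurrence = fewest
    cv = CVResult(component_grid=np.arange(1, a_max + 1), rmsecv=rmsecv, chosen=chosen)
    paths = _pls_coef_paths(X, y, a_max)
    if not paths:
        raise FitError("degenerate design matrix")
    n_comp = min(chosen, len(paths))
    coef, b0 = paths[n_comp - 1]
    model = CalibrationModel(
        kind="PLS",
        selected_idx=np.arange(k),
        coefficients=coef,
        intercept=b0,
        n_features=k,
        n_components=n_comp,
        training_meta={"seed": seed, "folds": folds, "max_components": max_components},
    )
    return model, cv


def fit_pls_fixed(X: np.ndarray, y: np.ndarray, n_components: int) -> CalibrationModel:
    """PLS1 at a fixed latent-variable count (no cross-validation).

    If the design exhausts its rank earlier, the largest achievable count
    is used and recorded on the model.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    paths = _pls_coef_paths(X, y, n_components)
    if not paths:
        raise FitError("degenerate design matrix")
    coef, b0 = paths[min(n_components, len(paths)) - 1]
    return CalibrationModel(
        kind="PLS",
        selected_idx=np.arange(X.shape[1]),
        coefficients=coef,
        intercept=b0,
        n_features=X.shape[1],
        n_components=min(n_components, len(paths)),
    )


# ---------------------------------------------------------------------------
# SPA
# ---------------------------------------------------------------------------

def _spa_chain(Xc: np.ndarray, start: int, max_vars: int, norms0: np.ndarray) -> list[int]:
    """Projection chain from one starting column.

    Successively projects the remaining columns onto the orthogonal
    complement of the selected span and follows the maximal residual norm.
    Stops early when every remaining residual is numerically zero
    (collinear with the chain), so duplicates are never selected.
    """
    n, k = Xc.shape
    resid = Xc.copy()
    chain = [start]
    taken = np.zeros(k, dtype=bool)
    taken[start] = True
    for _ in range(1, max_vars):
        u = resid[:, chain[-1]]
        uu = float(u @ u)
        if uu <= _TOL:
            break
        resid = resid - np.outer(u, (u @ resid) / uu)
        norms = np.linalg.norm(resid, axis=0)
        norms[taken] = -1.0
        cand = int(np.argmax(norms))
        if norms[cand] <= 1e-9 * max(1.0, norms0.max()):
            break
        chain.append(cand)
        taken[cand] = True
    return chain


def spa_select(
    Xcal: np.ndarray,
    ycal: np.ndarray,
    Xval: np.ndarray,
    yval: np.ndarray,
    max_vars: int = 30,
) -> np.ndarray:
    """Successive projections algorithm wavelength selection.

    For every admissible starting column a projection chain of up to
    ``max_vars`` variables is grown on the centered calibration columns;
    every chain prefix is scored by MLR validation RMSE.  The minimal-RMSE
    prefix wins; ties prefer shorter chains, then lower start index.
    """
    Xcal = np.atleast_2d(np.asarray(Xcal, dtype=float))
    Xval = np.atleast_2d(np.asarray(Xval, dtype=float))
    ycal = np.asarray(ycal, dtype=float)
    yval = np.asarray(yval, dtype=float)
    n, k = Xcal.shape
    if not 1 <= max_vars <= min(k, n - 1):
        raise ValueError(f"max_vars must lie in [1, min(k, n_cal-1)] = [1, {min(k, n - 1)}]")

    Xc = Xcal - Xcal.mean(axis=0)
    norms0 = np.linalg.norm(Xc, axis=0)
    admissible = np.flatnonzero(norms0 > _TOL * max(1.0, norms0.max()))
    if admissible.size == 0:
        raise SelectionError("all columns are constant/zero")

    best: tuple[float, int, int] | None = None  # (rmse, length, start)
    best_chain: list[int] | None = None
    for start in admissible:
        chain = _spa_chain(Xc, int(start), max_vars, norms0)
        for m in range(1, len(chain) + 1):
            sub = chain[:m]
            mlr = fit_mlr(Xcal[:, sub], ycal)
            pred = predict(mlr, Xval[:, sub])
            rmse = float(np.sqrt(np.mean((yval - pred) ** 2)))
            key = (rmse, m, int(start))
            if best is None or key < best:
                best = key
                best_chain = sub
    assert best_chain is not None
    return np.asarray(best_chain, dtype=int)


def fit_spa_mlr(
    Xcal: np.ndarray,
    ycal: np.ndarray,
    Xval: np.ndarray,
    yval: np.ndarray,
    max_vars: int = 30,
) -> CalibrationModel:
    """SPA selection followed by MLR on the selected wavelengths."""
    sel = spa_select(Xcal, ycal, Xval, yval, max_vars)
    mlr = fit_mlr(Xcal[:, sel], ycal)
    return CalibrationModel(
        kind="SPA-MLR",
        selected_idx=sel,
        coefficients=mlr.coefficients,
        intercept=mlr.intercept,
        n_features=Xcal.shape[1],
        training_meta={"max_vars": max_vars},
    )


# ---------------------------------------------------------------------------
# CARS
# ---------------------------------------------------------------------------

def edf_schedule(k: int, n_runs: int) -> np.ndarray:
    """Exponentially decreasing retained fraction r_i = a*exp(-b*i).

    The constants a, b are fixed by the endpoints r_1 = 1 (all k variables)
    and r_{n_runs} = 2/k (two variables).
    """
    if k < 3:
        raise ValueError("need k >= 3 variables")
    if n_runs < 2:
        raise ValueError("need n_runs >= 2")
    b = math.log(k / 2.0) / (n_runs - 1)
    a = math.exp(b)
    i = np.arange(1, n_runs + 1)
    return a * np.exp(-b * i)


def edf_counts(k: int, n_runs: int) -> np.ndarray:
    """Retained variable counts ceil(r_i * k), guarded against fp fuzz.

    Spans k at iteration 1 down to exactly 2 at iteration n_runs.
    """
    return np.ceil(edf_schedule(k, n_runs) * k - 1e-9).astype(int)


def cars_select(
    Xcal: np.ndarray,
    ycal: np.ndarray,
    n_runs: int = 500,
    folds: int = 10,
    seed: int = 0,
    max_components: int = 10,
    mc_fraction: float = 0.8,
) -> tuple[np.ndarray, SelectionTrace]:
    """Competitive adaptive reweighted sampling wavelength selection.

    Per iteration: (1) draw ``mc_fraction`` of the calibration rows without
    replacement; (2) fit PLS on the current variable subset; (3) enforced
    shrink — keep the top ceil(r_i * k) variables by absolute coefficient,
    r_i from :func:`edf_schedule`; (4) adaptive reweighted sampling — draw
    that many survivors without replacement with probability proportional
    to |coefficient| (zero-weight variables cannot be drawn, which is the
    only further pruning under without-replacement sampling); (5) record
    the K-fold RMSECV of PLS on the surviving subset over the full
    calibration set.  The subset with minimal RMSECV wins.
    """
    Xcal = np.atleast_2d(np.asarray(Xcal, dtype=float))
    ycal = np.asarray(ycal, dtype=float)
    n, k = Xcal.shape
    if k < 3:
        raise ValueError("CARS needs at least 3 variables")
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if not 0.0 < mc_fraction <= 1.0:
        raise ValueError("mc_fraction must lie in (0, 1]")

    rng = np.random.default_rng(seed)
    schedule = edf_counts(k, n_runs)
    n_sub = max(2, int(round(mc_fraction * n)))

    subset = np.arange(k)
    iterations: list[CarsIteration] = []
    for i in range(n_runs):
        rows = np.sort(rng.choice(n, size=n_sub, replace=False))
        a_max = int(min(max_components, n_sub - 1, subset.size))
        paths = _pls_coef_paths(Xcal[np.ix_(rows, subset)], ycal[rows], a_max)
        if not paths:
            break  # degenerate draw; keep last valid subset
        coef, _ = paths[-1]
        weights = np.abs(coef)

        m = min(int(schedule[i]), subset.size)
        order = np.argsort(-weights, kind="stable")
        survivors = subset[order[:m]]
        surv_w = weights[order[:m]]

        nz = surv_w > 0
        if np.count_nonzero(nz) < 2:
            break  # subset would collapse below 2 variables
        pool = survivors[nz]
        pw = surv_w[nz] / surv_w[nz].sum()
        draw = rng.choice(pool, size=min(m, pool.size), replace=False, p=pw)
        new_subset = np.sort(draw)
        if new_subset.size < 2:
            break

        a_cv = int(min(max_components, n - 1, new_subset.size))
        rmsecv = float(np.min(pls_rmsecv(Xcal[:, new_subset], ycal, a_cv, folds)))
        iterations.append(
            CarsIteration(
                retained_count=int(m),
                sampled_rows=rows,
                rmsecv=rmsecv,
                subset_idx=new_subset,
            )
        )
        subset = new_subset

    if not iterations:
        raise SelectionError("CARS produced no valid subset")
    chosen = int(np.argmin([it.rmsecv for it in iterations]))
    trace = SelectionTrace(iterations=iterations, chosen_iteration=chosen)
    return iterations[chosen].subset_idx.copy(), trace


def fit_cars_pls(
    Xcal: np.ndarray,
    ycal: np.ndarray,
    n_runs: int = 500,
    folds: int = 10,
    seed: int = 0,
    max_components: int = 10,
    mc_fraction: float = 0.8,
) -> tuple[CalibrationModel, SelectionTrace]:
    """CARS selection followed by an RMSECV-tuned PLS refit on the winners."""
    sel, trace = cars_select(
        Xcal, ycal, n_runs=n_runs, folds=folds, seed=seed,
        max_components=max_components, mc_fraction=mc_fraction,
    )
    pls, cv = fit_pls(Xcal[:, sel], ycal, max_components=max_components,
                      folds=folds, seed=seed)
    model = CalibrationModel(
        kind="CARS-PLS",
        selected_idx=sel,
        coefficients=pls.coefficients,
        intercept=pls.intercept,
        n_features=Xcal.shape[1],
        n_components=pls.n_components,
        training_meta={"seed": seed, "n_runs": n_runs, "folds": folds,
                       "rmsecv": cv.rmsecv.tolist()},
    )
    return model, trace
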