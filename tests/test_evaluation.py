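"""Metric and report tests: R, RMSE, RPD, category bands, evaluate_model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nirsoil import (
    CalibrationModel,
    evaluate_model,
    fit_mlr,
    pearson_r,
    rmse,
    rpd,
    rpd_category,
    spxy_split,
)
from nirsoil.errors import (
    InfiniteRPDError,
    UndefinedCorrelationError,
    ZeroSDError,
)

from conftest import make_spectra


class TestPearson:
    def test_identity(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_r(y, y) == pytest.approx(1.0)

    def test_sign_flip(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_r(y, -y) == pytest.approx(-1.0)

    def test_hand_formula(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        yhat = np.array([1.1, 1.9, 3.2, 3.8])
        cov = np.mean((y - y.mean()) * (yhat - yhat.mean()))
        expected = cov / (y.std() * yhat.std())
        assert pearson_r(y, yhat) == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_r(np.array([1.0, 2.0, 3.0]), np.full(3, 0.5))

    def test_short_vector_rejected(self):
        with pytest.raises(ValueError):
            pearson_r(np.array([1.0, 2.0]), np.array([1.0, 2.0]))


class TestRMSE:
    def test_perfect(self):
        y = np.array([0.5, 0.7])
        assert rmse(y, y) == 0.0

    def test_constant_offset(self):
        y = np.array([1.0, 2.0, 3.0])
        assert rmse(y, y + 0.25) == pytest.approx(0.25)

    def test_three_four(self):
        assert rmse(np.zeros(2), np.array([3.0, 4.0])) == pytest.approx(
            np.sqrt(25.0 / 2.0)
        )

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            rmse(np.zeros(2), np.zeros(3))


class TestRPD:
    def test_sd_equals_rmsep_gives_one(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        sd = float(np.std(y, ddof=1))
        assert rpd(y, sd) == pytest.approx(1.0)

    def test_derived_example(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert rpd(y, 0.5) == pytest.approx(np.std(y, ddof=1) / 0.5)
        assert rpd(y, 0.5) == pytest.approx(2.5820, abs=1e-4)

    def test_inverse_proportionality(self):
        y = np.array([0.2, 0.9, 1.4, 2.2, 3.0])
        assert rpd(y, 0.1) == pytest.approx(2.0 * rpd(y, 0.2))

    def test_zero_rmsep_rejected(self):
        with pytest.raises(InfiniteRPDError):
            rpd(np.array([1.0, 2.0]), 0.0)

    def test_constant_reference_rejected(self):
        with pytest.raises(ZeroSDError):
            rpd(np.full(4, 1.0), 0.5)


class TestRPDCategory:
    @pytest.mark.parametrize(
        "value,label",
        [
            (4.34, "agriculture-grade"),
            (3.0, "agriculture-grade"),
            (2.82, "good"),
            (2.0, "intermediate"),  # boundary falls to lower band
            (1.5, "intermediate"),
            (1.4, "poor"),  # boundary falls to lower band
            (1.25, "poor"),
            (0.94, "poor"),
        ],
    )
    def test_bands(self, value, label):
        assert rpd_category(value) == label

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            rpd_category(0.0)

    @settings(max_examples=50, deadline=None)
    @given(value=st.floats(0.01, 20.0))
    def test_property_consistent_with_thresholds(self, value):
        label = rpd_category(value)
        if value >= 3.0:
            assert label == "agriculture-grade"
        elif value > 2.0:
            assert label == "good"
        elif value > 1.4:
            assert label == "intermediate"
        else:
            assert label == "poor"


class TestEvaluateModel:
    def _linear_spectra(self, n=12, p=5, seed=0, noise=0.0):
        rng = np.random.default_rng(seed)
        nitrogen = np.linspace(0.1, 2.0, n)
        refl = 0.5 + np.outer(nitrogen, np.linspace(-0.05, 0.05, p))
        refl += noise * rng.standard_normal((n, p))
        return make_spectra(reflectance=refl, nitrogen=nitrogen)

    def test_perfect_model_flagged_infinite_rpd(self):
        ss = self._linear_spectra()
        split = spxy_split(ss, (2, 1))
        model = fit_mlr(ss.reflectance[split.calibration_idx],
                        ss.nitrogen[split.calibration_idx])
        report = evaluate_model(model, ss, split)
        assert report.r_c == pytest.approx(1.0)
        assert report.r_p == pytest.approx(1.0)
        assert report.rmsep == pytest.approx(0.0, abs=1e-9)
        if report.rmsep == 0.0:
            assert report.rpd == np.inf
            assert "infinite-rpd" in report.flags

    def test_intercept_only_model_surfaces_undefined_r(self):
        ss = self._linear_spectra(noise=0.01)
        split = spxy_split(ss, (2, 1))
        model = CalibrationModel(
            kind="MLR", selected_idx=np.arange(5), coefficients=np.zeros(5),
            intercept=float(ss.nitrogen.mean()), n_features=5,
        )
        report = evaluate_model(model, ss, split)
        assert np.isnan(report.r_c) and np.isnan(report.r_p)
        assert "undefined-correlation-cal" in report.flags
        assert "undefined-correlation-val" in report.flags

    def test_metrics_match_independent_recomputation(self):
        ss = self._linear_spectra(noise=0.005, seed=4)
        split = spxy_split(ss, (2, 1))
        cal, val = split.calibration_idx, split.validation_idx
        model = fit_mlr(ss.reflectance[cal][:, :2], ss.nitrogen[cal])
        model = CalibrationModel(
            kind="MLR", selected_idx=np.arange(2), coefficients=model.coefficients,
            intercept=model.intercept, n_features=5,
        )
        report = evaluate_model(model, ss, split)

        yhat_val = model.intercept + ss.reflectance[val][:, :2] @ model.coefficients
        y_val = ss.nitrogen[val]
        assert report.rmsep == pytest.approx(
            float(np.sqrt(np.mean((y_val - yhat_val) ** 2))), abs=1e-12
        )
        assert report.r_p == pytest.approx(
            float(np.corrcoef(y_val, yhat_val)[0, 1]), abs=1e-12
        )
        assert report.rpd == pytest.approx(
            float(np.std(y_val, ddof=1)) / report.rmsep, abs=1e-12
        )
        assert report.n_cal == len(cal) and report.n_val == len(val)

    def test_rpd_rmsep_identity(self):
        ss = self._linear_spectra(noise=0.01, seed=7)
        split = spxy_split(ss, (2, 1))
        model = fit_mlr(ss.reflectance[split.calibration_idx][:, :3],
                        ss.nitrogen[split.calibration_idx])
        model = CalibrationModel(
            kind="MLR", selected_idx=np.arange(3), coefficients=model.coefficients,
            intercept=model.intercept, n_features=5,
        )
        report = evaluate_model(model, ss, split)
        sd = float(np.std(ss.nitrogen[split.validation_idx], ddof=1))
        assert report.rpd * report.rmsep == pytest.approx(sd, abs=1e-9)

    def test_invariant_to_validation_order(self):
        ss = self._linear_spectra(noise=0.01, seed=9)
        split = spxy_split(ss, (2, 1))
        model = fit_mlr(ss.reflectance[split.calibration_idx][:, :3],
                        ss.nitrogen[split.calibration_idx])
        model = CalibrationModel(
            kind="MLR", selected_idx=np.arange(3), coefficients=model.coefficients,
            intercept=model.intercept, n_features=5,
        )
        a = evaluate_model(model, ss, split)
        split.validation_idx = split.validation_idx[::-1].copy()
        b = evaluate_model(model, ss, split)
        # invariant up to summation reordering (ulp level)
        assert a.r_p == pytest.approx(b.r_p, rel=1e-12)
        assert a.rmsep == pytest.approx(b.rmsep, rel=1e-12)
        assert a.rpd == pytest.approx(b.rpd, rel=1e-12)
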