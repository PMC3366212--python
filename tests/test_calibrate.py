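"""Calibration: OLS fitting, stepwise selection, published-model registry."""

import numpy as np
import pytest

from dialyspec import (
    CollinearityError,
    GridError,
    InvalidInputError,
    KindMismatchError,
    LinearModel,
    PUBLISHED_MODEL_NAMES,
    SampleRecord,
    SimConfig,
    Spectrum,
    WAVELENGTH_GRID,
    apply_model,
    fit_mlr,
    forward_stepwise,
    published_model,
    simulate_dataset,
)
from dialyspec.calibrate import NegativePredictionWarning


def make_records(values_matrix, y, grid=WAVELENGTH_GRID, kind="absorbance"):
    """Records from a (n_samples, n_wavelengths) value matrix."""
    return [
        SampleRecord(
            Spectrum(grid, row, kind, session_id=f"s{i}", time_min=float(i)),
            float(yi),
            "calibration",
            f"r{i}",
        )
        for i, (row, yi) in enumerate(zip(values_matrix, y))
    ]


@pytest.fixture(scope="module")
def random_spectra():
    rng = np.random.default_rng(21)
    return rng.normal(0.5, 0.2, size=(40, WAVELENGTH_GRID.size))


class TestFitMlr:
    def test_exact_recovery_of_linear_law(self, random_spectra):
        X = random_spectra
        idx294 = int(np.nonzero(WAVELENGTH_GRID == 294)[0][0])
        y = 2.0 + 5.0 * X[:, idx294]
        model = fit_mlr(make_records(X, y), [294], "absorbance")
        assert model.intercept == pytest.approx(2.0, abs=1e-8)
        assert model.coefficients[0] == pytest.approx(5.0, abs=1e-8)

    def test_constant_target_gives_flat_model(self, random_spectra):
        y = np.full(40, 77.0)
        model = fit_mlr(make_records(random_spectra, y), [250, 300], "absorbance")
        assert model.intercept == pytest.approx(77.0, abs=1e-8)
        assert np.allclose(model.coefficients, 0.0, atol=1e-8)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, WAVELENGTH_GRID.size))
        wavelengths = [266, 294, 312]
        idx = [int(np.nonzero(WAVELENGTH_GRID == w)[0][0]) for w in wavelengths]
        y = rng.normal(50, 10, size=20)
        model = fit_mlr(make_records(X, y), wavelengths, "absorbance")
        A = np.column_stack([np.ones(20), X[:, idx]])
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        np.testing.assert_allclose(
            [model.intercept, *model.coefficients], beta, atol=1e-8
        )

    def test_collinear_design_names_wavelengths(self, random_spectra):
        X = random_spectra.copy()
        idx294 = int(np.nonzero(WAVELENGTH_GRID == 294)[0][0])
        X[:, idx294 + 1] = X[:, idx294]  # duplicate column at 295 nm
        y = np.arange(40.0)
        with pytest.raises(CollinearityError) as err:
            fit_mlr(make_records(X, y), [294, 295], "absorbance")
        assert 294 in err.value.wavelengths and 295 in err.value.wavelengths

    def test_too_few_records_rejected(self, random_spectra):
        records = make_records(random_spectra[:3], [1.0, 2.0, 3.0])
        with pytest.raises(InvalidInputError):
            fit_mlr(records, [294, 300], "absorbance")

    def test_ols_residual_mean_is_zero(self, small_dataset):
        """Any intercept-containing OLS fit has calibration residuals with
        mean exactly zero — the reason calibration BIAS is always 0.00."""
        model = fit_mlr(small_dataset, [294, 312], "absorbance")
        records = small_dataset.split_records("calibration")
        resid = [
            apply_model(model, r.spectrum) - r.ua_umol_l for r in records
        ]
        assert np.mean(resid) == pytest.approx(0.0, abs=1e-10)


class TestApplyModel:
    def test_worked_examples_on_zero_spectra(self, zero_absorbance, zero_derivative):
        with pytest.warns(NegativePredictionWarning):
            assert apply_model(
                published_model("UVa_1WL"), zero_absorbance
            ) == pytest.approx(-2.28)
        with pytest.warns(NegativePredictionWarning):
            assert apply_model(
                published_model("UVd_3WL"), zero_derivative
            ) == pytest.approx(-3.56)

    def test_two_wavelength_hand_arithmetic(self, grid):
        values = np.zeros(grid.size)
        values[grid == 294] = 0.5
        values[grid == 312] = 0.2
        spec = Spectrum(grid, values, "absorbance")
        # -1.67 + 60.56*0.5 - 60.75*0.2
        assert apply_model(published_model("UVa_2WL"), spec) == pytest.approx(
            16.46, abs=1e-10
        )

    def test_signal_kind_mismatch_rejected(self, zero_derivative):
        with pytest.raises(KindMismatchError):
            apply_model(published_model("UVa_1WL"), zero_derivative)

    def test_missing_wavelength_rejected(self):
        short_grid = np.arange(190, 251, dtype=float)
        spec = Spectrum(short_grid, np.zeros(short_grid.size), "absorbance")
        with pytest.raises(GridError):
            apply_model(published_model("UVa_1WL"), spec)


class TestPublishedRegistry:
    def test_registry_holds_exactly_six_models(self):
        assert len(PUBLISHED_MODEL_NAMES) == 6
        for name in PUBLISHED_MODEL_NAMES:
            assert published_model(name).name == name

    def test_three_wavelength_absorbance_model(self):
        m = published_model("UVa_3WL")
        assert m.signal_kind == "absorbance"
        assert m.wavelengths == (294, 312, 266)
        assert m.intercept == pytest.approx(-1.55)
        assert m.coefficients == pytest.approx((75.38, -62.27, -7.36))

    def test_two_wavelength_derivative_model(self):
        m = published_model("UVd_2WL")
        assert m.signal_kind == "derivative"
        assert m.intercept == pytest.approx(-2.12)
        assert m.terms == ((300.0, -1111.09), (270.0, 128.67))

    def test_unknown_name_lists_valid_names(self):
        with pytest.raises(InvalidInputError) as err:
            published_model("UVa_9WL")
        for name in PUBLISHED_MODEL_NAMES:
            assert name in str(err.value)


class TestForwardStepwise:
    def test_signal_column_found_among_noise(self):
        """When one column carries the target and the rest are independent
        noise, step 1 must select that column; cross-checked against an
        exhaustive single-wavelength RMSE scan."""
        rng = np.random.default_rng(8)
        X = rng.normal(size=(60, WAVELENGTH_GRID.size))
        idx294 = int(np.nonzero(WAVELENGTH_GRID == 294)[0][0])
        y = 10.0 + 4.0 * X[:, idx294] + rng.normal(0, 0.05, size=60)
        records = make_records(X, y)
        result = forward_stepwise(records, "absorbance", max_steps=1)
        assert result.steps[0].wavelength_nm == 294

        # exhaustive oracle over all candidate wavelengths
        def scan_rmse(col):
            A = np.column_stack([np.ones(60), X[:, col]])
            beta = np.linalg.lstsq(A, y, rcond=None)[0]
            return np.sqrt(np.mean((A @ beta - y) ** 2))

        best = min(range(WAVELENGTH_GRID.size), key=scan_rmse)
        assert best == idx294

    def test_max_steps_caps_model_size(self, small_dataset):
        result = forward_stepwise(small_dataset, "absorbance", max_steps=1)
        assert len(result.model.terms) == 1

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_rmse_non_increasing_over_steps(self, seed):
        config = SimConfig(n_sessions=14, cal_count=9, seed=seed)
        ds = simulate_dataset(config)
        result = forward_stepwise(ds, "absorbance", max_steps=3, alpha=1.0)
        rmses = [s.rmse_cal for s in result.steps]
        assert all(b <= a + 1e-12 for a, b in zip(rmses, rmses[1:]))

    def test_noiseless_parameter_recovery(self, noiseless_dataset):
        """With true UA an exact linear function of A(294), stepwise picks
        294 nm first and returns the generating coefficients."""
        idx294 = int(np.nonzero(WAVELENGTH_GRID == 294)[0][0])
        records = [
            SampleRecord(
                r.spectrum,
                3.0 + 40.0 * r.spectrum.values[idx294],
                r.split,
                r.sample_id,
            )
            for r in noiseless_dataset.split_records("calibration")
        ]
        result = forward_stepwise(records, "absorbance", max_steps=1)
        assert result.steps[0].wavelength_nm == 294
        assert result.model.intercept == pytest.approx(3.0, abs=1e-6)
        assert result.model.coefficients[0] == pytest.approx(40.0, abs=1e-6)

    def test_roundtrip_prediction_matches_generator(self, noiseless_dataset):
        idx = int(np.nonzero(WAVELENGTH_GRID == 300)[0][0])
        records = [
            SampleRecord(
                r.spectrum, 1.5 + 20.0 * r.spectrum.values[idx], r.split,
                r.sample_id,
            )
            for r in noiseless_dataset.split_records("calibration")
        ]
        model = fit_mlr(records, [300], "absorbance")
        for r in records[:5]:
            assert apply_model(model, r.spectrum) == pytest.approx(
                r.ua_umol_l, abs=1e-6
            )

    def test_empty_calibration_set_rejected(self):
        with pytest.raises(InvalidInputError):
            forward_stepwise([], "absorbance")

    def test_stopping_reason_reported(self, small_dataset):
        res = forward_stepwise(small_dataset, "absorbance", max_steps=3)
        assert res.stopping_reason in {"max_steps", "no_significant_improvement"}
        if res.stopping_reason == "max_steps":
            assert len(res.steps) == 3


class TestLinearModelInvariants:
    def test_duplicate_wavelengths_rejected(self):
        with pytest.raises(Exception):
            LinearModel(0.0, ((294.0, 1.0), (294.0, 2.0)), "absorbance")

    def test_out_of_range_wavelength_rejected(self):
        with pytest.raises(Exception):
            LinearModel(0.0, ((400.0, 1.0),), "absorbance")
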