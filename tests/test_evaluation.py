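"""Relative errors, MSE/R^2, correlations, and summary statistics."""

import numpy as np
import pandas as pd
import pytest

from carpfrost import (
    FrozenStorageDataset,
    TrainingConfig,
    mse,
    pearson_matrix,
    percent_decrease,
    r_squared,
    relative_error,
    residual_fraction,
    train_incremental,
    validation_report,
)
from carpfrost.errors import (
    DimensionError,
    InsufficientDataError,
    UndefinedValueError,
)
from carpfrost.preprocess import (
    FIRST_OBSERVED,
    INPUT_NAMES,
    OUTPUT_NAMES,
    REQUIRE_T0,
    assemble_design,
    delta_transform,
    fit_minmax,
)


class TestRelativeError:
    @pytest.mark.parametrize("exp,pred,signed_2dp", [
        (16.81, 16.82, -0.06),   # FFA week 17
        (43.14, 43.17, -0.07),   # SSP week 17
    ])
    def test_printed_week17_pairs(self, exp, pred, signed_2dp):
        assert round(relative_error(exp, pred, "signed"), 2) == signed_2dp
        assert round(relative_error(exp, pred, "absolute"), 2) == abs(signed_2dp)

    def test_exact_prediction_is_zero(self):
        assert relative_error(5.0, 5.0) == 0.0

    def test_positive_iff_undershoot(self):
        assert relative_error(10.0, 9.0) > 0
        assert relative_error(10.0, 11.0) < 0

    def test_zero_experimental_undefined(self):
        with pytest.raises(UndefinedValueError):
            relative_error(0.0, 1.0)


class TestMseR2:
    def test_perfect_fit(self):
        y = np.array([1.0, 2.0, 3.0])
        assert mse(y, y) == 0.0
        assert r_squared(y, y) == 1.0

    def test_mean_prediction_gives_zero_r2(self):
        y = np.array([1.0, 2.0, 3.0])
        yhat = np.full(3, y.mean())
        assert r_squared(y, yhat) == pytest.approx(0.0)

    def test_simple_arithmetic(self):
        assert mse([1, 2, 3], [1, 2, 4]) == pytest.approx(1 / 3)

    def test_length_mismatch(self):
        with pytest.raises(DimensionError):
            mse([1, 2], [1, 2, 3])

    def test_zero_variance_r2_undefined(self):
        with pytest.raises(UndefinedValueError):
            r_squared([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


def _dataset_from_columns(columns: dict[str, list[float]]) -> FrozenStorageDataset:
    rows = []
    n = len(next(iter(columns.values())))
    for ind_name, vals in columns.items():
        for t, v in zip(range(n), vals):
            rows.append((253.0, float(t), ind_name, 1, float(v)))
    return FrozenStorageDataset(pd.DataFrame(
        rows, columns=["temperature_K", "time_weeks", "indicator",
                       "replicate", "value"]))


class TestPearsonMatrix:
    def _full_columns(self, n=6):
        base = np.linspace(1, 10, n)
        return {
            "TBARS": base, "FFA": 2 * base + 1, "SSP": 30 - base,
            "CA_ATPASE": 0.5 * (30 - base), "SH": 20 - 0.5 * base,
        }

    def test_perfect_linear_relation_gives_unit_r(self):
        ds = _dataset_from_columns(self._full_columns())
        table = pearson_matrix(ds)
        assert table.r.loc["TBARS", "FFA"] == pytest.approx(1.0)
        assert table.r.loc["TBARS", "SSP"] == pytest.approx(-1.0)

    def test_matches_textbook_covariance_formula_on_fixture(self, fixture_253):
        """Ca2+-ATPase vs SH over the ten 253 K weeks: strong positive r."""
        table = pearson_matrix(fixture_253)
        ca = [0.24, 0.20, 0.19, 0.17, 0.13, 0.09, 0.05, 0.04, 0.03, 0.05]
        sh = [6.71, 5.29, 5.15, 4.97, 3.49, 3.53, 3.52, 2.93, 2.85, 2.45]
        n = len(ca)
        mca, msh = sum(ca) / n, sum(sh) / n
        cov = sum((a - mca) * (b - msh) for a, b in zip(ca, sh)) / n
        oracle = cov / (np.sqrt(sum((a - mca) ** 2 for a in ca) / n)
                        * np.sqrt(sum((b - msh) ** 2 for b in sh) / n))
        r = table.r.loc["CA_ATPASE", "SH"]
        assert r == pytest.approx(oracle, abs=1e-12)
        assert 0.90 < r < 1.0  # ~0.95 here; 0.96 pooled over all temperatures

    def test_affine_rescaling_invariance(self, fixture_253):
        scaled_frame = fixture_253.frame.copy()
        mask = scaled_frame["indicator"] == "SH"
        scaled_frame.loc[mask, "value"] = scaled_frame.loc[mask, "value"] * 3.5 + 2.0
        scaled = FrozenStorageDataset(scaled_frame)
        a = pearson_matrix(fixture_253).r
        b = pearson_matrix(scaled).r
        pd.testing.assert_frame_equal(a, b, atol=1e-12, rtol=0)

    def test_diagonal_symmetry_bounds(self, fixture_253):
        t = pearson_matrix(fixture_253)
        vals = t.r.to_numpy()
        np.testing.assert_allclose(np.diag(vals), 1.0)
        np.testing.assert_allclose(vals, vals.T)
        assert (np.abs(vals) <= 1 + 1e-12).all()

    def test_insufficient_rows_rejected(self):
        cols = {k: v[:2] for k, v in self._full_columns().items()}
        with pytest.raises(InsufficientDataError):
            pearson_matrix(_dataset_from_columns(cols))


class TestSummaryStatistics:
    @pytest.mark.parametrize("c0,ct,expected", [
        (63.84, 22.46, 64.82),
        (66.74, 59.24, 11.24),
    ])
    def test_printed_ssp_decreases(self, c0, ct, expected):
        assert round(percent_decrease(c0, ct), 2) == expected

    def test_no_change_is_zero(self):
        assert percent_decrease(5.0, 5.0) == 0.0

    def test_printed_ca_atpase_residual(self):
        assert round(residual_fraction(0.27, 0.05), 2) == 18.52

    def test_no_change_is_full_residual(self):
        assert residual_fraction(5.0, 5.0) == 100.0

    @pytest.mark.parametrize("c0,ct", [(63.84, 22.46), (0.27, 0.05), (7.0, 7.0)])
    def test_decrease_and_residual_complement(self, c0, ct):
        assert percent_decrease(c0, ct) + residual_fraction(c0, ct) == \
            pytest.approx(100.0)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(UndefinedValueError):
            percent_decrease(0.0, 1.0)
        with pytest.raises(UndefinedValueError):
            residual_fraction(-1.0, 1.0)


class TestValidationReport:
    def _train_on(self, dataset, policy, max_neurons=10, spread=1.0):
        design = assemble_design(delta_transform(dataset, policy))
        xn = fit_minmax(design.X, INPUT_NAMES, pad_degenerate=True)
        yn = fit_minmax(design.Y, OUTPUT_NAMES)
        cfg = TrainingConfig(spread=spread,
                             max_neurons=min(max_neurons, len(design)), seed=0)
        net, _ = train_incremental(xn.transform(design.X), yn.transform(design.Y),
                                   cfg, INPUT_NAMES, OUTPUT_NAMES)
        net.x_norm, net.y_norm = xn, yn
        return net

    def test_interpolation_regime_passes_with_tiny_errors(self, fixture_253):
        net = self._train_on(fixture_253, FIRST_OBSERVED, max_neurons=10)
        rep = validation_report(net, fixture_253, 253.0, FIRST_OBSERVED)
        assert rep.passed
        assert rep.max_abs_rel_error < 0.5
        assert len(rep.rows) == 50  # 5 indicators x 10 weeks

    def test_zero_experimental_flagged_and_excluded(self):
        rows = [(253.0, float(t), ind, 1, v)
                for ind in ("TBARS", "FFA", "SSP", "CA_ATPASE", "SH")
                for t, v in [(0, 1.0), (1, 2.0), (2, 3.0), (3, 4.0)]]
        frame = pd.DataFrame(rows, columns=["temperature_K", "time_weeks",
                                            "indicator", "replicate", "value"])
        frame.loc[(frame["indicator"] == "SH") & (frame["time_weeks"] == 2.0),
                  "value"] = 0.0
        ds = FrozenStorageDataset(frame)
        net = self._train_on(ds, REQUIRE_T0, max_neurons=4)
        rep = validation_report(net, ds, 253.0, REQUIRE_T0)
        bad = rep.rows[(rep.rows["indicator"] == "SH")
                       & (rep.rows["time_weeks"] == 2.0)]
        assert not bad["defined"].iloc[0]
        assert any("SH" in w for w in rep.warnings)
        assert np.isfinite(rep.max_abs_rel_error)

    def test_pass_flag_matches_band(self, fixture_253):
        net = self._train_on(fixture_253, FIRST_OBSERVED, max_neurons=2)
        rep = validation_report(net, fixture_253, 253.0, FIRST_OBSERVED)
        assert rep.passed == (rep.max_abs_rel_error <= 10.0)

    def test_report_serializes(self, fixture_253):
        net = self._train_on(fixture_253, FIRST_OBSERVED, max_neurons=6)
        rep = validation_report(net, fixture_253, 253.0, FIRST_OBSERVED)
        text = rep.to_text()
        assert "Relative errors (%)" in text and "SSP" in text
        d = rep.to_dict()
        assert d["temperature_K"] == 253.0 and len(d["rows"]) == 50
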