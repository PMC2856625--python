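"""Autofluorescence fitting, threshold calibration, robust aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st_

import serochip as sc
from serochip.correction import (ProcessedArray, empirical_quantile,
                                 is_positive, tukey_biweight)
from serochip.errors import AnalysisError, CalibrationError


def processed(names, log2_green, log2_red, **extra):
    n = len(names)
    df = pd.DataFrame({
        "block": 1, "column": np.arange(1, n + 1), "row": 1,
        "name": names, "replicate_index": 1,
        "log2_red": np.asarray(log2_red, float),
        "log2_green": np.asarray(log2_green, float),
    })
    for k, v in extra.items():
        df[k] = v
    return ProcessedArray(data=df)


class TestPreprocess:
    def test_exact_powers_of_two(self):
        scan = sc.ArrayScan([sc.SpotRecord(1, 1, 1, "A01", 1, 1024.0, 256.0, 0)])
        arr = sc.preprocess(scan)
        assert arr.data.loc[0, "log2_red"] == 10.0
        assert arr.data.loc[0, "log2_green"] == 8.0

    def test_flagged_spots_dropped(self):
        spots = [sc.SpotRecord(1, i + 1, 1, "A01", i + 1, 4.0, 4.0,
                               -100 if i < 3 else 0) for i in range(10)]
        arr = sc.preprocess(sc.ArrayScan(spots))
        assert len(arr) == 7

    def test_zero_intensity_floored_to_log2_zero(self):
        scan = sc.ArrayScan([sc.SpotRecord(1, 1, 1, "A01", 1, 0.0, 0.5, 0)])
        arr = sc.preprocess(scan)
        assert arr.data.loc[0, "log2_red"] == 0.0
        assert arr.data.loc[0, "log2_green"] == 0.0

    def test_all_flagged_warns_and_is_empty(self):
        scan = sc.ArrayScan([sc.SpotRecord(1, 1, 1, "A01", 1, 4.0, 4.0, -75)])
        with pytest.warns(UserWarning, match="all spots flagged"):
            arr = sc.preprocess(scan)
        assert len(arr) == 0


class TestFit:
    def test_exact_line_recovered(self):
        layout = sc.small_layout(1)
        g = np.array([2.0, 4.0, 6.0, 8.0])
        arr = processed(["A01"] * 4, g, g)  # log2R = 1.0 * log2G + 0
        model = sc.fit_autofluorescence([arr], layout)
        row = model.table.loc["A01"]
        assert row["m"] == pytest.approx(1.0)
        assert row["b"] == pytest.approx(0.0, abs=1e-12)
        assert row["resid_sd"] == pytest.approx(0.0, abs=1e-12)

    def test_too_few_spots_marks_uncalibratable(self):
        layout = sc.small_layout(1)
        arr = processed(["A01"] * 2, [2.0, 4.0], [2.0, 4.0])
        model = sc.fit_autofluorescence([arr], layout)
        assert model.uncalibratable == ["A01"]
        assert not model.is_calibrated("A01")

    def test_zero_green_variance_falls_back_to_intercept(self):
        layout = sc.small_layout(1)
        arr = processed(["A01"] * 4, [5.0] * 4, [1.0, 2.0, 3.0, 4.0])
        with pytest.warns(UserWarning, match="zero green variance"):
            model = sc.fit_autofluorescence([arr], layout)
        assert model.table.loc["A01", "m"] == 0.0
        assert model.table.loc["A01", "b"] == pytest.approx(2.5)

    def test_no_mock_arrays_is_an_error(self):
        with pytest.raises(CalibrationError):
            sc.fit_autofluorescence([], sc.small_layout(1))

    def test_fit_invariant_to_spot_and_array_order(self, calibrated_small):
        config, scans, truth, model = calibrated_small
        mocks = [s for s in scans if s.meta.is_mock]
        shuffled = [sc.ArrayScan(list(reversed(s.spots)), s.meta)
                    for s in reversed(mocks)]
        model2 = sc.calibrate([sc.preprocess(s) for s in shuffled], config.layout)
        pd.testing.assert_frame_equal(model.table, model2.table)


class TestCorrect:
    def test_on_line_spot_corrects_to_zero_and_additivity(self):
        layout = sc.small_layout(1)
        fit_arr = processed(["A01"] * 4, [2.0, 4.0, 6.0, 8.0],
                            [3.0, 5.0, 7.0, 9.0])  # m=1, b=1
        model = sc.fit_autofluorescence([fit_arr], layout)
        probe = processed(["A01"] * 2, [5.0, 5.0], [6.0, 8.0])
        out = sc.correct(probe, model)
        assert out.data["corrected"].tolist() == pytest.approx([0.0, 2.0])

    def test_training_mock_residual_means_are_zero(self, calibrated_small):
        """Correcting the mocks used for fitting centres every allergen's
        corrected distribution exactly at 0 (least-squares property)."""
        config, scans, truth, model = calibrated_small
        mocks = [sc.preprocess(s) for s in scans if s.meta.is_mock]
        values = sc.pool_corrected([sc.correct(a, model) for a in mocks],
                                   config.layout)
        for allergen, vals in values.items():
            assert abs(np.mean(vals)) < 1e-10

    def test_uncalibrated_allergen_gets_missing(self):
        layout = sc.small_layout(2)
        fit_arr = processed(["A01"] * 3, [2.0, 4.0, 6.0], [2.0, 4.0, 6.0])
        model = sc.fit_autofluorescence([fit_arr], layout)  # A02 unfittable
        probe = processed(["A01", "A02"], [4.0, 4.0], [4.0, 4.0])
        out = sc.correct(probe, model)
        assert out.data.loc[0, "corrected"] == pytest.approx(0.0)
        assert np.isnan(out.data.loc[1, "corrected"])


class TestThresholds:
    def test_quantile_conventions_on_1_to_100(self):
        values = np.arange(1, 101)
        assert empirical_quantile(values, 0.99, "linear") == pytest.approx(99.01)
        assert empirical_quantile(values, 0.99, "exceedance") == pytest.approx(99.99)
        with pytest.raises(AnalysisError):
            empirical_quantile(values, 0.99, "nearest")

    def test_constant_corrected_values_give_zero_threshold(self):
        layout = sc.small_layout(1)
        arr = processed(["A01"] * 4, [2.0, 4.0, 6.0, 8.0], [2.0, 4.0, 6.0, 8.0])
        model = sc.fit_autofluorescence([arr], layout)
        model = sc.calibrate_thresholds({"A01": [0.0] * 30}, model)
        assert model.table.loc["A01", "tau"] == 0.0

    def test_empty_values_leave_no_threshold(self):
        layout = sc.small_layout(1)
        arr = processed(["A01"] * 4, [2.0, 4.0, 6.0, 8.0], [2.0, 4.0, 6.0, 8.0])
        model = sc.fit_autofluorescence([arr], layout)
        model = sc.calibrate_thresholds({"A01": []}, model)
        assert not model.has_threshold("A01")

    def test_few_values_flagged_low_confidence(self):
        layout = sc.small_layout(1)
        arr = processed(["A01"] * 4, [2.0, 4.0, 6.0, 8.0], [2.0, 4.0, 6.0, 8.0])
        model = sc.fit_autofluorescence([arr], layout)
        model = sc.calibrate_thresholds({"A01": [0.1, 0.2, 0.3]}, model)
        assert model.has_threshold("A01")
        assert bool(model.table.loc["A01", "low_confidence"])

    def test_apply_thresholds_boundary_and_missing(self):
        layout = sc.small_layout(1)
        fit_arr = processed(["A01"] * 4, [2.0, 4.0, 6.0, 8.0],
                            [2.0, 4.0, 6.0, 8.0])
        model = sc.fit_autofluorescence([fit_arr], layout)
        model = sc.calibrate_thresholds({"A01": list(np.linspace(0, 0.5, 50))},
                                        model)
        tau = model.table.loc["A01", "tau"]
        probe = processed(["A01"] * 3, [4.0] * 3,
                          [4.0 + tau, 4.0 + tau + 1.5, 4.0])
        probe.data.loc[2, "log2_green"] = np.nan  # induce missing corrected
        out = sc.apply_thresholds(sc.correct(probe, model), model)
        t = out.data["thresholded"]
        assert t[0] == pytest.approx(0.0, abs=1e-12)
        assert not is_positive(0.0)  # exactly at the threshold = negative call
        assert t[1] == pytest.approx(1.5)
        assert is_positive(t[1])
        assert np.isnan(t[2])

    def test_held_out_fpr_matches_nominal_rate(self):
        """Fresh null values exceed calibrated thresholds about 1% of the
        time (Monte-Carlo check of the false-positive calibration)."""
        rng = np.random.default_rng(17)
        train = rng.normal(size=106)
        tau = empirical_quantile(train, 0.99)
        held = rng.normal(size=200_000)
        fpr = np.mean(held > tau)
        # tau is itself random: allow nominal +- 3 * quantile sampling sd
        sd = np.sqrt(0.01 * 0.99 / 106)
        assert abs(fpr - 0.01) < 3 * sd


class TestAggregation:
    def test_constant_replicates_any_method(self):
        for method in ("biweight", "trimean", "mean"):
            assert sc.aggregate_replicates([2.0, 2.0, 2.0], 3, method) == 2.0

    def test_biweight_downweights_outlier(self):
        """(1, 2, 10) with c=5: centre 2, MAD 1, weights (0.9216, 1, 0),
        giving 2.9216 / 1.9216."""
        got = tukey_biweight([1.0, 2.0, 10.0], c=5.0)
        assert got == pytest.approx(2.9216 / 1.9216)
        assert got == pytest.approx(1.5204, abs=5e-4)

    def test_zero_mad_returns_median(self):
        assert tukey_biweight([5.0, 5.0, 5.0, 9.0]) == 5.0

    def test_majority_missing_rule(self):
        assert np.isnan(sc.aggregate_replicates([1.0], 3))
        assert np.isnan(sc.aggregate_replicates([1.0, np.nan, np.nan], 3))
        assert np.isfinite(sc.aggregate_replicates([1.0, 2.0, np.nan], 3))

    @settings(deadline=None, max_examples=50)
    @given(st_.lists(st_.floats(-50, 50), min_size=3, max_size=9),
           st_.floats(0.1, 10))
    def test_biweight_bounded_and_scale_equivariant(self, values, k):
        loc = tukey_biweight(values)
        assert min(values) - 1e-9 <= loc <= max(values) + 1e-9
        assert tukey_biweight([k * v for v in values]) == pytest.approx(
            k * loc, rel=1e-9, abs=1e-9)


class TestIgEMatrix:
    def test_matrix_shape_and_uncalibratable_column_absent(self, calibrated_small):
        config, scans, truth, model = calibrated_small
        samples = [s for s in scans if not s.meta.is_mock]
        processed_arrays = []
        for s in samples:
            arr = sc.preprocess(s)
            arr = sc.apply_thresholds(sc.correct(arr, model), model)
            processed_arrays.append(arr)
        matrix = sc.build_ige_matrix(processed_arrays, config.layout, model)
        assert matrix.values.shape == (2, 6)
        # drop one allergen's threshold -> its column disappears
        model.table.loc["A05", "tau"] = np.nan
        matrix2 = sc.build_ige_matrix(processed_arrays, config.layout, model)
        assert "A05" not in matrix2.allergens
        assert matrix2.values.shape == (2, 5)

    def test_no_sample_arrays_is_an_error(self, calibrated_small):
        config, scans, truth, model = calibrated_small
        with pytest.raises(AnalysisError):
            sc.build_ige_matrix([], config.layout, model)

    def test_matrix_correlates_with_true_effects(self, default_quantified):
        """Aggregated microarray units track the planted effects: linearly
        over all cells, and in rank among the sensitized cells."""
        config, truth, model, processed_arrays, per_array, collapsed = \
            default_quantified
        from scipy.stats import pearsonr, spearmanr
        truth_flat = truth.effects.loc[collapsed.values.index,
                                       collapsed.values.columns]
        ok = collapsed.values.notna().to_numpy()
        t = truth_flat.to_numpy()[ok]
        v = collapsed.values.to_numpy()[ok]
        assert pearsonr(t, v).statistic > 0.9
        sens = t > 0
        assert spearmanr(t[sens], v[sens]).statistic > 0.9


class TestStandardCurveQC:
    def test_simulated_mock_passes(self, small_config):
        arr = sc.preprocess(sc.simulate_mock_array(small_config))
        qc = sc.qc_standard_curve(arr, small_config.layout)
        assert qc.passed and not qc.skipped

    def test_shuffled_standards_fail(self, small_config):
        arr = sc.preprocess(sc.simulate_mock_array(small_config))
        df = arr.data
        ige = df["name"].str.startswith("IgE_")
        rng = np.random.default_rng(2)
        df.loc[ige, "log2_red"] = rng.permutation(df.loc[ige, "log2_red"].values)
        qc = sc.qc_standard_curve(ProcessedArray(df), small_config.layout)
        assert not qc.passed

    def test_flat_igg_iga_do_not_matter(self, small_config):
        arr = sc.preprocess(sc.simulate_mock_array(small_config))
        df = arr.data
        other = df["name"].str.startswith(("IgG_", "IgA_"))
        df.loc[other, "log2_red"] = 5.0
        qc = sc.qc_standard_curve(ProcessedArray(df), small_config.layout)
        assert qc.passed

    def test_absent_standards_skip_with_warning(self):
        layout = sc.small_layout(2)
        arr = processed(["A01", "A02"], [4.0, 4.0], [4.0, 4.0])
        with pytest.warns(UserWarning, match="skipped"):
            qc = sc.qc_standard_curve(arr, layout)
        assert qc.skipped


class TestModelSerialization:
    def test_json_roundtrip(self, calibrated_small, tmp_path):
        config, scans, truth, model = calibrated_small
        path = model.to_json(tmp_path / "cal.json")
        back = sc.CalibrationModel.from_json(path)
        assert back.percentile == model.percentile
        pd.testing.assert_series_equal(
            back.table["tau"], model.table["tau"],
            check_exact=False, rtol=1e-10)
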