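"""CV, ANOVA variance shares, replicate regression, paired tests,
ELISA calls and concordance tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st_
from scipy import stats as sps

import serochip as sc
from serochip.errors import AnalysisError
from serochip.stats import (INTER_ASSAY, INTER_SLIDE, INTRA_SLIDE,
                            ConcordanceTable)


def long_table(cells):
    """cells: list of (serum, allergen, day, slide, array, value)."""
    return pd.DataFrame(cells, columns=["serum_id", "allergen", "day",
                                        "slide_id", "array", "value"])


class TestCV:
    def test_identical_replicates_have_zero_cv(self):
        long = long_table([("s1", "A", "d1", "S1", a, 3.0) for a in range(3)])
        rep = sc.cv_report(long, INTRA_SLIDE, mean_floor=0.5)
        assert rep.per_cell["cv"].tolist() == [0.0]

    def test_hand_computed_cv(self):
        """(1, 2, 3): mean 2, sample sd 1, CV 0.5."""
        long = long_table([("s1", "A", "d1", "S1", a, v)
                           for a, v in enumerate([1.0, 2.0, 3.0])])
        rep = sc.cv_report(long, INTRA_SLIDE)
        assert rep.per_cell["cv"].tolist() == pytest.approx([0.5])

    def test_low_mean_cells_excluded(self):
        long = long_table([("s1", "A", "d1", "S1", 0, 0.1),
                           ("s1", "A", "d1", "S1", 1, 0.2)])
        rep = sc.cv_report(long, INTRA_SLIDE, mean_floor=0.5)
        assert rep.empty

    def test_levels_group_correctly(self):
        cells = []
        for day in ("d1", "d2"):
            for slide in ("S1", "S2"):
                for array in range(2):
                    cells.append(("s1", "A", day, f"{day}{slide}", array, 2.0))
        long = long_table(cells)
        for level, expected_cells in ((INTRA_SLIDE, 4), (INTER_SLIDE, 2),
                                      (INTER_ASSAY, 1)):
            rep = sc.cv_report(long, level)
            assert len(rep.per_cell) == expected_cells

    def test_class_medians(self):
        classes = {"A": "surface", "B": "cytoplasm"}
        cells = [("s1", "A", "d1", "S1", a, v)
                 for a, v in enumerate([1.0, 2.0, 3.0])]
        cells += [("s1", "B", "d1", "S1", a, v)
                  for a, v in enumerate([2.0, 2.0, 2.0])]
        rep = sc.cv_report(long_table(cells), INTRA_SLIDE, classes=classes)
        assert rep.summary.loc["surface", "median_cv"] == pytest.approx(0.5)
        assert rep.summary.loc["cytoplasm", "median_cv"] == 0.0

    @settings(deadline=None, max_examples=40)
    @given(st_.lists(st_.floats(0.6, 50), min_size=2, max_size=6),
           st_.floats(0.5, 20))
    def test_cv_scale_invariant(self, values, k):
        long1 = long_table([("s1", "A", "d1", "S1", i, v)
                            for i, v in enumerate(values)])
        long2 = long_table([("s1", "A", "d1", "S1", i, k * v)
                            for i, v in enumerate(values)])
        cv1 = sc.cv_report(long1, INTRA_SLIDE, mean_floor=0.0).per_cell["cv"]
        cv2 = sc.cv_report(long2, INTRA_SLIDE, mean_floor=0.0).per_cell["cv"]
        assert cv1.tolist() == pytest.approx(cv2.tolist(), rel=1e-9)


class TestAnova:
    def test_percent_shares_from_published_decomposition(self):
        """A five-component decomposition with SS (51.191, 363, 21378, 7132,
        13758) splits 0.12 / 0.85 / 50.09 / 16.71 / 32.23 percent."""
        shares = sc.variance_shares({"Array": 51.191, "Slide": 363.0,
                                     "Serum": 21378.0, "Allergen": 7132.0,
                                     "Error": 13758.0})
        assert round(shares["Array"], 2) == 0.12
        assert round(shares["Slide"], 2) == 0.85
        assert round(shares["Serum"], 2) == 50.09
        assert round(shares["Allergen"], 2) == 16.71
        assert round(shares["Error"], 2) == 32.23
        assert shares.sum() == pytest.approx(100.0)

    def test_balanced_one_factor_closed_form(self):
        """Two groups of four with means 0 and 1: between-group SS =
        n * sum((group mean - grand mean)^2) = 4 * (0.25 + 0.25) = 2."""
        df = pd.DataFrame({
            "value": [-0.5, 0.5, -0.5, 0.5, 0.5, 1.5, 0.5, 1.5],
            "group": ["a"] * 4 + ["b"] * 4,
        })
        comp = sc.anova_components(df, factors=("group",))
        assert comp.table.loc["group", "SS"] == pytest.approx(2.0)
        assert comp.table.loc["group", "df"] == 1

    def test_sequential_anova_on_crossed_design(self):
        rng = np.random.default_rng(0)
        rows = []
        for serum in range(3):
            for allergen in range(4):
                for array in range(2):
                    rows.append({"serum_id": f"s{serum}", "allergen": f"a{allergen}",
                                 "slide_id": "S1", "array": array,
                                 "value": serum + 0.5 * allergen + rng.normal()})
        df = pd.DataFrame(rows)
        comp = sc.anova_components(df)  # slide has one level -> dropped
        assert set(comp.table.index) == {"array", "serum_id", "allergen", "Error"}
        assert comp.table["pct_ss_total"].sum() == pytest.approx(100.0)
        # serum is the dominant source by construction
        assert comp.pct("serum_id") > comp.pct("allergen") > comp.pct("array")

    def test_row_order_invariance(self):
        rng = np.random.default_rng(1)
        # independent factor draws so no factor pair is confounded
        df = pd.DataFrame({
            "value": rng.normal(size=60),
            "serum_id": rng.choice(list("abc"), size=60),
            "allergen": rng.choice([f"g{i}" for i in range(4)], size=60),
            "slide_id": rng.choice(["S1", "S2"], size=60),
            "array": rng.choice([0, 1], size=60),
        })
        c1 = sc.anova_components(df)
        c2 = sc.anova_components(df.sample(frac=1.0, random_state=5))
        pd.testing.assert_frame_equal(c1.table, c2.table)

    def test_constant_response_has_zero_ss(self):
        df = pd.DataFrame({"value": [5.0] * 8, "group": list("aabb") * 2})
        comp = sc.anova_components(df, factors=("group",))
        assert comp.table.loc["group", "SS"] == pytest.approx(0.0, abs=1e-12)
        assert comp.table.loc["Error", "SS"] == pytest.approx(0.0, abs=1e-12)
        assert np.isnan(comp.table["pct_ss_total"]).all()


class TestReplicateRegression:
    def test_identical_profiles(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        e = sc.replicate_regression(x, x)
        assert e.slope == pytest.approx(1.0)
        assert e.r_squared == pytest.approx(1.0)

    def test_exact_half_slope(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        e = sc.replicate_regression(x, 0.5 * x)
        assert e.slope == pytest.approx(0.5)
        assert e.r_squared == pytest.approx(1.0)

    def test_degenerate_inputs(self):
        with pytest.raises(AnalysisError):
            sc.replicate_regression([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(AnalysisError):
            sc.replicate_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_independent_noise_r2_consistent_with_permutation_null(self):
        """R^2 between independent vectors sits inside the permutation null
        distribution of R^2 (not an outlier beyond its 99th percentile)."""
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=80), rng.normal(size=80)
        observed = sc.replicate_regression(x, y).r_squared
        null = np.array([sc.replicate_regression(x, rng.permutation(y)).r_squared
                         for _ in range(500)])
        assert observed <= np.quantile(null, 0.99)
        assert np.median(null) < 0.05

    def test_pairwise_medians_group_by_serum(self):
        profiles = pd.DataFrame(
            [[1.0, 2.0, 3.0], [1.1, 2.1, 3.1], [9.0, 1.0, 5.0]],
            index=["s1_a", "s1_b", "s2_a"])
        reg = sc.pairwise_replicate_regression(profiles, group=["s1", "s1", "s2"])
        assert len(reg.entries) == 1  # only the s1 pair
        assert reg.median_slope == pytest.approx(1.0)


class TestPairedComparison:
    def test_closed_form_t_and_p(self):
        """Differences (1, 2, 3, 4): t = mean / (sd / sqrt(n)), two-tailed p
        from the t distribution with 3 df."""
        matrix = pd.DataFrame({"A": [2.0, 4.0, 6.0, 8.0],
                               "B": [1.0, 2.0, 3.0, 4.0]})
        res = sc.paired_fraction_test(matrix, "A", "B")
        d = np.array([1.0, 2.0, 3.0, 4.0])
        t_expected = d.mean() / (d.std(ddof=1) / 2.0)
        assert res.t == pytest.approx(t_expected)
        assert res.df == 3
        assert res.p_value == pytest.approx(2 * sps.t.sf(t_expected, 3))
        # cross-check against the library paired test
        assert res.p_value == pytest.approx(
            sps.ttest_rel(matrix["A"], matrix["B"]).pvalue)

    def test_identical_fractions_degenerate(self):
        matrix = pd.DataFrame({"A": [1.0, 2.0, 3.0], "B": [1.0, 2.0, 3.0]})
        with pytest.raises(AnalysisError, match="zero variance"):
            sc.paired_fraction_test(matrix, "A", "B")

    def test_single_pair_rejected(self):
        matrix = pd.DataFrame({"A": [1.0], "B": [0.0]})
        with pytest.raises(AnalysisError):
            sc.paired_fraction_test(matrix, "A", "B")

    def test_missing_pairs_dropped(self):
        matrix = pd.DataFrame({"A": [2.0, np.nan, 6.0, 8.0],
                               "B": [1.0, 2.0, np.nan, 4.0]})
        res = sc.paired_fraction_test(matrix, "A", "B")
        assert res.n_pairs == 2


class TestElisaCalls:
    def test_strict_cutoff(self):
        calls = sc.elisa_calls([0.36, 0.35, 0.0])
        assert calls.tolist() == [True, False, False]

    def test_negative_values_rejected(self):
        with pytest.raises(AnalysisError):
            sc.elisa_calls([-0.1])


class TestConcordance:
    def test_published_style_2x2(self):
        """Counts (26, 116, 6, 92) over 240 pairs: proportions
        (0.11, 0.48, 0.03, 0.38) and 26/32 of ELISA positives captured."""
        tab = ConcordanceTable.from_counts(26, 116, 6, 92)
        assert tab.n == 240
        prop = tab.proportions
        assert prop.loc["ARRAY+", "ELISA+"] == pytest.approx(0.11, abs=0.005)
        assert prop.loc["ARRAY+", "ELISA-"] == pytest.approx(0.48, abs=0.005)
        assert prop.loc["ARRAY-", "ELISA+"] == pytest.approx(0.03, abs=0.005)
        assert prop.loc["ARRAY-", "ELISA-"] == pytest.approx(0.38, abs=0.005)
        assert tab.elisa_capture == pytest.approx(26 / 32)
        assert prop.to_numpy().sum() == pytest.approx(1.0)

    def test_from_paired_boolean_vectors(self):
        tab = sc.concordance_table([True, True, False, False],
                                   [True, False, True, False])
        assert (tab.counts.to_numpy() == 1).all()
        assert (tab.proportions.to_numpy() == 0.25).all()

    def test_perfect_agreement(self):
        tab = sc.concordance_table([True, False, True], [True, False, True])
        assert tab.counts.loc["ARRAY+", "ELISA-"] == 0
        assert tab.counts.loc["ARRAY-", "ELISA+"] == 0
        assert tab.elisa_capture == 1.0

    def test_missing_pairs_dropped_and_empty_errors(self):
        tab = sc.concordance_table([True, None, False], [True, True, None])
        assert tab.n == 1
        with pytest.raises(AnalysisError):
            sc.concordance_table([], [])
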