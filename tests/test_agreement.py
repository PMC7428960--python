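"""Agreement statistics: CCC, ICC, category limits, Mann-Whitney, report grid."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaquant import (
    StudySpec,
    categorize_agreement,
    icc_twoway,
    lin_ccc,
    mann_whitney_u,
    simulate_study,
    validation_report,
)
from gaquant.agreement import save_report, validate_table


class TestLinCCC:
    def test_perfect_concordance(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        r = lin_ccc(x, x)
        assert r.estimate == 1.0

    def test_constant_partner_gives_zero(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        r = lin_ccc(x, np.full(4, x.mean()))
        assert r.estimate == 0.0

    def test_four_point_moment_oracle(self):
        # hand-computed population moments for the printed 4-point pair:
        # means 2.5 / 2.575, s_x^2 = 1.25, s_y^2 = 1.286875, s_xy = 1.2625
        r = lin_ccc([1, 2, 3, 4], [1.1, 2.1, 2.9, 4.2])
        expected = 2 * 1.2625 / (1.25 + 1.286875 + (2.5 - 2.575) ** 2)
        assert r.estimate == pytest.approx(expected, abs=1e-10)
        assert r.ci95[0] <= r.estimate <= r.ci95[1]

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            lin_ccc([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            lin_ccc([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            lin_ccc([1.0, np.nan, 2.0], [1.0, 2.0, 3.0])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_ccc_never_exceeds_absolute_pearson(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 40))
        x = rng.normal(size=n)
        y = rng.normal(size=n) + rng.uniform(-1, 1) * x
        if np.var(x) == 0 or np.var(y) == 0:
            return
        ccc = lin_ccc(x, y).estimate
        r = np.corrcoef(x, y)[0, 1]
        assert abs(ccc) <= abs(r) + 1e-12

    def test_equals_pearson_when_moments_match(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=200)
        x = (x - x.mean()) / x.std()
        y = rng.normal(size=200)
        y = (y - y.mean()) / y.std()
        assert lin_ccc(x, y).estimate == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)

    def test_common_affine_invariance(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(5, 2, 50), rng.normal(5, 2, 50)
        base = lin_ccc(x, y).estimate
        assert lin_ccc(3.2 * x + 1.7, 3.2 * y + 1.7).estimate == pytest.approx(base, abs=1e-12)


def _anova_oracle(X):
    """Mean squares by explicit summation loops (independent of the package)."""
    n, k = len(X), len(X[0])
    grand = sum(sum(row) for row in X) / (n * k)
    row_means = [sum(row) / k for row in X]
    col_means = [sum(X[i][j] for i in range(n)) / n for j in range(k)]
    ssr = k * sum((m - grand) ** 2 for m in row_means)
    ssc = n * sum((m - grand) ** 2 for m in col_means)
    sst = sum((X[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = (sst - ssr - ssc) / ((n - 1) * (k - 1))
    return msr, msc, mse


FIXED_6x3 = np.array(
    [
        [9.0, 2.0, 5.0],
        [6.0, 1.0, 3.0],
        [8.0, 4.0, 6.0],
        [7.0, 1.0, 2.0],
        [10.0, 5.0, 6.0],
        [6.0, 2.0, 4.0],
    ]
)


class TestICC:
    def test_identical_columns_give_one_in_all_forms(self):
        X = np.tile(np.array([[3.0], [5.0], [9.0], [4.0]]), (1, 3))
        for model in ("random", "mixed"):
            for unit in ("single", "average"):
                assert icc_twoway(X, model, unit).estimate == 1.0

    def test_fixed_matrix_matches_mean_squares_oracle(self):
        n, k = FIXED_6x3.shape
        msr, msc, mse = _anova_oracle(FIXED_6x3.tolist())
        icc21 = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        icc31 = (msr - mse) / (msr + (k - 1) * mse)
        assert icc_twoway(FIXED_6x3, "random", "single").estimate == pytest.approx(icc21, abs=1e-10)
        assert icc_twoway(FIXED_6x3, "mixed", "single").estimate == pytest.approx(icc31, abs=1e-10)
        icc2k = (msr - mse) / (msr + (msc - mse) / n)
        icc3k = (msr - mse) / msr
        assert icc_twoway(FIXED_6x3, "random", "average").estimate == pytest.approx(icc2k, abs=1e-10)
        assert icc_twoway(FIXED_6x3, "mixed", "average").estimate == pytest.approx(icc3k, abs=1e-10)

    def test_matches_pingouin_cross_check(self):
        pg = pytest.importorskip("pingouin")
        X = FIXED_6x3
        n, k = X.shape
        long = pd.DataFrame(
            {
                "subj": np.repeat(np.arange(n), k),
                "rater": np.tile(np.arange(k), n),
                "y": X.ravel(),
            }
        )
        tab = pg.intraclass_corr(long, targets="subj", raters="rater", ratings="y").set_index("Type")
        pairs = {
            ("random", "single"): "ICC(A,1)",
            ("mixed", "single"): "ICC(C,1)",
            ("random", "average"): "ICC(A,k)",
            ("mixed", "average"): "ICC(C,k)",
        }
        for (model, unit), label in pairs.items():
            mine = icc_twoway(X, model, unit)
            assert mine.estimate == pytest.approx(tab.loc[label, "ICC"], abs=1e-10)
            lo, hi = tab.loc[label, "CI95"]
            assert mine.ci95[0] == pytest.approx(lo, abs=0.01)
            assert mine.ci95[1] == pytest.approx(hi, abs=0.01)

    def test_additive_model_recovery(self):
        # sigma_T^2 / sigma^2 = 9 -> ICC(2,1) ~ 0.9
        rng = np.random.default_rng(21)
        X = rng.normal(0, 3, (500, 1)) + rng.normal(0, 1, (500, 3))
        est = icc_twoway(X, "random", "single").estimate
        assert est == pytest.approx(0.9, abs=0.03)

    def test_zero_between_subject_variance_warns_and_returns_zero(self):
        X = np.tile(np.array([[1.0, 2.0, 3.0]]), (5, 1))
        with pytest.warns(UserWarning, match="between-subject"):
            r = icc_twoway(X, "random", "single")
        assert r.estimate == 0.0

    def test_incomplete_matrix_rejected(self):
        X = FIXED_6x3.copy()
        X[2, 1] = np.nan
        with pytest.raises(ValueError, match="complete"):
            icc_twoway(X, "random", "single")

    def test_common_affine_invariance(self):
        base = {
            (m, u): icc_twoway(FIXED_6x3, m, u).estimate
            for m in ("random", "mixed")
            for u in ("single", "average")
        }
        Y = 2.5 * FIXED_6x3 + 4.0
        for (m, u), v in base.items():
            assert icc_twoway(Y, m, u).estimate == pytest.approx(v, abs=1e-10)

    def test_estimates_converge_to_variance_ratio(self):
        # parameter recovery improves with n for the additive model
        target = 16 / 17
        errs = {}
        for n in (50, 200, 800):
            vals = []
            for seed in range(6):
                rng = np.random.default_rng(1000 * n + seed)
                X = rng.normal(0, 4, (n, 1)) + rng.normal(0, 1, (n, 3))
                vals.append(icc_twoway(X, "random", "single").estimate)
            errs[n] = np.mean(np.abs(np.array(vals) - target))
        assert errs[800] < errs[50]


class TestCategories:
    @pytest.mark.parametrize(
        "value,label",
        [
            (0.92, "moderate"),
            (0.97, "substantial"),
            (0.99, "almost perfect"),
            (0.89, "poor"),
            (0.94, "moderate"),
            (0.88, "poor"),
            (0.98, "substantial"),
            (0.95, "substantial"),
            (0.90, "moderate"),
            (0.50, "poor"),
        ],
    )
    def test_category_limits(self, value, label):
        assert categorize_agreement(value) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            categorize_agreement(1.2)


class TestMannWhitney:
    def test_separated_samples_match_full_enumeration(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        # enumerate all C(6,3)=20 rank assignments for the exact two-sided p
        ranks = range(1, 7)
        stats_all = []
        for combo in itertools.combinations(ranks, 3):
            r1 = sum(combo)
            u1 = r1 - 3 * 4 / 2
            stats_all.append(min(u1, 9 - u1))
        observed = 0.0
        p_exact = sum(s <= observed for s in stats_all) / len(stats_all)
        assert p == pytest.approx(p_exact, abs=1e-12)
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_identical_samples_give_p_one(self):
        _, p = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    def test_type_one_error_is_calibrated(self):
        rng = np.random.default_rng(77)
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            x, y = rng.normal(size=(2, 25))
            _, p = mann_whitney_u(x, y)
            rejections += p < 0.05
        assert 0.03 <= rejections / n_rep <= 0.07


class TestValidationReport:
    @staticmethod
    def _strata(df, rng):
        return pd.DataFrame(
            {
                "eye_id": df["eye_id"],
                "shape_class": rng.choice(["regular", "irregular"], len(df)),
                "number_class": rng.choice(["single", "multiple"], len(df)),
            }
        )

    def test_zero_noise_study_is_almost_perfect_everywhere(self):
        study = StudySpec(observer_sd=0.0, software_sd=0.0, observer_bias=(0, 0, 0), seed=2)
        df = simulate_study(study)
        rng = np.random.default_rng(4)
        report = validation_report(df, self._strata(df, rng))
        for key in ("ccc", "interobserver_icc", "intrasoftware_icc"):
            table = report[key]
            estimable = table[table["category"] != "not estimable"]
            assert estimable["estimate"].to_numpy() == pytest.approx(1.0)
            assert (estimable["category"] == "almost perfect").all()

    def test_report_contains_exactly_the_analysis_strata(self):
        df = simulate_study(StudySpec(seed=3))
        report = validation_report(df)
        assert list(report["ccc"]["sample"]) == [
            "whole",
            "regular",
            "irregular",
            "single",
            "multiple",
        ]

    def test_overall_ccc_matches_additive_model_algebra(self):
        # per-measure error SD sqrt(3) -> mean-of-3 error variance 1,
        # so CCC(mean manual, mean software) -> 16/17
        study = StudySpec(
            n_eyes=500,
            true_area_distribution=(30.0, 4.0, 0.1),
            observer_bias=(0.0, 0.0, 0.0),
            observer_sd=np.sqrt(3),
            software_sd=np.sqrt(3),
            seed=8,
        )
        report = validation_report(simulate_study(study))
        whole = report["ccc"].iloc[0]
        assert whole["estimate"] == pytest.approx(16 / 17, abs=0.02)

    def test_small_stratum_reported_not_estimable(self):
        df = simulate_study(StudySpec(n_eyes=10, seed=5))
        strata = pd.DataFrame(
            {
                "eye_id": df["eye_id"],
                "shape_class": ["regular"] * 9 + ["irregular"],
                "number_class": ["single"] * 10,
            }
        )
        report = validation_report(df, strata)
        row = report["ccc"].set_index("sample").loc["irregular"]
        assert row["category"] == "not estimable"
        assert np.isnan(row["estimate"])

    def test_summary_has_mann_whitney_and_ranges(self):
        df = simulate_study(StudySpec(seed=6))
        report = validation_report(df)
        summary = report["summary"].set_index("method")
        assert {"mean", "sd", "min", "max", "p_mann_whitney"} <= set(summary.columns)
        assert 0 <= summary.loc["automatic", "p_mann_whitney"] <= 1

    def test_save_report_writes_expected_files(self, tmp_path):
        df = simulate_study(StudySpec(seed=7))
        save_report(validation_report(df), tmp_path)
        for fname in (
            "table2_ccc.csv",
            "table3_interobserver.csv",
            "table4_intrasoftware.csv",
            "table5_summary.csv",
            "report.json",
        ):
            assert (tmp_path / fname).exists()

    def test_malformed_tables_rejected(self):
        with pytest.raises(ValueError, match="columns"):
            validate_table(pd.DataFrame({"eye_id": [1, 2], "foo": [1.0, 2.0]}))
        bad = simulate_study(StudySpec(seed=1)).copy()
        bad.loc[3, "rater_2"] = np.nan
        with pytest.raises(ValueError, match="row 3"):
            validate_table(bad)
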