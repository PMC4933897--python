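import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dcerepro import (categorize_icc, cov, design_matrix, icc,
                      icc_from_matrix, make_cohort, one_way_anova, paired_t)


def table_from_matrix(x, col="rater"):
    """Long-format table from a subjects x measurements matrix."""
    rows = []
    for i, row in enumerate(np.asarray(x), start=1):
        for j, v in enumerate(row, start=1):
            rec = {"subject": i, "rater": 1, "scan": 1, "replicate": 1,
                   "metric": "m", "value": float(v)}
            rec[col] = j
            rows.append(rec)
    return pd.DataFrame(rows)


class TestPairedT:
    def test_identical_vectors_flagged(self):
        r = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert np.isnan(r.estimate) and r.extra.get("undefined")

    def test_matches_hand_computation(self):
        a, b = np.array([1.0, 2, 3, 4]), np.array([2.0, 3, 5, 7])
        d = a - b
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(d.size))
        r = paired_t(a, b)
        assert r.estimate == pytest.approx(t_hand, rel=1e-12)

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(101)
        rejections = 0
        reps = 2000
        for _ in range(reps):
            a = rng.normal(0, 1, 21)
            b = rng.normal(0, 1, 21)
            if paired_t(a, b).p_value < 0.05:
                rejections += 1
        assert 0.035 <= rejections / reps <= 0.065


class TestAnova:
    def test_identical_groups_give_zero_f(self):
        g = [1.0, 2.0, 3.0]
        r = one_way_anova([g, g, g])
        assert r.estimate == pytest.approx(0.0)

    def test_matches_sums_of_squares_decomposition(self):
        groups = [np.array([1.0, 2, 3]), np.array([2.0, 4, 6]),
                  np.array([1.5, 2.5, 5.0])]
        allv = np.concatenate(groups)
        grand = allv.mean()
        ssb = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
        f_hand = (ssb / 2) / (ssw / (allv.size - 3))
        assert one_way_anova(groups).estimate == pytest.approx(f_hand, rel=1e-12)

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(202)
        rejections = 0
        reps = 2000
        for _ in range(reps):
            groups = [rng.normal(0, 1, 21) for _ in range(3)]
            if one_way_anova(groups).p_value < 0.05:
                rejections += 1
        assert 0.035 <= rejections / reps <= 0.065


class TestICC:
    def test_perfect_agreement(self):
        x = np.tile(np.arange(1.0, 7.0)[:, None], (1, 3))
        r = icc_from_matrix(x)
        assert r.estimate == pytest.approx(1.0)
        assert r.category == "good"

    def test_matches_mean_squares_oracle(self):
        # brute-force two-way ANOVA decomposition on a 6x4 layout
        rng = np.random.default_rng(33)
        x = rng.normal(5, 2, (6, 4)) + np.arange(6)[:, None]
        n, k = x.shape
        grand = x.mean()
        msr = k * ((x.mean(1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((x.mean(0) - grand) ** 2).sum() / (k - 1)
        mse = ((x - x.mean(1, keepdims=True) - x.mean(0, keepdims=True)
                + grand) ** 2).sum() / ((n - 1) * (k - 1))
        expected = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        assert icc_from_matrix(x).estimate == pytest.approx(expected, rel=1e-12)

    def test_matches_pingouin_absolute_agreement_single(self):
        pg = pytest.importorskip("pingouin")
        df = make_cohort(20, {"n_raters": 3},
                         {"between": 4, "rater": 0.5, "residual": 1}, seed=7)
        sub = df[(df["replicate"] == 1) & (df["scan"] == 1)]
        ref = pg.intraclass_corr(sub, targets="subject", raters="rater",
                                 ratings="value")
        ref = ref[ref["Type"] == "ICC(A,1)"].iloc[0] if \
            (ref["Type"] == "ICC(A,1)").any() else ref[ref["Type"] == "ICC2"].iloc[0]
        mine = icc(df, "inter")
        assert mine.estimate == pytest.approx(float(ref["ICC"]), abs=1e-10)
        assert mine.p_value == pytest.approx(float(ref["pval"]), rel=1e-6)

    def test_parameter_recovery_at_icc_09(self):
        ests = [icc(make_cohort(200, {"n_raters": 3},
                                {"between": 9, "rater": 0, "residual": 1},
                                seed=s), "inter").estimate
                for s in range(50)]
        assert np.mean(ests) == pytest.approx(0.9, abs=0.02)

    def test_variance_components_restatement(self):
        # on balanced data ICC(A,1) equals the variance-ratio form computed
        # from the same mean squares
        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, (15, 3)) + 2 * rng.normal(0, 1, 15)[:, None]
        r = icc_from_matrix(x)
        n, k = x.shape
        msr, msc, mse = r.extra["msr"], r.extra["msc"], r.extra["mse"]
        var_subj = (msr - mse) / k
        var_rater = (msc - mse) / n
        var_err = mse
        restated = var_subj / (var_subj + var_rater + var_err)
        assert r.estimate == pytest.approx(restated, abs=1e-8)

    @settings(derandomize=True, max_examples=20)
    @given(shift=st.floats(-5, 5), scale=st.floats(0.1, 10))
    def test_affine_invariance(self, shift, scale):
        rng = np.random.default_rng(12)
        x = rng.normal(3, 1, (10, 3)) + rng.normal(0, 2, 10)[:, None]
        a = icc_from_matrix(x).estimate
        b = icc_from_matrix(scale * x + shift).estimate
        assert b == pytest.approx(a, abs=1e-9)

    def test_incomplete_layout_rejected(self):
        df = table_from_matrix(np.ones((4, 3)))
        df = df.drop(df.index[2])
        with pytest.raises(ValueError, match="missing"):
            icc(df, "inter")

    def test_banding_rule(self):
        assert categorize_icc(0.9) == "good"
        assert categorize_icc(0.75) == "moderate"
        assert categorize_icc(0.5) == "moderate"
        assert categorize_icc(0.49) == "poor"
        assert categorize_icc(float("nan")) == "n/a"


class TestCoV:
    def test_identical_replicates_zero(self):
        x = np.tile(np.array([[3.0], [5.0], [7.0]]), (1, 2))
        df = table_from_matrix(x, col="scan")
        assert cov(df, "rescan").estimate == pytest.approx(0.0)

    def test_single_subject_arithmetic(self):
        x = np.array([[0.4, 0.6], [0.4, 0.6]])
        df = table_from_matrix(x, col="scan")
        expected = np.std([0.4, 0.6], ddof=1) / 0.5 * 100
        assert cov(df, "rescan").estimate == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(28.28, abs=0.01)

    def test_multiplicative_noise_recovery(self):
        # 5% multiplicative measurement noise, three readings per subject
        rng = np.random.default_rng(55)
        truth = rng.uniform(0.2, 0.8, 200)
        x = truth[:, None] * (1 + rng.normal(0, 0.05, (200, 3)))
        df = table_from_matrix(x, col="rater")
        assert 4.0 <= cov(df, "inter").estimate <= 6.0

    @settings(derandomize=True, max_examples=20)
    @given(scale=st.floats(0.1, 100))
    def test_scale_invariance(self, scale):
        rng = np.random.default_rng(3)
        x = rng.uniform(1, 2, (8, 3))
        a = cov(table_from_matrix(x), "inter").estimate
        b = cov(table_from_matrix(scale * x), "inter").estimate
        assert b == pytest.approx(a, rel=1e-9)

    def test_negative_mean_uses_absolute_value(self):
        x = np.array([[-1.0, -1.2], [-0.8, -1.0]])
        df = table_from_matrix(x, col="scan")
        r = cov(df, "rescan")
        assert r.estimate > 0
        assert r.extra["abs_mean_denominator"]

    def test_zero_mean_subject_excluded_and_counted(self):
        x = np.array([[-1.0, 1.0], [2.0, 4.0], [3.0, 3.0]])
        df = table_from_matrix(x, col="scan")
        r = cov(df, "rescan")
        assert r.extra["n_subjects_flagged_zero_mean"] == 1
        assert np.isfinite(r.estimate)


class TestCohort:
    def test_degenerate_variances_give_perfect_icc(self):
        df = make_cohort(6, {"n_raters": 3},
                         {"between": 1, "rater": 0, "residual": 0}, seed=1)
        assert icc(df, "inter").estimate == pytest.approx(1.0)

    def test_population_icc_recorded(self):
        df = make_cohort(5, variance_components={"between": 9, "rater": 0,
                                                 "residual": 1})
        assert df.attrs["population_icc"] == pytest.approx(0.9)

    def test_determinism(self):
        a = make_cohort(10, seed=3)
        b = make_cohort(10, seed=3)
        pd.testing.assert_frame_equal(a, b)


def test_design_matrix_shapes():
    df = make_cohort(7, {"n_raters": 3, "n_replicates": 2, "n_scans": 2}, seed=0)
    assert design_matrix(df, "inter").shape == (7, 3)
    assert design_matrix(df, "intra").shape == (7, 2)
    assert design_matrix(df, "rescan").shape == (7, 2)
    with pytest.raises(ValueError):
        design_matrix(df, "bogus")
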