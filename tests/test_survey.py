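import numpy as np
import pandas as pd
import pytest

from bevmod import (
    EstimationError,
    LonelyPsuError,
    SurveyDesign,
    age_group_lsmeans,
    paired_design_test,
    percent_change,
    population_ratio_mean,
    trend_regression,
)


def _one_stratum(n=6):
    return SurveyDesign(
        weights=np.ones(n),
        strata=np.zeros(n, int),
        psu=np.tile([0, 1], n // 2),
    )


class TestPopulationRatioMean:
    def test_constant_data_zero_se(self):
        d = _one_stratum()
        est = population_ratio_mean(np.full(6, 3.5), d)
        assert est.point == pytest.approx(3.5)
        assert est.se == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        d = SurveyDesign(weights=[1.0, 3.0], strata=[0, 0], psu=[0, 1])
        est = population_ratio_mean([10.0, 20.0], d)
        assert est.point == pytest.approx(17.5)

    def test_equal_weights_is_sample_mean(self, random_design):
        rng = np.random.default_rng(0)
        x, _, strata, psu = random_design(rng)
        d = SurveyDesign(np.ones(len(x)), strata, psu)
        est = population_ratio_mean(x, d)
        assert est.point == pytest.approx(float(np.mean(x)), rel=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(EstimationError):
            SurveyDesign(weights=[], strata=[], psu=[])

    def test_nonpositive_weights_rejected(self):
        with pytest.raises(EstimationError):
            SurveyDesign(weights=[1.0, 0.0], strata=[0, 0], psu=[0, 1])


class TestTaylorSE:
    def test_two_psu_closed_form(self):
        # one stratum, two PSUs: var = n_h/(n_h-1)·Σ(t_j − t̄)² = (t1−t2)²
        d = SurveyDesign(weights=[2.0, 1.0, 1.0], strata=[0, 0, 0], psu=[0, 0, 1])
        x = np.array([5.0, 3.0, 9.0])
        est = population_ratio_mean(x, d)
        R = (2 * 5 + 3 + 9) / 4.0
        t1 = (2 * (5 - R) + (3 - R)) / 4.0
        t2 = (9 - R) / 4.0
        assert est.se == pytest.approx(abs(t1 - t2))

    def test_lonely_psu_error_names_stratum(self):
        d = SurveyDesign(
            weights=[1.0, 1.0, 1.0], strata=["a", "a", "b"], psu=[0, 1, 0]
        )
        with pytest.raises(LonelyPsuError, match="b"):
            population_ratio_mean([1.0, 2.0, 3.0], d)

    def test_invariant_to_uniform_weight_rescaling(self, random_design):
        rng = np.random.default_rng(1)
        x, w, strata, psu = random_design(rng)
        e1 = population_ratio_mean(x, SurveyDesign(w, strata, psu))
        e2 = population_ratio_mean(x, SurveyDesign(w * 7.3, strata, psu))
        assert e1.point == pytest.approx(e2.point, rel=1e-12)
        assert e1.se == pytest.approx(e2.se, rel=1e-12)

    def test_matches_jackknife_oracle(self, random_design, jackknife_ratio_se):
        rng = np.random.default_rng(2)
        for _ in range(5):
            x, w, strata, psu = random_design(rng)
            est = population_ratio_mean(x, SurveyDesign(w, strata, psu))
            jk = jackknife_ratio_se(x, w, strata, psu)
            assert abs(est.se - jk) / jk < 0.15


def _regression_frame(rng, n=240, noise=0.0, slope=-60.0, intercept=487.0):
    age = rng.integers(1, 6, n)
    df = pd.DataFrame(
        {
            "age": age,
            "gender": rng.choice(["male", "female"], n),
            "ethnicity": rng.choice(["non_hispanic_white", "other"], n),
            "pir_category": rng.choice(["<1.35", ">1.85"], n),
            "weight": rng.lognormal(0, 0.4, n),
            "stratum": np.arange(n) % 8,
            "psu": (np.arange(n) // 8) % 2,
        }
    )
    df["y"] = intercept + slope * df["age"] + noise * rng.normal(size=n)
    return df


class TestTrendRegression:
    def test_constant_outcome_zero_slope(self):
        rng = np.random.default_rng(3)
        df = _regression_frame(rng, slope=0.0, noise=0.0, intercept=5.0)
        res = trend_regression(df, "y", SurveyDesign.from_frame(df))
        assert res.beta_age == pytest.approx(0.0, abs=1e-9)

    def test_noise_free_line_recovered_exactly(self):
        rng = np.random.default_rng(4)
        df = _regression_frame(rng, slope=-60.0, noise=0.0)
        res = trend_regression(df, "y", SurveyDesign.from_frame(df))
        assert res.beta_age == pytest.approx(-60.0, rel=1e-9)
        assert res.se == pytest.approx(0.0, abs=1e-6)

    def test_collinear_covariates_rejected(self):
        rng = np.random.default_rng(5)
        df = _regression_frame(rng, noise=10.0)
        df["gender_copy"] = df["gender"]
        with pytest.raises(EstimationError, match="rank"):
            trend_regression(
                df, "y", SurveyDesign.from_frame(df),
                covariates=("gender", "gender_copy"),
            )

    def test_slope_recovery_with_noise(self):
        rng = np.random.default_rng(6)
        df = _regression_frame(rng, n=2000, slope=-60.0, noise=80.0)
        res = trend_regression(df, "y", SurveyDesign.from_frame(df))
        assert abs(res.beta_age - (-60.0)) < 3 * res.se
        assert 0.0 <= res.p_value <= 1.0


class TestLsMeans:
    def test_saturated_age_model_reproduces_weighted_means(self):
        rng = np.random.default_rng(7)
        df = _regression_frame(rng, n=400, noise=30.0)
        design = SurveyDesign.from_frame(df)
        ls = age_group_lsmeans(df, "y", design, covariates=())
        for _, row in ls.iterrows():
            sub = df[df["age"] == row["age"]]
            wmean = np.average(sub["y"], weights=sub["weight"])
            assert row["lsmean"] == pytest.approx(wmean, rel=1e-9)


class TestPairedTest:
    def test_no_change_p_one(self):
        d = _one_stratum()
        x = np.arange(6, dtype=float)
        est = paired_design_test(x, x, d)
        assert est.point == 0.0
        assert est.p_value == 1.0
        assert est.degenerate

    def test_constant_shift_degenerate_flagged(self):
        d = _one_stratum()
        x = np.arange(6, dtype=float)
        est = paired_design_test(x, x + 2.5, d)
        assert est.point == pytest.approx(2.5)
        assert est.se == 0.0
        assert est.p_value == 0.0
        assert est.degenerate

    def test_equals_one_sample_test_on_differences(self, random_design):
        # direct difference-then-ratio-mean oracle
        from scipy import stats

        rng = np.random.default_rng(8)
        x, w, strata, psu = random_design(rng)
        b = x
        a = x + rng.normal(0, 10, len(x))
        design = SurveyDesign(w, strata, psu)
        est = paired_design_test(b, a, design)
        oracle = population_ratio_mean(a - b, design)
        assert est.point == pytest.approx(oracle.point, rel=1e-12)
        assert est.se == pytest.approx(oracle.se, rel=1e-12)
        p = 2 * stats.t.sf(abs(oracle.point / oracle.se), oracle.df)
        assert est.p_value == pytest.approx(p, rel=1e-12)

    def test_mismatched_subjects_rejected(self):
        d = _one_stratum()
        with pytest.raises(EstimationError):
            paired_design_test(np.zeros(6), np.zeros(5), d)


class TestPercentChange:
    @pytest.mark.parametrize(
        "first,last,expected",
        [
            (421.0, 348.0, -17.0),
            (16.5, 81.7, 395.0),
            (100.0, 100.0, 0.0),
            (72.5, 151.0, 108.0),
        ],
    )
    def test_examples(self, first, last, expected):
        assert percent_change(first, last) == expected

    def test_unrounded(self):
        assert percent_change(100.0, 150.5, rounded=False) == pytest.approx(50.5)

    def test_zero_first_rejected(self):
        with pytest.raises(EstimationError):
            percent_change(0.0, 5.0)
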