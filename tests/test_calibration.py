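"""Regional recalibration: OLS fits, coefficient simplification, thresholds."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

import fpscore as f
from fpscore.calibration import SimplificationRule, _MIN_N
from fpscore.scoring import TTA_COUNT_COEFFICIENTS

from conftest import make_cohort

REFERENCE_SLOPES = {"N_A": 0.056, "N_B": 1.172, "N_C": 22.161, "N_D": 36.198}
REFERENCE_INTERCEPT = 0.031


def ols_normal_equations(X, y):
    """Independent OLS oracle: solve the normal equations with an explicit
    intercept column via lstsq."""
    design = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return beta  # [intercept, slopes...]


class TestFitTTARegression:
    def test_noiseless_recovery(self, noiseless_tta_cohort):
        """TTA built exactly from the reference linear predictor is refit with
        R^2 = 1 and coefficients recovered to 1e-8."""
        fit = f.fit_tta_regression(noiseless_tta_cohort)
        assert fit.n == 27
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)
        assert fit.intercept == pytest.approx(REFERENCE_INTERCEPT, abs=1e-8)
        for name, truth in REFERENCE_SLOPES.items():
            assert fit.coefficients[name] == pytest.approx(truth, abs=1e-8)
        assert fit.unidentifiable == ()
        assert abs(fit.residuals.sum()) < 1e-8 * fit.n * 100

    def test_constant_tta_gives_zero_r2(self):
        rng = np.random.default_rng(0)
        rows = [tuple(rng.integers(0, 10, size=4)) for _ in range(12)]
        cohort = make_cohort(rows).with_tta(
            pd.Series(5.0, index=[f"T{i + 1}" for i in range(12)])
        )
        fit = f.fit_tta_regression(cohort)
        assert fit.r_squared == pytest.approx(0.0, abs=1e-10)
        for slope in fit.coefficients.values():
            assert slope == pytest.approx(0.0, abs=1e-8)

    def test_too_few_turtles_rejected(self):
        cohort = make_cohort([(1, 0, 0, 0), (0, 1, 0, 0), (0, 0, 1, 0)])
        cohort = cohort.with_tta(pd.Series([1.0, 2.0, 3.0], index=cohort.turtle_ids))
        with pytest.raises(ValueError, match=str(_MIN_N)):
            f.fit_tta_regression(cohort)

    def test_missing_tta_column_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="tta"):
            f.fit_tta_regression(small_cohort)

    def test_constant_class_flagged_unidentifiable(self):
        rng = np.random.default_rng(1)
        rows = [(int(a), int(b), int(c), 0) for a, b, c in rng.integers(0, 8, (10, 3))]
        cohort = make_cohort(rows)
        marg = cohort.marginals()
        tta = TTA_COUNT_COEFFICIENTS.evaluate(
            marg["N_A"], marg["N_B"], marg["N_C"], marg["N_D"]
        )
        cohort = cohort.with_tta(pd.Series(np.asarray(tta), index=cohort.turtle_ids))
        with pytest.warns(UserWarning, match="unidentifiable"):
            fit = f.fit_tta_regression(cohort)
        assert fit.unidentifiable == ("N_D",)
        assert np.isnan(fit.coefficients["N_D"])
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_matches_normal_equations_oracle(self):
        """On small datasets the fit equals a brute-force lstsq solve."""
        rng = np.random.default_rng(42)
        X = rng.integers(0, 12, size=(10, 4)).astype(float)
        y = rng.normal(20, 10, size=10)
        fit = f.fit_tta_regression(X, y)
        beta = ols_normal_equations(X, y)
        assert fit.intercept == pytest.approx(beta[0], abs=1e-8)
        for j, name in enumerate(["N_A", "N_B", "N_C", "N_D"]):
            assert fit.coefficients[name] == pytest.approx(beta[j + 1], abs=1e-8)

    def test_r2_invariant_under_unit_change(self):
        rng = np.random.default_rng(3)
        X = rng.integers(0, 12, size=(20, 4)).astype(float)
        y = rng.normal(20, 10, size=20)
        r2_cm2 = f.fit_tta_regression(X, y).r_squared
        r2_mm2 = f.fit_tta_regression(X, 100.0 * y + 7.0).r_squared
        assert r2_cm2 == pytest.approx(r2_mm2, abs=1e-12)

    def test_noisy_recovery_slopes_within_three_se(self):
        """With Gaussian noise (SD 5 cm^2) on 27-turtle subsets, identifiable
        slopes land within 3 standard errors of truth in >= 95% of seeded
        replicates (quick 60-replicate version of the full check)."""
        hits = total = 0
        for seed in range(60):
            cfg = f.default_config(seed=seed, tta_noise_sd=5.0)
            cohort = f.generate_cohort(cfg, with_subjective=False)
            fit = _fit_quiet(cohort)
            for name, truth in REFERENCE_SLOPES.items():
                b, se = fit.coefficients[name], fit.std_errors[name]
                if np.isnan(b):
                    continue
                total += 1
                hits += abs(b - truth) <= 3 * se
        assert hits / total >= 0.95


def _fit_quiet(cohort):
    """Fit while silencing the unidentifiable-class warning some replicates
    emit (their NaN slopes are excluded from the coverage tally)."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return f.fit_tta_regression(cohort)


class TestSimplifyCoefficients:
    def test_reference_slopes_simplify_to_canonical_weights(self):
        fit = f.RegressionFit(
            coefficients=dict(REFERENCE_SLOPES),
            intercept=REFERENCE_INTERCEPT,
            r_squared=0.9385,
            n=27,
            residuals=np.zeros(27),
        )
        coeff = f.simplify_coefficients(fit)
        assert coeff.weights == (0.1, 1, 20, 40)
        assert coeff.intercept == 0.0

    def test_candidate_values_are_fixed_points(self):
        fit = f.RegressionFit(
            coefficients={"N_A": 0.1, "N_B": 1.0, "N_C": 20.0, "N_D": 40.0},
            intercept=0.5,
            r_squared=1.0,
            n=10,
            residuals=np.zeros(10),
        )
        assert f.simplify_coefficients(fit).weights == (0.1, 1, 20, 40)

    def test_tie_goes_to_larger_candidate(self):
        rule = SimplificationRule(candidate_set=(20.0, 40.0))
        assert rule.snap(30.0) == 40.0

    def test_negative_slope_aborts(self):
        fit = f.RegressionFit(
            coefficients={"N_A": -0.1, "N_B": 1.0, "N_C": 20.0, "N_D": 40.0},
            intercept=0.0,
            r_squared=0.5,
            n=10,
            residuals=np.zeros(10),
        )
        with pytest.raises(ValueError, match="negative"):
            f.simplify_coefficients(fit)

    def test_non_monotone_result_rejected(self):
        fit = f.RegressionFit(
            coefficients={"N_A": 5.0, "N_B": 0.2, "N_C": 20.0, "N_D": 40.0},
            intercept=0.0,
            r_squared=0.5,
            n=10,
            residuals=np.zeros(10),
        )
        with pytest.raises(ValueError, match="non-decreasing"):
            f.simplify_coefficients(fit)

    def test_invalid_candidate_set_rejected(self):
        with pytest.raises(ValueError):
            SimplificationRule(candidate_set=(1.0, 1.0, 2.0))
        with pytest.raises(ValueError):
            SimplificationRule(candidate_set=(-1.0, 2.0))


class TestFitIndexRegression:
    def test_exact_linear_relation_recovered(self):
        rng = np.random.default_rng(5)
        X = rng.integers(0, 15, size=(30, 4)).astype(float)
        index = f.FPI_COEFFICIENTS.evaluate(X[:, 0], X[:, 1], X[:, 2], X[:, 3])
        y = 0.16 + 1.11 * np.asarray(index)
        fit = f.fit_index_regression(X, f.FPI_COEFFICIENTS, y=y)
        assert fit.coefficients["index"] == pytest.approx(1.11, abs=1e-10)
        assert fit.intercept == pytest.approx(0.16, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_permutation_null_gives_near_zero_r2(self):
        """TTA decoupled from the index by permutation leaves nothing to
        explain: R^2 below 0.1 at n = 200."""
        rng = np.random.default_rng(11)
        X = rng.integers(0, 15, size=(200, 4)).astype(float)
        index = np.asarray(
            f.FPI_COEFFICIENTS.evaluate(X[:, 0], X[:, 1], X[:, 2], X[:, 3])
        )
        y = 0.16 + 1.11 * rng.permutation(index)
        fit = f.fit_index_regression(X, f.FPI_COEFFICIENTS, y=y)
        assert fit.r_squared < 0.1

    def test_constant_index_rejected(self):
        X = np.tile([1.0, 2.0, 0.0, 0.0], (10, 1))
        with pytest.raises(ValueError, match="constant"):
            f.fit_index_regression(X, f.FPI_COEFFICIENTS, y=np.arange(10.0))


class TestDeriveThresholds:
    def test_canonical_round_trip(self):
        fit = f.RegressionFit(
            coefficients={"index": 1.11},
            intercept=0.16,
            r_squared=0.937,
            n=27,
            residuals=np.zeros(27),
        )
        thresh = f.derive_thresholds(fit)  # default cutpoints (44.56, 133.36)
        assert (thresh.mild_upper, thresh.moderate_upper) == (40.0, 120.0)

    def test_simple_inversion(self):
        fit = f.RegressionFit(
            coefficients={"index": 2.0},
            intercept=0.0,
            r_squared=1.0,
            n=10,
            residuals=np.zeros(10),
        )
        thresh = f.derive_thresholds(fit, tta_cutpoints=(80.0, 240.0))
        assert (thresh.mild_upper, thresh.moderate_upper) == (40.0, 120.0)

    def test_non_positive_slope_rejected(self):
        fit = f.RegressionFit(
            coefficients={"index": 0.0},
            intercept=0.0,
            r_squared=0.0,
            n=10,
            residuals=np.zeros(10),
        )
        with pytest.raises(ValueError, match="slope"):
            f.derive_thresholds(fit)


class TestFPICalibrator:
    def test_full_pipeline_on_noiseless_fixture(self, noiseless_tta_cohort):
        cal = f.FPICalibrator().fit(noiseless_tta_cohort)
        assert cal.coefficients_.weights == (0.1, 1, 20, 40)
        assert (cal.thresholds_.mild_upper, cal.thresholds_.moderate_upper) == (
            40.0,
            120.0,
        )
        assert cal.count_fit_.r_squared == pytest.approx(1.0, abs=1e-10)
        # simplified index remains an excellent TTA predictor
        assert cal.index_fit_.r_squared >= 0.9

    def test_predict_matches_index_line(self, noiseless_tta_cohort):
        cal = f.FPICalibrator().fit(noiseless_tta_cohort)
        X = np.array([[10, 10, 1, 0], [0, 0, 6, 1]], dtype=float)
        expected = cal.index_fit_.intercept + cal.index_fit_.coefficients[
            "index"
        ] * np.asarray(
            cal.coefficients_.evaluate(X[:, 0], X[:, 1], X[:, 2], X[:, 3])
        )
        np.testing.assert_allclose(cal.predict(X), expected)

    def test_to_scorer_applies_calibrated_thresholds(self, noiseless_tta_cohort):
        scorer = f.FPICalibrator().fit(noiseless_tta_cohort).to_scorer()
        assert list(scorer.predict(np.array([[0, 39, 0, 0], [0, 41, 0, 0]]))) == [
            "mild",
            "moderate",
        ]

    def test_sklearn_protocol(self):
        cal = f.FPICalibrator(threshold_granularity=5.0)
        assert clone(cal).get_params() == cal.get_params()
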