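"""Regional recalibration of the index and score thresholds.

The canonical FPI weights and (40, 120) thresholds were derived for green
sea turtles on the Southwest Atlantic coast; lesion-size profiles differ
between regions, so the same construction should be re-run on local data.
The workflow, given a cohort with measured total tumor area (TTA, cm^2) on
at least a subset of turtles:

1. ordinary least squares of TTA on the four size-class marginals
   (:func:`fit_tta_regression`);
2. simplification of the fitted slopes to "nice" field-usable weights
   (:func:`simplify_coefficients`), giving an FPI-style index;
3. simple OLS of TTA on the new index (:func:`fit_index_regression`);
4. inversion of that line at two TTA cutpoints to obtain ordinal score
   thresholds (:func:`derive_thresholds`).

:class:`FPICalibrator` packages the four steps as a scikit-learn estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .datamodel import Cohort, IndexCoefficients, RegressionFit, ScoreThresholds, warn
from .scoring import SeverityScorer
from .vocab import SIZE_CLASSES

#: Default "nice" candidate weights for coefficient simplification. Chosen so
#: that slopes near the canonical regression estimates (0.056, 1.172, 22.161,
#: 36.198) simplify to the published weights (0.1, 1, 20, 40); note 0.05 is
#: deliberately absent, see docs/methods.md.
DEFAULT_CANDIDATES: tuple[float, ...] = (0.1, 0.2, 0.5, 1, 2, 5, 10, 20, 40, 50, 100)

#: Default TTA cutpoints (cm^2): the canonical index-regression line
#: (TTA = 0.16 + 1.11 FPI) evaluated at FPI = 40 and 120, so inverting at
#: them recovers the canonical thresholds.
DEFAULT_TTA_CUTPOINTS: tuple[float, float] = (44.56, 133.36)

_MIN_N = 6  # fewer observations than intercept + 4 slopes + 1 is under-determined


@dataclass(frozen=True)
class SimplificationRule:
    """How fitted slopes become field-usable index weights.

    Each slope is mapped to the nearest value in ``candidate_set`` (ties go
    to the larger candidate); the regression intercept is dropped when
    ``drop_intercept`` so the index of a tumor-free turtle is exactly 0.
    """

    candidate_set: tuple[float, ...] = DEFAULT_CANDIDATES
    drop_intercept: bool = True

    def __post_init__(self) -> None:
        cs = tuple(self.candidate_set)
        if not cs or any(c <= 0 for c in cs) or list(cs) != sorted(set(cs)):
            raise ValueError(
                f"candidate_set must be strictly increasing and positive, got {cs}"
            )
        object.__setattr__(self, "candidate_set", cs)

    def snap(self, slope: float) -> float:
        """Nearest candidate to ``slope``; exact ties resolve to the larger."""
        best = min(self.candidate_set, key=lambda c: (abs(c - slope), -c))
        return best


def _extract_xy(cohort_or_X, y=None) -> tuple[np.ndarray, np.ndarray]:
    """Accept (Cohort with tta_cm2) or (X marginals, y TTA) and return arrays."""
    if isinstance(cohort_or_X, Cohort):
        if cohort_or_X.tta_cm2 is None:
            raise ValueError("cohort has no tta_cm2 column; measure TTA first")
        marg = cohort_or_X.marginals()
        mask = cohort_or_X.tta_cm2.notna()
        X = marg.loc[mask, [f"N_{c}" for c in SIZE_CLASSES]].to_numpy(float)
        yv = cohort_or_X.tta_cm2[mask].to_numpy(float)
        return X, yv
    X = np.asarray(cohort_or_X, dtype=float)
    if X.ndim != 2 or X.shape[1] != 4:
        raise ValueError(f"expected (n, 4) marginals, got shape {X.shape}")
    if y is None:
        raise ValueError("y (TTA values) required when passing a raw array")
    return X, np.asarray(y, dtype=float)


def fit_tta_regression(cohort_or_X, y=None) -> RegressionFit:
    """OLS of measured TTA on the four size-class marginals, with intercept.

    Requires at least 6 turtles with TTA. A size class that never varies in
    the data (e.g. no turtle has a D tumor) cannot be identified; its slope
    is reported as NaN with a warning and the fit proceeds without it.
    """
    X, yv = _extract_xy(cohort_or_X, y)
    n = len(yv)
    if n < _MIN_N:
        raise ValueError(
            f"need at least {_MIN_N} turtles with measured TTA, got {n}"
        )
    names = [f"N_{c}" for c in SIZE_CLASSES]
    variances = X.var(axis=0)
    dead = [names[j] for j in range(4) if variances[j] == 0]
    if len(dead) == 4:
        raise ValueError("all four size-class marginals are constant; cannot fit")
    if dead:
        warn(
            f"size-class predictors {dead} are constant in this cohort; "
            "their coefficients are unidentifiable and reported as NaN"
        )
    live = [j for j in range(4) if names[j] not in dead]
    design = sm.add_constant(X[:, live], has_constant="add")
    res = sm.OLS(yv, design).fit()

    coeffs = {name: float("nan") for name in names}
    ses = {name: float("nan") for name in names}
    for k, j in enumerate(live):
        coeffs[names[j]] = float(res.params[k + 1])
        ses[names[j]] = float(res.bse[k + 1])
    r2 = float(res.rsquared)
    # a constant response makes SS_tot = 0; report R^2 = 0 by convention
    if not np.isfinite(r2):
        r2 = 0.0
    return RegressionFit(
        coefficients=coeffs,
        intercept=float(res.params[0]),
        r_squared=min(max(r2, 0.0), 1.0),
        n=n,
        residuals=np.asarray(res.resid),
        std_errors=ses,
        unidentifiable=tuple(dead),
    )


def simplify_coefficients(
    fit: RegressionFit, rule: SimplificationRule | None = None
) -> IndexCoefficients:
    """Snap fitted slopes to the candidate set, producing index weights.

    Negative slopes abort (they indicate data problems a weight of zero would
    silently hide), as does a simplified weight order that decreases with
    size class.
    """
    rule = rule or SimplificationRule()
    names = [f"N_{c}" for c in SIZE_CLASSES]
    slopes = [fit.coefficients[name] for name in names]
    bad = [n_ for n_, s in zip(names, slopes) if not np.isfinite(s) or s < 0]
    if bad:
        raise ValueError(
            f"slopes for {bad} are negative or unidentifiable; review the data "
            "before simplifying"
        )
    snapped = [rule.snap(s) for s in slopes]
    if snapped != sorted(snapped):
        raise ValueError(
            f"simplified weights {snapped} are not non-decreasing across size "
            "classes; choose a different candidate set"
        )
    intercept = 0.0 if rule.drop_intercept else fit.intercept
    return IndexCoefficients(*snapped, intercept=intercept)


def fit_index_regression(
    cohort_or_X, coefficients: IndexCoefficients, y=None
) -> RegressionFit:
    """Simple OLS of measured TTA on the index defined by ``coefficients``."""
    X, yv = _extract_xy(cohort_or_X, y)
    if len(yv) < 3:
        raise ValueError(f"need at least 3 observations, got {len(yv)}")
    index = coefficients.evaluate(X[:, 0], X[:, 1], X[:, 2], X[:, 3])
    index = np.atleast_1d(index)
    if np.ptp(index) == 0:
        raise ValueError("index is constant over the cohort; cannot regress TTA on it")
    design = sm.add_constant(index, has_constant="add")
    res = sm.OLS(yv, design).fit()
    r2 = float(res.rsquared)
    if not np.isfinite(r2):
        r2 = 0.0
    return RegressionFit(
        coefficients={"index": float(res.params[1])},
        intercept=float(res.params[0]),
        r_squared=min(max(r2, 0.0), 1.0),
        n=len(yv),
        residuals=np.asarray(res.resid),
        std_errors={"index": float(res.bse[1])},
    )


def derive_thresholds(
    fit: RegressionFit,
    tta_cutpoints: tuple[float, float] = DEFAULT_TTA_CUTPOINTS,
    granularity: float | None = 10.0,
) -> ScoreThresholds:
    """Invert the TTA-on-index line at two TTA cutpoints to get index
    thresholds: t = (cutpoint - intercept) / slope, rounded to ``granularity``
    (None disables rounding)."""
    slope = fit.coefficients.get("index")
    if slope is None:
        raise ValueError("fit must be a TTA-on-index simple regression")
    if not slope > 0:
        raise ValueError(f"index slope must be positive, got {slope}")
    lo, hi = tta_cutpoints
    if not lo < hi:
        raise ValueError(f"tta_cutpoints must be increasing, got {tta_cutpoints}")
    ts = [(c - fit.intercept) / slope for c in (lo, hi)]
    if granularity:
        ts = [round(t / granularity) * granularity for t in ts]
    return ScoreThresholds(mild_upper=ts[0], moderate_upper=ts[1])


class FPICalibrator(RegressorMixin, BaseEstimator):
    """End-to-end index calibration as a scikit-learn regressor.

    ``fit(X, y)`` takes an (n, 4) array of size-class marginals (or a
    :class:`Cohort` carrying measured ``tta_cm2``) and measured TTA values,
    and runs the full workflow: count regression, weight simplification,
    index regression, threshold derivation. ``predict`` returns TTA
    predicted from the calibrated index, so ``score`` is the R^2 of the
    simplified-index predictor.

    Attributes (after fit)
    ----------------------
    count_fit_ : RegressionFit of TTA on the four marginals
    coefficients_ : IndexCoefficients, the simplified index weights
    index_fit_ : RegressionFit of TTA on the simplified index
    thresholds_ : ScoreThresholds for the ordinal score
    """

    def __init__(
        self,
        candidate_set: tuple[float, ...] = DEFAULT_CANDIDATES,
        drop_intercept: bool = True,
        tta_cutpoints: tuple[float, float] = DEFAULT_TTA_CUTPOINTS,
        threshold_granularity: float | None = 10.0,
    ) -> None:
        self.candidate_set = candidate_set
        self.drop_intercept = drop_intercept
        self.tta_cutpoints = tta_cutpoints
        self.threshold_granularity = threshold_granularity

    def fit(self, X, y=None) -> "FPICalibrator":
        rule = SimplificationRule(
            candidate_set=tuple(self.candidate_set),
            drop_intercept=self.drop_intercept,
        )
        self.count_fit_ = fit_tta_regression(X, y)
        self.coefficients_ = simplify_coefficients(self.count_fit_, rule)
        self.index_fit_ = fit_index_regression(X, self.coefficients_, y)
        self.thresholds_ = derive_thresholds(
            self.index_fit_,
            tta_cutpoints=tuple(self.tta_cutpoints),
            granularity=self.threshold_granularity,
        )
        self.n_features_in_ = 4
        return self

    def predict(self, X) -> np.ndarray:
        """TTA (cm^2) predicted from the calibrated index."""
        check_is_fitted(self)
        if isinstance(X, Cohort):
            X = X.marginals()[[f"N_{c}" for c in SIZE_CLASSES]]
        X = np.asarray(X, dtype=float)
        index = self.coefficients_.evaluate(X[:, 0], X[:, 1], X[:, 2], X[:, 3])
        return self.index_fit_.intercept + self.index_fit_.coefficients["index"] * (
            np.atleast_1d(index)
        )

    def to_scorer(self, system: str = "swa") -> SeverityScorer:
        """A :class:`SeverityScorer` configured with the calibrated weights
        and thresholds (fitted, ready to predict)."""
        check_is_fitted(self)
        return SeverityScorer(
            weights=self.coefficients_.weights,
            intercept=self.coefficients_.intercept,
            mild_upper=self.thresholds_.mild_upper,
            moderate_upper=self.thresholds_.moderate_upper,
            system=system,
        ).fit()
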