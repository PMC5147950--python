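"""Core severity formulas: size classes, ellipse tumor area, the FPI weighted
index, total-tumor-area (TTA) predictors, and the two ordinal classifiers.

The index and score system
--------------------------
Each turtle's external tumors are counted by diameter class (A: <1 cm,
B: 1-4 cm, C: >4-10 cm, D: >10 cm) across eleven body regions, giving
marginal totals N_A..N_D. The fibropapillomatosis index is the weighted sum

    FPI = 0.1 N_A + 1 N_B + 20 N_C + 40 N_D,

a rapid field proxy for the total cross-sectional tumor area (TTA, cm^2).
Two ordinal classifiers map a turtle to mild/moderate/severe:

* ``FPS_SWA`` (Southwest Atlantic score): FPI thresholded at 40 and 120.
* ``FPS_HWI`` (adapted Hawaii score): rule-based directly on the marginals —
  mild when N_C = N_D = 0 and N_A <= 5 and N_B <= 5; severe when N_D >= 1
  or N_C >= 4; moderate otherwise.

TTA itself can be predicted either from the four marginals
(TTA = 0.031 + 0.056 N_A + 1.172 N_B + 22.161 N_C + 36.198 N_D) or from the
index (TTA = 0.16 + 1.11 FPI); both linear predictors were estimated on a
27-turtle subset with fully measured tumors.
"""

from __future__ import annotations

import math
from collections.abc import Iterable

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .datamodel import Cohort, IndexCoefficients, ScoreThresholds, TumorMeasurement
from .vocab import SEVERITY_LEVELS, SIZE_CLASS_BOUNDS, SIZE_CLASSES

#: Canonical FPI weights.
FPI_COEFFICIENTS = IndexCoefficients(w_a=0.1, w_b=1.0, w_c=20.0, w_d=40.0)

#: Linear predictor of TTA (cm^2) from the four size-class marginals.
TTA_COUNT_COEFFICIENTS = IndexCoefficients(
    w_a=0.056, w_b=1.172, w_c=22.161, w_d=36.198, intercept=0.031
)

#: Simple-regression predictor of TTA (cm^2) from FPI: intercept + slope * FPI.
TTA_FPI_INTERCEPT = 0.16
TTA_FPI_SLOPE = 1.11

#: Canonical FPS_SWA thresholds on FPI.
DEFAULT_THRESHOLDS = ScoreThresholds(mild_upper=40.0, moderate_upper=120.0)

#: Absolute tolerance for comparisons of a float index against a threshold,
#: so that e.g. 400 class-A tumors (FPI exactly 40 in decimal arithmetic)
#: classify at the boundary regardless of binary-float rounding.
THRESHOLD_TOL = 1e-9


# ---------------------------------------------------------------------------
# elementary formulas
# ---------------------------------------------------------------------------

def size_class_of(diameter_cm: float) -> str:
    """Assign a tumor's size class from its diameter (largest axis, cm).

    Boundaries: d < 1 -> A; 1 <= d <= 4 -> B; 4 < d <= 10 -> C; d > 10 -> D.
    """
    if not diameter_cm > 0:
        raise ValueError(f"diameter must be positive, got {diameter_cm}")
    if diameter_cm < SIZE_CLASS_BOUNDS["A"][1]:
        return "A"
    if diameter_cm <= SIZE_CLASS_BOUNDS["B"][1]:
        return "B"
    if diameter_cm <= SIZE_CLASS_BOUNDS["C"][1]:
        return "C"
    return "D"


def ellipse_area(a: float, b: float) -> float:
    """Cross-sectional area (cm^2) of a tumor: pi * 0.5a * 0.5b for major
    axis a and minor axis b of an ellipse."""
    if not (b > 0):
        raise ValueError(f"axes must be positive, got a={a}, b={b}")
    if a < b:
        raise ValueError(f"major axis ({a}) must be >= minor axis ({b})")
    return math.pi * 0.5 * a * 0.5 * b


def total_tumor_area(measurements: Iterable[TumorMeasurement]) -> float:
    """Sum of ellipse areas (cm^2) over one turtle's measured tumors.

    Empty input gives 0. All measurements must carry the same turtle_id.
    """
    measurements = list(measurements)
    ids = {m.turtle_id for m in measurements}
    if len(ids) > 1:
        raise ValueError(
            f"measurements mix turtle ids {sorted(ids)}; TTA is per-turtle"
        )
    return sum(ellipse_area(m.major_axis_cm, m.minor_axis_cm) for m in measurements)


def fpi(n_a, n_b, n_c, n_d, coefficients: IndexCoefficients = FPI_COEFFICIENTS):
    """Weighted-sum severity index over the four size-class marginals.

    Vectorized: accepts scalars or equal-length arrays.
    """
    return coefficients.evaluate(n_a, n_b, n_c, n_d)


def tta_from_counts(n_a, n_b, n_c, n_d):
    """Predicted TTA (cm^2) from the four marginals via the full linear model."""
    return TTA_COUNT_COEFFICIENTS.evaluate(n_a, n_b, n_c, n_d)


def tta_from_fpi(fpi_value):
    """Predicted TTA (cm^2) from an FPI value via the simple linear model."""
    arr = np.asarray(fpi_value, dtype=float)
    if np.any(arr < 0):
        raise ValueError("FPI must be non-negative")
    out = TTA_FPI_INTERCEPT + TTA_FPI_SLOPE * arr
    return float(out) if np.ndim(out) == 0 else out


# ---------------------------------------------------------------------------
# ordinal classifiers
# ---------------------------------------------------------------------------

def classify_fps_swa(
    fpi_value: float, thresholds: ScoreThresholds = DEFAULT_THRESHOLDS
) -> str:
    """Southwest Atlantic score: mild (FPI < 40), moderate (40 <= FPI < 120),
    severe (FPI >= 120), with configurable thresholds."""
    if fpi_value < 0:
        raise ValueError(f"FPI must be non-negative, got {fpi_value}")
    if fpi_value >= thresholds.moderate_upper - THRESHOLD_TOL:
        return "severe"
    if fpi_value >= thresholds.mild_upper - THRESHOLD_TOL:
        return "moderate"
    return "mild"


def classify_fps_hwi(n_a: int, n_b: int, n_c: int, n_d: int) -> str:
    """Adapted Hawaii score from the four size-class marginals.

    (a) mild when the turtle has no C or D tumors and at most five each of A
    and B; (b) severe when it has any D tumor or four or more C tumors;
    (c) moderate otherwise. Rules (a) and (b) are mutually exclusive since
    (a) requires N_C = N_D = 0, so every input gets exactly one label.
    """
    counts = (n_a, n_b, n_c, n_d)
    if any(c < 0 for c in counts):
        raise ValueError(f"tumor counts must be non-negative, got {counts}")
    if n_c == 0 and n_d == 0 and n_a <= 5 and n_b <= 5:
        return "mild"
    if n_d >= 1 or n_c >= 4:
        return "severe"
    return "moderate"


def _classify_swa_array(values: np.ndarray, thresholds: ScoreThresholds):
    values = np.asarray(values, dtype=float)
    if np.any(values < 0):
        raise ValueError("FPI must be non-negative")
    out = np.full(values.shape, "mild", dtype=object)
    out[values >= thresholds.mild_upper - THRESHOLD_TOL] = "moderate"
    out[values >= thresholds.moderate_upper - THRESHOLD_TOL] = "severe"
    return out


# ---------------------------------------------------------------------------
# estimator interface
# ---------------------------------------------------------------------------

class SeverityScorer(TransformerMixin, BaseEstimator):
    """Rule-based severity scorer over size-class count marginals.

    A stateless scikit-learn estimator: ``transform`` maps an (n, 4) array of
    marginals (N_A, N_B, N_C, N_D) — or a :class:`Cohort` — to the continuous
    index, and ``predict`` maps it to ordinal labels under the configured
    system.

    Parameters
    ----------
    weights : tuple of 4 floats
        Size-class weights of the index (default: canonical FPI weights).
    intercept : float
        Index offset (0 for FPI).
    mild_upper, moderate_upper : float
        Index thresholds separating mild/moderate and moderate/severe.
    system : {"swa", "hwi"}
        Which classifier ``predict`` applies: the thresholded index ("swa")
        or the count-rule adapted Hawaii score ("hwi").
    """

    def __init__(
        self,
        weights: tuple[float, float, float, float] = FPI_COEFFICIENTS.weights,
        intercept: float = 0.0,
        mild_upper: float = DEFAULT_THRESHOLDS.mild_upper,
        moderate_upper: float = DEFAULT_THRESHOLDS.moderate_upper,
        system: str = "swa",
    ) -> None:
        self.weights = weights
        self.intercept = intercept
        self.mild_upper = mild_upper
        self.moderate_upper = moderate_upper
        self.system = system

    # the scorer learns nothing from data; fit only validates parameters
    def fit(self, X=None, y=None) -> "SeverityScorer":
        if self.system not in ("swa", "hwi"):
            raise ValueError(f"system must be 'swa' or 'hwi', got {self.system!r}")
        self.coefficients_ = IndexCoefficients(*self.weights, intercept=self.intercept)
        self.thresholds_ = ScoreThresholds(self.mild_upper, self.moderate_upper)
        self.classes_ = np.asarray(SEVERITY_LEVELS, dtype=object)
        self.n_features_in_ = 4
        return self

    @staticmethod
    def _as_marginals(X) -> np.ndarray:
        if isinstance(X, Cohort):
            X = X.marginals()[[f"N_{c}" for c in SIZE_CLASSES]]
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 4:
            raise ValueError(
                f"expected an (n, 4) array of N_A..N_D marginals, got shape {arr.shape}"
            )
        if np.any(arr < 0):
            raise ValueError("tumor counts must be non-negative")
        return arr

    def transform(self, X) -> np.ndarray:
        """Continuous index values, shape (n,)."""
        check_is_fitted(self)
        m = self._as_marginals(X)
        return self.coefficients_.evaluate(m[:, 0], m[:, 1], m[:, 2], m[:, 3])

    def predict(self, X) -> np.ndarray:
        """Ordinal severity labels, shape (n,), dtype object."""
        check_is_fitted(self)
        m = self._as_marginals(X)
        if self.system == "hwi":
            return np.asarray(
                [classify_fps_hwi(*row) for row in m.astype(int)], dtype=object
            )
        return _classify_swa_array(self.transform(X), self.thresholds_)

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X, y).predict(X)


# ---------------------------------------------------------------------------
# batch scoring
# ---------------------------------------------------------------------------

def score_cohort(
    cohort: Cohort,
    coefficients: IndexCoefficients = FPI_COEFFICIENTS,
    thresholds: ScoreThresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Score every turtle in a cohort.

    Returns a DataFrame indexed by turtle_id with columns N_A..N_D, N_all,
    FPI, TTA_hat (counts-model TTA prediction, cm^2), FPS_SWA and FPS_HWI,
    one row per turtle in cohort order.
    """
    marg = cohort.marginals()
    out = marg.copy()
    na, nb, nc, nd = (marg[f"N_{c}"].to_numpy() for c in SIZE_CLASSES)
    fpi_values = coefficients.evaluate(na, nb, nc, nd)
    out["FPI"] = np.atleast_1d(fpi_values)
    out["TTA_hat"] = np.atleast_1d(tta_from_counts(na, nb, nc, nd))
    if len(cohort):
        out["FPS_SWA"] = _classify_swa_array(out["FPI"].to_numpy(), thresholds)
        out["FPS_HWI"] = [
            classify_fps_hwi(*row) for row in zip(na, nb, nc, nd)
        ]
    else:
        out["FPS_SWA"] = pd.Series(dtype=object)
        out["FPS_HWI"] = pd.Series(dtype=object)
    return out
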