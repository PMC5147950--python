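"""Domain containers: tumor measurements, index coefficients, thresholds, cohorts.

The central container is :class:`Cohort`, a thin validated wrapper around a
wide pandas DataFrame of per-turtle tumor counts (11 regions x 4 size
classes), with optional parallel columns for measured total tumor area (TTA,
cm^2) and an expert subjective severity label on subsets of turtles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .vocab import (
    REGIONS,
    SEVERITY_LEVELS,
    SIZE_CLASSES,
    count_columns,
)

MARGINAL_COLUMNS = ["N_A", "N_B", "N_C", "N_D", "N_all"]


@dataclass(frozen=True)
class TumorMeasurement:
    """One tumor's ellipse axes (cm) on one turtle.

    ``major_axis_cm`` (a) must be >= ``minor_axis_cm`` (b) > 0.
    """

    turtle_id: str
    region: str
    major_axis_cm: float
    minor_axis_cm: float

    def __post_init__(self) -> None:
        from .vocab import validate_region

        validate_region(self.region)
        a, b = self.major_axis_cm, self.minor_axis_cm
        if not (b > 0):
            raise ValueError(
                f"tumor axes must be positive, got a={a}, b={b} "
                f"(turtle {self.turtle_id})"
            )
        if a < b:
            raise ValueError(
                f"major axis ({a}) smaller than minor axis ({b}) for turtle "
                f"{self.turtle_id}; swap the axes"
            )


@dataclass(frozen=True)
class IndexCoefficients:
    """Size-class weights (and optional cm^2 intercept) of a weighted-sum index.

    With the canonical weights (0.1, 1, 20, 40) and zero intercept this is the
    fibropapillomatosis index FPI = 0.1 N_A + 1 N_B + 20 N_C + 40 N_D.
    Weights must be non-negative and non-decreasing in size-class order:
    a larger tumor never counts for less.
    """

    w_a: float
    w_b: float
    w_c: float
    w_d: float
    intercept: float = 0.0

    def __post_init__(self) -> None:
        w = (self.w_a, self.w_b, self.w_c, self.w_d)
        if any(x < 0 for x in w):
            raise ValueError(f"index weights must be non-negative, got {w}")
        if not (self.w_a <= self.w_b <= self.w_c <= self.w_d):
            raise ValueError(
                f"index weights must be non-decreasing A..D, got {w}"
            )

    @property
    def weights(self) -> tuple[float, float, float, float]:
        return (self.w_a, self.w_b, self.w_c, self.w_d)

    def evaluate(self, n_a, n_b, n_c, n_d):
        """Evaluate the index at count marginals (scalars or arrays)."""
        counts = [np.asarray(x, dtype=float) for x in (n_a, n_b, n_c, n_d)]
        for c in counts:
            if np.any(c < 0):
                raise ValueError("tumor counts must be non-negative")
        out = self.intercept + sum(w * c for w, c in zip(self.weights, counts))
        return float(out) if np.ndim(out) == 0 else out


@dataclass(frozen=True)
class ScoreThresholds:
    """Two ordered cutoffs mapping a continuous index to mild/moderate/severe.

    mild: index < mild_upper; moderate: mild_upper <= index < moderate_upper;
    severe: index >= moderate_upper.
    """

    mild_upper: float
    moderate_upper: float

    def __post_init__(self) -> None:
        if not (0 < self.mild_upper < self.moderate_upper):
            raise ValueError(
                "thresholds must satisfy 0 < mild_upper < moderate_upper, "
                f"got ({self.mild_upper}, {self.moderate_upper})"
            )


@dataclass
class RegressionFit:
    """An ordinary-least-squares fit with intercept.

    ``coefficients`` maps predictor name to slope; predictors that could not
    be identified (constant column in the design) carry NaN and are listed in
    ``unidentifiable``. ``r_squared`` is plain (unadjusted) 1 - SS_res/SS_tot.
    """

    coefficients: dict[str, float]
    intercept: float
    r_squared: float
    n: int
    residuals: np.ndarray
    std_errors: dict[str, float] = field(default_factory=dict)
    unidentifiable: tuple[str, ...] = ()


def _validate_counts_frame(counts: pd.DataFrame) -> pd.DataFrame:
    cols = count_columns()
    missing = [c for c in cols if c not in counts.columns]
    if missing:
        raise ValueError(f"count table missing columns: {missing}")
    extra = [c for c in counts.columns if c not in cols]
    if extra:
        raise ValueError(f"count table has unknown columns: {extra}")
    counts = counts[cols]
    if counts.index.has_duplicates:
        dupes = counts.index[counts.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate turtle_id values: {dupes}")
    values = counts.to_numpy()
    if values.size:
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("tumor counts must be numeric")
        if np.any(~np.isfinite(values.astype(float))):
            raise ValueError("tumor counts must be finite")
        if np.any(values < 0):
            bad = counts.index[(values < 0).any(axis=1)].tolist()
            raise ValueError(f"negative tumor counts for turtles: {bad}")
        if np.any(values.astype(float) != np.round(values.astype(float))):
            bad = counts.index[
                (values.astype(float) != np.round(values.astype(float))).any(axis=1)
            ].tolist()
            raise ValueError(f"non-integer tumor counts for turtles: {bad}")
    return counts.astype(int)


class Cohort:
    """An ordered collection of turtles with per-region, per-class tumor counts.

    Parameters
    ----------
    counts
        DataFrame indexed by unique ``turtle_id`` with the 44 canonical
        ``<region>_<class>`` columns of non-negative integer counts.
    tta_cm2
        Optional Series of measured total tumor area (cm^2) for a subset of
        turtles (NaN elsewhere).
    subjective_score
        Optional Series of expert severity labels (mild/moderate/severe) for
        a subset of turtles (NaN elsewhere).
    metadata
        Optional DataFrame of pass-through columns (curved carapace length,
        body mass, state, alive flag) aligned to the same index.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        tta_cm2: pd.Series | None = None,
        subjective_score: pd.Series | None = None,
        metadata: pd.DataFrame | None = None,
    ) -> None:
        self.counts = _validate_counts_frame(pd.DataFrame(counts))
        self.counts.index = self.counts.index.astype(str)
        self.counts.index.name = "turtle_id"

        self.tta_cm2 = self._align_optional(tta_cm2, "tta_cm2")
        if self.tta_cm2 is not None:
            vals = self.tta_cm2.dropna()
            if np.any(vals < 0):
                bad = vals.index[vals < 0].tolist()
                raise ValueError(f"tta_cm2 must be >= 0, negative for: {bad}")

        self.subjective_score = self._align_optional(
            subjective_score, "subjective_score"
        )
        if self.subjective_score is not None:
            labels = self.subjective_score.dropna()
            bad = sorted(set(labels) - set(SEVERITY_LEVELS))
            if bad:
                raise ValueError(
                    f"unknown subjective severity labels {bad}; "
                    f"expected one of {SEVERITY_LEVELS}"
                )
        self.metadata = (
            metadata.reindex(self.counts.index) if metadata is not None else None
        )

    def _align_optional(self, series: pd.Series | None, name: str):
        if series is None:
            return None
        series = pd.Series(series)
        series.index = series.index.astype(str)
        unknown = series.index.difference(self.counts.index)
        if len(unknown):
            raise ValueError(f"{name} given for unknown turtles: {unknown.tolist()}")
        out = series.reindex(self.counts.index)
        out.name = name
        return out

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.counts)

    @property
    def turtle_ids(self) -> list[str]:
        return self.counts.index.tolist()

    def __eq__(self, other) -> bool:  # counts-level equality, used in tests
        if not isinstance(other, Cohort):
            return NotImplemented
        return self.counts.equals(other.counts)

    # -- derived quantities ------------------------------------------------
    def marginals(self) -> pd.DataFrame:
        """Per-turtle size-class totals N_A..N_D over all regions, plus N_all."""
        out = pd.DataFrame(index=self.counts.index)
        for cls in SIZE_CLASSES:
            cols = [f"{r}_{cls}" for r in REGIONS]
            out[f"N_{cls}"] = self.counts[cols].sum(axis=1)
        out["N_all"] = out[[f"N_{c}" for c in SIZE_CLASSES]].sum(axis=1)
        return out

    def region_class_matrix(self, turtle_id: str) -> pd.DataFrame:
        """One turtle's counts as an 11 x 4 region-by-class grid."""
        row = self.counts.loc[turtle_id]
        grid = pd.DataFrame(
            {c: [row[f"{r}_{c}"] for r in REGIONS] for c in SIZE_CLASSES},
            index=list(REGIONS),
        )
        return grid

    def subset(self, turtle_ids) -> "Cohort":
        """Sub-cohort restricted to the given ids (order preserved)."""
        ids = [str(t) for t in turtle_ids]
        missing = [t for t in ids if t not in self.counts.index]
        if missing:
            raise KeyError(f"unknown turtle ids: {missing}")
        return Cohort(
            self.counts.loc[ids],
            tta_cm2=self.tta_cm2.loc[ids] if self.tta_cm2 is not None else None,
            subjective_score=(
                self.subjective_score.loc[ids]
                if self.subjective_score is not None
                else None
            ),
            metadata=self.metadata.loc[ids] if self.metadata is not None else None,
        )

    def with_tta(self, tta: pd.Series) -> "Cohort":
        """New cohort with (possibly partial) measured TTA attached."""
        merged = tta if self.tta_cm2 is None else tta.combine_first(self.tta_cm2)
        return Cohort(
            self.counts,
            tta_cm2=merged,
            subjective_score=self.subjective_score,
            metadata=self.metadata,
        )

    def with_subjective(self, labels: pd.Series) -> "Cohort":
        merged = (
            labels
            if self.subjective_score is None
            else labels.combine_first(self.subjective_score)
        )
        return Cohort(
            self.counts,
            tta_cm2=self.tta_cm2,
            subjective_score=merged,
            metadata=self.metadata,
        )

    @classmethod
    def from_marginals(cls, marginals: pd.DataFrame, region: str = "carapace"):
        """Build a cohort from N_A..N_D marginals only, placing all counts in
        a single region. Convenience for index-level work where the anatomical
        split is irrelevant."""
        counts = pd.DataFrame(
            0, index=marginals.index, columns=count_columns(), dtype=int
        )
        for c in SIZE_CLASSES:
            counts[f"{region}_{c}"] = marginals[f"N_{c}"].astype(int)
        return cls(counts)


def empty_cohort() -> Cohort:
    """A cohort with zero turtles (valid degenerate input for readers)."""
    return Cohort(pd.DataFrame(columns=count_columns(), dtype=int))


def warn(message: str) -> None:
    warnings.warn(message, UserWarning, stacklevel=3)
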