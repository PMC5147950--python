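"""Weighted Cohen's kappa between two ordinal severity scorings.

Used to validate the objective score systems against the expert consensus
label: the observed weighted agreement P_o is compared with the agreement
P_e expected from the two raters' marginal label frequencies alone,

    kappa = (P_o - P_e) / (1 - P_e),

where disagreement cells are down-weighted by their ordinal distance. With
linear weights a mild/severe confusion counts twice as heavily as a
mild/moderate one; quadratic weights penalize it four times as heavily.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import Cohort
from .scoring import score_cohort
from .vocab import SEVERITY_LEVELS

WEIGHT_SCHEMES = ("linear", "quadratic")


@dataclass
class AgreementResult:
    """Confusion matrix and chance-corrected weighted agreement.

    ``kappa`` is NaN only in the degenerate case where both raters put every
    observation in the same single category (P_e = 1), in which case
    ``note`` explains why chance-corrected agreement is undefined.
    """

    confusion: pd.DataFrame
    kappa: float
    observed_weighted_agreement: float
    expected_weighted_agreement: float
    weight_scheme: str
    note: str = ""

    @property
    def n(self) -> int:
        return int(self.confusion.to_numpy().sum())

    @property
    def kappa_percent(self) -> float:
        return self.kappa * 100.0


def _check_labels(labels, name: str) -> np.ndarray:
    arr = np.asarray(list(labels), dtype=object)
    bad = sorted(set(arr) - set(SEVERITY_LEVELS))
    if bad:
        raise ValueError(
            f"{name} contains labels {bad} outside {SEVERITY_LEVELS}"
        )
    return arr


def confusion_matrix(labels1, labels2) -> pd.DataFrame:
    """3x3 count matrix: entry (i, j) = turtles labeled category i by system 1
    and category j by system 2, rows/columns ordered mild/moderate/severe."""
    a = _check_labels(labels1, "labels1")
    b = _check_labels(labels2, "labels2")
    if len(a) != len(b):
        raise ValueError(f"label vectors differ in length: {len(a)} vs {len(b)}")
    if len(a) == 0:
        raise ValueError("cannot build a confusion matrix from zero rating pairs")
    levels = list(SEVERITY_LEVELS)
    mat = pd.DataFrame(0, index=levels, columns=levels, dtype=int)
    for x, y in zip(a, b):
        mat.loc[x, y] += 1
    mat.index.name = "system1"
    mat.columns.name = "system2"
    return mat


def agreement_weights(k: int, scheme: str = "linear") -> np.ndarray:
    """Agreement weight matrix w_ij for k ordered categories: 1 on the
    diagonal, decreasing with ordinal distance |i - j|."""
    if scheme not in WEIGHT_SCHEMES:
        raise ValueError(f"scheme must be one of {WEIGHT_SCHEMES}, got {scheme!r}")
    i, j = np.indices((k, k))
    d = np.abs(i - j) / (k - 1)
    return 1.0 - (d if scheme == "linear" else d**2)


def weighted_kappa(confusion, scheme: str = "linear") -> AgreementResult:
    """Weighted Cohen's kappa from a k x k ordinal confusion matrix.

    P_o = sum w_ij p_ij over observed cell proportions; P_e = sum w_ij p_i q_j
    over the product of the two raters' marginals; kappa = (P_o - P_e)/(1 - P_e).
    """
    if isinstance(confusion, pd.DataFrame):
        frame = confusion.astype(float)
    else:
        arr = np.asarray(confusion, dtype=float)
        if arr.shape == (3, 3):
            frame = pd.DataFrame(
                arr, index=list(SEVERITY_LEVELS), columns=list(SEVERITY_LEVELS)
            )
        else:
            frame = pd.DataFrame(arr)
    m = frame.to_numpy()
    if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] < 2:
        raise ValueError(f"confusion matrix must be square (k >= 2), got {m.shape}")
    if np.any(m < 0):
        raise ValueError("confusion matrix entries must be non-negative")
    total = m.sum()
    if total < 1:
        raise ValueError("confusion matrix must contain at least one observation")

    k = m.shape[0]
    w = agreement_weights(k, scheme)
    p = m / total
    p_o = float((w * p).sum())
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    p_e = float((w * np.outer(row, col)).sum())

    if 1.0 - p_e < 1e-12:
        return AgreementResult(
            confusion=frame.astype(int),
            kappa=float("nan"),
            observed_weighted_agreement=p_o,
            expected_weighted_agreement=p_e,
            weight_scheme=scheme,
            note=(
                "kappa undefined: both raters used a single identical category "
                "for every observation, so expected agreement is 1 and there is "
                "no chance variation to correct for"
            ),
        )
    return AgreementResult(
        confusion=frame.astype(int),
        kappa=(p_o - p_e) / (1.0 - p_e),
        observed_weighted_agreement=p_o,
        expected_weighted_agreement=p_e,
        weight_scheme=scheme,
    )


def _labels_for(cohort: Cohort, system) -> np.ndarray:
    """Resolve a scoring system spec to per-turtle labels.

    ``system`` may be a callable Cohort -> labels, or one of the names
    "fps_swa", "fps_hwi" (computed from counts) or "subjective" (the stored
    expert column, which must cover every turtle in the cohort).
    """
    if callable(system):
        labels = np.asarray(list(system(cohort)), dtype=object)
        if len(labels) != len(cohort):
            raise ValueError(
                f"scoring callable returned {len(labels)} labels for "
                f"{len(cohort)} turtles"
            )
        return _check_labels(labels, "system output")
    name = str(system).lower()
    if name in ("fps_swa", "swa"):
        return score_cohort(cohort)["FPS_SWA"].to_numpy(dtype=object)
    if name in ("fps_hwi", "hwi"):
        return score_cohort(cohort)["FPS_HWI"].to_numpy(dtype=object)
    if name in ("subjective", "fps_sbj", "sbj"):
        if cohort.subjective_score is None:
            raise ValueError("cohort carries no subjective_score column")
        col = cohort.subjective_score
        missing = col.index[col.isna()].tolist()
        if missing:
            raise ValueError(
                f"turtles without a subjective label: {missing}; subset the "
                "cohort to the rated turtles first"
            )
        return _check_labels(col.to_numpy(dtype=object), "subjective_score")
    raise ValueError(
        f"unknown scoring system {system!r}; use a callable or one of "
        "'fps_swa', 'fps_hwi', 'subjective'"
    )


def compare_systems(
    cohort: Cohort, system1, system2, scheme: str = "linear"
) -> AgreementResult:
    """Label every turtle under both systems and compute weighted kappa."""
    if len(cohort) == 0:
        raise ValueError("cannot compare scoring systems on an empty cohort")
    labels1 = _labels_for(cohort, system1)
    labels2 = _labels_for(cohort, system2)
    return weighted_kappa(confusion_matrix(labels1, labels2), scheme=scheme)
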