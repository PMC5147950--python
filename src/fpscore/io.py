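"""Delimited-text readers and writers for cohorts, tumor measurements, scored
tables and index configuration.

Two cohort schemas are supported, both UTF-8 with a mandatory header row
(comma-delimited by default, tab accepted):

* long — one row per (turtle, region, size class): columns ``turtle_id,
  region, size_class, count``. The primary schema; cells not listed are
  taken as zero.
* wide — one row per turtle: ``turtle_id`` plus the 44 ``<region>_<class>``
  count columns, and optionally ``tta_cm2``, ``subjective_score`` and
  metadata columns (``ccl_cm``, ``mass_kg``, ``state``, ``alive``).
"""

from __future__ import annotations

import json
import logging
import os
from typing import Iterable

import numpy as np
import pandas as pd

from .datamodel import (
    Cohort,
    IndexCoefficients,
    ScoreThresholds,
    TumorMeasurement,
    warn,
)
from .vocab import (
    REGIONS,
    SIZE_CLASSES,
    count_columns,
    validate_region,
    validate_size_class,
)

logger = logging.getLogger(__name__)

SCORED_COLUMNS = [
    "turtle_id",
    "N_A",
    "N_B",
    "N_C",
    "N_D",
    "N_all",
    "FPI",
    "TTA_hat",
    "FPS_SWA",
    "FPS_HWI",
]

_METADATA_COLUMNS = ("ccl_cm", "mass_kg", "state", "alive")
_OPTIONAL_WIDE = ("tta_cm2", "subjective_score") + _METADATA_COLUMNS


def _read_table(path, sep: str | None) -> pd.DataFrame:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    return pd.read_csv(path, sep=sep, dtype={"turtle_id": str})


def _require_columns(frame: pd.DataFrame, required: Iterable[str], path) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")


def _parse_count(value, path, row_number: int) -> int:
    try:
        as_float = float(value)
    except (TypeError, ValueError):
        raise ValueError(
            f"{path}: row {row_number}: count {value!r} is not a number"
        ) from None
    if not np.isfinite(as_float) or as_float != int(as_float):
        raise ValueError(
            f"{path}: row {row_number}: count {value!r} is not an integer"
        )
    if as_float < 0:
        raise ValueError(
            f"{path}: row {row_number}: negative tumor count {value!r}"
        )
    return int(as_float)


def read_cohort(path, schema: str = "long", sep: str | None = None) -> Cohort:
    """Read a cohort table in ``long`` or ``wide`` schema.

    Unknown region or size-class tokens are rejected (internal/visceral
    sites are not representable); region x class cells absent from the file
    are taken as count 0 and logged. Row numbers in error messages count the
    header as row 1.
    """
    if schema not in ("long", "wide"):
        raise ValueError(f"schema must be 'long' or 'wide', got {schema!r}")
    frame = _read_table(path, sep)
    return (
        _cohort_from_long(frame, path) if schema == "long" else _cohort_from_wide(frame, path)
    )


def _cohort_from_long(frame: pd.DataFrame, path) -> Cohort:
    _require_columns(frame, ["turtle_id", "region", "size_class", "count"], path)
    if frame.empty:
        return Cohort(pd.DataFrame(columns=count_columns(), dtype=int))
    ids = list(dict.fromkeys(frame["turtle_id"].astype(str)))  # keep file order
    counts = pd.DataFrame(0, index=ids, columns=count_columns(), dtype=int)
    seen: set[tuple[str, str, str]] = set()
    for pos, row in enumerate(frame.itertuples(index=False), start=2):
        try:
            region = validate_region(str(row.region))
            cls = validate_size_class(str(row.size_class))
        except ValueError as exc:
            raise ValueError(f"{path}: row {pos}: {exc}") from None
        key = (str(row.turtle_id), region, cls)
        if key in seen:
            raise ValueError(
                f"{path}: row {pos}: duplicate cell for turtle {key[0]}, "
                f"{region}/{cls}"
            )
        seen.add(key)
        counts.loc[key[0], f"{region}_{cls}"] = _parse_count(row.count, path, pos)
    n_missing = len(ids) * 44 - len(seen)
    if n_missing:
        logger.info(
            "%s: %d region x size-class cells absent; treated as count 0",
            path,
            n_missing,
        )
    return Cohort(counts)


def _cohort_from_wide(frame: pd.DataFrame, path) -> Cohort:
    _require_columns(frame, ["turtle_id"], path)
    known = set(count_columns()) | set(_OPTIONAL_WIDE) | {"turtle_id"}
    unknown = [c for c in frame.columns if c not in known]
    if unknown:
        raise ValueError(
            f"{path}: unknown columns {unknown}; region/size tokens must be one "
            "of the 44 canonical <region>_<class> names"
        )
    frame = frame.set_index(frame["turtle_id"].astype(str)).drop(columns="turtle_id")
    absent = [c for c in count_columns() if c not in frame.columns]
    if absent:
        logger.info("%s: %d count columns absent; treated as 0", path, len(absent))
    counts = pd.DataFrame(0, index=frame.index, columns=count_columns(), dtype=object)
    for col in count_columns():
        if col in frame.columns:
            for pos, value in enumerate(frame[col].fillna(0), start=2):
                counts.loc[frame.index[pos - 2], col] = _parse_count(value, path, pos)
    tta = frame["tta_cm2"].astype(float) if "tta_cm2" in frame.columns else None
    subj = frame["subjective_score"] if "subjective_score" in frame.columns else None
    if subj is not None:
        subj = subj.where(subj.notna(), other=pd.NA)
    meta_cols = [c for c in _METADATA_COLUMNS if c in frame.columns]
    meta = frame[meta_cols] if meta_cols else None
    return Cohort(
        counts.astype(int), tta_cm2=tta, subjective_score=subj, metadata=meta
    )


def write_cohort(cohort: Cohort, path, schema: str = "long", sep: str = ",") -> None:
    """Write a cohort in the given schema. In long schema only nonzero cells
    are written (plus one explicit zero row for any all-zero turtle, so it
    survives the round trip); wide schema carries TTA/subjective columns."""
    if schema == "long":
        records = []
        for tid, row in cohort.counts.iterrows():
            nonzero = row[row > 0]
            if nonzero.empty:
                records.append((tid, REGIONS[0], "A", 0))
                continue
            for col, value in nonzero.items():
                region, cls = col.rsplit("_", 1)
                records.append((tid, region, cls, int(value)))
        frame = pd.DataFrame(
            records, columns=["turtle_id", "region", "size_class", "count"]
        )
        frame.to_csv(path, sep=sep, index=False)
    elif schema == "wide":
        frame = cohort.counts.copy()
        if cohort.tta_cm2 is not None:
            frame["tta_cm2"] = cohort.tta_cm2
        if cohort.subjective_score is not None:
            frame["subjective_score"] = cohort.subjective_score
        if cohort.metadata is not None:
            for col in cohort.metadata.columns:
                frame[col] = cohort.metadata[col]
        frame.reset_index().rename(columns={"index": "turtle_id"}).to_csv(
            path, sep=sep, index=False
        )
    else:
        raise ValueError(f"schema must be 'long' or 'wide', got {schema!r}")


def read_tumor_measurements(path, sep: str | None = None) -> list[TumorMeasurement]:
    """Read per-tumor ellipse axes. If a row's minor axis exceeds its major
    axis the two are swapped with a warning; non-positive axes are errors."""
    frame = _read_table(path, sep)
    _require_columns(
        frame, ["turtle_id", "region", "major_axis_cm", "minor_axis_cm"], path
    )
    out: list[TumorMeasurement] = []
    for pos, row in enumerate(frame.itertuples(index=False), start=2):
        a, b = float(row.major_axis_cm), float(row.minor_axis_cm)
        if a <= 0 or b <= 0:
            raise ValueError(
                f"{path}: row {pos}: tumor axes must be positive, got ({a}, {b})"
            )
        if b > a:
            warn(
                f"{path}: row {pos}: minor axis {b} > major axis {a}; swapping"
            )
            a, b = b, a
        try:
            out.append(
                TumorMeasurement(
                    turtle_id=str(row.turtle_id),
                    region=str(row.region),
                    major_axis_cm=a,
                    minor_axis_cm=b,
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: row {pos}: {exc}") from None
    return out


def write_scored_cohort(cohort: Cohort, scores: pd.DataFrame, path, sep: str = ",") -> None:
    """Write the per-turtle scored table (marginals, FPI, predicted TTA and
    both ordinal labels), aligned to the cohort by turtle_id."""
    cohort_ids = set(cohort.turtle_ids)
    score_ids = set(str(i) for i in scores.index)
    if cohort_ids != score_ids:
        missing = sorted(cohort_ids - score_ids)
        extra = sorted(score_ids - cohort_ids)
        raise ValueError(
            f"scores do not align with cohort; missing ids {missing}, extra ids {extra}"
        )
    out = scores.loc[cohort.turtle_ids].reset_index(names="turtle_id")
    _require_columns(out, SCORED_COLUMNS, "<scores>")
    out[SCORED_COLUMNS].to_csv(path, sep=sep, index=False)


def read_scored_cohort(path, sep: str | None = None) -> pd.DataFrame:
    """Read back a scored table written by :func:`write_scored_cohort`."""
    frame = _read_table(path, sep)
    _require_columns(frame, SCORED_COLUMNS, path)
    return frame.set_index(frame["turtle_id"].astype(str)).drop(columns="turtle_id")


# ---------------------------------------------------------------------------
# index configuration (regional variants)
# ---------------------------------------------------------------------------

def save_config(
    coefficients: IndexCoefficients, thresholds: ScoreThresholds, path
) -> None:
    """Persist index weights and score thresholds as JSON, the declarative
    carrier for regional score variants."""
    payload = {
        "coefficients": {
            "w_a": coefficients.w_a,
            "w_b": coefficients.w_b,
            "w_c": coefficients.w_c,
            "w_d": coefficients.w_d,
            "intercept": coefficients.intercept,
        },
        "thresholds": {
            "mild_upper": thresholds.mild_upper,
            "moderate_upper": thresholds.moderate_upper,
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def load_config(path) -> tuple[IndexCoefficients, ScoreThresholds]:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    try:
        coeff = IndexCoefficients(**payload["coefficients"])
        thresh = ScoreThresholds(**payload["thresholds"])
    except (KeyError, TypeError) as exc:
        raise ValueError(f"{path}: malformed index config: {exc}") from None
    return coeff, thresh
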