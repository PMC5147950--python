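"""Cohort descriptive statistics: per-region tumor burden and anatomical
distribution of tumors."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import Cohort, warn
from .vocab import REGIONS, SEVERITY_LEVELS, SIZE_CLASSES

#: Pooled region groups used for the anatomical distribution report. The four
#: groups partition the eleven regions.
POOLED_GROUPS: dict[str, tuple[str, ...]] = {
    "forelimbs": ("left_forelimb", "right_forelimb"),
    "hindlimbs": ("left_hindlimb", "right_hindlimb"),
    "neck": ("neck",),
    "remainder": (
        "left_eye",
        "right_eye",
        "head",
        "carapace",
        "plastron",
        "inguinal_tail",
    ),
}


def summarize_cohort(cohort: Cohort) -> pd.DataFrame:
    """Per-region tumor summary plus a grand-total row.

    One row per region in canonical order, then a ``total`` row. Columns:
    ``mean_X`` / ``sd_X`` for X in A..D and ``all`` (tumors per turtle,
    sample SD with n-1 denominator), ``n_turtles_with_tumors`` (turtles with
    at least one tumor in the region; whole cohort for the total row) and
    ``n_tumors``. For a single-turtle cohort SDs are undefined and reported
    as 0 with a warning.
    """
    n = len(cohort)
    if n == 0:
        raise ValueError("cannot summarize an empty cohort")
    if n == 1:
        warn("cohort has a single turtle; standard deviations are reported as 0")

    def sd(frame_or_series):
        s = frame_or_series.std(ddof=1)
        return s.fillna(0.0) if hasattr(s, "fillna") else (0.0 if np.isnan(s) else s)

    rows = {}
    for region in REGIONS:
        per_class = {
            c: cohort.counts[f"{region}_{c}"] for c in SIZE_CLASSES
        }
        region_total = sum(per_class.values())
        row = {}
        for c, series in per_class.items():
            row[f"mean_{c}"] = float(series.mean())
            row[f"sd_{c}"] = float(series.std(ddof=1)) if n > 1 else 0.0
        row["mean_all"] = float(region_total.mean())
        row["sd_all"] = float(region_total.std(ddof=1)) if n > 1 else 0.0
        row["n_turtles_with_tumors"] = int((region_total > 0).sum())
        row["n_tumors"] = int(region_total.sum())
        rows[region] = row

    marg = cohort.marginals()
    total = {}
    for c in SIZE_CLASSES:
        total[f"mean_{c}"] = float(marg[f"N_{c}"].mean())
        total[f"sd_{c}"] = float(marg[f"N_{c}"].std(ddof=1)) if n > 1 else 0.0
    total["mean_all"] = float(marg["N_all"].mean())
    total["sd_all"] = float(marg["N_all"].std(ddof=1)) if n > 1 else 0.0
    total["n_turtles_with_tumors"] = int((marg["N_all"] > 0).sum())
    total["n_tumors"] = int(marg["N_all"].sum())
    rows["total"] = total

    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "region"
    return out


@dataclass
class DistributionReport:
    """Anatomical distribution of tumors as percentages of the grand total."""

    region_pct: pd.Series  # per-region percentage, canonical order
    pooled_pct: dict[str, float]  # forelimbs / hindlimbs / neck / remainder
    n_tumors: int
    decimals: int


def anatomical_distribution(
    summary: pd.DataFrame, decimals: int = 0
) -> DistributionReport:
    """Percentage of all tumors per region and per pooled group.

    ``summary`` is the output of :func:`summarize_cohort` (or any frame with
    an ``n_tumors`` column indexed by region plus ``total``). Percentages are
    rounded to ``decimals`` (default whole percent).
    """
    counts = summary["n_tumors"]
    total = int(counts.loc["total"]) if "total" in counts.index else int(counts.sum())
    if total <= 0:
        raise ValueError("cohort contains zero tumors; distribution undefined")
    per_region = counts.reindex(list(REGIONS))
    region_pct = (per_region / total * 100).round(decimals)
    pooled = {
        group: round(float(per_region[list(members)].sum()) / total * 100, decimals)
        for group, members in POOLED_GROUPS.items()
    }
    if decimals == 0:
        region_pct = region_pct.astype(int).astype(float)
        pooled = {g: float(int(v)) for g, v in pooled.items()}
    return DistributionReport(
        region_pct=region_pct, pooled_pct=pooled, n_tumors=total, decimals=decimals
    )


def score_distribution(
    scored: pd.DataFrame, systems: tuple[str, ...] = ("FPS_SWA", "FPS_HWI")
) -> pd.DataFrame:
    """Tally of mild/moderate/severe per scoring system.

    ``scored`` is the output of :func:`fpscore.scoring.score_cohort` (or any
    frame with label columns). Returns a 3 x len(systems) count table whose
    columns each sum to the number of turtles.
    """
    out = pd.DataFrame(0, index=list(SEVERITY_LEVELS), columns=list(systems), dtype=int)
    for sys_name in systems:
        if sys_name not in scored.columns:
            raise ValueError(f"scored table has no column {sys_name!r}")
        tally = scored[sys_name].value_counts()
        for level in SEVERITY_LEVELS:
            out.loc[level, sys_name] = int(tally.get(level, 0))
    out.index.name = "severity"
    return out
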