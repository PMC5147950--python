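"""Seeded synthetic cohort generator.

Emulates the statistical structure of the Southwest Atlantic reference
cohort: 214 juvenile green sea turtles, all FP-positive, with per-region
per-size-class tumor counts whose cell means and SDs match the published
summary table; a 27-turtle subset with measured total tumor area (TTA); and
a 52-turtle subset with an expert subjective severity label.

Counts are drawn independently per region x size-class cell from a negative
binomial moment-matched to the cell's (mean, SD) — every reference cell is
overdispersed (SD > mean) — with a Poisson fallback when a configured cell
is not. Cells with mean 0 are structural zeros and never generate tumors.
All-zero turtles are redrawn by default, since the reference cohort contains
only turtles with at least one tumor. See docs/methods.md for what this
generator does and does not emulate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datamodel import Cohort
from .scoring import classify_fps_swa, fpi, tta_from_counts
from .vocab import REGIONS, SIZE_CLASSES, count_columns

logger = logging.getLogger(__name__)

#: Reference per-cell (mean, SD) tumors per turtle, by region and size class.
#: A dash in the published table (no tumor of that class ever observed in
#: that region) is a structural zero, encoded as mean 0. The head/C cell
#: prints mean 0.00 with SD 0.07 and is likewise treated as structural zero.
TABLE1_CELL_PARAMS: dict[tuple[str, str], tuple[float, float]] = {
    ("left_eye", "A"): (0.46, 0.72),
    ("left_eye", "B"): (0.19, 0.53),
    ("left_eye", "C"): (0.0, 0.0),
    ("left_eye", "D"): (0.0, 0.0),
    ("right_eye", "A"): (0.46, 0.72),
    ("right_eye", "B"): (0.15, 0.44),
    ("right_eye", "C"): (0.0, 0.0),
    ("right_eye", "D"): (0.0, 0.0),
    ("head", "A"): (0.06, 0.25),
    ("head", "B"): (0.12, 0.72),
    ("head", "C"): (0.0, 0.07),
    ("head", "D"): (0.0, 0.0),
    ("neck", "A"): (1.76, 3.04),
    ("neck", "B"): (1.67, 2.43),
    ("neck", "C"): (0.14, 0.42),
    ("neck", "D"): (0.0, 0.0),
    ("left_forelimb", "A"): (3.66, 4.70),
    ("left_forelimb", "B"): (3.81, 4.17),
    ("left_forelimb", "C"): (0.32, 0.78),
    ("left_forelimb", "D"): (0.02, 0.15),
    ("right_forelimb", "A"): (3.55, 4.54),
    ("right_forelimb", "B"): (3.91, 4.44),
    ("right_forelimb", "C"): (0.43, 0.99),
    ("right_forelimb", "D"): (0.01, 0.10),
    ("carapace", "A"): (0.12, 0.48),
    ("carapace", "B"): (0.21, 0.82),
    ("carapace", "C"): (0.02, 0.14),
    ("carapace", "D"): (0.01, 0.14),
    ("plastron", "A"): (0.55, 1.39),
    ("plastron", "B"): (0.71, 1.29),
    ("plastron", "C"): (0.08, 0.33),
    ("plastron", "D"): (0.0, 0.0),
    ("left_hindlimb", "A"): (2.30, 3.44),
    ("left_hindlimb", "B"): (2.89, 3.48),
    ("left_hindlimb", "C"): (0.49, 1.08),
    ("left_hindlimb", "D"): (0.05, 0.28),
    ("right_hindlimb", "A"): (2.87, 4.21),
    ("right_hindlimb", "B"): (2.69, 3.34),
    ("right_hindlimb", "C"): (0.46, 1.00),
    ("right_hindlimb", "D"): (0.02, 0.18),
    ("inguinal_tail", "A"): (0.37, 1.49),
    ("inguinal_tail", "B"): (0.28, 1.06),
    ("inguinal_tail", "C"): (0.02, 0.15),
    ("inguinal_tail", "D"): (0.0, 0.0),
}

#: Reference per-region tumor totals across the 214-turtle cohort.
TABLE1_REGION_TOTALS: dict[str, int] = {
    "left_eye": 140,
    "right_eye": 131,
    "head": 39,
    "neck": 763,
    "left_forelimb": 1674,
    "right_forelimb": 1690,
    "carapace": 77,
    "plastron": 288,
    "left_hindlimb": 1226,
    "right_hindlimb": 1292,
    "inguinal_tail": 144,
}

#: Reference counts of turtles with at least one tumor in each region.
TABLE1_TURTLES_WITH_TUMORS: dict[str, int] = {
    "left_eye": 88,
    "right_eye": 90,
    "head": 21,
    "neck": 152,
    "left_forelimb": 191,
    "right_forelimb": 188,
    "carapace": 38,
    "plastron": 96,
    "left_hindlimb": 171,
    "right_hindlimb": 170,
    "inguinal_tail": 54,
}

TABLE1_N_TURTLES = 214
TABLE1_TOTAL_TUMORS = 7464  # sum of the per-region totals


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic cohort.

    Defaults reproduce the reference study conditions: 214 FP-positive
    turtles, cell moments from the published summary table, TTA measured on
    27 turtles with Gaussian measurement/model noise (SD 5 cm^2), and a
    subjective label on 52 turtles agreeing with the index-based score with
    probability 0.75 (disagreements land on an adjacent category).
    """

    n_turtles: int = TABLE1_N_TURTLES
    cell_params: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=lambda: dict(TABLE1_CELL_PARAMS)
    )
    tta_subset_size: int = 27
    tta_noise_sd: float = 5.0
    subjective_subset_size: int = 52
    subjective_agreement: float = 0.75
    seed: int = 0
    require_positive: bool = True  # redraw all-zero turtles (FP-positive cohort)
    frailty_shape: float | None = None  # per-turtle gamma frailty, off by default

    def __post_init__(self) -> None:
        if self.n_turtles < 1:
            raise ValueError("n_turtles must be >= 1")
        for subset in (self.tta_subset_size, self.subjective_subset_size):
            if not (0 <= subset <= self.n_turtles):
                raise ValueError(
                    f"subset size {subset} must be in [0, n_turtles={self.n_turtles}]"
                )
        if not (0.0 <= self.subjective_agreement <= 1.0):
            raise ValueError("subjective_agreement must be a probability")
        if self.tta_noise_sd < 0:
            raise ValueError("tta_noise_sd must be >= 0")
        for (region, cls), (mean, sd) in self.cell_params.items():
            if region not in REGIONS or cls not in SIZE_CLASSES:
                raise ValueError(f"unknown cell ({region}, {cls})")
            if mean < 0 or sd < 0:
                raise ValueError(f"cell ({region}, {cls}) has negative moments")


def default_config(**overrides) -> SynthConfig:
    """The reference study conditions, optionally overridden field-by-field."""
    return replace(SynthConfig(), **overrides) if overrides else SynthConfig()


def _draw_cell(rng: np.random.Generator, mean: float, sd: float, size: int):
    """Counts from a negative binomial moment-matched to (mean, sd); Poisson
    when the cell is not overdispersed; structural zero when mean == 0."""
    if mean == 0:
        return np.zeros(size, dtype=int)
    var = sd * sd
    if var > mean:
        n_param = mean * mean / (var - mean)
        p_param = mean / var
        return rng.negative_binomial(n_param, p_param, size=size)
    logger.info(
        "cell not overdispersed (mean %.3f, sd %.3f); using Poisson", mean, sd
    )
    return rng.poisson(mean, size=size)


def generate_counts(
    config: SynthConfig | None = None, rng: np.random.Generator | None = None
) -> Cohort:
    """Draw a cohort of per-turtle tumor counts.

    Cells are independent across regions and size classes (optionally tied
    by a shared per-turtle gamma frailty when ``frailty_shape`` is set).
    With ``require_positive`` (the default) turtles with zero tumors overall
    are redrawn, matching a cohort defined as FP-positive.
    """
    config = config or default_config()
    if all(mean == 0 for mean, _ in config.cell_params.values()):
        raise ValueError(
            "all cells have mean 0; an FP-positive cohort cannot be generated"
        )
    rng = rng if rng is not None else np.random.default_rng(config.seed)

    def draw_block(n: int) -> np.ndarray:
        frailty = (
            rng.gamma(config.frailty_shape, 1.0 / config.frailty_shape, size=n)
            if config.frailty_shape
            else None
        )
        block = np.zeros((n, 44), dtype=int)
        for j, col in enumerate(count_columns()):
            region, cls = col.rsplit("_", 1)
            mean, sd = config.cell_params.get((region, cls), (0.0, 0.0))
            if frailty is None:
                block[:, j] = _draw_cell(rng, mean, sd, n)
            else:
                # scale each turtle's cell mean by its frailty, preserving
                # the mean-to-variance ratio of the base cell
                for i in range(n):
                    m_i = mean * frailty[i]
                    sd_i = sd * np.sqrt(frailty[i]) if mean > 0 else 0.0
                    block[i, j] = _draw_cell(rng, m_i, sd_i, 1)[0]
        return block

    values = draw_block(config.n_turtles)
    if config.require_positive:
        for _ in range(1000):
            zero_rows = np.flatnonzero(values.sum(axis=1) == 0)
            if zero_rows.size == 0:
                break
            values[zero_rows] = draw_block(zero_rows.size)
        else:
            raise RuntimeError(
                "could not produce FP-positive turtles after 1000 redraw rounds; "
                "cell means are too close to zero"
            )

    width = len(str(config.n_turtles))
    ids = [f"T{i + 1:0{width}d}" for i in range(config.n_turtles)]
    counts = pd.DataFrame(values, index=ids, columns=count_columns())
    return Cohort(counts)


def generate_tta_subset(
    cohort: Cohort,
    config: SynthConfig | None = None,
    rng: np.random.Generator | None = None,
) -> Cohort:
    """Attach measured TTA (cm^2) to a random subset of turtles.

    TTA is the counts-based linear predictor evaluated at the turtle's
    marginals plus Gaussian noise (SD ``tta_noise_sd``), truncated at 0 —
    the generating model under which the calibration workflow should recover
    the reference coefficients.
    """
    config = config or default_config()
    if config.tta_subset_size > len(cohort):
        raise ValueError(
            f"tta_subset_size {config.tta_subset_size} exceeds cohort size {len(cohort)}"
        )
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    chosen = rng.choice(len(cohort), size=config.tta_subset_size, replace=False)
    ids = [cohort.turtle_ids[i] for i in sorted(chosen)]
    marg = cohort.marginals().loc[ids]
    tta = tta_from_counts(
        marg["N_A"].to_numpy(),
        marg["N_B"].to_numpy(),
        marg["N_C"].to_numpy(),
        marg["N_D"].to_numpy(),
    )
    noise = (
        rng.normal(0.0, config.tta_noise_sd, size=len(ids))
        if config.tta_noise_sd > 0
        else 0.0
    )
    tta = np.maximum(np.atleast_1d(tta) + noise, 0.0)
    return cohort.with_tta(pd.Series(tta, index=ids, name="tta_cm2"))


def generate_subjective_scores(
    cohort: Cohort,
    config: SynthConfig | None = None,
    rng: np.random.Generator | None = None,
) -> Cohort:
    """Attach an expert-style subjective label to a random subset of turtles.

    With probability ``subjective_agreement`` the label equals the turtle's
    index-based (FPS_SWA) score; otherwise it moves to an adjacent category
    (a moderate turtle goes to mild or severe with equal probability; mild
    and severe go to moderate). Two-step confusions never occur, matching
    the adjacent-category disagreement pattern seen in expert panels.
    """
    config = config or default_config()
    if config.subjective_subset_size > len(cohort):
        raise ValueError(
            f"subjective_subset_size {config.subjective_subset_size} exceeds "
            f"cohort size {len(cohort)}"
        )
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    chosen = rng.choice(len(cohort), size=config.subjective_subset_size, replace=False)
    ids = [cohort.turtle_ids[i] for i in sorted(chosen)]
    marg = cohort.marginals().loc[ids]
    labels = []
    for _, row in marg.iterrows():
        base = classify_fps_swa(
            fpi(row["N_A"], row["N_B"], row["N_C"], row["N_D"])
        )
        if rng.random() < config.subjective_agreement:
            labels.append(base)
        elif base == "moderate":
            labels.append("mild" if rng.random() < 0.5 else "severe")
        else:
            labels.append("moderate")
    return cohort.with_subjective(pd.Series(labels, index=ids, name="subjective_score"))


def generate_cohort(
    config: SynthConfig | None = None,
    *,
    with_tta: bool = True,
    with_subjective: bool = True,
) -> Cohort:
    """Full pipeline: counts, then the TTA and subjective subsets, all driven
    by a single seeded generator so the result is reproducible bit-for-bit."""
    config = config or default_config()
    rng = np.random.default_rng(config.seed)
    cohort = generate_counts(config, rng)
    if with_tta and config.tta_subset_size:
        cohort = generate_tta_subset(cohort, config, rng)
    if with_subjective and config.subjective_subset_size:
        cohort = generate_subjective_scores(cohort, config, rng)
    return cohort


def table1_reference_cohort() -> Cohort:
    """A 214-turtle cohort whose per-region tumor totals equal the published
    reference totals exactly.

    The per-turtle allocation is synthetic and uninformative (each region's
    total is spread as evenly as possible over the turtles, all in size
    class B): only region-level aggregates — totals, per-region means, the
    anatomical distribution — are meaningful, not per-turtle scores.
    """
    n = TABLE1_N_TURTLES
    ids = [f"R{i + 1:03d}" for i in range(n)]
    counts = pd.DataFrame(0, index=ids, columns=count_columns(), dtype=int)
    for region, total in TABLE1_REGION_TOTALS.items():
        base, rem = divmod(total, n)
        col = np.full(n, base, dtype=int)
        col[:rem] += 1
        counts[f"{region}_B"] = col
    return Cohort(counts)
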