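"""Closed vocabularies for the scoring scheme.

Tumors are recorded per body region and per diameter size class. The region
vocabulary is closed (exactly eleven external anatomical regions, in a fixed
canonical order); internal tumors (oral cavity, viscera) are intentionally not
representable. Size classes partition tumor diameter (cm) into four ordered
categories A < B < C < D.
"""

from __future__ import annotations

import math

#: Canonical ordering of the eleven external body regions.
REGIONS: tuple[str, ...] = (
    "left_eye",
    "right_eye",
    "head",
    "neck",
    "left_forelimb",
    "right_forelimb",
    "carapace",
    "plastron",
    "left_hindlimb",
    "right_hindlimb",
    "inguinal_tail",
)

#: Size classes in increasing diameter order.
SIZE_CLASSES: tuple[str, ...] = ("A", "B", "C", "D")

#: Ordinal severity levels, mild < moderate < severe.
SEVERITY_LEVELS: tuple[str, ...] = ("mild", "moderate", "severe")

#: Diameter intervals (cm) for each class: A = (0, 1), B = [1, 4],
#: C = (4, 10], D = (10, inf). The only gapless, non-overlapping reading of
#: the conventional "A (<1), B (1-4), C (>4-10), D (>10)" notation; a tumor
#: of exactly 1 cm is class B, exactly 4 cm is B, exactly 10 cm is C.
SIZE_CLASS_BOUNDS: dict[str, tuple[float, float]] = {
    "A": (0.0, 1.0),
    "B": (1.0, 4.0),
    "C": (4.0, 10.0),
    "D": (10.0, math.inf),
}

SEVERITY_RANK: dict[str, int] = {lvl: i for i, lvl in enumerate(SEVERITY_LEVELS)}


def count_columns() -> list[str]:
    """Wide-format column names, ``<region>_<class>``, in canonical order."""
    return [f"{r}_{c}" for r in REGIONS for c in SIZE_CLASSES]


def validate_region(name: str) -> str:
    if name not in REGIONS:
        raise ValueError(
            f"unknown body region {name!r}; expected one of {', '.join(REGIONS)} "
            "(internal/visceral sites are not representable)"
        )
    return name


def validate_size_class(label: str) -> str:
    if label not in SIZE_CLASSES:
        raise ValueError(
            f"unknown size class {label!r}; expected one of {', '.join(SIZE_CLASSES)}"
        )
    return label
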