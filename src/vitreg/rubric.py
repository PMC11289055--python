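"""Radiographic severity rubrics and the scored-image container.

Two clinical scoring systems are modelled, both assessed per lung on a
0-4 scale whose sum gives a 0-8 global score:

* **GE (geographic extent)** grades the *area* of lung involvement:
  0 no engagement, 1 up to 25%, 2 25-50%, 3 50-75%, 4 more than 75%.
* **LO (lung opacity)** grades the *character* of the opacity:
  0 none, 1 ground-glass only, 2 ground glass mixed with consolidation
  covering less than half the lung, 3 consolidation-dominant mixture,
  4 complete opacification.

Fractions landing exactly on a bin edge (0.25, 0.50, 0.75) are assigned
to the lower bin; this tie-break is a package convention and is relied
on by the synthetic generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "SeverityRubric",
    "RUBRICS",
    "get_rubric",
    "ge_label_from_fraction",
    "lo_label_from_opacity",
    "ScoredImage",
]


@dataclass(frozen=True)
class SeverityRubric:
    """A per-lung severity scale and its induced global (two-lung) range.

    Parameters
    ----------
    name : str
        Rubric identifier, e.g. ``"GE"`` or ``"LO"``.
    per_lung_min, per_lung_max : float
        Range of a single-lung score (0 and 4 for GE/LO).
    increment : float
        Granularity of annotated scores. GE/LO global annotations are
        reported on a half-point grid; augmentation by label mixing can
        produce scores off the grid, so the grid is informative, not
        enforced by validation.
    global_max : float
        Maximum of the summed two-lung score; must equal
        ``2 * per_lung_max``.
    """

    name: str
    per_lung_min: float = 0.0
    per_lung_max: float = 4.0
    increment: float = 0.5
    global_max: float = 8.0

    def __post_init__(self) -> None:
        if self.per_lung_min > self.per_lung_max:
            raise ValueError("per_lung_min must not exceed per_lung_max")
        if self.increment <= 0:
            raise ValueError("increment must be positive")
        if self.global_max != 2 * self.per_lung_max:
            raise ValueError("global_max must equal 2 * per_lung_max")


RUBRICS = {
    "GE": SeverityRubric("GE"),
    "LO": SeverityRubric("LO"),
    "generic": SeverityRubric("generic"),
}


def get_rubric(name: str) -> SeverityRubric:
    try:
        return RUBRICS[name]
    except KeyError:
        raise KeyError(
            f"unknown rubric {name!r}; known: {sorted(RUBRICS)}"
        ) from None


#: Upper bin edges of the geographic-extent quartile bins.
_GE_EDGES = (0.25, 0.50, 0.75)


def ge_label_from_fraction(covered_fraction: float) -> int:
    """Geographic-extent score of one lung from its involved-area fraction.

    ``0`` for no involvement, then quartile bins: ``1`` for (0, 0.25],
    ``2`` for (0.25, 0.5], ``3`` for (0.5, 0.75] and ``4`` above 0.75.
    Edge values map to the lower bin.
    """
    f = float(covered_fraction)
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"covered_fraction must lie in [0, 1], got {f}")
    if f == 0.0:
        return 0
    return 1 + sum(f > e for e in _GE_EDGES)


def lo_label_from_opacity(consolidation_fraction: float, has_ground_glass: bool) -> int:
    """Lung-opacity score of one lung.

    Parameters
    ----------
    consolidation_fraction : float
        Fraction of the lung field covered by dense consolidation.
    has_ground_glass : bool
        Whether any (ground-glass or denser) opacity is present at all.

    Returns
    -------
    int
        0 no opacity; 1 ground glass only; 2 ground glass mixed with
        consolidation below half the lung; 3 consolidation-dominant
        mixture; 4 complete opacification (``consolidation_fraction == 1``).
        A consolidation fraction of exactly 0.5 maps to the lower grade.
    """
    cf = float(consolidation_fraction)
    if not 0.0 <= cf <= 1.0:
        raise ValueError(f"consolidation_fraction must lie in [0, 1], got {cf}")
    if cf > 0.0 and not has_ground_glass:
        raise ValueError(
            "consolidation without the opacity flag is inconsistent; "
            "set has_ground_glass=True when any opacity is present"
        )
    if not has_ground_glass:
        return 0
    if cf == 0.0:
        return 1
    if cf == 1.0:
        return 4
    return 2 if cf <= 0.5 else 3


@dataclass
class ScoredImage:
    """An image with severity annotation under one rubric.

    ``global_score`` must equal ``left_score + right_score`` whenever the
    per-lung pair is present. Images carrying only a global score are
    valid inputs for training and evaluation but are ineligible for the
    lung-replacement augmentation, which needs per-lung ground truth.
    Image-left columns correspond to ``left_score`` and image-right
    columns to ``right_score`` throughout the package (the anatomical
    side is irrelevant to the arithmetic).
    """

    image: np.ndarray
    global_score: float
    left_score: Optional[float] = None
    right_score: Optional[float] = None
    score_type: str = "generic"
    image_id: str = ""

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        if self.image.ndim not in (2, 3):
            raise ValueError("image must be 2-D or (H, W, C)")
        rub = get_rubric(self.score_type)
        if (self.left_score is None) != (self.right_score is None):
            raise ValueError("left_score and right_score must be given together")
        if self.left_score is not None:
            for s in (self.left_score, self.right_score):
                if not rub.per_lung_min <= s <= rub.per_lung_max:
                    raise ValueError(
                        f"per-lung score {s} outside rubric range "
                        f"[{rub.per_lung_min}, {rub.per_lung_max}]"
                    )
            if abs(self.global_score - (self.left_score + self.right_score)) > 1e-9:
                raise ValueError(
                    "global_score must equal left_score + right_score "
                    f"({self.global_score} != {self.left_score} + {self.right_score})"
                )
        if not 0.0 <= self.global_score <= rub.global_max:
            raise ValueError(
                f"global_score {self.global_score} outside [0, {rub.global_max}]"
            )

    @property
    def has_per_lung_scores(self) -> bool:
        return self.left_score is not None

    @property
    def shape(self) -> tuple:
        return self.image.shape
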