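"""Crop-rotation transition matrices and dominance summaries.

A rotation transition matrix cross-tabulates the main crop grown in one
season (``first``) against the main crop grown the following season
(``second``) over all surveyed fields. Mixed plantings recorded as a
single entry (``maize/manioc``) are kept as their own categories here —
the matrix describes land use as recorded — while diversity counting in
:mod:`strigasurvey.management_score` decomposes them into constituents.

``MIDWEST_MADAGASCAR_ROTATION_COUNTS`` holds the observed transition
counts for 281 field rotations from the 2019--2020 mid-west Madagascar
rice--maize survey system; they double as the default rotation process
for the synthetic landscape generator.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .crops import CropRegistry, DEFAULT_REGISTRY

__all__ = [
    "RotationSequence",
    "TransitionMatrix",
    "build_transition_matrix",
    "rotation_fraction",
    "cereal_cereal_pairs",
    "MIDWEST_MADAGASCAR_ROTATION_COUNTS",
]


@dataclass
class RotationSequence:
    """Ordered crop history for one field, oldest season first.

    Each season is a ``(main_crop, companion_crop_or_None)`` pair. Three
    seasons are required for management scoring; two suffice for
    transition counting.
    """

    field_id: str
    seasons: list[tuple[str, str | None]]

    def __post_init__(self):
        if len(self.seasons) < 2:
            raise ValueError(
                f"rotation for field {self.field_id} needs >= 2 seasons, "
                f"got {len(self.seasons)}"
            )

    def main_crops(self) -> list[str]:
        return [main for main, _ in self.seasons]

    def consecutive_pairs(self) -> list[tuple[str, str]]:
        """(first, second) main-crop pairs for consecutive seasons."""
        mains = self.main_crops()
        return list(zip(mains[:-1], mains[1:]))


@dataclass
class TransitionMatrix:
    """Counts of (first-season crop -> second-season crop) transitions.

    ``counts[s, f]`` is the number of fields that grew ``first_crops[f]``
    followed by ``second_crops[s]``.
    """

    first_crops: list[str]
    second_crops: list[str]
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (len(self.second_crops), len(self.first_crops)):
            raise ValueError("counts shape does not match label lists")
        if np.any(self.counts < 0):
            raise ValueError("transition counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def count(self, first: str, second: str) -> int:
        return int(
            self.counts[self.second_crops.index(second), self.first_crops.index(first)]
        )

    def support(self) -> set[tuple[str, str]]:
        """All (first, second) pairs with a positive count."""
        ss, ff = np.nonzero(self.counts)
        return {(self.first_crops[f], self.second_crops[s]) for s, f in zip(ss, ff)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.second_crops, columns=self.first_crops
        ).rename_axis(index="second_crop", columns="first_crop")

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)


def build_transition_matrix(
    rotations: Iterable[RotationSequence],
    first_order: Sequence[str] | None = None,
    second_order: Sequence[str] | None = None,
) -> TransitionMatrix:
    """Count consecutive main-crop transitions over all rotations.

    Labels default to sorted order; pass explicit orderings to reproduce a
    publication layout.
    """
    pairs: list[tuple[str, str]] = []
    for rot in rotations:
        pairs.extend(rot.consecutive_pairs())
    if not pairs:
        raise ValueError("no rotation pairs to count")

    firsts = list(first_order) if first_order else sorted({p[0] for p in pairs})
    seconds = list(second_order) if second_order else sorted({p[1] for p in pairs})
    counts = np.zeros((len(seconds), len(firsts)), dtype=int)
    for first, second in pairs:
        counts[seconds.index(second), firsts.index(first)] += 1
    return TransitionMatrix(firsts, seconds, counts)


def rotation_fraction(
    matrix: TransitionMatrix, pairs: Iterable[tuple[str, str]]
) -> float:
    """Fraction of all observed rotations falling in the named cells."""
    if matrix.total == 0:
        raise ValueError("empty transition matrix")
    total = 0
    for first, second in pairs:
        total += matrix.count(first, second)
    return total / matrix.total


def cereal_cereal_pairs(
    matrix: TransitionMatrix, registry: CropRegistry = DEFAULT_REGISTRY
) -> set[tuple[str, str]]:
    """Cells where a pure cereal is followed by a pure cereal.

    Pure means the season label has a single constituent (``rice``,
    ``maize``) — mixed categories such as ``maize/manioc`` are excluded
    from cereal dominance.
    """
    from .crops import constituents, base_crop

    def pure_cereal(label: str) -> bool:
        parts = constituents(label)
        return len(parts) == 1 and base_crop(parts[0]) in registry.cereals

    return {
        (f, s)
        for f, s in matrix.support()
        if pure_cereal(f) and pure_cereal(s)
    }


def _reference_counts() -> TransitionMatrix:
    first = [
        "rice",
        "maize",
        "fallow",
        "manioc",
        "bambara groundnut",
        "cowpea",
        "groundnut",
        "soybean",
        "sweet potato",
    ]
    second = [
        "rice",
        "maize",
        "bambara groundnut",
        "manioc",
        "fallow",
        "common bean",
        "groundnut",
        "maize/manioc",
        "manioc/bambara groundnut",
        "rice/bambara groundnut",
        "soybean",
        "sweet potato",
    ]
    counts = np.array(
        [
            [29, 37, 8, 9, 5, 0, 0, 2, 1],
            [16, 43, 2, 0, 0, 0, 0, 0, 0],
            [28, 9, 0, 1, 0, 0, 0, 0, 0],
            [16, 13, 0, 1, 0, 1, 0, 0, 0],
            [12, 6, 0, 0, 1, 0, 0, 0, 0],
            [1, 1, 0, 0, 0, 0, 0, 0, 0],
            [9, 11, 0, 0, 0, 0, 0, 0, 0],
            [2, 5, 0, 0, 0, 0, 0, 0, 0],
            [1, 1, 0, 0, 0, 0, 0, 0, 0],
            [2, 0, 0, 0, 0, 0, 0, 0, 0],
            [1, 0, 0, 0, 0, 0, 0, 0, 0],
            [3, 4, 0, 0, 0, 0, 0, 0, 0],
        ]
    )
    return TransitionMatrix(first, second, counts)


#: Observed main-crop transition counts (281 field rotations) from the
#: mid-west Madagascar rice--maize survey system, 2019--2020.
MIDWEST_MADAGASCAR_ROTATION_COUNTS: TransitionMatrix = _reference_counts()
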