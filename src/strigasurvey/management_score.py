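"""Composite management score for *Striga* control.

Four indicators are extracted from each field's three-season rotation
history:

* ``fallow_included`` — 1 if any season was left fallow (0--1);
* ``cereal_years`` — seasons with a cereal (rice or maize) main crop
  (observed range 2--3 in cereal-surveyed fields);
* ``legume_years`` — seasons in which a legume was present as main or
  companion crop (0--3), *Mimosa diplotricha* counted as a legume and no
  differentiation made between legume species;
* ``crop_diversity`` — number of distinct crops planted across the three
  seasons, counting companion crops and mixed-planting constituents,
  with distinct rice varieties as distinct crops and fallow as a
  land-use category (observed range 1--5).

The composite score is the dot product of the indicators with
coefficients from a single linear model of log(x+1) field mean density
on all four indicators jointly (intercept excluded from the score). With
the default fitted coefficients — all negative — a lower (more negative)
score indicates more of the practices associated with lower *Striga*
density, and the score is used as the predictor in a regression of
between-year change in mean density.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .crops import CropRegistry, DEFAULT_REGISTRY, base_crop, constituents
from .rotation import RotationSequence

__all__ = [
    "ManagementIndicators",
    "ScoreCoefficients",
    "ScoreRegressionResult",
    "DEFAULT_COEFFICIENTS",
    "INDICATOR_NAMES",
    "extract_indicators",
    "indicator_frame",
    "fit_score_coefficients",
    "composite_score",
    "score_change_regression",
]

INDICATOR_NAMES = ["fallow_included", "cereal_years", "legume_years", "crop_diversity"]


@dataclass(frozen=True)
class ManagementIndicators:
    fallow_included: int
    cereal_years: int
    legume_years: int
    crop_diversity: int

    def __post_init__(self):
        if not 0 <= self.fallow_included <= 1:
            raise ValueError("fallow_included must be 0 or 1")
        if not 0 <= self.cereal_years <= 3:
            raise ValueError("cereal_years must be in 0..3")
        if not 0 <= self.legume_years <= 3:
            raise ValueError("legume_years must be in 0..3")
        if self.crop_diversity < 1:
            raise ValueError("crop_diversity must be >= 1")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.fallow_included, self.cereal_years, self.legume_years,
             self.crop_diversity],
            dtype=float,
        )


@dataclass(frozen=True)
class ScoreCoefficients:
    """Per-indicator weights; the intercept is carried but never scored."""

    fallow: float
    cereal_years: float
    legume_years: float
    crop_diversity: float
    intercept: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.fallow, self.cereal_years, self.legume_years, self.crop_diversity],
            dtype=float,
        )


#: Fitted indicator weights from the mid-west Madagascar survey system
#: (joint linear model of log1p mean density on all four indicators).
DEFAULT_COEFFICIENTS = ScoreCoefficients(
    fallow=-0.2018,
    cereal_years=-0.09133,
    legume_years=-0.36512,
    crop_diversity=-0.26289,
)


@dataclass(frozen=True)
class ScoreRegressionResult:
    slope: float
    intercept: float
    F: float
    df: tuple[int, int]
    p: float
    n: int
    slope_se: float


def extract_indicators(
    rot: RotationSequence,
    registry: CropRegistry = DEFAULT_REGISTRY,
    include_fallow_in_diversity: bool = True,
) -> ManagementIndicators:
    """Derive the four management indicators from a 3-season rotation.

    Raises ``ValueError`` if the rotation has fewer than three seasons or
    contains a crop name absent from the registry.
    """
    if len(rot.seasons) != 3:
        raise ValueError(
            f"management scoring needs exactly 3 seasons, field {rot.field_id} "
            f"has {len(rot.seasons)}"
        )
    unknown: list[str] = []
    for main, comp in rot.seasons:
        unknown.extend(registry.unknown_names(main))
        if comp:
            unknown.extend(registry.unknown_names(comp))
    if unknown:
        raise ValueError(f"unknown crop name(s): {sorted(set(unknown))}")

    fallow = int(any(registry.is_fallow(main) for main, _ in rot.seasons))
    cereal = sum(registry.is_cereal(main) for main, _ in rot.seasons)
    legume = sum(
        registry.is_legume(main) or (comp is not None and registry.is_legume(comp))
        for main, comp in rot.seasons
    )
    distinct: set[str] = set()
    for main, comp in rot.seasons:
        for label in ([main, comp] if comp else [main]):
            for crop in constituents(label):
                if base_crop(crop) == registry.fallow_label:
                    if include_fallow_in_diversity:
                        distinct.add(registry.fallow_label)
                else:
                    distinct.add(crop)
    return ManagementIndicators(
        fallow_included=fallow,
        cereal_years=int(cereal),
        legume_years=int(legume),
        crop_diversity=len(distinct),
    )


def indicator_frame(
    rotations: Sequence[RotationSequence],
    registry: CropRegistry = DEFAULT_REGISTRY,
    **kwargs,
) -> pd.DataFrame:
    """Indicator table (one row per rotation) with a ``field_id`` column."""
    rows = []
    for rot in rotations:
        ind = extract_indicators(rot, registry, **kwargs)
        rows.append({"field_id": rot.field_id, **ind.__dict__})
    return pd.DataFrame(rows)


def fit_score_coefficients(data: pd.DataFrame, response: str = "log_density"
                           ) -> ScoreCoefficients:
    """OLS fit of log1p density on the four indicators jointly.

    ``data`` must contain the four indicator columns and the response.
    A rank-deficient indicator matrix (e.g. an indicator constant or an
    exact linear combination of the others) raises, naming the columns
    involved.
    """
    if len(data) < 6:
        raise ValueError(f"need at least 6 rows to fit four slopes, got {len(data)}")
    X = data[INDICATOR_NAMES].to_numpy(dtype=float)
    y = data[response].to_numpy(dtype=float)
    design = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        degenerate = [
            name
            for i, name in enumerate(INDICATOR_NAMES)
            if np.linalg.matrix_rank(np.delete(design, i + 1, axis=1)) == rank
        ]
        raise ValueError(
            "indicator matrix is rank deficient; collinear or constant "
            f"indicators: {degenerate}"
        )
    fit = sm.OLS(y, design).fit()
    return ScoreCoefficients(
        fallow=float(fit.params[1]),
        cereal_years=float(fit.params[2]),
        legume_years=float(fit.params[3]),
        crop_diversity=float(fit.params[4]),
        intercept=float(fit.params[0]),
    )


def composite_score(
    ind: ManagementIndicators,
    coef: ScoreCoefficients = DEFAULT_COEFFICIENTS,
) -> float:
    """Weighted sum of the four indicators; the intercept is excluded."""
    arr = coef.as_array()
    if not np.all(np.isfinite(arr)):
        raise ValueError("coefficients must be finite")
    return float(ind.as_array() @ arr)


def score_change_regression(
    scores: Sequence[float], deltas: Sequence[float]
) -> ScoreRegressionResult:
    """Simple OLS of change in mean density on the composite score.

    The slope is tested with an F test on (1, n-2) degrees of freedom.
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(deltas, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("scores and deltas must be 1-D and the same length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired fields")
    if np.ptp(x) == 0:
        raise ValueError("composite score is constant; slope undefined")

    xc = x - x.mean()
    slope = float(xc @ (y - y.mean()) / (xc @ xc))
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    rss = float(resid @ resid)
    tss = float((y - y.mean()) @ (y - y.mean()))
    df_resid = n - 2
    mse = rss / df_resid
    F = (tss - rss) / mse if mse > 0 else np.inf
    p = float(stats.f.sf(F, 1, df_resid)) if np.isfinite(F) else 0.0
    se = float(np.sqrt(mse / (xc @ xc))) if mse > 0 else 0.0
    return ScoreRegressionResult(
        slope=slope,
        intercept=intercept,
        F=float(F),
        df=(1, df_resid),
        p=p,
        n=n,
        slope_se=se,
    )
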