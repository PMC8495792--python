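"""Climate and spatial covariates for field-level density models.

Two covariates that the survey analysis needs but the raw records do not
carry directly:

* **Precipitation seasonality** — the coefficient of variation of the 12
  monthly precipitation totals, the bioclim-style (BIO15) measure of
  intra-annual rainfall variability. Convention: 100 x sd / mean with the
  sample (n-1) standard deviation and the mean *monthly* total as the
  denominator. The denominator is configurable because the quantity is
  sometimes described loosely as a ratio to "annual precipitation"; the
  mean-monthly reading is the standard one and the default.
* **Nearest-neighbour density** — the mean density of the closest other
  field surveyed in the same year (great-circle distance), a strong
  spatial predictor of within-field *Striga* density.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .survey_io import SurveyDataset, field_mean_density

__all__ = [
    "ClimateCovariates",
    "NeighborDensity",
    "precipitation_seasonality_cv",
    "haversine_m",
    "nearest_neighbor_density",
    "augment_field_frame",
]

EARTH_RADIUS_M = 6_371_000.0


@dataclass(frozen=True)
class ClimateCovariates:
    mean_annual_precip_mm: float
    precip_seasonality_cv: float  # percent
    mean_temp_C: float
    altitude_m: float


@dataclass(frozen=True)
class NeighborDensity:
    field_id: str
    neighbor_id: str
    distance_m: float
    neighbor_mean_density: float


def precipitation_seasonality_cv(
    monthly: Sequence[float],
    denominator: Literal["mean_monthly", "annual_total"] = "mean_monthly",
) -> float:
    """Coefficient of variation of monthly precipitation, in percent.

    Parameters
    ----------
    monthly
        Exactly 12 non-negative monthly precipitation totals (mm).
    denominator
        ``"mean_monthly"`` (default, the BIO15 convention) divides the
        sample standard deviation by the mean monthly total;
        ``"annual_total"`` divides by the annual sum (values 12x smaller).
    """
    arr = np.asarray(monthly, dtype=float)
    if arr.shape != (12,):
        raise ValueError(f"expected exactly 12 monthly values, got shape {arr.shape}")
    if np.any(arr < 0):
        raise ValueError("monthly precipitation must be non-negative")
    if np.all(arr == 0):
        raise ValueError("CV undefined for all-zero precipitation")
    sd = float(np.std(arr, ddof=1))
    denom = float(arr.mean()) if denominator == "mean_monthly" else float(arr.sum())
    return 100.0 * sd / denom


def haversine_m(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in metres on a sphere of radius 6,371 km."""
    p1, l1, p2, l2 = map(np.radians, (lat1, lon1, lat2, lon2))
    a = (
        np.sin((p2 - p1) / 2.0) ** 2
        + np.cos(p1) * np.cos(p2) * np.sin((l2 - l1) / 2.0) ** 2
    )
    return float(2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0))))


def nearest_neighbor_density(
    dataset: SurveyDataset, year: int
) -> list[NeighborDensity]:
    """Closest same-year field and its mean density, for every field.

    Ties in distance are broken towards the lexicographically smaller
    neighbour ``field_id`` so results are deterministic.
    """
    fields = [f for f in dataset.fields if f.year == year and f.quadrats]
    if len(fields) < 2:
        raise ValueError(f"need at least 2 surveyed fields in year {year}")
    fields = sorted(fields, key=lambda f: f.field_id)
    lat = np.array([f.lat for f in fields])
    lon = np.array([f.lon for f in fields])
    densities = [field_mean_density(f) for f in fields]

    out: list[NeighborDensity] = []
    for i, f in enumerate(fields):
        best_j, best_d = -1, np.inf
        for j in range(len(fields)):
            if j == i:
                continue
            d = haversine_m(lat[i], lon[i], lat[j], lon[j])
            # strict < keeps the lexicographically first field on ties
            if d < best_d:
                best_j, best_d = j, d
        out.append(
            NeighborDensity(
                field_id=f.field_id,
                neighbor_id=fields[best_j].field_id,
                distance_m=best_d,
                neighbor_mean_density=densities[best_j],
            )
        )
    return out


def augment_field_frame(
    dataset: SurveyDataset, field_frame: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Add precip_cv_pct and neighbour columns to the per-field-year table."""
    df = dataset.field_frame() if field_frame is None else field_frame.copy()
    precip_cols = [f"precip_m{m:02d}" for m in range(1, 13)]
    df["precip_cv_pct"] = [
        precipitation_seasonality_cv(row) for row in df[precip_cols].to_numpy()
    ]

    df["neighbor_id"] = pd.NA
    df["neighbor_distance_m"] = np.nan
    df["neighbor_mean_density"] = np.nan
    for year in sorted(df["year"].unique()):
        surveyed = [
            f for f in dataset.fields if f.year == year and f.quadrats
        ]
        if len(surveyed) < 2:
            continue
        for nb in nearest_neighbor_density(dataset, int(year)):
            mask = (df["field_id"] == nb.field_id) & (df["year"] == year)
            df.loc[mask, "neighbor_id"] = nb.neighbor_id
            df.loc[mask, "neighbor_distance_m"] = nb.distance_m
            df.loc[mask, "neighbor_mean_density"] = nb.neighbor_mean_density
    return df
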