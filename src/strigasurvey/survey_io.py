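"""Reading, validating and aggregating density-structured survey data.

The survey design this module models: fields sampled along road transects,
each field scored in up to three pairs of 10 x 20 m quadrats on a six-point
ordinal density scale (0 = *Striga* verified absent after a whole-field
walk-through, 5 = very high). The canonical on-disk format is a long CSV
with one row per quadrat-year and field-level columns repeated.

Field-level density is the unweighted arithmetic mean of quadrat states
(all quadrats cover an equal 200 m^2). Fields resurveyed under a
non-cereal (non-host) crop are retained in the dataset but excluded from
density analyses, mirroring the survey protocol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .crops import CropRegistry, DEFAULT_REGISTRY

__all__ = [
    "DensityState",
    "QuadratRecord",
    "FieldRecord",
    "SurveyDataset",
    "ValidationIssue",
    "LinkedYears",
    "SURVEY_COLUMNS",
    "read_survey_csv",
    "write_survey_csv",
    "field_mean_density",
    "link_years",
    "change_in_density",
]

PRECIP_COLUMNS = [f"precip_m{m:02d}" for m in range(1, 13)]

#: Canonical long-format header, one row per quadrat-year.
SURVEY_COLUMNS = [
    "field_id",
    "year",
    "transect",
    "lat",
    "lon",
    "altitude_m",
    "crop",
    "rice_variety",
    "companion_crop",
    "prev_crop_1",
    "prev_crop_2",
    "quadrat_index",
    "density_state",
    "crop_height_cm",
    "crop_cover_pct",
    "other_weed_cover_pct",
    *PRECIP_COLUMNS,
    "mean_temp_C",
    "no3_ppm",
]

#: Columns that must be present in every survey CSV. ``no3_ppm`` is the
#: only optional column (soil nitrate was measured in a subset of fields).
MANDATORY_COLUMNS = [c for c in SURVEY_COLUMNS if c != "no3_ppm"]

MAX_QUADRATS_PER_FIELD = 6  # three pairs of 10 x 20 m quadrats


class DensityState(int):
    """Ordinal density state on the six-point scale 0 (absent) .. 5 (very high)."""

    def __new__(cls, value):
        iv = int(value)
        if iv != float(value) or not 0 <= iv <= 5:
            raise ValueError(f"density state must be an integer in 0..5, got {value!r}")
        return super().__new__(cls, iv)


@dataclass
class QuadratRecord:
    """One 200 m^2 quadrat observation within a field-year."""

    field_id: str
    quadrat_index: int
    density: DensityState
    crop_height_cm: float
    crop_cover_pct: float
    other_weed_cover_pct: float

    def __post_init__(self):
        self.density = DensityState(self.density)
        if self.quadrat_index < 1:
            raise ValueError("quadrat_index must be >= 1")


@dataclass
class FieldRecord:
    """All observations for one field in one survey year."""

    field_id: str
    year: int
    transect: int
    lat: float
    lon: float
    altitude_m: float
    crop: str
    rice_variety: Optional[str]
    companion_crop: Optional[str]
    prev_crop_1: Optional[str]  # main crop one season before `year`
    prev_crop_2: Optional[str]  # main crop two seasons before `year`
    quadrats: list[QuadratRecord] = dc_field(default_factory=list)
    monthly_precip_mm: tuple[float, ...] = ()
    mean_temp_C: float = float("nan")
    no3_ppm: Optional[float] = None

    def __post_init__(self):
        if self.transect not in (1, 2):
            raise ValueError(f"transect must be 1 or 2, got {self.transect}")
        if self.monthly_precip_mm and len(self.monthly_precip_mm) != 12:
            raise ValueError("monthly_precip_mm must have exactly 12 entries")
        if len(self.quadrats) > MAX_QUADRATS_PER_FIELD:
            raise ValueError(
                f"field {self.field_id} year {self.year}: more than "
                f"{MAX_QUADRATS_PER_FIELD} quadrats"
            )

    @property
    def crop_label(self) -> str:
        """Season label of the current main crop, variety-qualified for rice."""
        if self.rice_variety:
            return f"{self.crop}-{self.rice_variety}"
        return self.crop

    def is_cereal(self, registry: CropRegistry = DEFAULT_REGISTRY) -> bool:
        return registry.is_cereal(self.crop)

    def season_labels(self) -> list[tuple[str, Optional[str]]]:
        """(main, companion) labels, oldest season first, for seasons on record."""
        seasons: list[tuple[str, Optional[str]]] = []
        if self.prev_crop_2:
            seasons.append((self.prev_crop_2, None))
        if self.prev_crop_1:
            seasons.append((self.prev_crop_1, None))
        seasons.append((self.crop_label, self.companion_crop or None))
        return seasons


@dataclass
class ValidationIssue:
    """A row-level problem found while reading a survey CSV."""

    row: int  # 1-based data row number (header excluded)
    field_id: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"row {self.row} (field {self.field_id}): {self.message}"


@dataclass
class SurveyDataset:
    """A validated collection of field-year records spanning one or two years."""

    fields: list[FieldRecord]
    provenance: str = ""
    validation_issues: list[ValidationIssue] = dc_field(default_factory=list)

    def __post_init__(self):
        keys = [(f.field_id, f.year) for f in self.fields]
        if len(keys) != len(set(keys)):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ValueError(f"duplicate (field_id, year) records: {dupes}")

    def years(self) -> list[int]:
        return sorted({f.year for f in self.fields})

    def for_year(self, year: int) -> "SurveyDataset":
        return SurveyDataset(
            [f for f in self.fields if f.year == year], provenance=self.provenance
        )

    def get(self, field_id: str, year: int) -> FieldRecord:
        for f in self.fields:
            if f.field_id == field_id and f.year == year:
                return f
        raise KeyError((field_id, year))

    def to_frame(self) -> pd.DataFrame:
        """Long-format table, one row per quadrat-year (the CSV layout)."""
        rows = []
        for f in self.fields:
            base = {
                "field_id": f.field_id,
                "year": f.year,
                "transect": f.transect,
                "lat": f.lat,
                "lon": f.lon,
                "altitude_m": f.altitude_m,
                "crop": f.crop,
                "rice_variety": f.rice_variety or "",
                "companion_crop": f.companion_crop or "",
                "prev_crop_1": f.prev_crop_1 or "",
                "prev_crop_2": f.prev_crop_2 or "",
            }
            precip = dict(zip(PRECIP_COLUMNS, f.monthly_precip_mm))
            tail = {
                "mean_temp_C": f.mean_temp_C,
                "no3_ppm": f.no3_ppm if f.no3_ppm is not None else np.nan,
            }
            for q in f.quadrats:
                rows.append(
                    {
                        **base,
                        "quadrat_index": q.quadrat_index,
                        "density_state": int(q.density),
                        "crop_height_cm": q.crop_height_cm,
                        "crop_cover_pct": q.crop_cover_pct,
                        "other_weed_cover_pct": q.other_weed_cover_pct,
                        **precip,
                        **tail,
                    }
                )
        return pd.DataFrame(rows, columns=SURVEY_COLUMNS)

    def field_frame(self, registry: CropRegistry = DEFAULT_REGISTRY) -> pd.DataFrame:
        """One row per field-year with the mean density and field covariates."""
        rows = []
        for f in self.fields:
            precip = np.asarray(f.monthly_precip_mm, dtype=float)
            rows.append(
                {
                    "field_id": f.field_id,
                    "year": f.year,
                    "transect": f.transect,
                    "lat": f.lat,
                    "lon": f.lon,
                    "altitude_m": f.altitude_m,
                    "crop": f.crop,
                    "crop_label": f.crop_label,
                    "rice_variety": f.rice_variety,
                    "companion_crop": f.companion_crop,
                    "prev_crop_1": f.prev_crop_1,
                    "prev_crop_2": f.prev_crop_2,
                    "is_cereal": f.is_cereal(registry),
                    "n_quadrats": len(f.quadrats),
                    "mean_density": field_mean_density(f) if f.quadrats else np.nan,
                    "other_weed_cover_pct": (
                        float(np.mean([q.other_weed_cover_pct for q in f.quadrats]))
                        if f.quadrats
                        else np.nan
                    ),
                    "mean_annual_precip_mm": (
                        float(precip.sum()) if precip.size else np.nan
                    ),
                    "mean_temp_C": f.mean_temp_C,
                    "no3_ppm": f.no3_ppm if f.no3_ppm is not None else np.nan,
                    **dict(zip(PRECIP_COLUMNS, f.monthly_precip_mm)),
                }
            )
        return pd.DataFrame(rows)


def field_mean_density(field: FieldRecord) -> float:
    """Unweighted mean of the field's quadrat density states (range 0..5)."""
    if not field.quadrats:
        raise ValueError(
            f"field {field.field_id} year {field.year} has no quadrats; "
            "mean density undefined"
        )
    return float(np.mean([int(q.density) for q in field.quadrats]))


def _opt_str(value) -> Optional[str]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    return s if s and s.lower() not in {"none", "na", "nan"} else None


def read_survey_csv(
    path: str | Path, registry: CropRegistry = DEFAULT_REGISTRY
) -> SurveyDataset:
    """Read a long-format survey CSV into a validated :class:`SurveyDataset`.

    Rows that violate row-level invariants (density outside 0..5, bad
    quadrat index, too many quadrats per field) are collected into
    ``dataset.validation_issues`` rather than silently dropped; a missing
    mandatory column is a hard failure naming the column.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"field_id": str})
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"survey CSV {path} is missing mandatory columns: {missing}")

    issues: list[ValidationIssue] = []
    fields: dict[tuple[str, int], FieldRecord] = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        fid = str(row.field_id)
        try:
            density = DensityState(row.density_state)
        except (ValueError, TypeError) as exc:
            issues.append(ValidationIssue(i, fid, str(exc)))
            continue
        key = (fid, int(row.year))
        if key not in fields:
            try:
                fields[key] = FieldRecord(
                    field_id=fid,
                    year=int(row.year),
                    transect=int(row.transect),
                    lat=float(row.lat),
                    lon=float(row.lon),
                    altitude_m=float(row.altitude_m),
                    crop=str(row.crop),
                    rice_variety=_opt_str(row.rice_variety),
                    companion_crop=_opt_str(row.companion_crop),
                    prev_crop_1=_opt_str(row.prev_crop_1),
                    prev_crop_2=_opt_str(row.prev_crop_2),
                    monthly_precip_mm=tuple(
                        float(getattr(row, c)) for c in PRECIP_COLUMNS
                    ),
                    mean_temp_C=float(row.mean_temp_C),
                    no3_ppm=(
                        float(row.no3_ppm)
                        if "no3_ppm" in df.columns and pd.notna(row.no3_ppm)
                        else None
                    ),
                )
            except ValueError as exc:
                issues.append(ValidationIssue(i, fid, str(exc)))
                continue
        rec = fields[key]
        try:
            quadrat = QuadratRecord(
                field_id=fid,
                quadrat_index=int(row.quadrat_index),
                density=density,
                crop_height_cm=float(row.crop_height_cm),
                crop_cover_pct=float(row.crop_cover_pct),
                other_weed_cover_pct=float(row.other_weed_cover_pct),
            )
        except ValueError as exc:
            issues.append(ValidationIssue(i, fid, str(exc)))
            continue
        if len(rec.quadrats) >= MAX_QUADRATS_PER_FIELD:
            issues.append(
                ValidationIssue(
                    i, fid, f"more than {MAX_QUADRATS_PER_FIELD} quadrats in a field-year"
                )
            )
            continue
        rec.quadrats.append(quadrat)

    dataset = SurveyDataset(
        list(fields.values()), provenance=str(path), validation_issues=issues
    )
    return dataset


def write_survey_csv(dataset: SurveyDataset, path: str | Path) -> None:
    """Write the dataset in the canonical long CSV layout (read round-trips)."""
    dataset.to_frame().to_csv(path, index=False)


@dataclass
class LinkedYears:
    """Fields paired across two survey years, with documented exclusions.

    ``pairs`` holds one row per field present and cereal-cropped in both
    years; ``exclusions`` lists every field left out, with a reason code
    (``unmatched`` — present in only one year; ``non-cereal`` — a non-host
    crop in at least one year, so density is not comparable).
    """

    pairs: pd.DataFrame  # columns: field_id, mean_2019, mean_2020
    exclusions: pd.DataFrame  # columns: field_id, reason
    year_first: int
    year_second: int


def link_years(
    d_first: SurveyDataset,
    d_second: SurveyDataset,
    registry: CropRegistry = DEFAULT_REGISTRY,
) -> LinkedYears:
    """Pair fields across the two survey years for change-in-density analysis."""

    def _by_id(ds: SurveyDataset) -> dict[str, FieldRecord]:
        out: dict[str, FieldRecord] = {}
        for f in ds.fields:
            if f.field_id in out:
                raise ValueError(
                    f"duplicate field_id {f.field_id!r} within year {f.year}"
                )
            out[f.field_id] = f
        return out

    first = _by_id(d_first)
    second = _by_id(d_second)
    y1 = d_first.fields[0].year if d_first.fields else 0
    y2 = d_second.fields[0].year if d_second.fields else 0

    pairs = []
    exclusions = []
    for fid in sorted(set(first) | set(second)):
        if fid not in first or fid not in second:
            exclusions.append({"field_id": fid, "reason": "unmatched"})
            continue
        f1, f2 = first[fid], second[fid]
        if not (f1.is_cereal(registry) and f2.is_cereal(registry)):
            exclusions.append({"field_id": fid, "reason": "non-cereal"})
            continue
        pairs.append(
            {
                "field_id": fid,
                f"mean_{y1}": field_mean_density(f1),
                f"mean_{y2}": field_mean_density(f2),
            }
        )
    return LinkedYears(
        pairs=pd.DataFrame(pairs, columns=["field_id", f"mean_{y1}", f"mean_{y2}"]),
        exclusions=pd.DataFrame(exclusions, columns=["field_id", "reason"]),
        year_first=y1,
        year_second=y2,
    )


def change_in_density(linked: LinkedYears) -> pd.DataFrame:
    """Per-field change in mean density, second year minus first (range -5..5)."""
    out = linked.pairs.copy()
    out["delta"] = (
        out[f"mean_{linked.year_second}"] - out[f"mean_{linked.year_first}"]
    )
    return out
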