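"""Synthetic two-year, density-structured survey landscapes.

Generates survey datasets with the statistical structure the analysis
pipeline assumes, with every effect size known, so that estimation can
be validated by parameter recovery:

* fields placed every kilometre along two road transects, alternating
  road sides, with climate covariates (precipitation seasonality, mean
  temperature, altitude, annual rainfall) varying smoothly with position
  — temperature and seasonality share the positional gradient and are
  therefore strongly collinear, as in the real system;
* three-season rotation histories sampled from an observed crop
  transition matrix (the surveyed season is always a cereal, as the
  survey protocol targets host crops);
* a latent log(x+1)-scale density per field-year: first-year latent =
  baseline + variety effect + legume effect + climate terms + spatial
  coupling to the previously placed field + noise; second-year latent =
  first-year latent + year effect + gamma x composite management score
  + noise;
* ordinal quadrat states obtained by adding quadrat-level noise to the
  field latent and discretising the implied plant count through fixed
  thresholds.

The generator returns both the survey dataset (what a field team would
record) and a ground-truth table of latent states and scores (what only
the simulation knows), the latter feeding recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .crops import DEFAULT_REGISTRY, CropRegistry
from .management_score import (
    DEFAULT_COEFFICIENTS,
    ScoreCoefficients,
    composite_score,
    extract_indicators,
)
from .rotation import (
    MIDWEST_MADAGASCAR_ROTATION_COUNTS,
    RotationSequence,
    TransitionMatrix,
)
from .survey_io import FieldRecord, QuadratRecord, SurveyDataset

__all__ = [
    "SyntheticConfig",
    "generate_landscape",
    "discretize_density",
    "sample_rotation",
    "generate_indicator_table",
    "DEFAULT_STATE_THRESHOLDS",
]

#: Plants per 200 m^2 quadrat separating ordinal states 0..5.
DEFAULT_STATE_THRESHOLDS = (0.5, 5.0, 20.0, 50.0, 150.0)

#: Rice varieties offered by the generator with their sampling weights
#: (from the relative frequencies of the common varieties in the
#: mid-west Madagascar system) and latent-density effects. Variety
#: effects are generator fixtures chosen to span the susceptible ->
#: resistant range; NERICA varieties are the resistant end.
DEFAULT_VARIETY_WEIGHTS = {
    "JEAN LOUIS": 0.23,
    "FAHITA TANETY": 0.22,
    "B22": 0.21,
    "NERICA4": 0.17,
    "CHOMRONG DHAN": 0.10,
    "NERICA10": 0.07,
}

DEFAULT_VARIETY_EFFECTS = {
    "B22": 0.40,
    "FAHITA TANETY": 0.30,
    "JEAN LOUIS": 0.20,
    "CHOMRONG DHAN": 0.00,
    "NERICA4": -0.30,
    "NERICA10": -0.80,
    "maize": 0.10,
}

DEFAULT_CLIMATE_SLOPES = {
    "precip_cv_pct": 0.05,  # per percentage point of seasonality CV
    "altitude_m": -0.003,  # per metre
}

_COMPANION_LEGUMES = ["groundnut", "soybean", "bambara groundnut", "cowpea"]


@dataclass(frozen=True)
class SyntheticConfig:
    """All effect sizes, rates and noise parameters of the generator.

    Defaults emulate the study system: ~220 fields split 4:1 across two
    transects at 1 km spacing, six 200 m^2 quadrats per field, two survey
    years, and interannual field-level noise large enough to reproduce
    the observed spread of between-year density changes.
    """

    n_fields: int = 220
    field_spacing_km: float = 1.0
    transect2_fraction: float = 0.2
    quadrats_per_field: int = 6
    baseline_log_density: float = 1.8
    rice_fraction: float = 0.6  # surveyed-year main crop: rice vs maize
    variety_weights: dict = dc_field(
        default_factory=lambda: dict(DEFAULT_VARIETY_WEIGHTS)
    )
    variety_effects: dict = dc_field(
        default_factory=lambda: dict(DEFAULT_VARIETY_EFFECTS)
    )
    legume_effect: float = -0.4
    climate_slopes: dict = dc_field(
        default_factory=lambda: dict(DEFAULT_CLIMATE_SLOPES)
    )
    neighbor_rho: float = 0.3
    year_effect: float = -0.3
    mgmt_gamma: float = -0.5
    noise_sd: float = 0.7
    quadrat_sd: float = 0.4
    companion_legume_prob: float = 0.2
    companion_other_prob: float = 0.15
    rotation_counts: TransitionMatrix = dc_field(
        default_factory=lambda: MIDWEST_MADAGASCAR_ROTATION_COUNTS
    )
    state_thresholds: tuple[float, ...] = DEFAULT_STATE_THRESHOLDS
    score_coefficients: ScoreCoefficients = DEFAULT_COEFFICIENTS
    # latent handicap applied when the resurveyed crop is a non-host:
    # emerged Striga all but vanishes without a cereal host
    nonhost_latent_penalty: float = 4.0
    no3_sample_fraction: float = 0.25
    year_first: int = 2019
    year_second: int = 2020
    seed: int = 0

    def validate(self) -> None:
        if self.n_fields < 2:
            raise ValueError("n_fields must be >= 2")
        if not 2 <= self.quadrats_per_field <= 6:
            raise ValueError("quadrats_per_field must be in 2..6")
        if not 0.0 <= self.neighbor_rho < 1.0:
            raise ValueError("neighbor_rho must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        thr = np.asarray(self.state_thresholds, dtype=float)
        if thr.size != 5 or np.any(np.diff(thr) <= 0):
            raise ValueError("state_thresholds must be 5 strictly increasing values")
        if not 0.0 < self.rice_fraction < 1.0:
            raise ValueError("rice_fraction must be in (0, 1)")
        if not 0.0 <= self.transect2_fraction < 1.0:
            raise ValueError("transect2_fraction must be in [0, 1)")


def discretize_density(
    latent: float, thresholds: Sequence[float] = DEFAULT_STATE_THRESHOLDS
) -> int:
    """Ordinal state implied by a latent log(x+1)-scale density.

    The latent maps to a plant count ``exp(latent) - 1`` per 200 m^2;
    the state is the number of thresholds strictly below that count,
    clamped to 0..5. Monotone in the latent by construction.
    """
    if not np.isfinite(latent):
        raise ValueError(f"latent density must be finite, got {latent}")
    count = np.expm1(latent)
    return int(np.sum(np.asarray(thresholds, dtype=float) < count))


def _col_normalized(matrix: TransitionMatrix, first: str) -> np.ndarray:
    """Forward transition probabilities P(second | first); uniform fallback."""
    j = matrix.first_crops.index(first)
    col = matrix.counts[:, j].astype(float)
    total = col.sum()
    if total == 0:
        return np.full(len(col), 1.0 / len(col))
    return col / total


def _row_normalized(matrix: TransitionMatrix, second: str) -> np.ndarray:
    """Backward probabilities P(first | second); uniform fallback."""
    i = matrix.second_crops.index(second)
    row = matrix.counts[i, :].astype(float)
    total = row.sum()
    if total == 0:
        return np.full(len(row), 1.0 / len(row))
    return row / total


def sample_rotation(
    rng: np.random.Generator, config: SyntheticConfig, field_id: str
) -> tuple[RotationSequence, Optional[str], Optional[str]]:
    """Sample a 3-season rotation centred on a cereal-surveyed season.

    The middle (first survey year) main crop is a cereal, as the survey
    targets host crops; the preceding season is drawn from the observed
    backward transition frequencies and the following season from the
    forward ones. Returns the rotation plus the companion crops of the
    two survey seasons.
    """
    m = config.rotation_counts
    s2 = "rice" if rng.random() < config.rice_fraction else "maize"
    s1 = str(rng.choice(m.first_crops, p=_row_normalized(m, s2)))
    s3 = str(rng.choice(m.second_crops, p=_col_normalized(m, s2)))

    def companion() -> Optional[str]:
        u = rng.random()
        if u < config.companion_legume_prob:
            return str(rng.choice(_COMPANION_LEGUMES))
        if u < config.companion_legume_prob + config.companion_other_prob:
            return "manioc"
        return None

    comp2, comp3 = companion(), companion()
    rot = RotationSequence(
        field_id=field_id, seasons=[(s1, None), (s2, comp2), (s3, comp3)]
    )
    return rot, comp2, comp3


def _assign_variety(rng: np.random.Generator, config: SyntheticConfig) -> str:
    names = list(config.variety_weights)
    probs = np.asarray([config.variety_weights[n] for n in names], dtype=float)
    probs = probs / probs.sum()
    return str(rng.choice(names, p=probs))


def _positions(config: SyntheticConfig) -> pd.DataFrame:
    """Field coordinates and climate covariates along the two transects."""
    n2 = int(round(config.n_fields * config.transect2_fraction))
    n1 = config.n_fields - n2
    rows = []
    idx = 0
    for transect, n_t, lat0, lon0 in ((1, n1, -19.60, 46.00), (2, n2, -18.80, 46.40)):
        for k in range(n_t):
            frac = k / max(n_t - 1, 1)
            km = k * config.field_spacing_km
            side = 1 if k % 2 == 0 else -1
            lat = lat0 + side * 0.0005
            lon = lon0 + km / (111.320 * np.cos(np.radians(lat0)))
            rows.append(
                {
                    "field_id": f"T{transect}-{k + 1:03d}",
                    "transect": transect,
                    "order": idx,
                    "frac": frac,
                    "lat": lat,
                    "lon": lon,
                }
            )
            idx += 1
    return pd.DataFrame(rows)


def generate_landscape(
    config: SyntheticConfig = SyntheticConfig(),
    registry: CropRegistry = DEFAULT_REGISTRY,
) -> tuple[SurveyDataset, pd.DataFrame]:
    """Generate a two-year survey dataset plus its ground-truth table.

    Returns ``(dataset, truth)`` where ``truth`` has one row per
    field-year with the latent log density, the composite management
    score, the four indicators and the climate covariates. Identical
    ``config`` (including its ``seed``) reproduces identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    pos = _positions(config)
    n = len(pos)

    # climate surfaces: seasonality and temperature rise together along
    # the transect while altitude falls, reproducing the collinearity
    # that forces separate models in the analysis
    frac = pos["frac"].to_numpy()
    altitude = 1000.0 - 300.0 * frac + rng.normal(0.0, 15.0, n)
    temp = 21.0 + 3.0 * frac + rng.normal(0.0, 0.3, n)
    annual = 1100.0 + 800.0 * frac + rng.normal(0.0, 50.0, n)
    amplitude = np.clip(0.5 + 0.4 * frac + rng.normal(0.0, 0.02, n), 0.0, 1.0)
    months = np.arange(12)
    season_shape = np.cos(2.0 * np.pi * (months - 0.5) / 12.0)
    monthly = (annual[:, None] / 12.0) * (1.0 + amplitude[:, None] * season_shape)
    monthly = np.clip(monthly, 0.0, None)
    cv = 100.0 * np.std(monthly, axis=1, ddof=1) / np.mean(monthly, axis=1)

    rotations: list[RotationSequence] = []
    comps2: list[Optional[str]] = []
    comps3: list[Optional[str]] = []
    varieties2: list[Optional[str]] = []
    varieties3: list[Optional[str]] = []
    for fid in pos["field_id"]:
        rot, c2, c3 = sample_rotation(rng, config, str(fid))
        rotations.append(rot)
        comps2.append(c2)
        comps3.append(c3)
        varieties2.append(
            _assign_variety(rng, config) if rot.seasons[1][0] == "rice" else None
        )
        varieties3.append(
            _assign_variety(rng, config) if rot.seasons[2][0] == "rice" else None
        )

    # scoring rotation: the exact label view a 2020 survey record carries
    # (previous crops without variety, current crop variety-qualified)
    scores = np.empty(n)
    indicators = []
    for i, rot in enumerate(rotations):
        s1, s2, s3 = rot.seasons
        s2_label = s2[0] if s2[1] is None else f"{s2[0]}/{s2[1]}"
        s3_main = (
            f"{s3[0]}-{varieties3[i]}" if varieties3[i] is not None else s3[0]
        )
        score_rot = RotationSequence(
            field_id=rot.field_id,
            seasons=[(s1[0], None), (s2_label, None), (s3_main, s3[1])],
        )
        ind = extract_indicators(score_rot, registry)
        indicators.append(ind)
        scores[i] = composite_score(ind, config.score_coefficients)

    # latent densities: single sweep in transect order so each field
    # couples to the previously placed (adjacent) field
    centered_cov = {
        "precip_cv_pct": cv - cv.mean(),
        "altitude_m": altitude - altitude.mean(),
        "mean_temp_C": temp - temp.mean(),
        "mean_annual_precip_mm": annual - annual.mean(),
    }
    mu = np.full(n, config.baseline_log_density)
    for i, rot in enumerate(rotations):
        label2 = varieties2[i] if varieties2[i] is not None else rot.seasons[1][0]
        mu[i] += config.variety_effects.get(label2, 0.0)
        legume_hist = any(
            registry.is_legume(main) or (comp is not None and registry.is_legume(comp))
            for main, comp in rot.seasons[:2]
        )
        if legume_hist:
            mu[i] += config.legume_effect
    for name, slope in config.climate_slopes.items():
        if name not in centered_cov:
            raise ValueError(f"unknown climate covariate in climate_slopes: {name!r}")
        mu += slope * centered_cov[name]

    latent1 = np.empty(n)
    eps1 = rng.normal(0.0, config.noise_sd, n)
    prev_idx_in_transect: dict[int, int] = {}
    for i in range(n):
        t = int(pos["transect"].iloc[i])
        if t in prev_idx_in_transect:
            j = prev_idx_in_transect[t]
            latent1[i] = mu[i] + config.neighbor_rho * (latent1[j] - mu[j]) + eps1[i]
        else:
            latent1[i] = mu[i] + eps1[i]
        prev_idx_in_transect[t] = i

    eps2 = rng.normal(0.0, config.noise_sd, n)
    latent2 = latent1 + config.year_effect + config.mgmt_gamma * scores + eps2

    no3_flags = rng.random(n) < config.no3_sample_fraction
    no3_vals = np.exp(rng.normal(3.0, 0.5, n))

    fields: list[FieldRecord] = []
    truth_rows = []
    for i in range(n):
        rot = rotations[i]
        s1, s2, s3 = rot.seasons
        s2_prev_label = s2[0] if comps2[i] is None else f"{s2[0]}/{comps2[i]}"
        base = dict(
            field_id=str(pos["field_id"].iloc[i]),
            transect=int(pos["transect"].iloc[i]),
            lat=float(pos["lat"].iloc[i]),
            lon=float(pos["lon"].iloc[i]),
            altitude_m=float(altitude[i]),
            monthly_precip_mm=tuple(float(v) for v in monthly[i]),
            mean_temp_C=float(temp[i]),
            no3_ppm=float(no3_vals[i]) if no3_flags[i] else None,
        )
        for year, crop_main, variety, comp, prev1, prev2, latent in (
            (
                config.year_first, s2[0], varieties2[i], comps2[i],
                s1[0], None, latent1[i],
            ),
            (
                config.year_second, s3[0], varieties3[i], comps3[i],
                s2_prev_label, s1[0], latent2[i],
            ),
        ):
            is_host = registry.is_cereal(crop_main)
            obs_latent = latent if is_host else latent - config.nonhost_latent_penalty
            quadrats = []
            for q in range(config.quadrats_per_field):
                qlat = obs_latent + rng.normal(0.0, config.quadrat_sd)
                state = discretize_density(qlat, config.state_thresholds)
                quadrats.append(
                    QuadratRecord(
                        field_id=base["field_id"],
                        quadrat_index=q + 1,
                        density=state,
                        crop_height_cm=float(
                            np.clip(rng.normal(90.0, 15.0), 10.0, 250.0)
                        ),
                        crop_cover_pct=float(np.clip(rng.normal(60.0, 15.0), 0, 100)),
                        other_weed_cover_pct=float(
                            np.clip(rng.normal(20.0, 10.0), 0, 100)
                        ),
                    )
                )
            fields.append(
                FieldRecord(
                    year=year,
                    crop=crop_main,
                    rice_variety=variety,
                    companion_crop=comp,
                    prev_crop_1=prev1,
                    prev_crop_2=prev2,
                    quadrats=quadrats,
                    **base,
                )
            )
            ind = indicators[i]
            truth_rows.append(
                {
                    "field_id": base["field_id"],
                    "year": year,
                    "latent_log_density": float(latent),
                    "score": float(scores[i]),
                    "fallow_included": ind.fallow_included,
                    "cereal_years": ind.cereal_years,
                    "legume_years": ind.legume_years,
                    "crop_diversity": ind.crop_diversity,
                    "is_host_crop": bool(is_host),
                    "precip_cv_pct": float(cv[i]),
                    "altitude_m": float(altitude[i]),
                    "mean_temp_C": float(temp[i]),
                    "mean_annual_precip_mm": float(annual[i]),
                }
            )

    dataset = SurveyDataset(
        fields,
        provenance=f"synthetic landscape (seed={config.seed}, n={config.n_fields})",
    )
    return dataset, pd.DataFrame(truth_rows)


def generate_indicator_table(
    n: int,
    effects: ScoreCoefficients = DEFAULT_COEFFICIENTS,
    sigma: float = 0.4,
    intercept: float = 2.0,
    seed: int = 0,
    config: SyntheticConfig | None = None,
    registry: CropRegistry = DEFAULT_REGISTRY,
) -> pd.DataFrame:
    """Indicator table with density generated from known indicator effects.

    Rotations are sampled from the configured transition process,
    indicators extracted, and ``log_density = intercept + effects .
    indicators + N(0, sigma)``. Used to validate coefficient recovery by
    :func:`strigasurvey.management_score.fit_score_coefficients`.
    """
    cfg = config if config is not None else SyntheticConfig()
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        rot, c2, c3 = sample_rotation(rng, cfg, f"S{i:04d}")
        s1, s2, s3 = rot.seasons
        variety = _assign_variety(rng, cfg) if s3[0] == "rice" else None
        s3_main = f"{s3[0]}-{variety}" if variety else s3[0]
        score_rot = RotationSequence(
            field_id=rot.field_id,
            seasons=[
                (s1[0], None),
                (s2[0] if c2 is None else f"{s2[0]}/{c2}", None),
                (s3_main, c3),
            ],
        )
        ind = extract_indicators(score_rot, registry)
        rows.append({"field_id": rot.field_id, **ind.__dict__})
    df = pd.DataFrame(rows)
    X = df[["fallow_included", "cereal_years", "legume_years", "crop_diversity"]]
    df["log_density"] = (
        intercept
        + X.to_numpy(dtype=float) @ effects.as_array()
        + rng.normal(0.0, sigma, n)
    )
    return df
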