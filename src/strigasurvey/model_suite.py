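"""Predictor battery: sequential (type I) ANOVA on log-transformed density.

Each candidate predictor of *Striga* density is tested in its own linear
model of log(x+1) field mean density with three terms fitted and tested
sequentially: survey ``year`` first, the predictor (``effect``) second,
and the ``year x effect`` interaction last — the interaction enters last
to respect marginality. Type I (sequential) sums of squares are used:
each term's SS is the drop in residual SS when the term joins a model
already containing all earlier terms. F statistics divide each term's
mean square by the residual mean square of the full model.

Strongly collinear climate predictors are screened with a two-predictor
variance inflation factor and fitted in separate models, never jointly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnovaRow",
    "CollinearityResult",
    "GroupSummary",
    "PredictorSpec",
    "log1p_density",
    "sequential_anova",
    "run_predictor_battery",
    "vif_two_predictor",
    "group_summaries",
    "DEFAULT_PREDICTORS",
]

logger = logging.getLogger(__name__)

TERM_ORDER = ("year", "effect", "year_x_effect")


@dataclass(frozen=True)
class AnovaRow:
    """One term of the sequential decomposition (Year -> Effect -> Year x Effect)."""

    term: str
    ss: float
    F: float
    df: tuple[int, int]  # (numerator, residual of the full model)
    p: float


@dataclass(frozen=True)
class CollinearityResult:
    r_squared: float
    vif: float


@dataclass(frozen=True)
class GroupSummary:
    level: str
    n: int
    mean_log_density: float
    se: float


@dataclass(frozen=True)
class PredictorSpec:
    """One battery entry: display name, source column, and variable kind."""

    name: str
    column: str
    kind: Literal["categorical", "continuous"] = "categorical"


def log1p_density(mean_density) -> float | np.ndarray:
    """Natural log of (density + 1); the transform used for all responses."""
    arr = np.asarray(mean_density, dtype=float)
    if np.any(arr < 0):
        raise ValueError("density must be non-negative")
    out = np.log1p(arr)
    return float(out) if np.isscalar(mean_density) or out.ndim == 0 else out


def _dummies(values: np.ndarray) -> np.ndarray:
    """Treatment-coded dummy columns (first level is the reference)."""
    levels = pd.unique(values)
    cols = [np.asarray(values == lev, dtype=float) for lev in levels[1:]]
    return np.column_stack(cols) if cols else np.empty((len(values), 0))


def _rss(design: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Residual sum of squares and rank of a least-squares fit."""
    beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return float(resid @ resid), int(rank)


def sequential_anova(
    response: Sequence[float],
    year: Sequence,
    effect: Sequence,
    effect_kind: Literal["categorical", "continuous", "auto"] = "auto",
) -> list[AnovaRow]:
    """Type I decomposition fitting year first, effect second, interaction last.

    ``year`` is always treated as a factor. ``effect`` is treated as a
    factor unless numeric (or ``effect_kind`` overrides). Degrees of
    freedom come from design-matrix rank increments, so aliased levels
    are handled consistently; a saturated model (zero residual df) or a
    single-level year factor raises.
    """
    y = np.asarray(response, dtype=float)
    year_arr = np.asarray(year)
    eff_arr = np.asarray(effect)
    if not (len(y) == len(year_arr) == len(eff_arr)):
        raise ValueError("response, year and effect must be the same length")
    n = len(y)

    if len(pd.unique(year_arr)) < 2:
        raise ValueError("year factor must have at least 2 levels")
    if effect_kind == "auto":
        effect_kind = (
            "continuous"
            if np.issubdtype(eff_arr.dtype, np.number)
            else "categorical"
        )
    if effect_kind == "categorical" and len(pd.unique(eff_arr)) < 2:
        raise ValueError("effect factor must have at least 2 levels")

    X_year = _dummies(year_arr)
    if effect_kind == "categorical":
        X_eff = _dummies(eff_arr)
    else:
        X_eff = np.asarray(eff_arr, dtype=float).reshape(-1, 1)
    # interaction: every year dummy crossed with every effect column
    X_int = np.column_stack(
        [X_year[:, i] * X_eff[:, j]
         for i in range(X_year.shape[1]) for j in range(X_eff.shape[1])]
    ) if X_year.size and X_eff.size else np.empty((n, 0))

    intercept = np.ones((n, 1))
    designs = [
        intercept,
        np.column_stack([intercept, X_year]),
        np.column_stack([intercept, X_year, X_eff]),
        np.column_stack([intercept, X_year, X_eff, X_int]),
    ]
    rss, ranks = zip(*(_rss(d, y) for d in designs))
    df_resid = n - ranks[-1]
    if df_resid <= 0:
        raise ValueError("saturated model: no residual degrees of freedom")
    mse = rss[-1] / df_resid

    rows: list[AnovaRow] = []
    for k, term in enumerate(TERM_ORDER):
        delta_ss = rss[k] - rss[k + 1]
        delta_df = ranks[k + 1] - ranks[k]
        if delta_df == 0:
            rows.append(AnovaRow(term, 0.0, np.nan, (0, df_resid), np.nan))
            continue
        F = (delta_ss / delta_df) / mse if mse > 0 else np.inf
        p = float(stats.f.sf(F, delta_df, df_resid)) if np.isfinite(F) else 0.0
        rows.append(AnovaRow(term, float(delta_ss), float(F), (delta_df, df_resid), p))
    return rows


#: The battery reported for the Madagascar survey: management variables
#: first, ecological variables second.
DEFAULT_PREDICTORS = [
    PredictorSpec("rice variety", "rice_variety", "categorical"),
    PredictorSpec("previous crop", "prev_crop_1", "categorical"),
    PredictorSpec("companion crop", "companion_crop", "categorical"),
    PredictorSpec("previous legume", "prev_legume", "categorical"),
    PredictorSpec("neighbor density", "neighbor_mean_density", "continuous"),
    PredictorSpec("mean rainfall", "mean_annual_precip_mm", "continuous"),
    PredictorSpec("precipitation seasonality", "precip_cv_pct", "continuous"),
    PredictorSpec("altitude", "altitude_m", "continuous"),
    PredictorSpec("mean temperature", "mean_temp_C", "continuous"),
    PredictorSpec("NO3", "no3_ppm", "continuous"),
    PredictorSpec("other weed cover", "other_weed_cover_pct", "continuous"),
]


def run_predictor_battery(
    field_table: pd.DataFrame,
    predictors: Sequence[PredictorSpec] = tuple(DEFAULT_PREDICTORS),
    response: str = "mean_density",
) -> pd.DataFrame:
    """One sequential-ANOVA model per predictor on log1p field mean density.

    Every predictor gets its own model — correlated predictors are never
    fitted jointly. Rows with a missing value for a given predictor are
    dropped from that predictor's model only, so per-model n (and hence
    residual df) varies across the battery, as in surveys where some
    covariates are measured on subsets of fields. Predictors with fewer
    than 2 observed levels are skipped with a logged warning.

    Returns a tidy table with columns
    ``predictor, term, ss, F, df_num, df_den, p, n``.
    """
    out_rows = []
    for spec in predictors:
        if spec.column not in field_table.columns:
            logger.warning("predictor %r: column %r absent; skipped",
                           spec.name, spec.column)
            continue
        sub = field_table[["year", spec.column, response]].dropna()
        if spec.kind == "categorical":
            n_levels = sub[spec.column].nunique()
        else:
            n_levels = sub[spec.column].astype(float).nunique()
        if len(sub) < 4 or n_levels < 2:
            logger.warning(
                "predictor %r: <2 observed levels or too few rows; skipped",
                spec.name,
            )
            continue
        try:
            rows = sequential_anova(
                log1p_density(sub[response].to_numpy()),
                sub["year"].to_numpy(),
                sub[spec.column].to_numpy(),
                effect_kind=spec.kind,
            )
        except ValueError as exc:
            logger.warning("predictor %r: %s; skipped", spec.name, exc)
            continue
        for row in rows:
            out_rows.append(
                {
                    "predictor": spec.name,
                    "term": row.term,
                    "ss": row.ss,
                    "F": row.F,
                    "df_num": row.df[0],
                    "df_den": row.df[1],
                    "p": row.p,
                    "n": len(sub),
                }
            )
    return pd.DataFrame(
        out_rows,
        columns=["predictor", "term", "ss", "F", "df_num", "df_den", "p", "n"],
    )


def vif_two_predictor(x1: Sequence[float], x2: Sequence[float]) -> CollinearityResult:
    """Variance inflation factor between two continuous predictors.

    R^2 from the OLS of ``x1`` on ``x2`` (symmetric for two variables);
    VIF = 1 / (1 - R^2).
    """
    a = np.asarray(x1, dtype=float)
    b = np.asarray(x2, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant predictor; collinearity undefined")
    r = float(np.corrcoef(a, b)[0, 1])
    r2 = r * r
    vif = np.inf if r2 >= 1.0 else 1.0 / (1.0 - r2)
    return CollinearityResult(r_squared=r2, vif=float(vif))


def group_summaries(
    field_table: pd.DataFrame,
    grouping: str,
    response: str = "mean_density",
    singleton_se: float = 0.0,
) -> list[GroupSummary]:
    """Per-level n, mean log1p density and standard error, sorted by mean.

    Levels observed once report ``singleton_se`` (default 0.0) instead of
    a propagating NaN.
    """
    if grouping not in field_table.columns:
        raise ValueError(f"grouping column {grouping!r} not present")
    sub = field_table[[grouping, response]].dropna()
    out: list[GroupSummary] = []
    for level, grp in sub.groupby(grouping, sort=False):
        vals = log1p_density(grp[response].to_numpy())
        vals = np.atleast_1d(vals)
        n = len(vals)
        se = float(np.std(vals, ddof=1) / np.sqrt(n)) if n > 1 else singleton_se
        out.append(GroupSummary(str(level), n, float(np.mean(vals)), se))
    return sorted(out, key=lambda g: g.mean_log_density)
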