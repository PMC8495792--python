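"""End-to-end survey analysis runs: simulate/load -> covariates ->
predictor battery -> rotation matrix -> management scores -> change
regression, with a machine-readable manifest for reproducibility.

Every dropped field is logged with a reason code (``unmatched``,
``non-cereal``, ``missing predictor``) so a run documents its own
exclusions the way a survey report would.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .covariates import augment_field_frame
from .crops import DEFAULT_REGISTRY, CropRegistry
from .management_score import (
    DEFAULT_COEFFICIENTS,
    composite_score,
    extract_indicators,
    fit_score_coefficients,
    score_change_regression,
)
from .model_suite import (
    DEFAULT_PREDICTORS,
    PredictorSpec,
    log1p_density,
    run_predictor_battery,
)
from .rotation import RotationSequence, build_transition_matrix
from .survey_io import (
    SurveyDataset,
    change_in_density,
    link_years,
    read_survey_csv,
    write_survey_csv,
)
from .synthetic_landscape import SyntheticConfig, generate_landscape

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "rotations_from_dataset"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """A fully serialisable description of one pipeline run."""

    out_dir: str | Path = "strigasurvey_run"
    survey_csv: Optional[str | Path] = None  # load this instead of simulating
    synthetic: Optional[SyntheticConfig] = None  # defaults applied if both None
    predictors: Sequence[PredictorSpec] = tuple(DEFAULT_PREDICTORS)
    refit_coefficients: bool = False  # refit score weights on the run's own data
    seed: int = 0
    log_level: str = "INFO"


def parse_predictors(entries) -> list[PredictorSpec]:
    """Validate a predictor spec list (e.g. loaded from YAML)."""
    out = []
    for i, entry in enumerate(entries):
        if isinstance(entry, PredictorSpec):
            out.append(entry)
            continue
        if not isinstance(entry, dict) or "name" not in entry or "column" not in entry:
            raise ValueError(
                f"malformed predictor spec entry #{i}: {entry!r} "
                "(need keys: name, column[, kind])"
            )
        kind = entry.get("kind", "categorical")
        if kind not in ("categorical", "continuous"):
            raise ValueError(
                f"malformed predictor spec entry #{i} ({entry['name']!r}): "
                f"kind must be 'categorical' or 'continuous', got {kind!r}"
            )
        out.append(PredictorSpec(entry["name"], entry["column"], kind))
    return out


def rotations_from_dataset(
    dataset: SurveyDataset,
) -> list[RotationSequence]:
    """One rotation per field from its most recent record's crop history."""
    latest: dict[str, object] = {}
    for f in dataset.fields:
        if f.field_id not in latest or f.year > latest[f.field_id].year:
            latest[f.field_id] = f
    rotations = []
    for f in latest.values():
        seasons = f.season_labels()
        if len(seasons) >= 2:
            rotations.append(RotationSequence(field_id=f.field_id, seasons=seasons))
    return rotations


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write all outputs under ``out_dir``.

    Outputs: ``survey.csv`` (the input data, canonical layout),
    ``survey_covariates.csv`` (field-level table with climate/spatial
    covariates), ``battery.csv`` (sequential-ANOVA battery),
    ``transition_matrix.csv``, ``scores.csv`` (per-field indicators and
    composite score), ``score_regression.json`` (change-in-density
    regression, when two years are present), ``truth.csv`` (synthetic
    runs only) and ``manifest.json``. Returns the manifest dict.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    registry = DEFAULT_REGISTRY
    outputs: dict[str, Path] = {}

    # --- acquire -----------------------------------------------------
    stage = "acquire"
    try:
        predictors = parse_predictors(config.predictors)
        if config.survey_csv is not None:
            dataset = read_survey_csv(config.survey_csv, registry)
            truth = None
            for issue in dataset.validation_issues:
                logger.warning("validation: %s", issue)
        else:
            syn = config.synthetic or SyntheticConfig()
            syn = replace(syn, seed=config.seed)
            dataset, truth = generate_landscape(syn, registry)
        write_survey_csv(dataset, out / "survey.csv")
        outputs["survey"] = out / "survey.csv"
        if truth is not None:
            truth.to_csv(out / "truth.csv", index=False)
            outputs["truth"] = out / "truth.csv"
    except (ValueError, OSError) as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- covariates --------------------------------------------------
    stage = "covariates"
    try:
        field_table = augment_field_frame(dataset)
        field_table["prev_legume"] = [
            (
                "legume"
                if isinstance(v, str) and v and registry.is_legume(v)
                else "non-legume"
            )
            for v in field_table["prev_crop_1"].fillna("")
        ]
        field_table.to_csv(out / "survey_covariates.csv", index=False)
        outputs["covariates"] = out / "survey_covariates.csv"
    except ValueError as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- battery -----------------------------------------------------
    stage = "battery"
    try:
        host = field_table[field_table["is_cereal"] & field_table["mean_density"].notna()]
        dropped = set(field_table["field_id"]) - set(host["field_id"])
        for fid in sorted(dropped):
            logger.info("battery: field %s dropped (non-cereal)", fid)
        battery = run_predictor_battery(host, predictors)
        battery.to_csv(out / "battery.csv", index=False)
        outputs["battery"] = out / "battery.csv"
    except ValueError as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- rotation matrix ---------------------------------------------
    stage = "rotation"
    try:
        rotations = rotations_from_dataset(dataset)
        matrix = build_transition_matrix(rotations)
        matrix.to_csv(out / "transition_matrix.csv")
        outputs["rotation"] = out / "transition_matrix.csv"
    except ValueError as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- management scores -------------------------------------------
    stage = "score"
    regression_summary: Optional[dict] = None
    try:
        scorable = [r for r in rotations if len(r.seasons) == 3]
        rows = []
        for rot in scorable:
            try:
                ind = extract_indicators(rot, registry)
            except ValueError as exc:
                logger.warning("score: field %s skipped (%s)", rot.field_id, exc)
                continue
            rows.append({"field_id": rot.field_id, **ind.__dict__})
        scores_df = pd.DataFrame(rows)

        coef = DEFAULT_COEFFICIENTS
        years = dataset.years()
        if config.refit_coefficients and not scores_df.empty:
            train = scores_df.merge(
                field_table[field_table["is_cereal"]][
                    ["field_id", "year", "mean_density"]
                ],
                on="field_id",
            ).dropna(subset=["mean_density"])
            train["log_density"] = log1p_density(train["mean_density"].to_numpy())
            coef = fit_score_coefficients(train)
            logger.info("score: refitted coefficients %s", coef)

        if not scores_df.empty:
            scores_df["composite_score"] = [
                composite_score(
                    extract_indicators(rot, registry), coef
                )
                for rot in scorable
            ]
        scores_df.to_csv(out / "scores.csv", index=False)
        outputs["scores"] = out / "scores.csv"

        if len(years) >= 2 and not scores_df.empty:
            linked = link_years(
                dataset.for_year(years[0]), dataset.for_year(years[-1]), registry
            )
            for row in linked.exclusions.itertuples(index=False):
                logger.info(
                    "score: field %s excluded from pairing (%s)",
                    row.field_id,
                    row.reason,
                )
            deltas = change_in_density(linked).merge(scores_df, on="field_id")
            if len(deltas) >= 3 and deltas["composite_score"].nunique() > 1:
                res = score_change_regression(
                    deltas["composite_score"], deltas["delta"]
                )
                regression_summary = {
                    "slope": res.slope,
                    "intercept": res.intercept,
                    "F": res.F,
                    "df": list(res.df),
                    "p": res.p,
                    "n": res.n,
                    "slope_se": res.slope_se,
                }
                (out / "score_regression.json").write_text(
                    json.dumps(regression_summary, indent=2)
                )
                outputs["score_regression"] = out / "score_regression.json"
            else:
                logger.warning(
                    "score: too few paired fields for the change regression"
                )
        else:
            logger.warning(
                "score: only one survey year present; "
                "change-in-density regression skipped"
            )
    except ValueError as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- manifest ----------------------------------------------------
    manifest = {
        "strigasurvey_version": __version__,
        "seed": config.seed,
        "n_fields": len({f.field_id for f in dataset.fields}),
        "years": dataset.years(),
        "score_regression": regression_summary,
        "outputs": {name: _sha256(path) for name, path in outputs.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
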