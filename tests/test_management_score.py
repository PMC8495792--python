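"""Management indicators, composite score, and the change regression."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from strigasurvey.management_score import (
    DEFAULT_COEFFICIENTS,
    INDICATOR_NAMES,
    ManagementIndicators,
    ScoreCoefficients,
    composite_score,
    extract_indicators,
    fit_score_coefficients,
    score_change_regression,
)
from strigasurvey.rotation import RotationSequence
from strigasurvey.synthetic_landscape import generate_indicator_table


def seasons(*entries):
    """Each entry is a main crop or a (main, companion) tuple."""
    out = []
    for e in entries:
        out.append(e if isinstance(e, tuple) else (e, None))
    return out


class TestExtractIndicators:
    def test_cereal_rotation_with_legume_companion(self):
        rot = RotationSequence(
            "F1",
            seasons("rice-B22", ("maize", "groundnut"), "rice-NERICA4"),
        )
        ind = extract_indicators(rot)
        assert ind == ManagementIndicators(0, 3, 1, 4)

    def test_fallow_counts_in_rotation_and_diversity(self):
        rot = RotationSequence("F1", seasons("fallow", "rice-B22", "maize"))
        ind = extract_indicators(rot)
        assert ind == ManagementIndicators(1, 2, 0, 3)

    def test_monoculture_degenerate(self):
        rot = RotationSequence("F1", seasons("rice-B22", "rice-B22", "rice-B22"))
        ind = extract_indicators(rot)
        assert ind == ManagementIndicators(0, 3, 0, 1)

    def test_distinct_rice_varieties_are_distinct_crops(self):
        rot = RotationSequence("F1", seasons("rice-B22", "rice-NERICA4", "maize"))
        assert extract_indicators(rot).crop_diversity == 3

    def test_mixed_labels_decomposed_for_diversity(self):
        rot = RotationSequence("F1", seasons("maize/manioc", "rice", "maize"))
        ind = extract_indicators(rot)
        assert ind.crop_diversity == 3
        assert ind.cereal_years == 3  # maize/manioc season counts as cereal

    def test_mimosa_counts_as_legume(self):
        rot = RotationSequence("F1", seasons("rice", ("maize", "mimosa"), "maize"))
        assert extract_indicators(rot).legume_years == 1

    def test_unknown_crop_listed_in_error(self):
        rot = RotationSequence("F1", seasons("rice", "quinoa", "maize"))
        with pytest.raises(ValueError, match="quinoa"):
            extract_indicators(rot)

    def test_two_season_rotation_rejected_for_scoring(self):
        rot = RotationSequence("F1", seasons("rice", "maize"))
        with pytest.raises(ValueError, match="3 seasons"):
            extract_indicators(rot)


class TestCompositeScore:
    @pytest.mark.parametrize(
        "indicators, expected",
        [
            ((0, 2, 1, 3), -1.33645),
            ((1, 2, 2, 4), -2.16626),
            ((1, 2, 1, 4), -1.80114),
            ((0, 3, 0, 2), -0.79977),
        ],
    )
    def test_reference_worked_examples(self, indicators, expected):
        ind = ManagementIndicators(*indicators)
        assert composite_score(ind, DEFAULT_COEFFICIENTS) == pytest.approx(
            expected, abs=5e-6
        )

    def test_linearity_in_indicators(self):
        a = ManagementIndicators(0, 1, 0, 1)
        b = ManagementIndicators(0, 1, 1, 1)
        ab = ManagementIndicators(0, 2, 1, 2)
        assert composite_score(a) + composite_score(b) == pytest.approx(
            composite_score(ab), abs=1e-12
        )

    def test_intercept_never_scored(self):
        coef = ScoreCoefficients(-0.2, -0.1, -0.3, -0.25, intercept=99.0)
        ind = ManagementIndicators(1, 2, 1, 3)
        assert composite_score(ind, coef) == pytest.approx(
            -0.2 - 0.2 - 0.3 - 0.75, abs=1e-12
        )

    def test_monotone_decreasing_in_each_indicator_with_defaults(self):
        base = ManagementIndicators(0, 2, 1, 3)
        s0 = composite_score(base)
        for bump in [(1, 2, 1, 3), (0, 3, 1, 3), (0, 2, 2, 3), (0, 2, 1, 4)]:
            assert composite_score(ManagementIndicators(*bump)) < s0

    def test_nonfinite_coefficients_rejected(self):
        coef = ScoreCoefficients(np.nan, -0.1, -0.3, -0.25)
        with pytest.raises(ValueError, match="finite"):
            composite_score(ManagementIndicators(0, 2, 1, 3), coef)


class TestFitScoreCoefficients:
    def test_noiseless_recovery(self, rng):
        n = 60
        df = pd.DataFrame(
            {
                "fallow_included": rng.integers(0, 2, n),
                "cereal_years": rng.integers(1, 4, n),
                "legume_years": rng.integers(0, 4, n),
                "crop_diversity": rng.integers(1, 6, n),
            }
        )
        df["log_density"] = 1.0 - 0.3 * df["legume_years"]
        coef = fit_score_coefficients(df)
        assert coef.legume_years == pytest.approx(-0.3, abs=1e-9)
        assert coef.fallow == pytest.approx(0.0, abs=1e-9)
        assert coef.intercept == pytest.approx(1.0, abs=1e-9)

    def test_row_permutation_invariance(self):
        df = generate_indicator_table(n=200, sigma=0.4, seed=7)
        coef1 = fit_score_coefficients(df)
        coef2 = fit_score_coefficients(df.sample(frac=1.0, random_state=0))
        assert coef1.as_array() == pytest.approx(coef2.as_array(), rel=1e-9)

    def test_rank_deficiency_names_offenders(self, rng):
        n = 30
        df = pd.DataFrame(
            {
                "fallow_included": np.ones(n, dtype=int),  # constant
                "cereal_years": rng.integers(1, 4, n),
                "legume_years": rng.integers(0, 4, n),
                "crop_diversity": rng.integers(1, 6, n),
            }
        )
        df["log_density"] = rng.normal(size=n)
        with pytest.raises(ValueError, match="fallow_included"):
            fit_score_coefficients(df)

    def test_estimates_within_two_se_of_truth(self):
        """Monte-Carlo: at n=400, sigma=0.4, each coefficient lies within
        2 SE of truth at the nominal ~95% rate. The pass mark (180/200)
        is the 99.9% binomial lower bound for a true coverage of 95%."""
        truth = ScoreCoefficients(-0.2, -0.09, -0.37, -0.26)
        hits = np.zeros(4, dtype=int)
        reps = 200
        for rep in range(reps):
            df = generate_indicator_table(
                n=400, effects=truth, sigma=0.4, seed=1000 + rep
            )
            coef = fit_score_coefficients(df)
            # independent SE oracle
            X = sm.add_constant(df[INDICATOR_NAMES].to_numpy(dtype=float))
            ses = sm.OLS(df["log_density"].to_numpy(), X).fit().bse[1:]
            hits += (
                np.abs(coef.as_array() - truth.as_array()) <= 2.0 * ses
            ).astype(int)
        assert (hits >= 180).all(), hits

    def test_fitted_values_equal_score_plus_intercept(self):
        df = generate_indicator_table(n=150, sigma=0.3, seed=3)
        coef = fit_score_coefficients(df)
        scores = df[INDICATOR_NAMES].to_numpy(dtype=float) @ coef.as_array()
        X = sm.add_constant(df[INDICATOR_NAMES].to_numpy(dtype=float))
        fitted = sm.OLS(df["log_density"].to_numpy(), X).fit().fittedvalues
        assert scores == pytest.approx(fitted - coef.intercept, abs=1e-9)


class TestScoreChangeRegression:
    def test_perfect_linear_fit(self):
        scores = np.array([-2.0, -1.5, -1.0, -0.5, 0.0])
        deltas = 2.0 * scores + 1.0
        res = score_change_regression(scores, deltas)
        assert res.slope == pytest.approx(2.0, abs=1e-12)
        assert res.intercept == pytest.approx(1.0, abs=1e-12)
        assert res.df == (1, 3)
        assert res.p < 1e-10

    def test_duplicating_rows_keeps_slope(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=20)
        deltas = -0.4 * scores + rng.normal(scale=0.5, size=20)
        r1 = score_change_regression(scores, deltas)
        r2 = score_change_regression(
            np.concatenate([scores, scores]), np.concatenate([deltas, deltas])
        )
        assert r2.slope == pytest.approx(r1.slope, rel=1e-12)
        assert r2.n == 2 * r1.n
        assert r2.df == (1, 2 * r1.n - 2)

    def test_constant_score_error(self):
        with pytest.raises(ValueError, match="constant"):
            score_change_regression([1.0, 1.0, 1.0], [0.1, 0.2, 0.3])

    def test_null_type_one_error_rate(self):
        """Under independence the slope test rejects at ~5%."""
        rng = np.random.default_rng(2024)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            scores = rng.normal(size=30)
            deltas = rng.normal(size=30)
            if score_change_regression(scores, deltas).p < 0.05:
                rejections += 1
        assert 0.035 <= rejections / reps <= 0.065
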