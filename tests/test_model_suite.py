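"""Sequential (type I) ANOVA, VIF screening and group summaries."""

import numpy as np
import pandas as pd
import pytest

from strigasurvey.model_suite import (
    GroupSummary,
    PredictorSpec,
    group_summaries,
    log1p_density,
    run_predictor_battery,
    sequential_anova,
    vif_two_predictor,
)


class TestLog1p:
    def test_closed_forms(self):
        assert log1p_density(0.0) == 0.0
        assert log1p_density(np.e - 1.0) == pytest.approx(1.0, rel=1e-12)

    def test_monotone(self, rng):
        x = np.sort(rng.uniform(0, 5, 50))
        y = log1p_density(x)
        assert np.all(np.diff(y) > 0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            log1p_density(-0.1)


def _nested_rss(y, *design_blocks):
    """Independent oracle: residual SS of an incremental least-squares fit."""
    n = len(y)
    X = np.ones((n, 1))
    out = []
    for block in design_blocks:
        X = np.column_stack([X, block]) if block.size else X
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        out.append(float(resid @ resid))
    return out


class TestSequentialAnova:
    def test_term_order_fixed(self, rng):
        rows = sequential_anova(
            rng.normal(size=24),
            np.repeat([2019, 2020], 12),
            np.tile(["a", "b", "c"], 8),
        )
        assert [r.term for r in rows] == ["year", "effect", "year_x_effect"]

    def test_balanced_design_is_order_invariant(self, rng):
        # in a balanced crossed design the factors are orthogonal, so the
        # sequential SS of a term does not depend on entry order
        year = np.repeat([2019, 2020], 12)
        effect = np.tile(np.repeat(["a", "b", "c"], 4), 2)
        y = rng.normal(size=24)
        first = sequential_anova(y, year, effect)
        swapped = sequential_anova(y, effect, year)  # effect fitted first
        assert first[1].ss == pytest.approx(swapped[0].ss, abs=1e-8)
        assert first[0].ss == pytest.approx(swapped[1].ss, abs=1e-8)
        assert first[2].ss == pytest.approx(swapped[2].ss, abs=1e-8)

    def test_ss_conservation(self, rng):
        for _ in range(20):
            n = int(rng.integers(12, 40))
            year = rng.choice([2019, 2020], size=n)
            if len(np.unique(year)) < 2:
                continue
            effect = rng.choice(["a", "b", "c"], size=n)
            y = rng.normal(size=n)
            rows = sequential_anova(y, year, effect)
            tss = float(np.sum((y - y.mean()) ** 2))
            # residual SS from an independent full-model fit
            dummies = pd.get_dummies(pd.DataFrame({"y_": year, "e_": effect}),
                                     columns=["y_", "e_"], drop_first=True)
            inter = np.einsum(
                "ni,nj->nij",
                dummies.filter(like="y_").to_numpy(float),
                dummies.filter(like="e_").to_numpy(float),
            ).reshape(n, -1)
            X = np.column_stack([np.ones(n), dummies.to_numpy(float), inter])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            rss = float(np.sum((y - X @ beta) ** 2))
            assert sum(r.ss for r in rows) + rss == pytest.approx(tss, abs=1e-8)

    def test_continuous_effect_uses_one_df(self, rng):
        rows = sequential_anova(
            rng.normal(size=30),
            rng.choice([2019, 2020], size=30),
            rng.normal(size=30),
        )
        assert rows[1].df[0] == 1
        assert rows[2].df[0] == 1

    def test_interaction_tested_last_against_full_residual(self, rng):
        n = 36
        year = np.repeat([2019, 2020], n // 2)
        effect = rng.normal(size=n)
        y = rng.normal(size=n)
        rows = sequential_anova(y, year, effect)
        # residual df: n - (1 intercept + 1 year + 1 slope + 1 interaction)
        assert all(r.df[1] == n - 4 for r in rows)

    def test_single_level_year_rejected(self, rng):
        with pytest.raises(ValueError, match="2 levels"):
            sequential_anova(
                rng.normal(size=10), np.full(10, 2019), rng.normal(size=10)
            )

    def test_saturated_model_rejected(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        with pytest.raises(ValueError, match="saturated"):
            sequential_anova(y, ["a", "a", "b", "b"], ["x", "y", "x", "y"])


class TestVif:
    def test_orthogonal_vectors(self):
        u = np.array([1.0, -1.0, 1.0, -1.0])
        v = np.array([1.0, 1.0, -1.0, -1.0])
        res = vif_two_predictor(u, v)
        assert res.vif == pytest.approx(1.0, abs=1e-12)

    def test_known_r_squared(self):
        u = np.array([1.0, -1.0, 1.0, -1.0])
        v = np.array([1.0, 1.0, -1.0, -1.0])
        x2 = np.sqrt(3.0) * u + v  # corr(u, x2) = sqrt(3)/2, R^2 = 0.75
        res = vif_two_predictor(u, x2)
        assert res.r_squared == pytest.approx(0.75, abs=1e-12)
        assert res.vif == pytest.approx(4.0, abs=1e-9)

    def test_near_singularity(self, rng):
        x1 = rng.normal(size=100)
        x2 = x1 + rng.normal(scale=1e-3, size=100)
        assert vif_two_predictor(x1, x2).vif > 100

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            vif_two_predictor([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestBattery:
    def _table(self, rng, n=60):
        return pd.DataFrame(
            {
                "year": rng.choice([2019, 2020], size=n),
                "mean_density": rng.uniform(0, 5, size=n),
                "variety": rng.choice(["a", "b", "c"], size=n),
                "altitude_m": rng.uniform(700, 1000, size=n),
                "no3_ppm": np.where(
                    rng.random(n) < 0.5, rng.uniform(10, 50, n), np.nan
                ),
            }
        )

    def test_one_row_triple_per_predictor(self, rng):
        table = self._table(rng)
        specs = [
            PredictorSpec("variety", "variety", "categorical"),
            PredictorSpec("altitude", "altitude_m", "continuous"),
        ]
        out = run_predictor_battery(table, specs)
        assert len(out) == 6
        assert list(out["predictor"].unique()) == ["variety", "altitude"]
        assert list(out[out["predictor"] == "variety"]["term"]) == [
            "year", "effect", "year_x_effect",
        ]

    def test_missing_values_dropped_per_model_only(self, rng):
        table = self._table(rng)
        specs = [
            PredictorSpec("altitude", "altitude_m", "continuous"),
            PredictorSpec("NO3", "no3_ppm", "continuous"),
        ]
        out = run_predictor_battery(table, specs)
        n_alt = out[out["predictor"] == "altitude"]["n"].iloc[0]
        n_no3 = out[out["predictor"] == "NO3"]["n"].iloc[0]
        assert n_alt == len(table)
        assert n_no3 == table["no3_ppm"].notna().sum()
        # residual df tracks the per-model n
        assert (out[out["predictor"] == "NO3"]["df_den"] == n_no3 - 4).all()

    def test_degenerate_predictor_skipped_not_fatal(self, rng):
        table = self._table(rng)
        table["constant"] = "only-level"
        specs = [
            PredictorSpec("constant", "constant", "categorical"),
            PredictorSpec("altitude", "altitude_m", "continuous"),
        ]
        out = run_predictor_battery(table, specs)
        assert set(out["predictor"]) == {"altitude"}


class TestGroupSummaries:
    def test_direct_computation(self):
        table = pd.DataFrame(
            {"level": ["A", "A", "B"], "mean_density": [0.0, 2.0, 4.0]}
        )
        out = group_summaries(table, "level")
        by = {g.level: g for g in out}
        assert by["A"].mean_log_density == pytest.approx(
            (np.log(1.0) + np.log(3.0)) / 2.0
        )
        assert by["A"].n == 2
        assert by["B"].n == 1
        assert by["B"].se == 0.0  # singleton level: configured value, not NaN

    def test_sorted_by_mean_and_order_stable_under_shift(self, rng):
        dens = rng.uniform(0, 4, 30)
        table = pd.DataFrame(
            {"level": rng.choice(["A", "B", "C"], 30), "mean_density": dens}
        )
        out1 = [g.level for g in group_summaries(table, "level")]
        table2 = table.assign(mean_density=table["mean_density"] + 1.0)
        out2 = [g.level for g in group_summaries(table2, "level")]
        assert out1 == out2
        means = [g.mean_log_density for g in group_summaries(table, "level")]
        assert means == sorted(means)

    def test_missing_grouping_column(self):
        with pytest.raises(ValueError, match="variety"):
            group_summaries(pd.DataFrame({"mean_density": [1.0]}), "variety")
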