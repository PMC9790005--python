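"""Cross-tabs, marginals, group tests and restricted OLS contrasts."""

import numpy as np
import pandas as pd
import pytest

from epimobility import (
    CLASS_LEVELS,
    GeneratorConfig,
    ValidationError,
    crosstab_means,
    generate_cohort,
    group_tests,
    marginal_from_cells,
    restricted_mobility_ols,
    round_half_away,
)
from epimobility.published import CELL_NS, CROSSTAB_CELLS


def _tab(values):
    return pd.DataFrame(values, index=CLASS_LEVELS, columns=CLASS_LEVELS, dtype=float)


class TestMarginals:
    def test_published_origin_disadvantaged_row(self):
        """Count-weighted mean of the first published panel row is 0.13."""
        row, _, _ = marginal_from_cells(CROSSTAB_CELLS["horvath"], CELL_NS)
        assert round_half_away(row["disadvantaged"]) == 0.13

    def test_published_destination_disadvantaged_column(self):
        _, col, _ = marginal_from_cells(CROSSTAB_CELLS["hannum"], CELL_NS)
        assert round_half_away(col["disadvantaged"]) == 0.05

    def test_constant_outcome_marginals_ignore_weights(self):
        means = _tab(np.full((3, 3), 1.7))
        row, col, grand = marginal_from_cells(means, CELL_NS)
        assert np.allclose(row, 1.7) and np.allclose(col, 1.7) and grand == pytest.approx(1.7)

    def test_positive_count_with_missing_mean_raises(self):
        means = _tab(np.full((3, 3), 1.0))
        means.iloc[0, 0] = np.nan
        with pytest.raises(ValidationError):
            marginal_from_cells(means, CELL_NS)

    def test_half_away_from_zero_rounding(self):
        assert round_half_away(0.125) == 0.13
        assert round_half_away(-0.125) == -0.13
        assert round_half_away(0.114999) == 0.11


class TestCrosstab:
    def test_constant_outcome(self, small_cohort):
        df = small_cohort.assign(acc=2.0)
        tab = crosstab_means(df, "acc")
        assert np.allclose(tab.cell_means, 2.0) and tab.grand == pytest.approx(2.0)
        assert tab.n == len(df)

    def test_noiseless_generator_round_trip(self):
        """sigma = 0 cohort cross-tab equals the generating DRM cell means."""
        cfg = GeneratorConfig(
            p=0.6, delta=(1.0, 0.0, -1.0), beta0=0.2, sigma=0.0,
            covariate_effects={}, seed=8,
        )
        df = generate_cohort(cfg)
        tab = crosstab_means(df, "y")
        delta = np.array(cfg.delta)
        for i, oc in enumerate(CLASS_LEVELS):
            for j, dc in enumerate(CLASS_LEVELS):
                expected = cfg.beta0 + (
                    delta[i] if i == j else cfg.p * delta[i] + (1 - cfg.p) * delta[j]
                )
                assert tab.cell_means.loc[oc, dc] == pytest.approx(expected, abs=1e-12)

    def test_marginals_match_person_level_computation(self, small_cohort):
        tab = crosstab_means(small_cohort, "y")
        assert tab.grand == pytest.approx(small_cohort["y"].mean(), abs=1e-12)
        by_origin = small_cohort.groupby("origin", observed=True)["y"].mean()
        for c in CLASS_LEVELS:
            assert tab.row_totals[c] == pytest.approx(by_origin[c], abs=1e-12)

    def test_empty_cell_reported_missing(self):
        df = pd.DataFrame(
            {
                "origin": ["disadvantaged", "advantaged"],
                "destination": ["disadvantaged", "advantaged"],
                "acc": [1.0, 3.0],
            }
        )
        tab = crosstab_means(df, "acc")
        assert np.isnan(tab.cell_means.loc["disadvantaged", "advantaged"])
        assert tab.cell_ns.loc["disadvantaged", "advantaged"] == 0
        assert tab.cell_means.loc["disadvantaged", "disadvantaged"] == 1.0


class TestGroupTests:
    def test_identical_groups_t_zero(self):
        y = pd.Series([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        g = pd.Series(["a"] * 3 + ["b"] * 3)
        out = group_tests(y, g)
        assert out["test"] == "t"
        assert out["statistic"] == pytest.approx(0.0, abs=1e-12)
        assert out["p_value"] == pytest.approx(1.0)

    def test_pooled_t_hand_computed(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([2.0, 4.0, 6.0, 8.0])
        sp2 = (3 * a.var(ddof=1) + 3 * b.var(ddof=1)) / 6
        t_oracle = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 4 + 1 / 4))
        out = group_tests(pd.Series(np.r_[a, b]), pd.Series(["a"] * 4 + ["b"] * 4))
        assert out["statistic"] == pytest.approx(t_oracle, abs=1e-10)

    def test_three_identical_groups_f_zero(self):
        y = pd.Series([1.0, 2.0] * 3)
        g = pd.Series(["a", "a", "b", "b", "c", "c"])
        out = group_tests(y, g)
        assert out["test"] == "F" and out["statistic"] == pytest.approx(0.0, abs=1e-12)

    def test_single_observation_group_rejected(self):
        with pytest.raises(ValidationError):
            group_tests(pd.Series([1.0, 2.0, 3.0]), pd.Series(["a", "a", "b"]))


class TestRestrictedOLS:
    def _cohort(self, shift=1.0):
        """Downward mobile vs stably advantaged, covariates balanced, sigma = 0."""
        half = pd.DataFrame(
            {
                "female": [0, 1, 0, 1],
                "z_age": [-1.0, -0.5, 0.5, 1.0],
            }
        )
        down = half.assign(origin="advantaged", destination="disadvantaged")
        stable = half.assign(origin="advantaged", destination="advantaged")
        df = pd.concat([down, stable], ignore_index=True)
        df["z_age_sq"] = df["z_age"] ** 2
        df["acc"] = 0.5 * df["female"] + shift * (df["destination"] == "disadvantaged")
        return df

    def test_exact_contrast_with_zero_noise(self):
        out = restricted_mobility_ols(self._cohort(), "acc", "down_vs_stable_advantaged")
        assert out["coefficient"] == pytest.approx(1.0, abs=1e-10)
        lo, hi = out["conf_int"]
        assert hi - lo == pytest.approx(0.0, abs=1e-8)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(12)
        df = self._cohort()
        df["acc"] += rng.normal(0, 0.3, len(df))
        out = restricted_mobility_ols(df, "acc", "down_vs_stable_advantaged")
        X = np.column_stack(
            [
                np.ones(len(df)),
                (df["destination"] == "disadvantaged").astype(float),
                df[["female", "z_age", "z_age_sq"]].to_numpy(float),
            ]
        )
        beta = np.linalg.solve(X.T @ X, X.T @ df["acc"].to_numpy())
        assert out["coefficient"] == pytest.approx(beta[1], abs=1e-10)

    def test_upward_comparison_selects_correct_groups(self):
        df = self._cohort()
        up = df.head(4).assign(origin="disadvantaged", destination="advantaged")
        stable_dis = df.head(4).assign(origin="disadvantaged", destination="disadvantaged")
        both = pd.concat([up, stable_dis, df], ignore_index=True)
        out = restricted_mobility_ols(both, "acc", "up_vs_stable_disadvantaged")
        assert out["n_exposed"] == 4 and out["n_reference"] == 4

    def test_empty_group_raises(self):
        df = self._cohort()
        only_stable = df[df["destination"] == "advantaged"]
        with pytest.raises(ValidationError):
            restricted_mobility_ols(only_stable, "acc", "down_vs_stable_advantaged")
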