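"""Diagonal reference model estimation."""

import numpy as np
import pandas as pd
import pytest

from epimobility import (
    CLASS_LEVELS,
    GeneratorConfig,
    IdentifiabilityError,
    RankError,
    ValidationError,
    compare_models,
    fit_drm,
    generate_cohort,
    predict_cell_means,
    standardize_covariates,
)
from epimobility.drm import _EFFECT_CODING, DRMData, build_design, fit_at_p, _gaussian_logl


def _data(frame, outcome="y", scheme="none", covariates=("female",)):
    return DRMData.from_frame(frame, outcome=outcome, scheme=scheme, covariates=covariates)


def _one_person_frame(origin, destination, p=None):
    return pd.DataFrame(
        {
            "origin": [origin, "disadvantaged", "advantaged"],
            "destination": [destination, "disadvantaged", "advantaged"],
            "y": [0.0, 0.0, 0.0],
            "female": [0.0, 0.0, 0.0],
        }
    )


class TestBuildDesign:
    def test_immobile_row_is_pure_effect_coding(self):
        for k, label in enumerate(CLASS_LEVELS):
            data = _data(_one_person_frame(label, label))
            X, names = build_design(data, p=0.37)
            assert np.allclose(X[0, 1:3], _EFFECT_CODING[k])
            assert names[:3] == ["const", "delta_1", "delta_2"]

    def test_p_one_mobile_row_equals_origin_coding(self):
        data = _data(_one_person_frame("disadvantaged", "advantaged"))
        X, _ = build_design(data, p=1.0)
        assert np.allclose(X[0, 1:3], _EFFECT_CODING[0])

    def test_half_weight_blend_hand_built(self):
        data = _data(_one_person_frame("disadvantaged", "intermediate"))
        X, _ = build_design(data, p=0.5)
        assert np.allclose(X[0, 1:3], 0.5 * _EFFECT_CODING[0] + 0.5 * _EFFECT_CODING[1])

    def test_p_outside_unit_interval_rejected(self):
        data = _data(_one_person_frame("disadvantaged", "intermediate"))
        with pytest.raises(ValidationError):
            build_design(data, p=1.2)


class TestFitAtP:
    def test_noiseless_interpolation_recovers_truth(self):
        cfg = GeneratorConfig(
            cell_counts=tuple((5, 5, 5) for _ in range(3)),
            p=0.7,
            delta=(0.8, -0.2, -0.6),
            beta0=0.4,
            sigma=0.0,
            seed=2,
        )
        frame = generate_cohort(cfg)
        frame["female"] = (frame["sex"] == "female").astype(float)
        coef, sigma2, _ = fit_at_p(_data(frame), p=0.7)
        assert coef["const"] == pytest.approx(0.4, abs=1e-8)
        assert coef["delta_1"] == pytest.approx(0.8, abs=1e-8)
        assert coef["delta_2"] == pytest.approx(-0.2, abs=1e-8)
        assert coef["female"] == pytest.approx(-1.0, abs=1e-8)
        assert sigma2 == pytest.approx(0.0, abs=1e-14)

    def test_balanced_cells_intercept_is_grand_mean(self, small_cohort):
        data = DRMData.from_frame(small_cohort, outcome="y", covariates=())
        coef, _, _ = fit_at_p(data, p=0.5)
        assert coef["const"] == pytest.approx(small_cohort["y"].mean(), abs=1e-10)

    def test_matches_normal_equations_oracle(self, drm_cohort):
        data = DRMData.from_frame(
            drm_cohort, outcome="y", scheme="direction",
            covariates=("female", "z_age", "z_age_sq"),
        )
        for p in (0.0, 0.25, 0.61, 1.0):
            X, _ = build_design(data, p)
            oracle = np.linalg.solve(X.T @ X, X.T @ data.y)
            coef, _, _ = fit_at_p(data, p)
            assert np.allclose(coef.to_numpy(), oracle, atol=1e-8)

    def test_loglik_decreases_with_variance(self):
        assert _gaussian_logl(100, 2.0) < _gaussian_logl(100, 1.0)

    def test_rank_deficiency_names_columns(self, drm_cohort):
        frame = drm_cohort.copy()
        frame["dup"] = frame["female"]
        with pytest.raises(RankError) as err:
            fit_at_p(_data(frame, covariates=("female", "dup")), 0.5)
        assert "dup" in err.value.aliased


class TestFitDrm:
    def test_noiseless_recovery_of_p_and_delta(self):
        cfg = GeneratorConfig(p=0.67, delta=(0.5, 0.0, -0.5), sigma=0.0, seed=4)
        frame = standardize_covariates(generate_cohort(cfg))
        fit = fit_drm(frame, outcome="y", compute_se=False)
        assert fit.p_hat == pytest.approx(0.67, abs=1e-4)
        assert np.allclose(fit.delta.to_numpy(), [0.5, 0.0, -0.5], atol=1e-6)

    def test_stochastic_recovery_study_shape(self, drm_cohort):
        fit = fit_drm(drm_cohort, outcome="y")
        assert abs(fit.p_hat - 0.67) <= 0.05
        assert np.abs(fit.delta.to_numpy() - [0.5, 0.0, -0.5]).max() <= 0.1
        # reported uncertainty is in the right ballpark for this design
        assert 0.01 < fit.se["origin_weight"] < 0.1

    def test_immobile_only_data_unidentified(self):
        frame = pd.DataFrame(
            {
                "origin": ["disadvantaged"] * 5 + ["advantaged"] * 5,
                "destination": ["disadvantaged"] * 5 + ["advantaged"] * 5,
                "y": np.arange(10.0),
                "female": [0.0, 1.0] * 5,
            }
        )
        with pytest.raises(IdentifiabilityError):
            fit_drm(frame, outcome="y", covariates=("female",))

    def test_weights_sum_to_one_and_delta_sums_to_zero(self, drm_cohort):
        fit = fit_drm(drm_cohort, outcome="y", scheme="any", compute_se=False)
        assert fit.p_hat + fit.destination_weight == 1.0
        assert fit.delta.sum() == pytest.approx(0.0, abs=1e-10)

    def test_swap_symmetry(self, drm_cohort):
        """Swapping origin/destination maps p to 1 - p, logL unchanged."""
        fit = fit_drm(drm_cohort, outcome="y", compute_se=False)
        swapped = drm_cohort.rename(
            columns={"origin": "destination", "destination": "origin"}
        )
        fit_sw = fit_drm(swapped, outcome="y", compute_se=False)
        assert fit_sw.p_hat == pytest.approx(1.0 - fit.p_hat, abs=1e-6)
        assert fit_sw.logL == pytest.approx(fit.logL, abs=1e-6)

    def test_class_relabelling_permutes_delta(self, drm_cohort):
        perm = {
            "disadvantaged": "advantaged",
            "intermediate": "disadvantaged",
            "advantaged": "intermediate",
        }
        relabelled = drm_cohort.copy()
        relabelled["origin"] = relabelled["origin"].map(perm)
        relabelled["destination"] = relabelled["destination"].map(perm)
        fit = fit_drm(drm_cohort, outcome="y", compute_se=False)
        fit_rel = fit_drm(relabelled, outcome="y", compute_se=False)
        assert fit_rel.p_hat == pytest.approx(fit.p_hat, abs=1e-6)
        assert fit_rel.logL == pytest.approx(fit.logL, abs=1e-6)
        for old, new in perm.items():
            assert fit_rel.delta[new] == pytest.approx(fit.delta[old], abs=1e-6)

    def test_profile_grid_consistent_with_refined_optimum(self, drm_cohort):
        fit = fit_drm(drm_cohort, outcome="y", compute_se=False)
        assert np.all(fit.logL >= fit.profile_logL - 1e-9)
        nearest = np.argmin(np.abs(fit.profile_p - fit.p_hat))
        assert fit.logL >= fit.profile_logL[nearest] - 1e-6

    def test_boundary_flag_and_na_interval_for_p(self):
        cfg = GeneratorConfig(p=1.0, delta=(1.0, 0.0, -1.0), sigma=0.05, seed=9)
        frame = standardize_covariates(generate_cohort(cfg))
        fit = fit_drm(frame, outcome="y")
        assert fit.boundary and fit.p_hat > 0.995
        assert np.isnan(fit.se["origin_weight"])
        assert np.isnan(fit.conf_int.loc["origin_weight"]).all()

    def test_wald_interval_covers_truth_in_typical_draw(self, drm_cohort):
        fit = fit_drm(drm_cohort, outcome="y")
        lo, hi = fit.conf_int.loc["origin_weight"]
        assert lo < 0.67 < hi


class TestCompareAndPredict:
    def test_single_fit_ranking(self, drm_cohort):
        fit = fit_drm(drm_cohort, outcome="y", compute_se=False)
        tab = compare_models([fit])
        assert len(tab) == 1 and tab.loc[0, "dAIC"] == 0.0

    def test_different_outcomes_not_comparable(self, drm_cohort):
        f1 = fit_drm(drm_cohort, outcome="y", compute_se=False)
        other = drm_cohort.assign(y2=drm_cohort["y"] + 1.0)
        f2 = fit_drm(other, outcome="y2", compute_se=False)
        with pytest.raises(ValidationError):
            compare_models([f1, f2])

    def test_no_mobility_truth_prefers_model_1_by_bic(self, drm_cohort):
        fits = [
            fit_drm(drm_cohort, outcome="y", scheme=s, compute_se=False)
            for s in ("none", "any", "direction", "steps")
        ]
        tab = compare_models(fits)
        assert tab.sort_values("BIC").iloc[0]["scheme"] == "none"

    def test_predict_cell_means_hand_arithmetic(self, drm_cohort):
        fit = fit_drm(drm_cohort, outcome="y", compute_se=False)
        fit.p_hat, fit.beta0 = 0.5, 0.0
        fit.delta = pd.Series([1.0, 0.0, -1.0], index=CLASS_LEVELS)
        cells = predict_cell_means(fit)
        assert cells.loc["disadvantaged", "advantaged"] == pytest.approx(0.0)
        assert np.allclose(np.diag(cells), [1.0, 0.0, -1.0])

    def test_predict_with_p_one_is_origin_only(self, drm_cohort):
        fit = fit_drm(drm_cohort, outcome="y", compute_se=False)
        fit.p_hat = 1.0
        cells = predict_cell_means(fit)
        for origin in CLASS_LEVELS:
            assert cells.loc[origin].nunique() == 1
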