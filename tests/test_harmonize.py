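"""Residualization, imputation and stepwise selection."""

import numpy as np
import pandas as pd
import pytest

from admri.harmonize import (
    apply_correction,
    fit_correction,
    impute_missing,
    stepwise_select,
)
from admri.phantom import sample_feature_table


def _toy_table():
    X = pd.DataFrame(
        {"f0": [1.0, 2.0, 4.0, 3.0]}, index=["a", "b", "c", "d"]
    )
    cov = pd.DataFrame(
        {"age": [70.0, 75.0, 80.0, 85.0], "sex": ["F", "M", "F", "M"]},
        index=["a", "b", "c", "d"],
    )
    return X, cov


class TestCorrection:
    def test_closed_form_normal_equations(self):
        """4-subject toy table: coefficients equal the lstsq solve exactly."""
        X, cov = _toy_table()
        model = fit_correction(X, cov, ["a", "b", "c", "d"])
        D = np.column_stack(
            [np.ones(4), cov["age"], (cov["sex"] == "M").astype(float)]
        )
        beta = np.linalg.lstsq(D, X["f0"].to_numpy(), rcond=None)[0]
        assert np.allclose(model.coef.loc["f0"].to_numpy(), beta, atol=1e-10)

    def test_planted_slope_recovered(self):
        X, y, cov = sample_feature_table(
            {"HC": 200}, 1, effect_size_d=0.0, age_slope=0.05, seed=4
        )
        noise = np.random.default_rng(0).normal(0, 0.1, 200)
        X["f000"] = 0.05 * (cov["age"] - 75.0) + noise
        model = fit_correction(X, cov, list(X.index))
        assert abs(model.coef.loc["f000", "age"] - 0.05) / 0.05 < 0.10

    def test_independent_features_near_zero_coefficients(self):
        X, y, cov = sample_feature_table({"HC": 300}, 3, effect_size_d=0.0, seed=5)
        model = fit_correction(X, cov, list(X.index))
        se = 1.0 / np.sqrt(300)  # rough SE of a unit-variance regression
        assert (model.coef["age"].abs() < 3 * se).all()

    def test_single_sex_controls_rejected(self):
        X, cov = _toy_table()
        cov["sex"] = "F"
        with pytest.raises(ValueError, match="rank"):
            fit_correction(X, cov, list(X.index))

    def test_residual_age_slope_zero_on_controls(self):
        X, y, cov = sample_feature_table(
            {"HC": 100, "AD": 100}, 2, effect_size_d=1.0, informative={0},
            age_slope=0.08, sex_offset=0.4, seed=6,
        )
        ctrl = [i for i in y.index if y[i] == "HC"]
        model = fit_correction(X, cov, ctrl)
        Xc = apply_correction(X, model, cov)
        slope = np.polyfit(cov.loc[ctrl, "age"], Xc.loc[ctrl, "f001"], 1)[0]
        assert abs(slope) < 1e-10

    def test_disease_effect_preserved(self):
        """Correction must not eat a group effect orthogonal to age/sex."""
        X, y, cov = sample_feature_table(
            {"HC": 400, "AD": 400}, 1, informative={0}, effect_size_d=1.0,
            age_slope=0.05, seed=7,
        )
        # reference: the same draws without covariate terms (same seed)
        X0, _, _ = sample_feature_table(
            {"HC": 400, "AD": 400}, 1, informative={0}, effect_size_d=1.0,
            age_slope=0.0, seed=7,
        )
        ctrl = [i for i in y.index if y[i] == "HC"]
        model = fit_correction(X, cov, ctrl)
        Xc = apply_correction(X, model, cov)
        ref_diff = X0.loc[y == "HC", "f000"].mean() - X0.loc[y == "AD", "f000"].mean()
        cor_diff = Xc.loc[y == "HC", "f000"].mean() - Xc.loc[y == "AD", "f000"].mean()
        assert abs(cor_diff - ref_diff) / abs(ref_diff) < 0.02

    def test_refit_on_corrected_controls_is_null(self):
        X, y, cov = sample_feature_table(
            {"HC": 150}, 2, effect_size_d=0.0, age_slope=0.1, sex_offset=0.5, seed=8
        )
        model = fit_correction(X, cov, list(X.index))
        Xc = apply_correction(X, model, cov)
        model2 = fit_correction(Xc, cov, list(X.index))
        assert np.abs(model2.coef.to_numpy()).max() < 1e-10

    def test_missing_cells_excluded_not_zeroed(self):
        X, cov = _toy_table()
        X.loc["a", "f0"] = np.nan
        model = fit_correction(X, cov, list(X.index))
        D = np.column_stack(
            [np.ones(3), cov["age"][1:], (cov["sex"][1:] == "M").astype(float)]
        )
        beta = np.linalg.lstsq(D, X["f0"][1:].to_numpy(), rcond=None)[0]
        assert np.allclose(model.coef.loc["f0"].to_numpy(), beta, atol=1e-10)
        Xc = apply_correction(X, model, cov)
        assert np.isnan(Xc.loc["a", "f0"])


class TestImpute:
    def test_no_missing_identity(self):
        X, _ = _toy_table()
        assert impute_missing(X, "train-mean", list(X.index)).equals(X)

    def test_train_mean_fill(self):
        X = pd.DataFrame({"f": [1.0, 2.0, 3.0, np.nan]}, index=list("abcd"))
        out = impute_missing(X, "train-mean", ["a", "b", "c"])
        assert out.loc["d", "f"] == 2.0

    def test_test_subjects_never_in_statistics(self):
        X = pd.DataFrame({"f": [1.0, 2.0, 3.0, 100.0, np.nan]}, index=list("abcde"))
        out = impute_missing(X, "train-mean", ["a", "b", "c"])
        assert out.loc["e", "f"] == 2.0  # 100.0 (id 'd') is not training

    def test_drop_subject_counts(self):
        X, y, cov = sample_feature_table(
            {"HC": 50, "AD": 50}, 4, effect_size_d=0.0,
            missing_spec={"columns": [0], "fraction": 0.13}, seed=9,
        )
        dropped = impute_missing(X, "drop-subject")
        assert len(dropped) == 100 - int(np.floor(100 * 0.13 + 0.5))

    def test_all_training_missing_raises(self):
        X = pd.DataFrame({"f": [np.nan, np.nan, 3.0]}, index=list("abc"))
        with pytest.raises(ValueError, match="missing"):
            impute_missing(X, "train-mean", ["a", "b"])


class TestStepwise:
    def test_strong_single_feature_selected(self):
        X, y, _ = sample_feature_table(
            {"HC": 50, "AD": 50}, 3, informative={1}, effect_size_d=3.0, seed=10
        )
        rep = stepwise_select(X, y)
        assert "f001" in rep.selected

    def test_null_first_step_inclusion_rate(self):
        """All-noise features: ~p_enter of candidates pass at the first step."""
        from admri.harmonize import _partial_f_pvalues

        frac = []
        for seed in range(30):
            X, y, _ = sample_feature_table(
                {"HC": 40, "AD": 40}, 20, effect_size_d=0.0, seed=100 + seed
            )
            yy = (y == "AD").to_numpy(float)
            Xm = np.column_stack([np.ones(len(yy)), X.to_numpy()])
            p = _partial_f_pvalues(Xm, yy, [], list(range(20)))
            frac.append(np.mean([v < 0.05 for v in p.values()]))
        assert abs(np.mean(frac) - 0.05) < 0.02

    def test_recovery_of_informative_set(self):
        X, y, _ = sample_feature_table(
            {"HC": 100, "AD": 100}, 30, informative={0, 1, 2}, effect_size_d=0.8,
            seed=11,
        )
        rep = stepwise_select(X, y)
        recall = len({"f000", "f001", "f002"} & set(rep.selected)) / 3
        assert recall >= 2 / 3

    def test_non_binary_labels_rejected(self):
        X, y, _ = sample_feature_table(
            {"HC": 10, "S-MCI": 10, "AD": 10}, 2, effect_size_d=0.0, seed=12
        )
        with pytest.raises(ValueError, match="binary"):
            stepwise_select(X, y)

    def test_p_enter_greater_than_p_remove_rejected(self):
        X, y, _ = sample_feature_table({"HC": 10, "AD": 10}, 2, seed=13)
        with pytest.raises(ValueError, match="p_enter"):
            stepwise_select(X, y, p_enter=0.2, p_remove=0.1)

    def test_deterministic(self):
        X, y, _ = sample_feature_table(
            {"HC": 60, "AD": 60}, 10, informative={0, 4}, effect_size_d=0.7, seed=14
        )
        assert stepwise_select(X, y).selected == stepwise_select(X, y).selected
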