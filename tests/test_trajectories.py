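import numpy as np
import pandas as pd
import pytest

from conntda import (
    MODEL_NAMES,
    fdr_bh,
    fit_lme,
    fit_trajectory_model,
    impute_pds,
    model_selection,
    network_trajectories,
    sample_intercept_curve,
    simulate_cohort,
    simulate_features,
)
from conntda.experiments import REFERENCE_B0_NETWORK_PVALUES


def brute_force_bh(p, q):
    """Step-up straight from the definition: largest i with
    p_(i) <= i*q/m, reject everything at or below it."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    thresh = (np.arange(1, m + 1) * q) / m
    below = np.flatnonzero(sorted_p <= thresh)
    flags = np.zeros(m, dtype=bool)
    if below.size:
        flags[order[: below[-1] + 1]] = True
    return flags


class TestFdr:
    def test_published_network_pvalues_flag_exactly_fpn(self):
        flags = fdr_bh(REFERENCE_B0_NETWORK_PVALUES, q=0.05)
        assert flags.sum() == 1
        assert flags[5]  # FPN position in the canonical label order
        assert REFERENCE_B0_NETWORK_PVALUES[5] == 0.001

    def test_all_ones_reject_nothing(self):
        assert not fdr_bh([1.0] * 7).any()

    def test_hand_worked_step_up(self):
        flags = fdr_bh([0.001, 0.010, 0.165, 0.205], q=0.05)
        np.testing.assert_array_equal(flags, [True, True, False, False])

    def test_empty_input(self):
        assert fdr_bh([]).size == 0

    def test_agrees_with_brute_force_definition(self, rng):
        for _ in range(2000):
            m = int(rng.integers(1, 40))
            p = rng.uniform(0, 1, m)
            if rng.random() < 0.3:
                p[: m // 2] **= 4  # sprinkle small p-values
            q = float(rng.uniform(0.01, 0.2))
            np.testing.assert_array_equal(fdr_bh(p, q), brute_force_bh(p, q))


class TestImputePds:
    def test_under_ten_rule(self):
        cohort, _ = simulate_cohort(seed=1)
        cohort.loc[0, "age"] = 8.2
        cohort.loc[0, "pds"] = np.nan
        out = impute_pds(cohort)
        assert out.loc[0, "pds"] == 1.0
        assert out.loc[0, "pds_imputed"]

    def test_complete_table_returned_unchanged(self):
        cohort, _ = simulate_cohort(seed=2)
        cohort["pds"] = cohort["pds"].fillna(2.0)
        out = impute_pds(cohort)
        pd.testing.assert_frame_equal(
            out.drop(columns="pds_imputed"), cohort, check_dtype=False
        )
        assert not out["pds_imputed"].any()

    def test_heldout_recovery_within_half_point(self):
        # monotone true PDS(age): mask 50 observed values at age >= 10
        # and compare the imputed values against the held-out truth
        from conntda.synthetic import _logistic_pds

        cohort, gt = simulate_cohort(n_subjects=120, seed=3)
        mid = np.where(cohort.sex == "F", gt.pds_midpoint_f, gt.pds_midpoint_m)
        cohort["pds"] = np.clip(
            np.round(_logistic_pds(cohort.age.to_numpy(), mid, gt.pds_slope)), 1, 4
        )
        cohort.loc[cohort.age < 10, "pds"] = 1.0
        rng = np.random.default_rng(0)
        eligible = cohort.index[cohort["age"] >= 10.0].to_numpy()
        held = rng.choice(eligible, size=50, replace=False)
        truth = cohort.loc[held, "pds"].copy()
        cohort.loc[held, "pds"] = np.nan
        out = impute_pds(cohort)
        err = np.abs(out.loc[held, "pds"].to_numpy() - truth.to_numpy())
        assert (err <= 0.5).mean() >= 0.90

    def test_all_missing_stratum_rejected(self):
        cohort, _ = simulate_cohort(seed=4)
        # no under-10 females left, so the under-10 rule cannot repopulate
        cohort = cohort[(cohort.sex == "M") | (cohort.age >= 10)].reset_index(drop=True)
        cohort.loc[cohort.sex == "F", "pds"] = np.nan
        with pytest.raises(ValueError, match="sex"):
            impute_pds(cohort)


class TestFitModels:
    def test_aic_identity_for_every_model(self, cohort_and_features):
        cohort, features, _ = cohort_and_features
        merged = cohort.merge(
            features[features.network == "ALL"], on="session_id"
        )
        y = merged["b0_auc"].to_numpy()
        for name in MODEL_NAMES:
            fit = fit_trajectory_model(y, merged, name)
            assert fit.aic == pytest.approx(2 * fit.k - 2 * fit.loglik, abs=1e-8)
            assert fit.edf >= 1.0
            assert 0.0 <= fit.p_value <= 1.0
            assert 0.0 <= fit.sw_resid_p <= 1.0

    def test_aic_formula_example(self):
        # k = 5, lnL = -100 -> AIC = 210
        assert 2 * 5 - 2 * (-100) == 210

    def test_lme_slope_recovery_across_replicates(self):
        # y = 2 + 0.3 age + b(0.5) + e(0.2), 100 subjects x 2 sessions
        rng = np.random.default_rng(0)
        hits = 0
        n_reps = 100
        for _ in range(n_reps):
            n_sub = 100
            sub = np.repeat(np.arange(n_sub), 2)
            age = rng.uniform(6.7, 18.1, sub.size)
            y = 2 + 0.3 * age + rng.normal(0, 0.5, n_sub)[sub] \
                + rng.normal(0, 0.2, sub.size)
            cohort = pd.DataFrame(
                {"subject_id": sub, "session_index": np.tile([1, 2], n_sub),
                 "session_id": np.arange(sub.size).astype(str),
                 "age": age, "sex": np.where(sub % 2 == 0, "F", "M"),
                 "pds": 2.0, "mean_fd": np.full(sub.size, 0.1),
                 "coil": "8ch", "qc_pass": True}
            )
            fit = fit_lme(y, cohort, "LME-Age")
            hits += 0.25 <= fit.fixed_effects["age"] <= 0.35
        assert hits >= 95

    def test_zero_variance_random_effect_recovered(self):
        rng = np.random.default_rng(1)
        sub = np.repeat(np.arange(80), 2)
        age = rng.uniform(6.7, 18.1, sub.size)
        y = 1.0 + 0.2 * age + rng.normal(0, 0.3, sub.size)  # no subject effect
        cohort = pd.DataFrame(
            {"subject_id": sub, "session_index": np.tile([1, 2], 80),
             "session_id": np.arange(sub.size).astype(str), "age": age,
             "sex": "F", "pds": 2.0, "mean_fd": 0.1, "coil": "8ch",
             "qc_pass": True}
        )
        fit = fit_lme(y, cohort, "LME-Age")
        re_var = fit.fit.tau["subject"] * fit.fit.sigma2
        assert re_var < 0.01

    def test_gamm_linear_truth_keeps_edf_near_one(self):
        rng = np.random.default_rng(0)
        hits = 0
        n_reps = 200
        for _ in range(n_reps):
            seed = int(rng.integers(2 ** 31))
            cohort, gt = simulate_cohort(seed=seed, effect_amplitude=0.0)
            cohort = impute_pds(cohort)
            cohort = cohort[cohort.qc_pass].reset_index(drop=True)
            feats = simulate_features(cohort, gt)
            merged = cohort.merge(feats[feats.network == "ALL"], on="session_id")
            y = merged["b0_auc"].to_numpy() + 0.5 * merged["pds"].to_numpy()
            fit = fit_trajectory_model(y, merged, "GAMM-PDS")
            hits += fit.edf <= 1.3
        assert hits / n_reps >= 0.80

    def test_gamm_power_against_peaked_effect(self):
        # standardized peaked effect around d ~ 0.8 at 90 subjects
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(100):
            seed = int(rng.integers(2 ** 31))
            cohort, gt = simulate_cohort(
                n_subjects=90, seed=seed, effect_amplitude=2.0
            )
            cohort = impute_pds(cohort)
            cohort = cohort[cohort.qc_pass].reset_index(drop=True)
            feats = simulate_features(cohort, gt)
            merged = cohort.merge(feats[feats.network == "ALL"], on="session_id")
            fit = fit_trajectory_model(merged["b0_auc"].to_numpy(), merged, "GAMM-PDS")
            hits += fit.p_value < 0.05
        assert hits >= 80


class TestModelSelection:
    def test_battery_returns_eight_models_and_best(self, cohort_and_features):
        cohort, features, _ = cohort_and_features
        merged = cohort.merge(features[features.network == "ALL"], on="session_id")
        sel = model_selection(merged["b0_auc"].to_numpy(), merged)
        assert len(sel["aic_table"]) == 8
        assert sel["best"] in MODEL_NAMES
        assert sel["aic_table"]["aic"].min() == sel["best_fit"].aic


class TestSampleInterceptCurve:
    def test_one_session_per_subject_equals_grand_mean(self, rng):
        curves = rng.normal(5, 1, (30, 12))
        grid = np.linspace(0, 2, 12)
        out = sample_intercept_curve(curves, np.arange(30), grid)
        np.testing.assert_allclose(
            out["intercept"], curves.mean(axis=0), atol=1e-6
        )
        assert (out["lo95"] <= out["intercept"]).all()

    def test_duplicated_sessions_weight_subjects_equally(self, rng):
        base = rng.normal(0, 1, (12, 6))
        curves = np.vstack([base, base])
        subjects = np.concatenate([np.arange(12), np.arange(12)])
        out = sample_intercept_curve(curves, subjects, np.linspace(0, 2, 6))
        np.testing.assert_allclose(out["intercept"], base.mean(axis=0), atol=1e-5)


class TestNetworkTrajectories:
    def test_bookkeeping_thirteen_networks_plus_whole_brain(self, cohort_and_features):
        cohort, features, _ = cohort_and_features
        report = network_trajectories(features, cohort)
        for resp in ("b0_auc", "b1_auc"):
            block = report["responses"][resp]
            assert len(block["network_table"]) == 13
            assert block["best_model"] in MODEL_NAMES
            assert set(block["whole_brain"]) == {"edf", "F", "p"}

    def test_injected_fpn_effect_is_flagged(self, cohort_and_features):
        cohort, features, _ = cohort_and_features
        report = network_trajectories(features, cohort, responses=("b0_auc",))
        table = report["responses"]["b0_auc"]["network_table"]
        assert bool(table.loc[table.network == "FPN", "significant"].iloc[0])
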