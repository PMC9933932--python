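"""Validation studies: oracle checks, null-model ordering, and
model-recovery/calibration simulations.

These are the package's own evidence that the shipped algorithms are
correct and the statistical battery is calibrated. Each study is a pure
function of its seed so the test suite and the acceptance script can
rerun it from scratch.
"""

from __future__ import annotations

import numpy as np

from .connectome import Connectome, to_distance
from .nulls import rewire_connectome
from .reference import betti_curves_brute, mst_edge_weights
from .synthetic import simulate_cohort, simulate_features
from .tda import (
    betti_auc,
    betti_curve,
    curve_landmarks,
    rips_persistence,
)
from .trajectories import fdr_bh, impute_pds, model_selection, network_trajectories

#: Published per-network smooth-term p-values for the component-count
#: area (B0-AUC) used in the worked FDR example; order follows the 13
#: canonical network labels (AUD, CBL, CON, DMN, DAN, FPN, MEM, SAL,
#: SMH, SMM, SUB, VAN, VIS).
REFERENCE_B0_NETWORK_PVALUES = (
    0.493, 0.838, 0.067, 0.543, 0.203, 0.001, 0.794,
    0.045, 0.1, 0.178, 0.162, 0.691, 0.053,
)


def random_distance_matrix(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random symmetric matrix with positive off-diagonal distances in
    (0, 2], zero diagonal."""
    a = rng.uniform(0.05, 2.0, size=(n, n))
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 0.0)
    return a


def betti_oracle_study(n_matrices: int = 1000, max_n: int = 10, seed: int = 0) -> dict:
    """Fraction of random instances where the production Betti curves
    match the brute-force boundary-rank computation at every distinct
    filtration value (both dimensions, exact integer equality)."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_matrices):
        n = int(rng.integers(3, max_n + 1))
        d = random_distance_matrix(rng, n)
        diagram = rips_persistence(d)
        values, b0_ref, b1_ref = betti_curves_brute(d, diagram.maxscale)
        b0 = betti_curve(diagram, 0, values).counts
        b1 = betti_curve(diagram, 1, values).counts
        agree += int(np.array_equal(b0, b0_ref) and np.array_equal(b1, b1_ref))
    return {"agreement_rate": agree / n_matrices, "n": n_matrices}


def mst_identity_study(n_matrices: int = 1000, max_n: int = 25, seed: int = 0) -> dict:
    """Fraction of random instances where the finite H0 deaths equal the
    minimum-spanning-forest edge weights as a multiset."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_matrices):
        n = int(rng.integers(3, max_n + 1))
        d = random_distance_matrix(rng, n)
        diagram = rips_persistence(d, maxdim=0)
        deaths = np.sort(
            [dd for dim, _, dd in diagram.intervals if dim == 0 and np.isfinite(dd)]
        )
        agree += int(np.allclose(deaths, mst_edge_weights(d), atol=1e-12))
    return {"agreement_rate": agree / n_matrices, "n": n_matrices}


def auc_identity_study(
    n_matrices: int = 200, max_n: int = 15, seed: int = 0, step: float = 1e-3
) -> dict:
    """Maximum absolute gap between diagram total persistence and
    left-rule grid integration of the Betti curve."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_matrices):
        n = int(rng.integers(3, max_n + 1))
        d = random_distance_matrix(rng, n)
        diagram = rips_persistence(d)
        grid = np.arange(0.0, diagram.maxscale, step)
        for dim in (0, 1):
            exact = betti_auc(diagram, dim)
            approx = float(betti_curve(diagram, dim, grid).counts.sum() * step)
            worst = max(worst, abs(exact - approx))
    return {"max_abs_error": worst, "n": n_matrices}


def fdr_worked_example(q: float = 0.05) -> dict:
    """BH step-up on the published 13-network p-values: how many
    networks survive, and which index (0-based) they sit at."""
    flags = fdr_bh(REFERENCE_B0_NETWORK_PVALUES, q=q)
    return {
        "n_flagged": int(flags.sum()),
        "flagged_indices": [int(i) for i in np.flatnonzero(flags)],
        "n": len(REFERENCE_B0_NETWORK_PVALUES),
    }


def modular_connectome(
    rng: np.random.Generator,
    n_rois: int = 60,
    n_modules: int = 4,
    rho_within: float = 0.6,
    rho_between: float = 0.1,
    t: int = 150,
) -> Connectome:
    """Empirical correlation matrix of a block-modular multivariate
    normal sample (T volumes), the observed-side input of the
    null-ordering study."""
    module = np.arange(n_rois) % n_modules
    r = np.where(module[:, None] == module[None, :], rho_within, rho_between)
    np.fill_diagonal(r, 1.0)
    lam, u = np.linalg.eigh(r)
    root = u * np.sqrt(np.clip(lam, 0.0, None))
    x = rng.standard_normal((t, n_rois)) @ root.T
    return Connectome(r=np.corrcoef(x, rowvar=False))


def null_ordering_study(
    n_seeds: int = 100,
    n_rois: int = 60,
    n_modules: int = 4,
    seed: int = 0,
) -> dict:
    """Rewired vs observed ordering on modular connectomes.

    For each seed, the rewired connectome should reach the single
    component at a lower filtration value (smaller eps_single) and show
    a higher Betti-1 curve maximum than the observed modular one.
    """
    streams = np.random.SeedSequence(seed).spawn(n_seeds)
    hits_eps = hits_b1 = hits_both = 0
    for s in streams:
        rng = np.random.default_rng(s)
        obs = modular_connectome(rng, n_rois=n_rois, n_modules=n_modules)
        rew = rewire_connectome(obs, rng)
        lm_obs = curve_landmarks(rips_persistence(to_distance(obs)))
        lm_rew = curve_landmarks(rips_persistence(to_distance(rew)))
        eps_ok = lm_rew["eps_single"] < lm_obs["eps_single"]
        b1_ok = lm_rew["b1_max"] > lm_obs["b1_max"]
        hits_eps += int(eps_ok)
        hits_b1 += int(b1_ok)
        hits_both += int(eps_ok and b1_ok)
    return {
        "fraction_eps_single": hits_eps / n_seeds,
        "fraction_b1_max": hits_b1 / n_seeds,
        "fraction_both": hits_both / n_seeds,
        "n": n_seeds,
    }


def _prepared_cohort(n_subjects, seed, effect_amplitude):
    cohort, gt = simulate_cohort(
        n_subjects=n_subjects, seed=seed, effect_amplitude=effect_amplitude
    )
    cohort = impute_pds(cohort)
    cohort = cohort[cohort["qc_pass"]].reset_index(drop=True)
    feats = simulate_features(cohort, gt)
    return cohort, feats


def selection_recovery_study(
    n_reps: int = 100, n_subjects: int = 98, seed: int = 0,
    effect_amplitude: float = 2.0,
) -> dict:
    """How often the 8-model battery picks the pubertal-status smooth
    (GAMM-PDS) on cohorts whose true effect is the peaked g(PDS)."""
    rng = np.random.default_rng(seed)
    wins: dict[str, int] = {}
    for rep in range(n_reps):
        rep_seed = int(rng.integers(2 ** 31))
        cohort, feats = _prepared_cohort(n_subjects, rep_seed, effect_amplitude)
        merged = cohort.merge(
            feats[feats["network"] == "ALL"], on="session_id"
        )
        sel = model_selection(merged["b0_auc"].to_numpy(), merged)
        wins[sel["best"]] = wins.get(sel["best"], 0) + 1
    return {
        "gamm_pds_rate": wins.get("GAMM-PDS", 0) / n_reps,
        "winners": wins,
        "n": n_reps,
    }


def age_recovery_study(
    n_reps: int = 100, n_subjects: int = 98, seed: int = 0, slope: float = 0.3
) -> dict:
    """With a pure linear-age effect and no pubertal one, an Age model
    (LME-Age, or GAMM-Age at EDF near 1) should win the battery."""
    rng = np.random.default_rng(seed)
    age_wins = 0
    winners: dict[str, int] = {}
    for rep in range(n_reps):
        rep_seed = int(rng.integers(2 ** 31))
        cohort, feats = _prepared_cohort(n_subjects, rep_seed, 0.0)
        merged = cohort.merge(feats[feats["network"] == "ALL"], on="session_id")
        y = merged["b0_auc"].to_numpy() + slope * merged["age"].to_numpy()
        sel = model_selection(y, merged)
        winners[sel["best"]] = winners.get(sel["best"], 0) + 1
        age_wins += int(sel["best"] in ("LME-Age", "GAMM-Age"))
    return {"age_model_rate": age_wins / n_reps, "winners": winners, "n": n_reps}


def type1_study(n_reps: int = 1000, n_subjects: int = 98, seed: int = 0,
                alpha: float = 0.05) -> dict:
    """Smooth-term rejection rate of the pubertal-status model on null
    cohorts (no developmental effect anywhere)."""
    from .trajectories import fit_trajectory_model

    rng = np.random.default_rng(seed)
    rejections = 0
    for rep in range(n_reps):
        rep_seed = int(rng.integers(2 ** 31))
        cohort, feats = _prepared_cohort(n_subjects, rep_seed, 0.0)
        merged = cohort.merge(feats[feats["network"] == "ALL"], on="session_id")
        fit = fit_trajectory_model(merged["b0_auc"].to_numpy(), merged, "GAMM-PDS")
        rejections += int(fit.p_value < alpha)
    return {"rejection_rate": rejections / n_reps, "n": n_reps, "alpha": alpha}


def localization_study(
    n_reps: int = 100, n_subjects: int = 98, seed: int = 0,
    effect_amplitude: float = 2.0, q: float = 0.05,
) -> dict:
    """Effect injected only in the fronto-parietal network (and hence the
    whole brain): the per-network FDR pass should flag FPN and at most
    one other network."""
    rng = np.random.default_rng(seed)
    hits = 0
    fpn_flagged = 0
    extra_counts = []
    for rep in range(n_reps):
        rep_seed = int(rng.integers(2 ** 31))
        cohort, feats = _prepared_cohort(n_subjects, rep_seed, effect_amplitude)
        report = network_trajectories(feats, cohort, responses=("b0_auc",), q=q)
        table = report["responses"]["b0_auc"]["network_table"]
        flagged = set(table.loc[table["significant"], "network"])
        fpn = "FPN" in flagged
        extras = len(flagged - {"FPN"})
        fpn_flagged += int(fpn)
        extra_counts.append(extras)
        hits += int(fpn and extras <= 1)
    return {
        "success_rate": hits / n_reps,
        "fpn_rate": fpn_flagged / n_reps,
        "mean_extra_flags": float(np.mean(extra_counts)),
        "n": n_reps,
    }


def fdr_calibration_study(
    n_reps: int = 200, n_subjects: int = 98, seed: int = 0, q: float = 0.05
) -> dict:
    """On effect-free cohorts the per-response network pass should flag
    on average no more than ~q networks (family-level false positives)."""
    rng = np.random.default_rng(seed)
    false_flags = []
    for rep in range(n_reps):
        rep_seed = int(rng.integers(2 ** 31))
        cohort, feats = _prepared_cohort(n_subjects, rep_seed, 0.0)
        report = network_trajectories(feats, cohort, responses=("b0_auc",), q=q)
        table = report["responses"]["b0_auc"]["network_table"]
        false_flags.append(int(table["significant"].sum()))
    return {"mean_false_flags": float(np.mean(false_flags)), "n": n_reps}
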