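"""Developmental-trajectory modeling of topological features.

Eight candidate models per response (B0-AUC or B1-AUC), all with subject
random intercepts, mean framewise displacement and head-coil covariates,
estimated by maximum likelihood:

    LME-Age, LME-Age.Sex          linear age (+ age-by-sex interaction)
    GAMM-Age, GAMM-Age.Sex        penalized-spline age (per-sex smooths)
    GAMM-PDS, GAMM-PDS.Sex        penalized-spline pubertal status
    GAMM-AgePDS, GAMM-AgePDS.Sex  tensor-product age x PDS smooth

The winner is the model with the lowest AIC = 2k - 2lnL; its
developmental term is tested with a Wood-type F test, and per-network
p-values are corrected by Benjamini-Hochberg FDR across the 13
functional networks. Shapiro-Wilk normality checks run on the
conditional residuals and on the estimated random intercepts of every
fit. Pubertal status (PDS, ordinal 1-4) is imputed where missing: under
age 10 it is set to level 1, otherwise predicted from a per-sex smooth
of PDS on age with subject random intercepts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import shapiro
from statsmodels.stats.multitest import multipletests

from .connectome import NETWORKS, WHOLE_BRAIN
from .lmm import (
    MixedFit,
    PSpline1D,
    TensorSpline2D,
    fit_mixed_ml,
    intercept_with_subject_re,
    linear_term_test,
    smooth_term_test,
)

logger = logging.getLogger(__name__)

MODEL_NAMES = (
    "LME-Age",
    "LME-Age.Sex",
    "GAMM-Age",
    "GAMM-Age.Sex",
    "GAMM-PDS",
    "GAMM-PDS.Sex",
    "GAMM-AgePDS",
    "GAMM-AgePDS.Sex",
)

REQUIRED_COLUMNS = (
    "subject_id", "session_index", "age", "sex", "pds", "mean_fd", "coil",
)

SMOOTH_BASIS_DIM = 10  # shrunk automatically to #distinct covariate values
TENSOR_BASIS_DIM = 5


@dataclass
class FitResult:
    """One fitted trajectory model and its battery summaries."""

    name: str
    response: str
    loglik: float
    k: float
    aic: float
    fixed_effects: dict[str, float]
    edf: float | None
    f_stat: float | None
    p_value: float | None
    sw_resid_p: float
    sw_re_p: float
    converged: bool
    n_obs: int
    fit: MixedFit = field(repr=False, default=None)


def validate_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    bad_sex = set(cohort["sex"].unique()) - {"F", "M"}
    if bad_sex:
        raise ValueError(f"sex must be F or M, found {bad_sex}")
    bad_coil = set(cohort["coil"].unique()) - {"8ch", "32ch"}
    if bad_coil:
        raise ValueError(f"coil must be 8ch or 32ch, found {bad_coil}")
    if (cohort["age"] <= 0).any():
        raise ValueError("ages must be positive")
    pds = cohort["pds"].dropna()
    if ((pds < 1) | (pds > 4)).any():
        raise ValueError("PDS must lie in [1, 4]")
    return cohort


# ---------------------------------------------------------------------------
# PDS imputation


def impute_pds(cohort: pd.DataFrame) -> pd.DataFrame:
    """Fill missing PDS values.

    Sessions under age 10 get PDS level 1. Remaining gaps are predicted
    from a per-sex penalized-spline of PDS on age with subject random
    intercepts, clipped to [1, 4]. Adds a boolean ``pds_imputed`` column.
    """
    cohort = validate_cohort(cohort.copy())
    if "pds_imputed" not in cohort.columns:
        cohort["pds_imputed"] = False
    miss = cohort["pds"].isna()
    if not miss.any():
        return cohort
    under10 = miss & (cohort["age"] < 10.0)
    cohort.loc[under10, "pds"] = 1.0
    cohort.loc[under10, "pds_imputed"] = True
    miss = cohort["pds"].isna()
    for sex in ("F", "M"):
        sel = cohort["sex"] == sex
        need = miss & sel
        if not need.any():
            continue
        obs = sel & ~miss
        if obs.sum() == 0:
            raise ValueError(f"all PDS values missing for sex {sex!r}")
        age_obs = cohort.loc[obs, "age"].to_numpy()
        y_obs = cohort.loc[obs, "pds"].to_numpy(dtype=float)
        subj_obs = cohort.loc[obs, "subject_id"].to_numpy()
        if np.unique(age_obs).size < 3 or obs.sum() < 6:
            pred = np.full(int(need.sum()), float(np.mean(y_obs)))
        else:
            sp = PSpline1D(k=min(SMOOTH_BASIS_DIM, 6)).fit(age_obs)
            xf, zs = sp.transform(age_obs)
            x = np.column_stack([np.ones(obs.sum()), xf])
            subjects, inv = np.unique(subj_obs, return_inverse=True)
            z = np.zeros((int(obs.sum()), subjects.size))
            z[np.arange(int(obs.sum())), inv] = 1.0
            fit = fit_mixed_ml(y_obs, x, {"smooth": zs, "subject": z})
            age_new = cohort.loc[need, "age"].to_numpy()
            xf_new, zs_new = sp.transform(age_new)
            pred = (
                fit.coef[0]
                + xf_new.ravel() * fit.coef[1]
                + zs_new @ fit.random_effects("smooth")
            )
            # subject BLUPs where the subject contributed observed PDS
            blup = dict(zip(subjects, fit.random_effects("subject")))
            pred = pred + np.array(
                [blup.get(s, 0.0) for s in cohort.loc[need, "subject_id"]]
            )
        cohort.loc[need, "pds"] = np.clip(pred, 1.0, 4.0)
        cohort.loc[need, "pds_imputed"] = True
    n_imp = int(cohort["pds_imputed"].sum())
    if n_imp:
        logger.info("imputed %d PDS value(s)", n_imp)
    return cohort


# ---------------------------------------------------------------------------
# design construction


def _subject_matrix(cohort: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    subjects, inv = np.unique(cohort["subject_id"].to_numpy(), return_inverse=True)
    z = np.zeros((len(cohort), subjects.size))
    z[np.arange(len(cohort)), inv] = 1.0
    return z, subjects


def _base_covariates(cohort: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    fd = cohort["mean_fd"].to_numpy(dtype=float)
    coil = (cohort["coil"].to_numpy() == "32ch").astype(float)
    cols, names = [fd], ["mean_fd"]
    if np.ptp(coil) > 0:
        cols.append(coil)
        names.append("coil_32ch")
    else:
        logger.info("coil covariate dropped: single level present")
    return np.column_stack(cols), names


def _build_design(cohort: pd.DataFrame, name: str) -> dict:
    """Fixed matrix, random blocks and developmental-term bookkeeping
    for one model of the battery."""
    n = len(cohort)
    age = cohort["age"].to_numpy(dtype=float)
    pds = cohort["pds"].to_numpy(dtype=float)
    sex_m = (cohort["sex"].to_numpy() == "M").astype(float)
    cov, cov_names = _base_covariates(cohort)
    z_sub, subjects = _subject_matrix(cohort)

    cols = [np.ones((n, 1))]
    names = ["intercept"]
    blocks: dict[str, np.ndarray] = {}
    dev_fixed: list[int] = []
    dev_blocks: list[str] = []
    is_gamm = name.startswith("GAMM")

    def add(colmat, colnames, dev=False):
        start = sum(c.shape[1] for c in cols)
        cols.append(np.atleast_2d(colmat.T).T if colmat.ndim == 1 else colmat)
        names.extend(colnames)
        if dev:
            dev_fixed.extend(range(start, start + (1 if colmat.ndim == 1 else colmat.shape[1])))

    if name == "LME-Age":
        add(age[:, None], ["age"], dev=True)
    elif name == "LME-Age.Sex":
        add(age[:, None], ["age"], dev=True)
        add(sex_m[:, None], ["sex_M"])
        add((age * sex_m)[:, None], ["age:sex_M"], dev=True)
    elif name in ("GAMM-Age", "GAMM-PDS"):
        xvar = age if name == "GAMM-Age" else pds
        sp = PSpline1D(k=SMOOTH_BASIS_DIM).fit(xvar)
        xf, zs = sp.transform(xvar)
        add(xf, [f"s({name[5:].lower()})_lin"], dev=True)
        blocks["smooth"] = zs
        dev_blocks.append("smooth")
    elif name in ("GAMM-Age.Sex", "GAMM-PDS.Sex"):
        xvar = age if "Age" in name else pds
        add(sex_m[:, None], ["sex_M"])
        sp = PSpline1D(k=SMOOTH_BASIS_DIM).fit(xvar)
        xf, zs = sp.transform(xvar)
        for label, ind in (("F", 1.0 - sex_m), ("M", sex_m)):
            add(xf * ind[:, None], [f"s_lin_{label}"], dev=True)
            blocks[f"smooth_{label}"] = zs * ind[:, None]
            dev_blocks.append(f"smooth_{label}")
    elif name == "GAMM-AgePDS":
        ts = TensorSpline2D(ka=TENSOR_BASIS_DIM, kb=TENSOR_BASIS_DIM).fit(age, pds)
        xf, zparts = ts.transform(age, pds)
        add(xf, ["te_age", "te_pds", "te_agepds"], dev=True)
        for i, z in enumerate(zparts, 1):
            blocks[f"tensor{i}"] = z
            dev_blocks.append(f"tensor{i}")
    elif name == "GAMM-AgePDS.Sex":
        add(sex_m[:, None], ["sex_M"])
        ts = TensorSpline2D(ka=TENSOR_BASIS_DIM, kb=TENSOR_BASIS_DIM).fit(age, pds)
        xf, zparts = ts.transform(age, pds)
        for label, ind in (("F", 1.0 - sex_m), ("M", sex_m)):
            add(
                xf * ind[:, None],
                [f"te_age_{label}", f"te_pds_{label}", f"te_agepds_{label}"],
                dev=True,
            )
        # per-sex coefficient sets; each tensor component's smoothing
        # parameter is shared across sexes to keep the optimizer low-dim
        for i, z in enumerate(zparts, 1):
            blocks[f"tensor{i}"] = np.hstack(
                [z * (1.0 - sex_m)[:, None], z * sex_m[:, None]]
            )
            dev_blocks.append(f"tensor{i}")
    else:
        raise ValueError(f"unknown model name {name!r}; valid: {MODEL_NAMES}")

    add(cov, cov_names)
    x = np.hstack(cols)
    blocks["subject"] = z_sub
    return {
        "x": x,
        "names": names,
        "blocks": blocks,
        "dev_fixed": dev_fixed,
        "dev_blocks": dev_blocks,
        "subjects": subjects,
        "is_gamm": is_gamm,
    }


def _finish_fit(name: str, response: str, y, design, fit: MixedFit) -> FitResult:
    n = y.size
    p_fixed = design["x"].shape[1]
    n_smooth_params = len([b for b in design["blocks"] if b != "subject"])
    if design["is_gamm"]:
        # effective parameters of the smooth: edf1 charges for
        # smoothing-parameter adaptivity, keeping nested richer smooths
        # from winning on noise
        smooth_edf = float(
            sum(fit.edf1_col[fit.col_slices[b]].sum() for b in design["dev_blocks"])
        )
        k = p_fixed + smooth_edf + 2 + n_smooth_params
        test = smooth_term_test(fit, design["dev_fixed"], design["dev_blocks"])
    else:
        k = p_fixed + 2
        test = linear_term_test(fit, design["dev_fixed"])
    aic = 2.0 * k - 2.0 * fit.loglik
    resid = fit.residuals
    re_hat = fit.random_effects("subject")
    sw_resid_p = float(shapiro(resid).pvalue) if np.ptp(resid) > 0 else 1.0
    sw_re_p = float(shapiro(re_hat).pvalue) if np.ptp(re_hat) > 0 else 1.0
    return FitResult(
        name=name,
        response=response,
        loglik=float(fit.loglik),
        k=float(k),
        aic=float(aic),
        fixed_effects=dict(zip(design["names"], fit.coef[: p_fixed])),
        edf=float(test["edf"]),
        f_stat=float(test["F"]),
        p_value=float(test["p"]),
        sw_resid_p=sw_resid_p,
        sw_re_p=sw_re_p,
        converged=fit.converged,
        n_obs=n,
        fit=fit,
    )


def fit_trajectory_model(
    y: np.ndarray, cohort: pd.DataFrame, name: str, response: str = "response"
) -> FitResult:
    """Fit one named model of the battery to a response vector."""
    y = np.asarray(y, dtype=float).ravel()
    if y.size != len(cohort):
        raise ValueError("response length must match cohort rows")
    design = _build_design(cohort, name)
    fit = fit_mixed_ml(y, design["x"], design["blocks"])
    if not fit.converged:
        logger.warning("model %s did not converge cleanly", name)
    return _finish_fit(name, response, y, design, fit)


def fit_lme(y, cohort, name: str = "LME-Age", response: str = "response") -> FitResult:
    if not name.startswith("LME"):
        raise ValueError("fit_lme expects an LME model name")
    return fit_trajectory_model(y, cohort, name, response)


def fit_gamm(y, cohort, name: str = "GAMM-PDS", response: str = "response") -> FitResult:
    if not name.startswith("GAMM"):
        raise ValueError("fit_gamm expects a GAMM model name")
    return fit_trajectory_model(y, cohort, name, response)


def model_selection(
    y: np.ndarray, cohort: pd.DataFrame, response: str = "response"
) -> dict:
    """Fit the full 8-model battery and pick the lowest-AIC model.

    Non-converged fits are reported but excluded from the argmin.
    """
    results: dict[str, FitResult] = {}
    for name in MODEL_NAMES:
        try:
            results[name] = fit_trajectory_model(y, cohort, name, response)
        except Exception as exc:  # keep battery going; record the failure
            logger.warning("model %s failed: %s", name, exc)
    usable = {k: v for k, v in results.items() if v.converged}
    if not usable:
        raise RuntimeError("no trajectory model converged")
    best = min(usable, key=lambda k: usable[k].aic)
    aic_table = pd.DataFrame(
        {
            "model": list(results),
            "aic": [results[k].aic for k in results],
            "loglik": [results[k].loglik for k in results],
            "k": [results[k].k for k in results],
            "sw_resid_p": [results[k].sw_resid_p for k in results],
            "sw_re_p": [results[k].sw_re_p for k in results],
            "converged": [results[k].converged for k in results],
        }
    )
    return {"fits": results, "best": best, "aic_table": aic_table,
            "best_fit": results[best]}


def fdr_bh(pvalues, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags, in input order."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def sample_intercept_curve(
    curves: np.ndarray, subject_ids, grid: np.ndarray
) -> pd.DataFrame:
    """Cohort-representative Betti curve: per filtration value, the fixed
    intercept of an intercept-only model with subject random intercepts
    (ML), with a +/-1.96 SE band."""
    curves = np.asarray(curves, dtype=float)
    if curves.ndim != 2:
        raise ValueError("curves must be (n_sessions, n_grid)")
    if curves.shape[0] != len(subject_ids):
        raise ValueError("subject_ids must align with curve rows")
    mu, se = intercept_with_subject_re(curves, np.asarray(subject_ids))
    return pd.DataFrame(
        {"grid": np.asarray(grid, dtype=float), "intercept": mu,
         "lo95": mu - 1.96 * se, "hi95": mu + 1.96 * se}
    )


def network_trajectories(
    features: pd.DataFrame,
    cohort: pd.DataFrame,
    responses: tuple[str, ...] = ("b0_auc", "b1_auc"),
    q: float = 0.05,
) -> dict:
    """Whole-brain model selection, per-network refits and FDR flags.

    ``features`` holds one row per session x network (column ``network``,
    whole brain labelled "ALL") and the response columns; ``cohort`` one
    row per session, aligned via ``session_id``.
    """
    cohort = validate_cohort(cohort)
    if cohort["pds"].isna().any():
        cohort = impute_pds(cohort)
    if "qc_pass" in cohort.columns:
        cohort = cohort[cohort["qc_pass"]].reset_index(drop=True)
    report: dict = {"q": q, "responses": {}}
    for response in responses:
        wide = features.pivot_table(
            index="session_id", columns="network", values=response
        )
        merged = cohort.merge(
            wide, left_on="session_id", right_index=True, how="inner"
        )
        if WHOLE_BRAIN not in merged.columns:
            raise ValueError("features must include the whole-brain 'ALL' rows")
        sel = model_selection(
            merged[WHOLE_BRAIN].to_numpy(dtype=float), merged, response
        )
        present = [n for n in NETWORKS if n in merged.columns]
        net_rows = []
        for net in present:
            fit = fit_trajectory_model(
                merged[net].to_numpy(dtype=float), merged, sel["best"], response
            )
            net_rows.append(
                {"network": net, "edf": fit.edf, "F": fit.f_stat, "p": fit.p_value}
            )
        net_table = pd.DataFrame(net_rows)
        net_table["significant"] = fdr_bh(net_table["p"].to_numpy(), q=q)
        report["responses"][response] = {
            "best_model": sel["best"],
            "aic_table": sel["aic_table"],
            "whole_brain": {
                "edf": sel["best_fit"].edf,
                "F": sel["best_fit"].f_stat,
                "p": sel["best_fit"].p_value,
            },
            "network_table": net_table,
        }
    return report
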