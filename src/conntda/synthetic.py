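"""Synthetic longitudinal cohorts with ground truth for recovery tests.

Emulates the statistical structure the analysis assumes: a cohort of
~98 children and adolescents (54% female, ages 6.7-18.1) with up to
three sessions (second after ~5 y in ~42% of subjects, third ~2 y later
in ~16%), pubertal status (PDS, ordinal 1-4) rising as a clipped
logistic in age with earlier onset in females, head motion declining
with age, a minority 32-channel-coil subset, and block-modular
connectomes whose fronto-parietal within-module connectivity varies
nonlinearly with PDS (rise from level 1 to 2, then a soft decline).

Two generation routes share the same ground truth: full per-session ROI
time series (for the connectome/TDA pipeline) and a direct per-session
feature table (for the model-recovery and calibration studies, where
thousands of replicates are needed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import NETWORKS, Parcellation, RoiTimeSeries

AGE_RANGE = (6.7, 18.1)
FEMALE_FRACTION = 0.54
SECOND_SESSION_FRACTION = 0.42
THIRD_SESSION_FRACTION = 0.16
FOLLOWUP1_YEARS = 5.0
FOLLOWUP2_YEARS = 2.0
PDS_MISSING_RATE = 0.05
COIL32_FRACTION = 0.13
QC_FAIL_FRACTION = 0.12

EFFECT_NETWORK = "FPN"


def peak_effect(pds: np.ndarray) -> np.ndarray:
    """Developmental effect shape g(PDS): linear rise from level 1 to a
    peak at level 2, then a soft linear decline toward level 4."""
    pds = np.asarray(pds, dtype=float)
    return np.where(pds <= 2.0, pds - 1.0, 1.0 - 0.25 * (pds - 2.0))


@dataclass
class GroundTruth:
    """Everything needed to score recovery of the generated effects."""

    seed: int
    subject_intercept_sd: float
    residual_sd: float
    effect_network: str
    effect_amplitude: float
    pds_midpoint_f: float
    pds_midpoint_m: float
    pds_slope: float
    module_of_network: dict[str, int]
    rho_within: float
    rho_between: float
    fpn_rho_base: float
    fpn_rho_amplitude: float
    subject_intercepts: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        return cls(**json.loads(text))


def _logistic_pds(age, midpoint, slope):
    return 1.0 + 3.0 / (1.0 + np.exp(-(age - midpoint) / slope))


def simulate_cohort(
    n_subjects: int = 98,
    seed: int = 0,
    effect_network: str = EFFECT_NETWORK,
    effect_amplitude: float = 2.0,
    subject_intercept_sd: float = 0.5,
    residual_sd: float = 0.5,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Longitudinal cohort table plus its generating ground truth.

    PDS is the ordinal rounding of a clipped logistic in age (midpoint
    one year earlier for females) plus noise; sessions under age 10 are
    forced to level 1 and ~5% of entries are masked missing. Mean
    framewise displacement is lognormal and declines with age; ~13% of
    sessions use the 32-channel coil; ~12% fail motion QC.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    rng = np.random.default_rng(seed)
    gt = GroundTruth(
        seed=int(seed),
        subject_intercept_sd=subject_intercept_sd,
        residual_sd=residual_sd,
        effect_network=effect_network,
        effect_amplitude=effect_amplitude,
        pds_midpoint_f=11.5,
        pds_midpoint_m=12.5,
        pds_slope=1.1,
        module_of_network=_default_modules(),
        rho_within=0.35,
        rho_between=0.08,
        fpn_rho_base=0.30,
        fpn_rho_amplitude=0.15,
    )
    lo, hi = AGE_RANGE
    subjects = [f"sub{i:03d}" for i in range(n_subjects)]
    sex = np.where(rng.random(n_subjects) < FEMALE_FRACTION, "F", "M")
    age0 = rng.uniform(lo, hi, n_subjects)
    gt.subject_intercepts = {
        s: float(v)
        for s, v in zip(subjects, rng.normal(0.0, subject_intercept_sd, n_subjects))
    }

    # returners drawn among subjects young enough that follow-ups stay
    # inside the printed age range
    gap1 = FOLLOWUP1_YEARS + rng.normal(0.0, 0.3, n_subjects)
    gap2 = FOLLOWUP2_YEARS + rng.normal(0.0, 0.2, n_subjects)
    eligible2 = np.flatnonzero(age0 + gap1 <= hi)
    n2 = min(int(round(SECOND_SESSION_FRACTION * n_subjects)), eligible2.size)
    returners2 = rng.choice(eligible2, size=n2, replace=False)
    eligible3 = returners2[age0[returners2] + gap1[returners2] + gap2[returners2] <= hi]
    n3 = min(int(round(THIRD_SESSION_FRACTION * n_subjects)), eligible3.size)
    returners3 = rng.choice(eligible3, size=n3, replace=False)

    rows = []
    for i, subj in enumerate(subjects):
        ages = [age0[i]]
        if i in returners2:
            ages.append(age0[i] + gap1[i])
        if i in returners3:
            ages.append(age0[i] + gap1[i] + gap2[i])
        for k, age in enumerate(ages):
            mid = gt.pds_midpoint_f if sex[i] == "F" else gt.pds_midpoint_m
            pds_latent = _logistic_pds(age, mid, gt.pds_slope) + rng.normal(0.0, 0.2)
            pds = float(np.clip(np.round(pds_latent), 1, 4))
            if age < 10.0:
                pds = 1.0
            mean_fd = float(
                np.exp(math.log(0.14) - 0.05 * (age - 12.0) + rng.normal(0.0, 0.35))
            )
            rows.append(
                {
                    "subject_id": subj,
                    "session_index": k + 1,
                    "session_id": f"{subj}_s{k + 1}",
                    "age": float(age),
                    "sex": sex[i],
                    "pds": pds,
                    "mean_fd": mean_fd,
                    "coil": "32ch" if rng.random() < COIL32_FRACTION else "8ch",
                    "qc_pass": True,
                }
            )
    cohort = pd.DataFrame(rows)
    # motion-linked QC failures: the highest-FD sessions fail most often
    fd_rank = cohort["mean_fd"].rank(pct=True).to_numpy()
    p_fail = QC_FAIL_FRACTION * 2.0 * fd_rank  # mean = QC_FAIL_FRACTION
    cohort["qc_pass"] = rng.random(len(cohort)) >= p_fail
    # mask some PDS entries missing
    mask = rng.random(len(cohort)) < PDS_MISSING_RATE
    cohort.loc[mask, "pds"] = np.nan
    return cohort, gt


def _default_modules() -> dict[str, int]:
    """Network -> covariance-module map: the effect-carrying
    fronto-parietal network is its own module; the other 12 networks are
    grouped into 3 composite modules."""
    modules = {EFFECT_NETWORK: 0}
    others = [n for n in NETWORKS if n != EFFECT_NETWORK]
    for i, net in enumerate(others):
        modules[net] = 1 + i % 3
    return modules


def make_parcellation(n_rois: int = 264) -> Parcellation:
    """Round-robin assignment of ``n_rois`` ROIs to the 13 networks."""
    if n_rois < 3 * len(NETWORKS):
        raise ValueError("need at least 3 ROIs per network")
    roi_ids = [f"roi{i:03d}" for i in range(n_rois)]
    network = [NETWORKS[i % len(NETWORKS)] for i in range(n_rois)]
    return Parcellation(roi_ids=roi_ids, network=sorted(network, key=NETWORKS.index))


def session_correlation(
    gt: GroundTruth,
    session: pd.Series | dict,
    parcellation: Parcellation,
) -> np.ndarray:
    """Ground-truth ROI correlation matrix for one session: block
    structure over modules, with the effect network's within-block
    correlation modulated by g(PDS) plus the subject intercept."""
    nets = np.asarray(parcellation.network)
    module = np.asarray([gt.module_of_network[n] for n in nets])
    n = nets.size
    r = np.full((n, n), gt.rho_between)
    same = module[:, None] == module[None, :]
    r[same] = gt.rho_within
    pds = float(session["pds"]) if not pd.isna(session["pds"]) else 1.0
    b = gt.subject_intercepts.get(str(session["subject_id"]), 0.0)
    rho_fpn = gt.fpn_rho_base + gt.fpn_rho_amplitude * (
        gt.effect_amplitude * float(peak_effect(pds)) + 0.3 * b
    )
    rho_fpn = float(np.clip(rho_fpn, 0.02, 0.9))
    eff = nets == gt.effect_network
    blk = np.outer(eff, eff)
    r[blk & same] = rho_fpn
    np.fill_diagonal(r, 1.0)
    return r


def _nearest_psd(r: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    lam, u = np.linalg.eigh(r)
    if lam.min() >= floor:
        return r
    lam = np.clip(lam, floor, None)
    r2 = (u * lam) @ u.T
    d = np.sqrt(np.diag(r2))
    r2 = r2 / np.outer(d, d)
    np.fill_diagonal(r2, 1.0)
    return r2


def simulate_session_timeseries(
    gt: GroundTruth,
    session: pd.Series | dict,
    parcellation: Parcellation,
    t: int = 150,
    tr: float = 2.0,
    obs_noise_sd: float = 0.1,
    rng: np.random.Generator | None = None,
) -> RoiTimeSeries:
    """Multivariate-normal ROI time series drawn from the session's
    ground-truth block correlation matrix, plus white observation noise."""
    if rng is None:
        rng = np.random.default_rng(gt.seed)
    r = session_correlation(gt, session, parcellation)
    r = _nearest_psd(r)
    lam, u = np.linalg.eigh(r)
    lam = np.clip(lam, 0.0, None)
    root = u * np.sqrt(lam)
    z = rng.standard_normal((t, r.shape[0]))
    data = z @ root.T + obs_noise_sd * rng.standard_normal((t, r.shape[0]))
    return RoiTimeSeries(data=data, tr=tr, roi_ids=list(parcellation.roi_ids))


def simulate_motion_trace(
    mean_fd: float, t: int = 150, tr: float = 2.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Per-volume FD draws (lognormal) with the requested mean."""
    if rng is None:
        rng = np.random.default_rng(0)
    sigma = 0.6
    mu = math.log(max(mean_fd, 1e-4)) - 0.5 * sigma ** 2
    return rng.lognormal(mu, sigma, t)


def simulate_features(
    cohort: pd.DataFrame,
    gt: GroundTruth,
    rng: np.random.Generator | None = None,
    fd_slope: float = -1.0,
    coil_shift: float = 0.2,
    responses: tuple[str, ...] = ("b0_auc", "b1_auc"),
) -> pd.DataFrame:
    """Per-session, per-network feature table drawn directly from the
    ground-truth effect model (fast route for recovery studies):

        y = mu + amp * g(PDS) [effect network and whole brain only]
              + b_subject + beta_fd * FD + coil shift + noise.
    """
    if rng is None:
        rng = np.random.default_rng(gt.seed + 1)
    pds = cohort["pds"].to_numpy(dtype=float)
    g = peak_effect(np.where(np.isnan(pds), 1.0, pds))
    b = cohort["subject_id"].map(gt.subject_intercepts).fillna(0.0).to_numpy()
    fd = cohort["mean_fd"].to_numpy(dtype=float)
    coil = (cohort["coil"].to_numpy() == "32ch").astype(float)
    rows = []
    for label in ("ALL", *NETWORKS):
        carries = label in ("ALL", gt.effect_network)
        base = b + fd_slope * fd + coil_shift * coil
        for resp in responses:
            eff = gt.effect_amplitude * g if carries else 0.0
            vals = (
                10.0
                + eff
                + base
                + rng.normal(0.0, gt.residual_sd, len(cohort))
            )
            for sid, v in zip(cohort["session_id"], vals):
                rows.append({"session_id": sid, "network": label, "response": resp, "value": v})
    out = pd.DataFrame(rows).pivot_table(
        index=["session_id", "network"], columns="response", values="value"
    ).reset_index()
    out.columns.name = None
    return out


def generate_dataset(
    outdir: str | Path,
    n_subjects: int = 30,
    n_rois: int = 60,
    t: int = 150,
    tr: float = 2.0,
    seed: int = 0,
    effect_amplitude: float = 2.0,
) -> Path:
    """Write a complete on-disk dataset consumable by the pipeline:
    cohort TSV, parcellation TSV, per-session time-series and FD files,
    and the ground truth as JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort, gt = simulate_cohort(
        n_subjects=n_subjects, seed=seed, effect_amplitude=effect_amplitude
    )
    parc = make_parcellation(n_rois)
    rng = np.random.default_rng(seed + 1)
    ts_dir = outdir / "timeseries"
    fd_dir = outdir / "motion"
    ts_dir.mkdir(exist_ok=True)
    fd_dir.mkdir(exist_ok=True)
    for _, session in cohort.iterrows():
        ts = simulate_session_timeseries(gt, session, parc, t=t, tr=tr, rng=rng)
        df = pd.DataFrame(ts.data, columns=ts.roi_ids)
        df.to_csv(ts_dir / f"{session['session_id']}.tsv", sep="\t", index=False)
        fdvals = simulate_motion_trace(session["mean_fd"], t=t, tr=tr, rng=rng)
        np.savetxt(fd_dir / f"{session['session_id']}.txt", fdvals, fmt="%.6f")
    cohort.to_csv(outdir / "cohort.tsv", sep="\t", index=False)
    pd.DataFrame({"roi_id": parc.roi_ids, "network": parc.network}).to_csv(
        outdir / "parcellation.tsv", sep="\t", index=False
    )
    (outdir / "ground_truth.json").write_text(gt.to_json())
    (outdir / "meta.json").write_text(
        json.dumps({"n_subjects": n_subjects, "n_rois": n_rois, "t": t,
                    "tr": tr, "seed": seed}, indent=2)
    )
    return outdir
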