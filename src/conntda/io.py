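"""Delimited-text readers and writers for the pipeline's artifacts.

Everything is plain TSV (plus JSON sidecars) so that datasets, feature
tables, diagrams and reports stay diffable and portable.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import Connectome, DistanceMatrix, MotionTrace, Parcellation, RoiTimeSeries
from .nulls import NullEnsemble
from .tda import PersistenceDiagram


def read_timeseries(path: str | Path, tr: float) -> RoiTimeSeries:
    df = pd.read_csv(path, sep="\t")
    return RoiTimeSeries(data=df.to_numpy(dtype=float), tr=tr, roi_ids=list(df.columns))


def write_timeseries(ts: RoiTimeSeries, path: str | Path) -> None:
    pd.DataFrame(ts.data, columns=ts.roi_ids).to_csv(path, sep="\t", index=False)


def _read_square(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), list(df.columns)


def read_connectome(path: str | Path) -> Connectome:
    m, ids = _read_square(path)
    return Connectome(r=m, roi_ids=ids)


def write_connectome(c: Connectome, path: str | Path) -> None:
    pd.DataFrame(c.r, index=c.roi_ids, columns=c.roi_ids).to_csv(
        path, sep="\t", float_format="%.17g"
    )


def read_distance(path: str | Path) -> DistanceMatrix:
    m, ids = _read_square(path)
    return DistanceMatrix(d=m, roi_ids=ids)


def write_distance(d: DistanceMatrix, path: str | Path) -> None:
    pd.DataFrame(d.d, index=d.roi_ids, columns=d.roi_ids).to_csv(
        path, sep="\t", float_format="%.17g"
    )


def read_parcellation(path: str | Path) -> Parcellation:
    df = pd.read_csv(path, sep="\t")
    return Parcellation(
        roi_ids=list(df["roi_id"].astype(str)), network=list(df["network"])
    )


def write_parcellation(p: Parcellation, path: str | Path) -> None:
    pd.DataFrame({"roi_id": p.roi_ids, "network": p.network}).to_csv(
        path, sep="\t", index=False
    )


def read_motion(path: str | Path, tr: float) -> MotionTrace:
    fd = np.loadtxt(path, ndmin=1)
    return MotionTrace(fd=fd, tr=tr)


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["pds"] = pd.to_numeric(df["pds"], errors="coerce")
    if "qc_pass" in df.columns:
        df["qc_pass"] = df["qc_pass"].astype(bool)
    return df


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, sep="\t", index=False)


def write_diagram(pd_: PersistenceDiagram, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("dim\tbirth\tdeath\n")
        for dim, birth, death in pd_.intervals:
            dstr = "inf" if math.isinf(death) else f"{death:.17g}"
            fh.write(f"{dim}\t{birth:.17g}\t{dstr}\n")


def read_diagram(
    path: str | Path, maxscale: float, n_points: int = 0
) -> PersistenceDiagram:
    intervals = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            dim, birth, death = line.split("\t")
            intervals.append(
                (int(dim), float(birth), math.inf if death.strip() == "inf" else float(death))
            )
    return PersistenceDiagram(intervals=intervals, maxscale=maxscale, n_points=n_points)


def write_ensemble(ens: NullEnsemble, stem: str | Path) -> None:
    stem = Path(stem)
    pd.DataFrame(
        {"grid": ens.grid, "mean": ens.mean_curve, "lo95": ens.lo95, "hi95": ens.hi95}
    ).to_csv(stem.with_suffix(".tsv"), sep="\t", index=False)
    stem.with_suffix(".json").write_text(
        json.dumps({"n_boot": ens.n_boot, "seed": ens.seed, "dim": ens.dim}, indent=2)
    )
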