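"""File I/O: rupture-sample CSV dialect, fit reports, occupancy tables.

The on-disk rupture-sample format is plain CSV with a mandatory header
``event_id,force_pN,time_s,D_um,delta_nm,censored`` (decimal point, no
locale variants).  Censored events carry empty force/time fields and
``censored=True``.  Fit reports and provenance sidecars are JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .beads import DnaOccupancy
from .fitting import FitResult
from .simulate import RuptureSample

__all__ = [
    "RUPTURE_CSV_COLUMNS",
    "write_rupture_csv",
    "read_rupture_csv",
    "write_json",
    "read_json",
    "fit_report_dict",
    "write_occupancy_csv",
    "read_occupancy_csv",
    "occupancy_from_table",
]

RUPTURE_CSV_COLUMNS = ["event_id", "force_pN", "time_s", "D_um", "delta_nm", "censored"]


def write_rupture_csv(sample: RuptureSample, path: str | Path) -> None:
    """Write a rupture sample in the package CSV dialect."""
    if sample.events is not None:
        df = sample.events[RUPTURE_CSV_COLUMNS]
    else:
        df = pd.DataFrame(
            {
                "event_id": np.arange(sample.n),
                "force_pN": sample.forces_pn,
                "time_s": np.nan,
                "D_um": np.nan,
                "delta_nm": np.nan,
                "censored": False,
            }
        )
    df.to_csv(path, index=False)


def read_rupture_csv(path: str | Path) -> RuptureSample:
    """Read a rupture sample; raises with row/column context on bad input."""
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: no rupture events (empty table)")
    missing = [c for c in ("force_pN",) if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if "censored" not in df.columns:
        df["censored"] = False
    df["censored"] = df["censored"].astype(bool)
    bad = df.index[~df["censored"] & ~np.isfinite(df["force_pN"].astype(float))]
    if len(bad):
        raise ValueError(
            f"{path}: non-numeric or missing force_pN in uncensored row(s) "
            f"{list(bad[:5])} (column 'force_pN')"
        )
    forces = df.loc[~df["censored"], "force_pN"].to_numpy(dtype=float)
    for col in RUPTURE_CSV_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan if col != "event_id" else np.arange(len(df))
    return RuptureSample(
        forces_pn=forces,
        n_censored=int(df["censored"].sum()),
        events=df[RUPTURE_CSV_COLUMNS],
    )


def write_json(obj: dict[str, Any], path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path) -> dict[str, Any]:
    return json.loads(Path(path).read_text())


def fit_report_dict(
    fit: FitResult, extra: dict[str, Any] | None = None
) -> dict[str, Any]:
    """JSON-serialisable fit report (parameters, CIs, objective, seeds)."""
    rep = dataclasses.asdict(fit)
    for key in ("ci90_k0", "ci90_delta"):
        if rep[key] is not None:
            rep[key] = list(rep[key])
    if extra:
        rep.update(extra)
    return rep


def write_occupancy_csv(table: pd.DataFrame, path: str | Path) -> None:
    table[["dna_id", "position_um"]].to_csv(path, index=False)


def read_occupancy_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("dna_id", "position_um"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    return df


def occupancy_from_table(table: pd.DataFrame, n_dna: int | None = None) -> list[DnaOccupancy]:
    """Convert an occupancy table into per-DNA position lists.

    ``n_dna`` (default: max dna_id + 1) controls how many zero-occupancy
    DNAs are represented: DNAs absent from the table get empty position
    arrays, so sampling from the returned list reproduces the empirical
    occupancy distribution including unoccupied molecules.
    """
    groups = {int(k): v["position_um"].to_numpy() for k, v in table.groupby("dna_id")}
    if n_dna is None:
        n_dna = (max(groups) + 1) if groups else 0
    return [
        DnaOccupancy(positions_um=groups.get(i, np.empty(0))) for i in range(n_dna)
    ]
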