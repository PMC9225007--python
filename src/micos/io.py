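"""Table and parameter I/O.

Trajectory tables travel as tidy CSV with one row per sample × time:
``sample_id,time_h,<species codes...>,butyrate_mM,lactate_mM,acetate_mM,
succinate_mM`` — the same schema as the deposited experimental dataset.
Missing metabolites are empty fields.  gLV parameter sets are a single YAML
document with the third-order tensor stored as a sparse (i, j, k, value)
list.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import DEFAULT_POOL, METABOLITES, CommunityDesign, GLVParams, TrajectoryTable

_MET_COLS = [f"{m}_mM" for m in METABOLITES]


def tables_to_frame(tables: list[TrajectoryTable]) -> pd.DataFrame:
    rows = []
    for tb in tables:
        for ti, t in enumerate(tb.times):
            row: dict[str, object] = {"sample_id": tb.sample_id, "time_h": t}
            for si, sp in enumerate(tb.design.pool):
                row[sp] = tb.X[ti, si]
            if tb.C is not None:
                for mi, mc in enumerate(_MET_COLS):
                    row[mc] = tb.C[ti, mi]
            else:
                for mc in _MET_COLS:
                    row[mc] = np.nan
            rows.append(row)
    return pd.DataFrame(rows)


def write_trajectories(tables: list[TrajectoryTable], path: str | Path) -> None:
    tables_to_frame(tables).to_csv(path, index=False)


def read_trajectories(path: str | Path,
                      pool: tuple[str, ...] | None = None) -> list[TrajectoryTable]:
    df = pd.read_csv(path)
    for col in ("sample_id", "time_h"):
        if col not in df.columns:
            raise ValueError(f"malformed trajectory CSV: missing column {col!r}")
    if pool is None:
        pool = tuple(c for c in df.columns
                     if c not in ("sample_id", "time_h") and c not in _MET_COLS)
    missing = [sp for sp in pool if sp not in df.columns]
    if missing:
        raise ValueError(f"malformed trajectory CSV: missing species columns {missing}")
    has_mets = all(c in df.columns for c in _MET_COLS)
    tables = []
    for sid, grp in df.groupby("sample_id", sort=False):
        grp = grp.sort_values("time_h")
        X = grp[list(pool)].to_numpy(dtype=float)
        if not np.all(np.isfinite(X)):
            bad = np.argwhere(~np.isfinite(X))[0]
            raise ValueError(f"malformed trajectory CSV: non-finite abundance for "
                             f"sample {sid!r}, row {bad[0]}, species {pool[bad[1]]}")
        present = tuple(int(np.any(X[:, i] > 0)) for i in range(len(pool)))
        design = CommunityDesign(present, tuple(pool))
        C = None
        if has_mets:
            C_raw = grp[_MET_COLS].to_numpy(dtype=float)
            if not np.all(np.isnan(C_raw)):
                C = C_raw
        tables.append(TrajectoryTable(sample_id=str(sid), design=design,
                                      times=grp["time_h"].to_numpy(dtype=float),
                                      X=X, C=C))
    return tables


def write_glv_params(params: GLVParams, path: str | Path) -> None:
    doc: dict[str, object] = {
        "n_species": params.n_species,
        "r": params.r.tolist(),
        "A": params.A.tolist(),
    }
    if params.B is not None:
        idx = np.argwhere(params.B != 0.0)
        doc["B"] = [[int(i), int(j), int(k), float(params.B[i, j, k])]
                    for i, j, k in idx]
    Path(path).write_text(yaml.safe_dump(doc))


def read_glv_params(path: str | Path) -> GLVParams:
    doc = yaml.safe_load(Path(path).read_text())
    n = int(doc["n_species"])
    B = None
    if "B" in doc:
        B = np.zeros((n, n, n))
        for i, j, k, v in doc["B"]:
            B[i, j, k] = v
    return GLVParams(r=np.array(doc["r"]), A=np.array(doc["A"]), B=B)


def write_designs(designs: list[CommunityDesign], path: str | Path,
                  labels: list[str] | None = None) -> None:
    pool = designs[0].pool
    rows = []
    for di, d in enumerate(designs):
        row: dict[str, object] = {"design_id": f"D{di:04d}"}
        row.update({sp: p for sp, p in zip(pool, d.present)})
        if labels is not None:
            row["group"] = labels[di]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_designs(path: str | Path,
                 pool: tuple[str, ...] | None = None) -> list[CommunityDesign]:
    df = pd.read_csv(path)
    if pool is None:
        pool = tuple(c for c in df.columns if c in DEFAULT_POOL) or tuple(
            c for c in df.columns if c not in ("design_id", "group"))
    return [CommunityDesign(tuple(int(row[sp]) for sp in pool), tuple(pool))
            for _, row in df.iterrows()]
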