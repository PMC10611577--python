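"""Tabular readers/writers: confound TSVs, behavior CSVs, cluster tables.

Column dialect for motion confounds: ``trans_x, trans_y, trans_z`` in mm
and ``rot_x, rot_y, rot_z`` in radians, one row per volume, tab-separated
with a header row.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ShapeMismatchError

MOTION_COLUMNS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]


def write_motion_tsv(params: np.ndarray, path: str | Path) -> None:
    p = np.asarray(params, dtype=float)
    if p.ndim != 2 or p.shape[1] != 6:
        raise ShapeMismatchError("motion parameters must be T x 6")
    pd.DataFrame(p, columns=MOTION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_motion_tsv(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MOTION_COLUMNS if c not in df.columns]
    if missing:
        raise ShapeMismatchError(f"motion table missing columns {missing}")
    return df[MOTION_COLUMNS].to_numpy(dtype=float)


def write_behavior_csv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_behavior_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_cluster_tsv(clusters: list[dict], path: str | Path) -> None:
    rows = []
    for c in clusters:
        row = {
            "size": c["size"],
            "peak_i": c["peak_ijk"][0],
            "peak_j": c["peak_ijk"][1],
            "peak_k": c["peak_ijk"][2],
            "peak_stat": c["peak_stat"],
        }
        if "peak_world_mm" in c:
            row["peak_x_mm"], row["peak_y_mm"], row["peak_z_mm"] = c["peak_world_mm"]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
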