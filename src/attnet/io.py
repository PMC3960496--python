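"""Reading and writing the pipeline's plain-text formats.

Everything tabular is TSV with a header row; motion parameter files use
the 6-column-per-frame realignment dialect (three rotations in radians,
then three translations in mm — the MCFLIRT ``.par`` column order).
Schema violations are reported with row numbers.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix, RoiTimeSeriesMatrix
from .inference import CohortDesign
from .motion import RealignmentTrace

__all__ = [
    "load_node_table",
    "read_node_table",
    "write_node_table",
    "read_timeseries",
    "write_timeseries",
    "read_motion_params",
    "write_motion_params",
    "read_manifest",
    "write_manifest",
    "read_connectivity",
    "write_connectivity",
    "write_ground_truth",
    "read_ground_truth",
]

_NODE_COLUMNS = ["label", "hemisphere", "x_mni_mm", "y_mni_mm", "z_mni_mm",
                 "radius_mm", "peak_z"]


def load_node_table() -> pd.DataFrame:
    """The packaged 68-ROI visual-attention node table (MNI mm, peak Z)."""
    with resources.files("attnet.data").joinpath(
        "visual_attention_nodes.tsv"
    ).open() as fh:
        return _validate_node_table(pd.read_csv(fh, sep="\t"))


def _validate_node_table(tab: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _NODE_COLUMNS if c not in tab.columns]
    if missing:
        raise ValueError(f"node table missing columns: {missing}")
    if tab["label"].duplicated().any():
        dups = tab.loc[tab["label"].duplicated(), "label"].tolist()
        raise ValueError(f"duplicate node labels: {dups}")
    return tab


def read_node_table(path: str | Path) -> pd.DataFrame:
    return _validate_node_table(pd.read_csv(path, sep="\t"))


def write_node_table(tab: pd.DataFrame, path: str | Path) -> None:
    _validate_node_table(tab).to_csv(path, sep="\t", index=False)


def read_timeseries(path: str | Path, tr: float, subject_id: str | None = None
                    ) -> RoiTimeSeriesMatrix:
    """Read a nodes x frames TSV (node ids as row labels, frames as columns)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = df.to_numpy()
    if values.dtype == object or not np.issubdtype(values.dtype, np.number):
        for row_num, (_, row) in enumerate(df.iterrows(), start=2):
            if pd.to_numeric(row, errors="coerce").isna().any():
                raise ValueError(f"{path}: non-numeric or missing cell at line {row_num}")
    if df.isna().any().any():
        bad = int(np.argwhere(df.isna().to_numpy())[0][0]) + 2
        raise ValueError(f"{path}: missing value at line {bad}")
    sid = subject_id if subject_id is not None else Path(path).stem
    return RoiTimeSeriesMatrix(list(df.index.astype(str)), values.astype(float), tr, sid)


def write_timeseries(ts: RoiTimeSeriesMatrix, path: str | Path) -> None:
    df = pd.DataFrame(ts.data, index=ts.node_ids,
                      columns=[f"frame_{i}" for i in range(ts.n_frames)])
    df.index.name = "node"
    df.to_csv(path, sep="\t", float_format="%.8g")


def read_motion_params(path: str | Path, subject_id: str | None = None
                       ) -> RealignmentTrace:
    """Read a 6-column realignment file: rotations (rad) then translations (mm)."""
    rows = []
    with open(path) as fh:
        for line_num, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6:
                raise ValueError(
                    f"{path}: expected 6 columns at line {line_num}, got {len(parts)}"
                )
            try:
                rows.append([float(v) for v in parts])
            except ValueError as err:
                raise ValueError(f"{path}: non-numeric value at line {line_num}") from err
    arr = np.asarray(rows)
    sid = subject_id if subject_id is not None else Path(path).stem
    return RealignmentTrace(rotations=arr[:, :3], translations=arr[:, 3:], subject_id=sid)


def write_motion_params(trace: RealignmentTrace, path: str | Path) -> None:
    np.savetxt(path, trace.parameters, fmt="%.8g")


def read_manifest(path: str | Path) -> CohortDesign:
    """Read the cohort manifest TSV into a validated design table."""
    return CohortDesign(pd.read_csv(path, sep="\t"))


def write_manifest(design: CohortDesign, path: str | Path) -> None:
    design.table.to_csv(path, sep="\t", index=False)


def read_connectivity(path: str | Path, subject_id: str | None = None
                      ) -> ConnectivityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index.astype(str)) != [str(c) for c in df.columns]:
        raise ValueError(f"{path}: row and column node ids disagree")
    return ConnectivityMatrix(list(df.index.astype(str)), df.to_numpy(dtype=float),
                              subject_id)


def write_connectivity(conn: ConnectivityMatrix, path: str | Path) -> None:
    df = pd.DataFrame(conn.values, index=conn.node_ids, columns=conn.node_ids)
    df.index.name = "node"
    df.to_csv(path, sep="\t", float_format="%.8g")


def write_ground_truth(truth, path: str | Path) -> None:
    payload = {
        "planted_edges": [list(e) for e in truth.planted_edges],
        "group_assignment": truth.group_assignment,
        "effect_size": truth.effect_size,
        "covariance_control": np.asarray(truth.covariance_control).tolist(),
        "covariance_patient": np.asarray(truth.covariance_patient).tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ground_truth(path: str | Path) -> dict:
    payload = json.loads(Path(path).read_text())
    payload["planted_edges"] = [tuple(e) for e in payload["planted_edges"]]
    payload["covariance_control"] = np.asarray(payload["covariance_control"])
    payload["covariance_patient"] = np.asarray(payload["covariance_patient"])
    return payload
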