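"""Reading and writing the pipeline's file artifacts.

Traces travel as delimited text with one header row of ROI labels, one row
per frame and one column per cell — the layout microscope software exports.
Ensemble results and comparisons are serialized as JSON so that round trips
are lossless and machine-checkable.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd


@dataclasses.dataclass
class TraceMatrix:
    """Raw fluorescence per frame per ROI, with acquisition metadata.

    ``values`` has shape (n_frames, n_cells) in arbitrary fluorescence
    units; ``frame_period`` is the seconds elapsed between frames;
    ``cell_ids`` are the ordered ROI labels.
    """

    values: np.ndarray
    frame_period: float = 5.0
    cell_ids: Optional[list[str]] = None
    fov_id: str = "fov"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D frames x cells array")
        if self.values.shape[0] < 1 or self.values.shape[1] < 1:
            raise ValueError("need at least 1 frame and 1 cell")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace values must be finite")
        if self.frame_period <= 0:
            raise ValueError("frame_period must be > 0")
        if self.cell_ids is None:
            width = max(3, len(str(self.values.shape[1])))
            self.cell_ids = [f"cell_{i:0{width}d}" for i in range(self.values.shape[1])]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if len(self.cell_ids) != self.values.shape[1]:
            raise ValueError("cell_ids length must match number of columns")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate ROI labels")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]


def read_trace_table(
    path: str | Path,
    frame_period: float = 5.0,
    transpose: bool = False,
    fov_id: Optional[str] = None,
) -> TraceMatrix:
    """Read a delimited fluorescence table into a :class:`TraceMatrix`.

    The first row is a header of ROI labels; each following row is one
    frame.  ``transpose=True`` accepts the opposite orientation (rows =
    ROIs).  Non-numeric cells raise an error naming the offending row and
    column; ragged or empty tables are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"trace table not found: {path}")
    with open(path, newline="") as fh:
        rows = [row for row in csv.reader(fh) if row and any(f.strip() for f in row)]
    if not rows:
        raise ValueError(f"empty table: {path}")
    header = [h.strip() for h in rows[0]]
    if len(set(header)) != len(header):
        raise ValueError(f"duplicate ROI labels in {path}")
    body = rows[1:]
    if not body:
        raise ValueError(f"empty table (header only): {path}")
    n_col = len(header)
    values = np.empty((len(body), n_col), dtype=float)
    for i, row in enumerate(body):
        if len(row) != n_col:
            raise ValueError(
                f"ragged rows in {path}: row {i + 2} has {len(row)} fields, "
                f"expected {n_col}"
            )
        for j, field in enumerate(row):
            try:
                values[i, j] = float(field)
            except ValueError:
                raise ValueError(
                    f"non-numeric value {field!r} at row {i + 2}, "
                    f"column {header[j]!r} in {path}"
                ) from None
    if transpose:
        values = values.T
        cell_ids = [f"cell_{i:03d}" for i in range(values.shape[1])]
    else:
        cell_ids = header
    return TraceMatrix(
        values=values,
        frame_period=frame_period,
        cell_ids=cell_ids,
        fov_id=fov_id if fov_id is not None else path.stem,
    )


def write_trace_table(traces: TraceMatrix, path: str | Path) -> None:
    """Write a trace matrix as delimited text (full float precision)."""
    df = pd.DataFrame(traces.values, columns=traces.cell_ids)
    df.to_csv(path, index=False, float_format="%.17g")


def write_matrix_table(
    values: np.ndarray, columns: Sequence[str], path: str | Path
) -> None:
    """Write any frames x cells matrix (ΔF/F, spike probability) as text."""
    pd.DataFrame(np.asarray(values), columns=list(columns)).to_csv(
        path, index=False, float_format="%.17g"
    )


# ---------------------------------------------------------------------------
# Ensemble reports


def write_ensemble_report(result, path: str | Path) -> None:
    """Serialize an :class:`~calnet.ensembles.EnsembleSet` to JSON.

    The report carries the ensemble count, per-ensemble frames and member
    lists, core ensembles, the binarization/co-activity thresholds, and the
    shuffle-null summary; reading it back reproduces every count.
    """
    from .ensembles import summarize_ensembles  # local import, avoids cycle

    summary = summarize_ensembles(result)
    null = result.null
    payload = {
        "n_ensembles": summary["n_ensembles"],
        "mean_cells_per_ensemble": summary["mean_cells_per_ensemble"],
        "n_core_ensembles": summary["n_core_ensembles"],
        "mean_cells_per_core": summary["mean_cells_per_core"],
        "coactivity_threshold": result.coactivity_threshold,
        "ensembles": [
            {
                "frames": list(map(int, e.frames)),
                "members": [result.cell_ids[m] for m in e.members]
                if result.cell_ids
                else list(map(int, e.members)),
                "member_indices": list(map(int, e.members)),
            }
            for e in result.ensembles
        ],
        "core_ensembles": [
            {
                "cells": [result.cell_ids[m] for m in c.cells]
                if result.cell_ids
                else list(map(int, c.cells)),
                "cell_indices": list(map(int, c.cells)),
                "parents": list(map(int, c.parents)),
            }
            for c in result.core_ensembles
        ],
        "null_summary": None
        if null is None
        else {
            "n_shuffles": null.n_shuffles,
            "alpha": null.alpha,
            "seed": null.seed,
            "shuffle_mode": null.shuffle_mode,
            "null_mode": null.null_mode,
            "no_activity": null.no_activity,
            "tail_p": {str(c): p for c, p in null.tail_p.items()},
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def read_ensemble_report(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# Spine record tables


def write_spine_table(table, path: str | Path) -> None:
    """Write a :class:`~calnet.spines.SpineRecordTable` as delimited text.

    One row per spine; dendrites without spines contribute one row with an
    empty ``spine_length_um`` field so the dendrite survives a round trip.
    """
    table.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_spine_table(path: str | Path):
    from .spines import SpineRecordTable

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"spine table not found: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    return SpineRecordTable.from_frame(df)


def write_json(payload: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
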