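"""Background subtraction, saturated-cell exclusion and ΔF/F conversion.

ΔF/F uses a causal sliding baseline: at each frame the baseline is the mean
of the lower half of the values in the previous 10 frames, so slow offsets
divide out while transients (which occupy the upper half of the window) do
not drag the baseline up.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Optional, Union

import numpy as np
import pandas as pd

from .io import TraceMatrix

logger = logging.getLogger(__name__)

SATURATED_REASON = "saturated-range"


@dataclasses.dataclass
class PreprocessedTraces:
    """ΔF/F traces of kept cells plus the exclusion log and per-cell summaries."""

    dff: np.ndarray  # (n_frames, n_kept)
    kept_cell_ids: list[str]
    excluded: dict[str, str]  # cell_id -> reason
    baseline_median: np.ndarray  # per kept cell, raw-intensity units
    intensity_range: np.ndarray  # per kept cell, max - min
    frame_period: float = 5.0


def subtract_background(
    traces: TraceMatrix, background: Union[float, np.ndarray]
) -> TraceMatrix:
    """Subtract a scalar or per-frame background; clip negatives to zero.

    Background is measured in cell-free areas of the field of view and
    applies to every ROI.  Clipped entries are counted and logged.
    """
    bg = np.asarray(background, dtype=float)
    if not np.all(np.isfinite(bg)):
        raise ValueError("background must be finite")
    if bg.ndim == 0:
        sub = traces.values - bg
    elif bg.ndim == 1:
        if bg.shape[0] != traces.n_frames:
            raise ValueError(
                f"per-frame background length {bg.shape[0]} != "
                f"{traces.n_frames} frames"
            )
        sub = traces.values - bg[:, None]
    else:
        raise ValueError("background must be a scalar or per-frame series")
    n_clipped = int(np.sum(sub < 0))
    if n_clipped:
        logger.info("background subtraction clipped %d negative values to 0", n_clipped)
    return TraceMatrix(
        values=np.clip(sub, 0.0, None),
        frame_period=traces.frame_period,
        cell_ids=list(traces.cell_ids),
        fov_id=traces.fov_id,
    )


def saturation_mask(traces: TraceMatrix, exclusion_fraction: float = 0.10) -> np.ndarray:
    """Boolean mask of excluded cells: min(F) >= (1 - f) * max(F).

    Such cells spend the whole recording within ``exclusion_fraction`` of
    their maximum — saturated or silent at a fixed level — and carry no
    usable transient.  Constant cells always satisfy the rule.
    """
    lo = traces.values.min(axis=0)
    hi = traces.values.max(axis=0)
    return lo >= (1.0 - exclusion_fraction) * hi


def exclude_saturated_cells(
    traces: TraceMatrix, exclusion_fraction: float = 0.10
) -> tuple[TraceMatrix, dict[str, str]]:
    """Drop saturated-range cells; return kept traces and the exclusion log."""
    mask = saturation_mask(traces, exclusion_fraction)
    excluded = {cid: SATURATED_REASON for cid, m in zip(traces.cell_ids, mask) if m}
    if mask.all():
        raise ValueError("all cells excluded by the saturated-range rule")
    kept = TraceMatrix(
        values=traces.values[:, ~mask],
        frame_period=traces.frame_period,
        cell_ids=[c for c, m in zip(traces.cell_ids, mask) if not m],
        fov_id=traces.fov_id,
    )
    return kept, excluded


def compute_dff(
    traces: TraceMatrix, window: int = 10, lower_fraction: float = 0.5
) -> np.ndarray:
    """Sliding lower-half-baseline ΔF/F.

    For frame t (0-based) with w = min(window, t) previous frames, the
    baseline is the mean of the floor(w * lower_fraction) smallest values
    among those w frames (at least one value), and
    dff_t = (F_t - baseline_t) / baseline_t.  The first frame, having no
    previous frames, gets dff = 0; early frames use the shortened window
    rather than being discarded.

    Raises if any baseline is exactly zero, naming the cell and frame —
    add a small offset upstream if raw traces can reach zero.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if not 0.0 < lower_fraction <= 1.0:
        raise ValueError("lower_fraction must be in (0, 1]")
    F = traces.values
    T, N = F.shape
    dff = np.zeros((T, N), dtype=float)
    for t in range(1, T):
        w = min(window, t)
        k = max(1, math.floor(w * lower_fraction))
        window_vals = np.sort(F[t - w : t], axis=0)
        baseline = window_vals[:k].mean(axis=0)
        zero = baseline == 0
        if np.any(zero):
            cell = traces.cell_ids[int(np.argmax(zero))]
            raise ValueError(f"zero baseline for cell {cell!r} at frame {t}")
        dff[t] = (F[t] - baseline) / baseline
    return dff


def summarize_cells(traces: TraceMatrix) -> pd.DataFrame:
    """Per-cell distribution summaries of the raw (background-subtracted) traces.

    ``baseline_median`` is the median fluorescence over all frames (the
    resting level); ``intensity_range`` is max - min (the ΔF range).  These
    are the quantities whose relative-frequency distributions are compared
    between groups.
    """
    values = traces.values
    return pd.DataFrame(
        {
            "baseline_median": np.median(values, axis=0),
            "intensity_range": values.max(axis=0) - values.min(axis=0),
        },
        index=pd.Index(traces.cell_ids, name="cell_id"),
    )


def preprocess_traces(
    traces: TraceMatrix,
    background: Union[float, np.ndarray] = 0.0,
    window: int = 10,
    lower_fraction: float = 0.5,
    exclusion_fraction: float = 0.10,
    dff_offset: Optional[float] = None,
) -> PreprocessedTraces:
    """Full preprocessing chain: subtract, exclude, summarize, convert to ΔF/F.

    The exclusion rule runs after background subtraction, and the per-cell
    summaries are computed on the background-subtracted traces of kept
    cells only.  ``dff_offset`` (default: 1% of the global maximum) is
    added before ΔF/F conversion to keep baselines strictly positive; it
    cancels out of the summaries, which use the unshifted traces.
    """
    sub = subtract_background(traces, background)
    kept, excluded = exclude_saturated_cells(sub, exclusion_fraction)
    summary = summarize_cells(kept)
    if dff_offset is None:
        dff_offset = 0.01 * max(float(kept.values.max()), 1e-12)
    shifted = TraceMatrix(
        values=kept.values + dff_offset,
        frame_period=kept.frame_period,
        cell_ids=list(kept.cell_ids),
        fov_id=kept.fov_id,
    )
    dff = compute_dff(shifted, window=window, lower_fraction=lower_fraction)
    return PreprocessedTraces(
        dff=dff,
        kept_cell_ids=list(kept.cell_ids),
        excluded=excluded,
        baseline_median=summary["baseline_median"].to_numpy(),
        intensity_range=summary["intensity_range"].to_numpy(),
        frame_period=traces.frame_period,
    )
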