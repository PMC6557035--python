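"""Dendritic-spine inclusion criteria and density quantification.

Two measurement contexts are supported.  "ex-vivo" dendrites are apical
shafts in brain sections: the whole dendrite must have a 2–4 µm shaft and
at least 100 µm of discernible segment, and spines must protrude at least
0.4 µm and be separated from neighboring dendrites.  "in-vitro" records
are distal-neurite segments of cultured neurons, where spines are
protrusions 0.4–10 µm long (a fixed 20 µm segment makes density simply
count x 0.5).  Density is spines per 10 µm of segment; the animal (not the
dendrite) is the statistical unit for group comparisons.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Optional

import numpy as np
import pandas as pd

MIN_PROTRUSION_UM = 0.4
MAX_LENGTH_IN_VITRO_UM = 10.0
SHAFT_WIDTH_RANGE_UM = (2.0, 4.0)
MIN_SEGMENT_EX_VIVO_UM = 100.0

# rejection reason codes
BELOW_MIN = "below-0.4"
ABOVE_MAX = "above-10"
SEPARATION = "separation"
DENDRITE_SHAFT = "dendrite-shaft-width"
DENDRITE_SHORT = "dendrite-segment-short"


@dataclasses.dataclass
class Spine:
    length: float  # µm
    marker_positive: bool = False
    separation_ok: bool = True  # >= 4 µm from a neighboring dendrite (measured upstream)

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("spine length must be > 0")


@dataclasses.dataclass
class SpineRecord:
    dendrite_id: str
    animal_id: str
    context: str  # "ex-vivo" | "in-vitro"
    segment_length: float  # µm
    shaft_width: Optional[float] = None  # µm, ex vivo only
    spines: list[Spine] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        if self.context not in ("ex-vivo", "in-vitro"):
            raise ValueError("context must be 'ex-vivo' or 'in-vitro'")
        if self.segment_length <= 0:
            raise ValueError("segment_length must be > 0")


@dataclasses.dataclass
class SpineRecordTable:
    records: list[SpineRecord]

    def to_frame(self) -> pd.DataFrame:
        """Flatten to one row per spine (zero-spine dendrites keep one row)."""
        rows = []
        for r in self.records:
            base = {
                "dendrite_id": r.dendrite_id,
                "animal_id": r.animal_id,
                "context": r.context,
                "segment_length_um": r.segment_length,
                "shaft_width_um": r.shaft_width,
            }
            if not r.spines:
                rows.append({**base, "spine_length_um": np.nan,
                             "marker_positive": np.nan, "separation_ok": np.nan})
            for s in r.spines:
                rows.append({**base, "spine_length_um": s.length,
                             "marker_positive": s.marker_positive,
                             "separation_ok": s.separation_ok})
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SpineRecordTable":
        records = []
        for dendrite_id, grp in df.groupby("dendrite_id", sort=False):
            first = grp.iloc[0]
            shaft = first.get("shaft_width_um")
            spines = [
                Spine(
                    length=float(row["spine_length_um"]),
                    marker_positive=bool(row["marker_positive"]),
                    separation_ok=bool(row["separation_ok"]),
                )
                for _, row in grp.iterrows()
                if pd.notna(row["spine_length_um"])
            ]
            records.append(
                SpineRecord(
                    dendrite_id=str(dendrite_id),
                    animal_id=str(first["animal_id"]),
                    context=str(first["context"]),
                    segment_length=float(first["segment_length_um"]),
                    shaft_width=None if pd.isna(shaft) else float(shaft),
                    spines=spines,
                )
            )
        return cls(records)


@dataclasses.dataclass
class FilteredDendrite:
    record: SpineRecord
    dendrite_rejected: Optional[str]  # reason code, or None if eligible
    valid: list[Spine]
    rejected: list[tuple[Spine, str]]


@dataclasses.dataclass
class DensityResult:
    """Per-dendrite density summary after filtering."""

    dendrite_id: str
    animal_id: str
    density: float  # valid spines per 10 µm
    marker_density: float  # marker-positive valid spines per 10 µm
    mean_length: float  # µm, over valid spines (nan when none)
    n_valid_spines: int
    n_rejected: int
    rejection_reasons: dict[str, int]


def filter_spines(record: SpineRecord) -> FilteredDendrite:
    """Apply the inclusion criteria to one dendrite.

    Ex vivo: the dendrite is rejected wholly when the shaft width falls
    outside 2–4 µm or the segment is shorter than 100 µm; individual spines
    are rejected when shorter than 0.4 µm or failing the 4-µm separation
    flag.  In vitro: spines outside 0.4–10 µm are rejected.
    """
    if record.context == "ex-vivo":
        if record.shaft_width is None:
            raise ValueError(
                f"ex-vivo dendrite {record.dendrite_id!r} lacks shaft_width"
            )
        if not SHAFT_WIDTH_RANGE_UM[0] <= record.shaft_width <= SHAFT_WIDTH_RANGE_UM[1]:
            return FilteredDendrite(record, DENDRITE_SHAFT, [],
                                    [(s, DENDRITE_SHAFT) for s in record.spines])
        if record.segment_length < MIN_SEGMENT_EX_VIVO_UM:
            return FilteredDendrite(record, DENDRITE_SHORT, [],
                                    [(s, DENDRITE_SHORT) for s in record.spines])
    valid: list[Spine] = []
    rejected: list[tuple[Spine, str]] = []
    for s in record.spines:
        if s.length < MIN_PROTRUSION_UM:
            rejected.append((s, BELOW_MIN))
        elif record.context == "in-vitro" and s.length > MAX_LENGTH_IN_VITRO_UM:
            rejected.append((s, ABOVE_MAX))
        elif record.context == "ex-vivo" and not s.separation_ok:
            rejected.append((s, SEPARATION))
        else:
            valid.append(s)
    return FilteredDendrite(record, None, valid, rejected)


def spine_density(n_valid: int, segment_length: float) -> float:
    """Spines per 10 µm: count / length x 10.

    For the fixed 20 µm in-vitro segment this reduces to count x 0.5.
    """
    if segment_length <= 0:
        raise ValueError("segment_length must be > 0")
    return n_valid / segment_length * 10.0


def compute_densities(table: SpineRecordTable) -> pd.DataFrame:
    """Filter every dendrite and tabulate per-dendrite densities.

    Wholly rejected dendrites are omitted from the density table (they do
    not enter any average) but appear in :func:`rejection_log`.
    """
    rows = []
    for record in table.records:
        filt = filter_spines(record)
        if filt.dendrite_rejected is not None:
            continue
        reasons: dict[str, int] = {}
        for _, why in filt.rejected:
            reasons[why] = reasons.get(why, 0) + 1
        n_valid = len(filt.valid)
        n_marker = sum(s.marker_positive for s in filt.valid)
        rows.append(
            dataclasses.asdict(
                DensityResult(
                    dendrite_id=record.dendrite_id,
                    animal_id=record.animal_id,
                    density=spine_density(n_valid, record.segment_length),
                    marker_density=spine_density(n_marker, record.segment_length),
                    mean_length=float(np.mean([s.length for s in filt.valid]))
                    if filt.valid
                    else float("nan"),
                    n_valid_spines=n_valid,
                    n_rejected=len(filt.rejected),
                    rejection_reasons=reasons,
                )
            )
        )
    return pd.DataFrame(rows)


def rejection_log(table: SpineRecordTable) -> pd.DataFrame:
    """One row per rejected dendrite or spine, with its reason code."""
    rows = []
    for record in table.records:
        filt = filter_spines(record)
        if filt.dendrite_rejected is not None:
            rows.append({"dendrite_id": record.dendrite_id, "level": "dendrite",
                         "reason": filt.dendrite_rejected, "spine_length_um": np.nan})
            continue
        for spine, why in filt.rejected:
            rows.append({"dendrite_id": record.dendrite_id, "level": "spine",
                         "reason": why, "spine_length_um": spine.length})
    return pd.DataFrame(rows, columns=["dendrite_id", "level", "reason", "spine_length_um"])


def summarize_group(
    tables: SpineRecordTable | Iterable[SpineRecordTable],
) -> dict:
    """Per-animal-first group summary.

    Densities and spine lengths are averaged within each animal, then
    across animals; the animal is the statistical unit, so the group n is
    the number of animals.  Returns the per-animal table plus group mean
    and SEM of density and mean spine length.
    """
    if isinstance(tables, SpineRecordTable):
        tables = [tables]
    records = [r for t in tables for r in t.records]
    densities = compute_densities(SpineRecordTable(records))
    if densities.empty:
        raise ValueError("no eligible dendrites in group")
    per_animal = densities.groupby("animal_id").agg(
        density=("density", "mean"),
        marker_density=("marker_density", "mean"),
        mean_length=("mean_length", "mean"),
        n_dendrites=("dendrite_id", "count"),
    )
    n = len(per_animal)
    def _sem(x: pd.Series) -> float:
        return float(x.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return {
        "per_animal": per_animal,
        "n_animals": n,
        "mean_density": float(per_animal["density"].mean()),
        "sem_density": _sem(per_animal["density"]),
        "mean_marker_density": float(per_animal["marker_density"].mean()),
        "sem_marker_density": _sem(per_animal["marker_density"]),
        "mean_length": float(per_animal["mean_length"].mean()),
        "sem_length": _sem(per_animal["mean_length"]),
    }
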