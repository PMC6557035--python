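"""Network-ensemble detection from binarized spike probabilities.

A cell is "active" in a frame when its spike probability exceeds 3 SD
(taken about zero) of the pooled population values.  Each cell's activity
is then shuffled across frames 1000 times to build a null distribution of
per-frame co-activity; the smallest co-active count that is significant at
p < 0.05 becomes the threshold, and every frame reaching it is a
high-activity frame whose active cells form one network ensemble.  Core
ensembles are the maximal cell groups shared by more than one ensemble.

Two null modes are provided.  ``"max"`` (default) thresholds on the upper
tail of the per-shuffle *maximum* co-activity, controlling the family-wise
chance of any false high-activity frame across the recording at alpha.
``"pooled"`` thresholds on the pooled per-frame shuffled distribution; it
is the literal per-frame reading of "p < 0.05" but, applied to every frame
of a recording, lets through about T * alpha false frames.
"""

from __future__ import annotations

import dataclasses
from itertools import combinations
from typing import Optional, Sequence

import numpy as np

from .deconvolution import SpikeProbabilityMatrix

_SHUFFLE_CHUNK = 200  # shuffles per vectorized block; bounds memory


@dataclasses.dataclass
class BinaryRaster:
    """Thresholded activity raster with the threshold that produced it."""

    active: np.ndarray  # (n_frames, n_cells) 0/1
    threshold_value: float
    sd_multiplier: float
    cell_ids: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.active = np.asarray(self.active)
        if not np.isin(self.active, (0, 1)).all():
            raise ValueError("raster must be 0/1")
        self.active = self.active.astype(np.uint8)
        if self.threshold_value < 0:
            raise ValueError("threshold_value must be >= 0")


@dataclasses.dataclass
class NullSummary:
    """Shuffle-null summary: tail probabilities and the chosen threshold."""

    coactivity_threshold: Optional[int]
    tail_p: dict[int, float]  # candidate count -> null P(co-activity >= count)
    n_shuffles: int
    alpha: float
    seed: Optional[int]
    shuffle_mode: str
    null_mode: str
    no_activity: bool = False


@dataclasses.dataclass
class Ensemble:
    frames: tuple[int, ...]
    members: tuple[int, ...]


@dataclasses.dataclass
class CoreEnsemble:
    cells: tuple[int, ...]
    parents: tuple[int, ...]


@dataclasses.dataclass
class EnsembleSet:
    """Detected ensembles, derived core ensembles and the null behind them."""

    ensembles: list[Ensemble]
    core_ensembles: list[CoreEnsemble]
    coactivity_threshold: Optional[int]
    null: Optional[NullSummary]
    cell_ids: Optional[list[str]] = None
    n_frames: int = 0


def binarize(
    spikes: SpikeProbabilityMatrix | np.ndarray,
    sd_multiplier: float = 3.0,
    sd_mode: str = "rms",
    cell_ids: Optional[list[str]] = None,
) -> BinaryRaster:
    """Threshold spike probabilities at ``sd_multiplier`` population SDs.

    The SD is pooled over every value in the matrix.  ``sd_mode="rms"``
    takes it about zero (root mean square), the literal "3 SD above zero";
    ``"mean"`` takes the conventional SD about the pooled mean.  Activity
    is strict: value > threshold, so an all-zero matrix stays all-zero.
    """
    if isinstance(spikes, SpikeProbabilityMatrix):
        values = spikes.values
        cell_ids = cell_ids if cell_ids is not None else spikes.cell_ids
    else:
        values = np.asarray(spikes, dtype=float)
    if values.min() < 0 or values.max() > 1:
        raise ValueError("spike probabilities must lie in [0, 1]")
    if sd_mode == "rms":
        sd = float(np.sqrt(np.mean(values**2)))
    elif sd_mode == "mean":
        sd = float(values.std())
    else:
        raise ValueError("sd_mode must be 'rms' or 'mean'")
    threshold = sd_multiplier * sd
    return BinaryRaster(
        active=(values > threshold).astype(np.uint8),
        threshold_value=threshold,
        sd_multiplier=sd_multiplier,
        cell_ids=cell_ids,
    )


def _shuffled_coactivity(
    active: np.ndarray, n_shuffles: int, rng: np.random.Generator, mode: str
) -> np.ndarray:
    """Per-frame co-activity counts for shuffled rasters, shape (n_shuffles, T).

    ``"permute"`` independently permutes each cell's activity across frames
    (preserving its total active count, destroying co-activity and
    autocorrelation); ``"circular"`` rolls each cell by a random offset,
    preserving autocorrelation as well.
    """
    T, N = active.shape
    counts = np.empty((n_shuffles, T), dtype=np.int32)
    for start in range(0, n_shuffles, _SHUFFLE_CHUNK):
        m = min(_SHUFFLE_CHUNK, n_shuffles - start)
        if mode == "permute":
            block = np.broadcast_to(active, (m, T, N)).copy()
            rng.permuted(block, axis=1, out=block)
        elif mode == "circular":
            shifts = rng.integers(0, T, size=(m, N))
            idx = (np.arange(T)[None, :, None] - shifts[:, None, :]) % T
            block = np.take_along_axis(np.broadcast_to(active, (m, T, N)), idx, axis=1)
        else:
            raise ValueError("shuffle mode must be 'permute' or 'circular'")
        counts[start : start + m] = block.sum(axis=2, dtype=np.int32)
    return counts


def shuffle_null(
    raster: BinaryRaster,
    n_shuffles: int = 1000,
    alpha: float = 0.05,
    seed: Optional[int] = None,
    shuffle_mode: str = "permute",
    null_mode: str = "max",
) -> NullSummary:
    """Build the shuffled co-activity null and pick the significance threshold.

    The threshold is the smallest candidate count c >= 2 whose null tail
    probability P(co-activity >= c) falls below ``alpha``.  In ``"pooled"``
    mode the tail is over all shuffled frames; in ``"max"`` mode it is over
    the per-shuffle maximum co-activity.  A raster with no active entries
    has no defined threshold (``no_activity`` marker).
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    active = raster.active
    T, N = active.shape
    if active.sum() == 0:
        return NullSummary(None, {}, n_shuffles, alpha, seed, shuffle_mode,
                           null_mode, no_activity=True)
    rng = np.random.default_rng(seed)
    counts = _shuffled_coactivity(active, n_shuffles, rng, shuffle_mode)
    if null_mode == "pooled":
        pool = counts.ravel()
    elif null_mode == "max":
        pool = counts.max(axis=1)
    else:
        raise ValueError("null_mode must be 'pooled' or 'max'")
    hist = np.bincount(pool, minlength=N + 2)
    tail = hist[::-1].cumsum()[::-1] / pool.size  # tail[c] = P(count >= c)
    tail_p = {c: float(tail[c]) for c in range(2, N + 1)}
    threshold = None
    for c in range(2, N + 2):
        p = float(tail[c]) if c < tail.size else 0.0
        if p < alpha:
            threshold = c
            break
    return NullSummary(
        coactivity_threshold=threshold,
        tail_p=tail_p,
        n_shuffles=n_shuffles,
        alpha=alpha,
        seed=seed,
        shuffle_mode=shuffle_mode,
        null_mode=null_mode,
    )


def detect_ensembles(
    raster: BinaryRaster,
    coactivity_threshold: int,
    null: Optional[NullSummary] = None,
) -> EnsembleSet:
    """Collect high-activity frames into ensembles.

    Every frame whose co-active count reaches ``coactivity_threshold``
    (floored at 2 — a single active cell is never an ensemble) yields one
    ensemble of that frame's active cells; consecutive significant frames
    with identical member sets are merged into a single event.
    """
    threshold = max(int(coactivity_threshold), 2)
    active = raster.active
    coactivity = active.sum(axis=1)
    ensembles: list[Ensemble] = []
    for t in np.flatnonzero(coactivity >= threshold):
        members = tuple(int(i) for i in np.flatnonzero(active[t]))
        if (
            ensembles
            and ensembles[-1].members == members
            and ensembles[-1].frames[-1] == t - 1
        ):
            ensembles[-1] = Ensemble(
                frames=ensembles[-1].frames + (int(t),), members=members
            )
        else:
            ensembles.append(Ensemble(frames=(int(t),), members=members))
    result = EnsembleSet(
        ensembles=ensembles,
        core_ensembles=[],
        coactivity_threshold=threshold,
        null=null,
        cell_ids=raster.cell_ids,
        n_frames=active.shape[0],
    )
    result.core_ensembles = find_core_ensembles(result)
    return result


def find_core_ensembles(ensembles: EnsembleSet | Sequence[Ensemble]) -> list[CoreEnsemble]:
    """Maximal cell groups co-activated in more than one ensemble.

    Every pairwise intersection of ensemble member sets with >= 2 cells is
    a candidate core; candidates that are strict subsets of another are
    dropped, and each surviving core records all ensembles containing it.
    """
    members = [
        frozenset(e.members)
        for e in (ensembles.ensembles if isinstance(ensembles, EnsembleSet) else ensembles)
    ]
    candidates: set[frozenset[int]] = set()
    for a, b in combinations(range(len(members)), 2):
        inter = members[a] & members[b]
        if len(inter) >= 2:
            candidates.add(inter)
    maximal = [
        c for c in candidates
        if not any(c < other for other in candidates)
    ]
    cores = [
        CoreEnsemble(
            cells=tuple(sorted(c)),
            parents=tuple(i for i, m in enumerate(members) if c <= m),
        )
        for c in maximal
    ]
    cores.sort(key=lambda c: (-len(c.cells), c.cells))
    return cores


def summarize_ensembles(result: EnsembleSet) -> dict:
    """Headline counts: ensembles, cells per ensemble, cores, cells per core."""
    sizes = [len(e.members) for e in result.ensembles]
    core_sizes = [len(c.cells) for c in result.core_ensembles]
    return {
        "n_ensembles": len(sizes),
        "mean_cells_per_ensemble": float(np.mean(sizes)) if sizes else 0.0,
        "n_core_ensembles": len(core_sizes),
        "mean_cells_per_core": float(np.mean(core_sizes)) if core_sizes else 0.0,
    }


def analyze_raster(
    raster: BinaryRaster,
    n_shuffles: int = 1000,
    alpha: float = 0.05,
    seed: Optional[int] = None,
    shuffle_mode: str = "permute",
    null_mode: str = "max",
) -> EnsembleSet:
    """Shuffle null + detection + core extraction in one call."""
    null = shuffle_null(
        raster, n_shuffles=n_shuffles, alpha=alpha, seed=seed,
        shuffle_mode=shuffle_mode, null_mode=null_mode,
    )
    if null.no_activity or null.coactivity_threshold is None:
        return EnsembleSet(
            ensembles=[], core_ensembles=[], coactivity_threshold=None,
            null=null, cell_ids=raster.cell_ids, n_frames=raster.active.shape[0],
        )
    return detect_ensembles(raster, null.coactivity_threshold, null=null)
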