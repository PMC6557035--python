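"""Synthetic recordings with planted co-activation ensembles.

The generator emulates the study conditions the analysis was designed for:
10-minute recordings sampled every 5 s (120 frames) from fields of view of
roughly 100–160 cells, sparse Poisson background firing, a handful of
scheduled multi-cell co-activation events, AR(1) calcium kinetics rendered
multiplicatively on a per-cell baseline, optional linear drift, and additive
Gaussian noise.  Ground truth (the spike raster and the event schedule) is
returned alongside, so every downstream stage can be scored against it.

A second generator produces tabular dendritic-spine records (Poisson spine
counts, log-normal spine lengths) for the spine-density module.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence, Union

import numpy as np
from scipy.signal import lfilter

from .io import TraceMatrix


@dataclasses.dataclass(frozen=True)
class EnsembleSpec:
    """One planted ensemble: a fixed member set co-activated at scheduled frames.

    ``participation_prob`` is the chance each member actually spikes at
    each of its ensemble's events.
    """

    member_count: int
    n_events: int = 1
    participation_prob: float = 1.0

    def __post_init__(self) -> None:
        if self.member_count < 2:
            raise ValueError("ensembles need at least 2 members")
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")
        if not 0.0 < self.participation_prob <= 1.0:
            raise ValueError("participation_prob must be in (0, 1]")


@dataclasses.dataclass
class SimulationConfig:
    """Forward-model parameters for one synthetic field of view.

    Defaults follow the recording protocol being emulated: 120 frames at
    5 s per frame, ~120 cells, sparse background firing (0.02 spikes per
    cell per frame ≈ one spontaneous event per cell per 4 min), baseline
    fluorescence 50 a.u. (the observed per-cell medians are a few tens of
    a.u.), a half-unit ΔF/F transient per spike, and noise at 1/10 of the
    single-spike fluorescence jump.  ``gamma_true`` defaults to
    exp(-frame_period / 2 s), a 2-s indicator decay sampled every 5 s.
    """

    n_cells: int = 120
    n_frames: int = 120
    frame_period: float = 5.0
    background_rate: float = 0.02
    ensembles: Sequence[EnsembleSpec] = ()
    calcium_amplitude: float = 0.5
    gamma_true: Optional[float] = None
    baseline_f0: Union[float, np.ndarray] = 50.0
    noise_sd: float = 2.5
    drift_slope: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.ensembles = tuple(
            e if isinstance(e, EnsembleSpec) else EnsembleSpec(*e)
            for e in self.ensembles
        )
        if self.n_cells < 1 or self.n_frames < 1:
            raise ValueError("n_cells and n_frames must be >= 1")
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")
        if self.gamma_true is not None and not 0.0 < self.gamma_true < 1.0:
            raise ValueError("gamma_true must be in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for e in self.ensembles:
            if e.member_count > self.n_cells:
                raise ValueError("ensemble member_count exceeds n_cells")
        total_events = sum(e.n_events for e in self.ensembles)
        if total_events > self.n_frames:
            raise ValueError(
                f"{total_events} scheduled events exceed {self.n_frames} frames"
            )

    @property
    def effective_gamma(self) -> float:
        if self.gamma_true is not None:
            return self.gamma_true
        return float(np.exp(-self.frame_period / 2.0))


@dataclasses.dataclass
class GroundTruth:
    """Planted spike raster and the ensemble-event schedule behind it."""

    spikes: np.ndarray  # (n_frames, n_cells) uint8
    ensemble_schedule: list[tuple[int, frozenset[int]]]
    member_sets: list[frozenset[int]]


def generate_spike_trains(
    config: SimulationConfig, seed: Optional[int] = None
) -> GroundTruth:
    """Draw background spikes and overlay scheduled ensemble co-activations.

    Background activity is independent Bernoulli(``background_rate``) per
    cell per frame.  Ensemble event frames are drawn without replacement
    (all events land on distinct frames); at each event every member of
    that ensemble spikes with probability ``participation_prob``.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    T, N = config.n_frames, config.n_cells
    spikes = (rng.random((T, N)) < config.background_rate).astype(np.uint8)

    total_events = sum(e.n_events for e in config.ensembles)
    event_frames = rng.choice(T, size=total_events, replace=False)
    schedule: list[tuple[int, frozenset[int]]] = []
    member_sets: list[frozenset[int]] = []
    pos = 0
    for spec in config.ensembles:
        members = np.sort(rng.choice(N, size=spec.member_count, replace=False))
        member_sets.append(frozenset(int(m) for m in members))
        for _ in range(spec.n_events):
            frame = int(event_frames[pos])
            pos += 1
            firing = members[rng.random(spec.member_count) < spec.participation_prob]
            spikes[frame, firing] = 1
            schedule.append((frame, frozenset(int(m) for m in firing)))
    schedule.sort(key=lambda fr: fr[0])
    return GroundTruth(spikes=spikes, ensemble_schedule=schedule, member_sets=member_sets)


def render_fluorescence(
    truth: GroundTruth, config: SimulationConfig, seed: Optional[int] = None
) -> TraceMatrix:
    """Render a spike raster into noisy fluorescence traces.

    Per cell the calcium state follows C_t = gamma * C_{t-1} + spike_t and
    fluorescence is F_t = F0 * (1 + a * C_t) + drift * t + eps_t with
    Gaussian noise eps; post-noise values are clipped at zero.  The
    multiplicative form makes the noiseless ground-truth ΔF/F equal to
    ``a * C_t`` regardless of the per-cell baseline F0.
    """
    spikes = np.asarray(truth.spikes, dtype=float)
    T, N = spikes.shape
    if (T, N) != (config.n_frames, config.n_cells):
        raise ValueError("spike raster shape does not match config")
    gamma = config.effective_gamma
    calcium = lfilter([1.0], [1.0, -gamma], spikes, axis=0)
    f0 = np.broadcast_to(np.asarray(config.baseline_f0, dtype=float), (N,))
    drift = config.drift_slope * np.arange(T, dtype=float)[:, None]
    values = f0[None, :] * (1.0 + config.calcium_amplitude * calcium) + drift
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed if seed is None else seed)
        values = values + rng.normal(0.0, config.noise_sd, size=(T, N))
    return TraceMatrix(
        values=np.clip(values, 0.0, None),
        frame_period=config.frame_period,
        fov_id="simulated",
    )


def simulate_recording(
    config: SimulationConfig, seed: Optional[int] = None
) -> tuple[GroundTruth, TraceMatrix]:
    """Generate ground truth and its rendered traces from one seed.

    Spike generation and noise rendering consume independent child streams
    of the seed, so the pair is reproducible as a unit.
    """
    base = config.seed if seed is None else seed
    ss = np.random.SeedSequence(base)
    spike_seed, noise_seed = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    truth = generate_spike_trains(config, seed=spike_seed)
    traces = render_fluorescence(truth, config, seed=noise_seed)
    return truth, traces


# ---------------------------------------------------------------------------
# Synthetic dendritic-spine records


def generate_spine_records(
    n_dendrites: int,
    mean_density: float,
    segment_length: float,
    context: str = "ex-vivo",
    seed: Optional[int] = None,
    *,
    marker_fraction: float = 0.15,
    length_median: float = 1.5,
    length_sigma: float = 0.35,
    animal_id: str = "animal_1",
    shaft_width_range: tuple[float, float] = (2.2, 3.8),
    id_prefix: str = "dend",
):
    """Generate a synthetic spine-record table for one animal.

    Spine counts per dendrite are Poisson(mean_density * length / 10);
    spine lengths are log-normal with median ``length_median`` (≈1.5 µm,
    matching the observed group means), truncated by rejection to the
    context's admissible range (0.4–10 µm).  Marker positivity (e.g. a
    postsynaptic-density stain) is Bernoulli(``marker_fraction``).
    """
    from .spines import Spine, SpineRecord, SpineRecordTable

    if mean_density < 0:
        raise ValueError("mean_density must be >= 0")
    if segment_length <= 0:
        raise ValueError("segment_length must be > 0")
    if context not in ("ex-vivo", "in-vitro"):
        raise ValueError("context must be 'ex-vivo' or 'in-vitro'")
    rng = np.random.default_rng(seed)
    lo, hi = 0.4, 10.0
    counts = rng.poisson(mean_density * segment_length / 10.0, size=n_dendrites)
    records = []
    for d, count in enumerate(counts):
        lengths = np.empty(0)
        while lengths.size < count:
            draw = rng.lognormal(np.log(length_median), length_sigma, size=max(count, 8))
            draw = draw[(draw >= lo) & (draw <= hi)]
            lengths = np.concatenate([lengths, draw])
        lengths = lengths[:count]
        spines = [
            Spine(
                length=float(x),
                marker_positive=bool(rng.random() < marker_fraction),
                separation_ok=True,
            )
            for x in lengths
        ]
        shaft = float(rng.uniform(*shaft_width_range)) if context == "ex-vivo" else None
        records.append(
            SpineRecord(
                dendrite_id=f"{id_prefix}_{d + 1:03d}",
                animal_id=animal_id,
                context=context,
                segment_length=float(segment_length),
                shaft_width=shaft,
                spines=spines,
            )
        )
    return SpineRecordTable(records)


def generate_spine_experiment(
    n_animals: int,
    dendrites_per_animal: int,
    mean_density: float,
    animal_sd: float,
    segment_length: float = 100.0,
    context: str = "ex-vivo",
    seed: Optional[int] = None,
    group_label: str = "group",
    **kwargs,
):
    """Generate a grouped spine dataset with between-animal variability.

    Each animal's true density is Normal(mean_density, animal_sd), floored
    at zero; its dendrites are then drawn with :func:`generate_spine_records`.
    Mirrors the published design of six analyzed dendrites per animal.
    """
    from .spines import SpineRecordTable

    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_animals + 1)]
    rng = np.random.default_rng(child_seeds[0])
    records = []
    for a in range(n_animals):
        density_a = max(0.0, rng.normal(mean_density, animal_sd))
        table_a = generate_spine_records(
            dendrites_per_animal,
            density_a,
            segment_length,
            context=context,
            seed=child_seeds[a + 1],
            animal_id=f"{group_label}_animal_{a + 1}",
            id_prefix=f"{group_label}_a{a + 1}",
            **kwargs,
        )
        records.extend(table_a.records)
    return SpineRecordTable(records)
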