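"""Run-level configuration for the network-ensemble pipeline.

All analysis stages share one :class:`RunConfig`.  The defaults are the
published protocol parameters: a 10-frame sliding window whose lower-50%
values define the ΔF/F baseline, a 10% saturated-cell exclusion rule, a
3-SD spike-probability threshold, and a 1000-shuffle co-activity null at
p < 0.05.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Optional

import yaml


@dataclasses.dataclass
class RunConfig:
    """Parameters controlling preprocessing, deconvolution and ensemble detection.

    Attributes
    ----------
    dff_window : int
        Number of previous frames over which the running ΔF/F baseline is
        taken (default 10).
    dff_lower_fraction : float
        Fraction of the window's smallest values averaged into the baseline
        (default 0.5, the "lower 50%" rule).
    exclusion_fraction : float
        A cell is excluded as saturated when its whole-recording range is
        within this fraction of its maximum, i.e. ``min >= (1 - f) * max``
        (default 0.10).
    sd_multiplier : float
        Spike-probability binarization threshold in population SDs above
        zero (default 3).
    n_shuffles : int
        Number of per-cell permutations building the co-activity null
        (default 1000).
    alpha : float
        Significance level for the co-activity threshold (default 0.05).
    gamma : float, optional
        AR(1) calcium decay per frame in (0, 1).  When None it is derived
        from the frame period as ``exp(-frame_period / tau)`` with an
        indicator decay constant tau = 2 s.
    sparsity_weight : float, optional
        L1 weight on inferred spike amplitudes; ``None`` selects the
        noise-scaled default 4/sigma per cell (an amplitude floor of four
        noise SDs).
    seed : int, optional
        Seed for every stochastic stage (shuffling, simulation).
    shuffle_mode : str
        "permute" (full per-cell permutation) or "circular" (random circular
        shift per cell, preserving autocorrelation).
    null_mode : str
        "max" (family-wise threshold from the per-shuffle maximum
        co-activity; default) or "pooled" (per-frame threshold from the
        pooled shuffled co-activity distribution).
    sd_mode : str
        "rms" (SD about zero, the literal "3 SD above zero") or "mean"
        (SD about the pooled mean).
    """

    dff_window: int = 10
    dff_lower_fraction: float = 0.5
    exclusion_fraction: float = 0.10
    sd_multiplier: float = 3.0
    n_shuffles: int = 1000
    alpha: float = 0.05
    gamma: Optional[float] = None
    sparsity_weight: Optional[float] = None
    seed: Optional[int] = None
    shuffle_mode: str = "permute"
    null_mode: str = "max"
    sd_mode: str = "rms"

    def __post_init__(self) -> None:
        if self.dff_window < 1:
            raise ValueError("dff_window must be >= 1")
        if not 0.0 < self.dff_lower_fraction <= 1.0:
            raise ValueError("dff_lower_fraction must be in (0, 1]")
        if not 0.0 <= self.exclusion_fraction < 1.0:
            raise ValueError("exclusion_fraction must be in [0, 1)")
        if self.sd_multiplier < 0:
            raise ValueError("sd_multiplier must be >= 0")
        if self.n_shuffles < 1:
            raise ValueError("n_shuffles must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.gamma is not None and not 0.0 < self.gamma < 1.0:
            raise ValueError("gamma must be in (0, 1)")
        if self.sparsity_weight is not None and self.sparsity_weight < 0:
            raise ValueError("sparsity_weight must be >= 0")
        if self.shuffle_mode not in ("permute", "circular"):
            raise ValueError("shuffle_mode must be 'permute' or 'circular'")
        if self.null_mode not in ("max", "pooled"):
            raise ValueError("null_mode must be 'max' or 'pooled'")
        if self.sd_mode not in ("rms", "mean"):
            raise ValueError("sd_mode must be 'rms' or 'mean'")

    def gamma_for(self, frame_period: float, tau: float = 2.0) -> float:
        """Effective AR(1) decay: explicit ``gamma`` or exp(-frame_period/tau)."""
        if self.gamma is not None:
            return self.gamma
        return math.exp(-frame_period / tau)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a config from a YAML or JSON file (keys mirror field names)."""
        text = Path(path).read_text()
        if str(path).endswith(".json"):
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} does not contain a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
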