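"""End-to-end analysis of one field of view from raw traces to ensembles."""

from __future__ import annotations

import dataclasses
from typing import Optional, Union

import numpy as np

from .config import RunConfig
from .deconvolution import DeconvolutionModel, SpikeProbabilityMatrix, deconvolve_matrix, to_spike_probability
from .ensembles import BinaryRaster, EnsembleSet, analyze_raster, binarize, summarize_ensembles
from .io import TraceMatrix
from .preprocess import PreprocessedTraces, preprocess_traces


@dataclasses.dataclass
class PipelineResult:
    preprocessed: PreprocessedTraces
    spikes: SpikeProbabilityMatrix
    raster: BinaryRaster
    ensembles: EnsembleSet
    summary: dict


def analyze_traces(
    traces: TraceMatrix,
    config: Optional[RunConfig] = None,
    background: Union[float, np.ndarray] = 0.0,
) -> PipelineResult:
    """Run the full chain: preprocess, deconvolve, binarize, detect ensembles.

    Stages and their parameters all come from ``config`` (defaults are the
    published protocol).  The shuffle null uses ``config.seed``.
    """
    cfg = config or RunConfig()
    pre = preprocess_traces(
        traces,
        background=background,
        window=cfg.dff_window,
        lower_fraction=cfg.dff_lower_fraction,
        exclusion_fraction=cfg.exclusion_fraction,
    )
    model = DeconvolutionModel(
        gamma=cfg.gamma_for(traces.frame_period),
        sparsity_weight=cfg.sparsity_weight,
    )
    amplitudes = deconvolve_matrix(pre.dff, model)
    spikes = to_spike_probability(amplitudes, cell_ids=pre.kept_cell_ids)
    raster = binarize(spikes, sd_multiplier=cfg.sd_multiplier, sd_mode=cfg.sd_mode)
    ensembles = analyze_raster(
        raster,
        n_shuffles=cfg.n_shuffles,
        alpha=cfg.alpha,
        seed=cfg.seed,
        shuffle_mode=cfg.shuffle_mode,
        null_mode=cfg.null_mode,
    )
    summary = summarize_ensembles(ensembles)
    summary["n_excluded_cells"] = len(pre.excluded)
    summary["n_kept_cells"] = len(pre.kept_cell_ids)
    summary["coactivity_threshold"] = ensembles.coactivity_threshold
    summary["binarization_threshold"] = raster.threshold_value
    return PipelineResult(
        preprocessed=pre, spikes=spikes, raster=raster,
        ensembles=ensembles, summary=summary,
    )
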