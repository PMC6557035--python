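# Methods

This note documents the models and procedures implemented in `calnet`, the
parameter choices behind the defaults, and what the synthetic-data
experiments do and do not demonstrate.

## Scope and data model

The pipeline starts from ROI-by-frame raw fluorescence tables (one column
per cell soma, one row per imaging frame), the format exported by
microscope software after manual ROI tracing. It does not ingest image
stacks or segment ROIs. The reference recording geometry is a 10-minute
acquisition sampled every 5 s (120 frames) over fields of view of roughly
100–160 cells; the frame period is carried as explicit metadata because
acquisition protocols often report both a frame interval and an internal
streaming rate, and only the deconvolution decay constant consumes it.

## Preprocessing

**Background subtraction.** A scalar or per-frame background level,
measured in cell-free areas, is subtracted from every trace. Negative
results are clipped to zero (fluorescence is non-negative) and clip events
are logged.

**Saturated-cell exclusion.** A cell is excluded when its whole-recording
fluorescence range stays within 10% of its maximum, i.e.
`min(F) >= 0.9 * max(F)`. Such cells are either saturated or flat and
carry no usable transient; constant traces always satisfy the rule. The
rule is applied after background subtraction (configurable), and the rule
is monotone: lowering the fraction never excludes a cell kept at a higher
fraction.

**ΔF/F conversion.** For frame *t* with `w = min(10, t)` previous frames,
the baseline is the mean of the `floor(w/2)` smallest values among those
`w` frames (at least one value), and `dff_t = (F_t - baseline_t) /
baseline_t`. Averaging the lower half of a short causal window tracks slow
baseline drift while excluding transient frames, which occupy the upper
half of the window. Conventions chosen where the procedure is
underdetermined: the first frame gets ΔF/F = 0 and early frames use the
shortened window (discarding 10 of 120 frames would be wasteful); "the
lower 50% of values" means the `floor(w/2)` smallest *values* (ties
resolved by value, deterministic); a baseline of exactly zero is an error
rather than a silent NaN, and the pipeline wrapper adds a small positive
offset (1% of the global maximum) before conversion so clipped-to-zero
stretches cannot produce zero baselines. ΔF/F is scale-invariant:
multiplying a trace by a positive constant leaves it unchanged.

**Per-cell summaries.** The median raw (background-subtracted)
fluorescence (resting level) and the max-minus-min range (ΔF) are computed
per kept cell; their relative-frequency distributions are the inputs to
the nonparametric group comparison.

## Spike inference

Calcium is modeled as AR(1): `C_t = gamma * C_{t-1} + s_t` with
non-negative spike amplitudes `s_t`. Given a ΔF/F trace `y`, the solver
returns the global minimizer of the convex program

```
minimize   (1 / 2 sigma^2) * sum_t (y_t - C_t)^2 + lambda * sum_t s_t
subject to s_1 = C_1 >= 0,  s_t = C_t - gamma * C_{t-1} >= 0
```

via a log-barrier interior-point method. The Newton system at each
iteration is tridiagonal (the AR(1) difference operator is bidiagonal), so
each iteration costs O(T); the barrier weight is reduced tenfold per stage
until the duality gap falls below the tolerance (default 1e-8). Entries at
the barrier floor (~gap/lambda) are zeroed on exit — they are numerical
dust, and per-cell max normalization would otherwise rescale a spikeless
cell's dust to order one.

Parameter defaults, with rationale:

- `gamma = exp(-frame_period / tau)` with tau = 2 s. At 5-s sampling a
  typical high-affinity indicator transient decays almost completely
  between frames (gamma ≈ 0.08); gamma is freely configurable because
  indicator kinetics at slow sampling are not identifiable from the data.
- `sigma` is estimated per cell as `median(|diff(y)|) / (sqrt(2) * 0.6745)`
  — a MAD-based high-frequency estimate that ignores slow trends — and
  floored at 1e-6.
- `lambda = 4 / sigma`. The L1 term acts as an amplitude soft threshold at
  roughly `lambda * sigma^2`, so this sets the detection floor at four
  noise SDs: over a 120-frame recording the expected number of
  noise-driven amplitudes per cell is well below one, while transients at
  the recording's typical SNR (~10) pass essentially unattenuated. A floor
  at one noise SD, by contrast, passes ~16% of pure-noise frames, and
  after max normalization those flood the downstream raster.
- Batch deconvolution median-centers each cell's ΔF/F first (switchable).
  The lower-half sliding baseline sits ~0.7 noise SD below the noise mean
  by construction; uncentered, the AR(1)+L1 fit reads this positive offset
  as constant low-level firing.

**Spike probability.** Amplitudes are mapped to [0, 1] by dividing each
cell by its own maximum (all-zero cells stay zero). This is a declared
convention — the bounded "spike probability" scale used downstream is not
uniquely defined by the deconvolution — and it is isolated in one function
so it can be swapped.

## Ensemble detection

**Binarization.** The activity threshold is `3 * SD` of the pooled spike
probabilities of the whole field of view, with the SD taken about zero
(root mean square) per the "3 SD above zero" rule; SD about the mean is
available by flag. Activity is strict (`value > threshold`), so an all-zero
matrix yields an all-zero raster.

**Shuffle null.** Each of 1000 surrogates independently permutes each
cell's activity across frames, preserving per-cell rates while destroying
co-activity and autocorrelation (a circular-shift variant preserving
autocorrelation is available). The co-activity threshold is the smallest
count `c >= 2` whose null tail probability is below alpha = 0.05.

Two null modes are implemented because the literal "p < 0.05 against
shuffles" prescription is ambiguous about multiplicity across frames:

- **max (default):** the tail is over the per-shuffle *maximum* frame
  co-activity, a family-wise threshold. Under a fully independent raster
  the chance that any of the 120 frames is called significant is ~alpha.
- **pooled:** the tail is over all shuffled frames. This is the literal
  per-frame reading, but applying a per-frame p < 0.05 rule to every frame
  of a recording necessarily passes ~T * p(c*) false frames per recording
  (about two, at these rates); under the pooled rule nearly every
  null recording yields at least one false ensemble. The max-statistic
  default is what makes the detector's false-positive behavior match the
  significance level it advertises; the pooled mode is retained by flag
  for comparability.

**Ensembles.** Every frame reaching the co-activity threshold is a
high-activity frame and yields one ensemble whose members are that frame's
active cells; consecutive significant frames with identical member sets
merge into one event. No similarity clustering of frames is attempted. A
single active cell is never an ensemble (floor of 2).

**Core ensembles.** Every pairwise intersection of ensemble member sets
with at least two cells is a candidate; non-maximal candidates (strict
subsets of another candidate) are dropped, and each surviving core records
all ensembles containing it. The two-cell minimum exists because a
one-cell "co-activated group" is vacuous.

## Spine metrics

Ex vivo dendrites (brain sections): the whole dendrite is ineligible if
the shaft width falls outside 2–4 µm or less than 100 µm of segment is
discernible; spines must protrude at least 0.4 µm and carry a satisfied
4-µm-separation flag (measured upstream during tracing — it is not
computable from tabular records). In vitro records (cultured neurons,
fixed 20 µm distal segments): spines are protrusions 0.4–10 µm long.
Density is `count / segment_length * 10` (spines per 10 µm); for the 20 µm
in-vitro segment this is `count * 0.5`, and the implementation uses the
general formula because it is the only reading consistent with the unit.
Group summaries average densities within each animal first, then across
animals — the animal is the statistical unit.

## Group statistics

Per-coverslip or per-animal summaries are compared with the classical
pooled-variance unpaired two-tailed t test (df = n_a + n_b − 2; pooled
rather than Welch, matching the degrees of freedom convention of the
summaries this feeds). Per-cell distributions use the two-tailed
Mann–Whitney U with midranks; p is exact (enumeration over all
`C(n_a + n_b, n_a)` assignments) when both groups have at most 8 values,
and otherwise uses the normal approximation with tie-corrected variance
and a 0.5 continuity correction. Degenerate inputs (all values identical;
zero pooled variance) return the limiting p-values rather than NaN.
Relative-frequency histograms use half-open bins and proportions that sum
to one.

## Synthetic data

The generator emulates the features the analysis relies on: independent
Bernoulli background firing, planted ensembles (a fixed member set
co-activated at scheduled frames, each member participating with a given
probability, events at distinct frames), AR(1) calcium, multiplicative
rendering `F = F0 * (1 + a * C) + drift * t + noise`, and additive
Gaussian noise clipped at zero. Multiplicative rendering makes the
ground-truth ΔF/F (`a * C`) independent of the per-cell baseline.
Defaults: 120 cells × 120 frames at 5 s, background 0.02 spikes/cell/frame,
F0 = 50 a.u., a = 0.5 (a 25 a.u. jump per spike, matching the observed
tens-of-a.u. baselines and ranges), noise 2.5 a.u. (single-spike SNR 10),
`gamma_true = exp(-frame_period / 2 s)`.

Spine records: Poisson spine counts at the requested density, log-normal
lengths (median 1.5 µm, sigma 0.35 — strictly positive, right-skewed,
median matched to observed group means) truncated by rejection to
0.4–10 µm, Bernoulli marker positivity. The grouped generator draws each
animal's true density from Normal(group mean, between-animal SD).

What the generator does *not* emulate: spatial structure, cell-type
diversity, bursting dynamics beyond scheduled co-activation, photobleaching,
movement artifacts, or correlated (shot-to-shot) noise. Passing the
recovery experiments therefore shows the chain is correct and well-behaved
under the model it assumes, not that it is robust to every artifact of
real recordings.

## Validation experiments and problem sizes

The test suite and `scripts/acceptance.py` run the same families of
experiments: brute-force oracle equivalence for ΔF/F (100 random traces,
1e-12 relative); constrained-QP oracle equivalence for the deconvolution
(50 random traces up to 50 frames, 1e-6 relative; noiseless single-spike
recovery to 1e-3); single-spike localization at SNR 10 (200 trials, ±1
frame); exact per-cell-total conservation under shuffling and exact
enumeration of the toy 3-cell null; type-I behavior over 200 null
simulations in both null modes; end-to-end recovery of three planted
8-cell ensembles over 100 runs; a 50-pair directional contrast between
sparse (4 ensembles × 5 cells) and dense (8 × 8) configurations; and a
100-run two-group spine experiment at group means 13.7 and 17.2 spines
per 10 µm (8 animals × 6 dendrites, between-animal SDs matched to the
group SEMs). These sizes keep the full suite to a few minutes on one CPU
while leaving Monte-Carlo error well inside the asserted margins.

## Known limitations

- "Spike probability" is a per-cell max-normalized amplitude, not a
  calibrated probability; cells with a single transient peak at exactly 1.
- The deconvolution model omits an explicit baseline term; the batch
  wrapper's median centering stands in for it and assumes spikes are
  sparse within each trace.
- The pooled null mode is reported for comparability but does not control
  recording-level false positives (see above).
- Ex vivo spine eligibility depends on flags (separation, shaft width)
  that must be measured during tracing; the table format trusts them.
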