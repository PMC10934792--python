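# Methods

## Problem and model

Two-class motor-imagery (MI) decoding from epoched EEG rests on
event-related desynchronization (ERD): imagining a movement suppresses
band power of the sensorimotor rhythms (mu/alpha 8–12 Hz, beta 14–30 Hz)
over task-specific scalp sites, in a time window and frequency band that
vary across subjects. `mitfopt` treats the choice of that time–frequency
segment as an optimization problem and wraps the full decoder inside it:

1. **Segment search.** A sparrow search algorithm (SSA) explores segments
   `(fstart, fwidth, tstart, twidth)`. The fitness of a candidate segment
   is `1 − (mean cross-validated accuracy)` of the downstream decoder on
   the training partition, so the swarm minimizes decoding error
   directly (a wrapper objective, not a proxy statistic).
2. **Channel selection (CCS).** After per-trial, per-channel z-scoring,
   each trial's channel-by-channel Pearson correlation matrix is reduced
   to row means; channels with high mean correlation to the rest carry
   shared task signal. The top `Ns` channels of each of `Nt` trials vote,
   and the `Ns` most frequent channels are kept.
3. **Feature extraction (RCSP).** Regularized common spatial patterns:
   per-class covariances are a convex blend (weight `alpha`) of
   trace-normalized scatter matrices `E E'/tr(E E')` and ordinary sample
   covariances, then shrunk toward a scaled identity (weight `beta`).
   The generalized eigenproblem `Q1 w = λ Q2 w` yields the filter bank of
   the `m` largest and `m` smallest eigenvalues; features are
   log-variances of the filtered trials.
4. **Classification.** RBF-kernel SVM with exhaustive grid search over
   `C, γ ∈ {10⁻³ … 10³}`, scored by stratified five-fold cross-validation
   with seeded fold assignment.

The evaluation protocol is a stratified 7:3 train/test split. The
optimizer sees only the training partition; every cross-validation fold
recomputes channel selection and spatial filters on its own training part
so no validation data leaks into the decoder. The held-out partition is
wrapped in an access guard that records each read; a correct run reads it
exactly once, after optimization — the audit is part of the result object.

## Parameters

| Parameter | Default | Meaning |
|---|---|---|
| `ssa.n` | 10 | swarm size |
| `ssa.itermax` | 20 | iterations (n·(itermax+1) = 210 fitness evaluations) |
| `ssa.producer_ratio` | 0.7 | fraction of best-ranked sparrows that explore |
| `ssa.scout_ratio` | 0.2 | fraction redrawn each iteration as scouts |
| `bounds` | 0–4 s, 1–40 Hz | search box; min widths 2 Hz, 0.5 s |
| `ccs.n_select` | all channels | voted channel count `Ns` |
| `ccs.n_trials` | all training trials | voting trial count `Nt` |
| `rcsp.m` | 2 | filter pairs (4 features) |
| `rcsp.alpha` | 0.4 | covariance-estimator blend |
| `rcsp.beta` | 0.01 | identity shrinkage (guarantees a definite `Q2`) |
| `svm.k` | 5 | cross-validation folds |
| `svm.C_grid`, `g_grid` | 10⁻³…10³ | final-model grids |
| `split.train_fraction` | 0.7 | stratified train share |

## Design choices where the design was open

- **Normalized search coordinates.** The SSA producer rule is
  multiplicative (`x · exp(−i/(α·itermax))`), which contracts positions
  toward the origin. On heterogeneous physical units (Hz vs. seconds)
  that contraction would bias the four dimensions unequally, so the swarm
  runs in `[0,1]⁴` and positions are decoded affinely to segments
  (start-then-width, widths floored at 2 Hz / 0.5 s). The decoding is
  total: any point of the box maps to a valid segment, so the optimizer
  needs no rejection step.
- **Random-scalar scoping in SSA.** The safety threshold `ST ~ U(0.5,1)`
  is drawn once per run, the alarm `R2 ~ U(0,1)` once per iteration,
  `α ∈ (0,1]` and `Q ~ N(0,1)` per sparrow per iteration, and the scout
  scalars `β ~ N(0,1)`, `K ~ U(−1,1)` per scout per iteration, matching
  the granularity of the original SSA reference implementation. `K` is a
  direction, hence the signed range; a config switch (`scout_k_positive`)
  restricts it to (0,1). Rank `i` in the producer/scrounger rules is the
  1-based rank within the role. The scrounger "follow" branch adds the
  scalar mean over dimensions of `r_j·|x_j − xbest_j|` to the best
  producer's updated position. Elitism (best-ever position retained) makes
  the reported fitness history non-increasing.
- **Fitness = 1 − CV accuracy**, so lower is better and chance-level
  decoding scores ≈ 0.5. Segments that leave fewer than 2 samples or
  fewer than `2m` channels score the worst fitness (1.0) instead of
  raising, keeping the objective total over the box. Inside the fitness
  loop a 3×3 SVM subgrid (`{0.1, 1, 10}`, centered on the standardized
  feature scale) bounds cost; per fold, each (C, γ) pair is scored on the
  validation part and the best pair's mean fold accuracy defines fitness.
  The final model always uses the full 7×7 grid. Fitness values are
  cached on the segment rounded to 1e-6 in normalized coordinates.
- **Crop-then-filter** order in `apply_segment`; with zero-phase
  filtering the difference versus filter-then-crop is confined to window
  edges.
- **Filters.** 4th-order Butterworth applied forward-backward
  (zero-phase, reflect padding), notch as a second-order IIR band-stop
  with Q=30, resampling by polyphase FIR with a rational rate
  approximation. Time conventions: seconds, half-open windows
  `[start, end)`, sample index `round-half-away-from-zero((t−t0)·sfreq)`.
- **CCS row means include the diagonal** (a uniform +1/N shift that
  cannot change the ranking; a flag excludes it). Selection inside each
  CV fold uses only that fold's training part. With no configured `Ns`
  all channels are kept — the voting path still runs, but on spatially
  independent data any forced `Ns < N` would discard informative channels
  at random.
- **RCSP conventions.** `var(·)` is the sample variance over time
  (mean removed, 1/(n−1)); the smaller class label maps to `Q1`;
  eigenvectors are scaled to `w'Q2w = 1` with the first non-negligible
  component positive, so fitted models are byte-reproducible. The
  generalized problem is solved directly (no composite-whitening
  shortcut, which is only exact without regularization), and every
  returned eigenpair is verified by its residual
  `‖Q1w − λQ2w‖ ≤ 1e-8·‖Q1w‖` rather than trusted from the solver.
- **Stratified folds and splits** everywhere (plain k-fold can produce
  degenerate class counts at small n); one master seed derives the split,
  optimizer, and fold seeds, making a run bit-reproducible end to end.

## Synthetic data: what it emulates and what it does not

The generator plants a known ground truth so every stage is verifiable
offline. Each trial is independent `1/f^γ` background noise per channel
(γ=1, unit RMS — the canonical EEG spectral slope) plus a band-limited
"sensorimotor rhythm" on all channels for the whole trial. ERD is
amplitude attenuation of that rhythm by `sqrt(1 − erd_depth)` on the
informative channels of a trial's class, only inside the planted time
window, with 100 ms raised-cosine ramps so window edges create no
broadband transient cue. An optional common-mode component (shared
band-limited oscillation on a channel subset) produces the correlated
channel groups the channel selector is designed to find; at
`common_scale = background_scale` the planted pairwise correlation is
≈ 0.5.

Reference conditions: 16 channels, 100 trials per class at 125 Hz, 4 s
epochs, ERD depth 0.8 at 9–13 Hz, 0.5–2.5 s on two informative channels.
The oscillation RMS default (0.7 of background) sets the in-band SNR so a
correctly placed segment decodes at ≈ 95–100% while wide or mis-placed
segments lose tens of accuracy points — i.e., the segment search has a
real gradient and recovering the planted segment is both necessary and
sufficient for high accuracy.

Not emulated: volume conduction (channels are spatially independent
except for the optional common mode), ocular/muscle artifacts, ERS
rebound, non-stationarity across trials, and realistic electrode
geometry. Passing the recovery experiments therefore shows the pipeline
recovers planted time–frequency–space structure at realistic SNR; it does
not certify performance on real recordings, where the preprocessing
chain (notch, 1–50 Hz band-pass, downsampling, baseline correction) and
per-subject variability matter.

## Numerical notes and limitations

- `beta = 0` with rank-deficient covariances makes `Q2` singular; the
  fit fails with an actionable error suggesting `beta > 0`.
- Degenerate trials (zero variance under a filter, zero-energy trials,
  constant channels) raise with the trial/channel named.
- Fixture data is little-endian float32; round-trips are bit-exact at
  that precision and files are byte-identical across platforms.
- The optimizer benchmark (sphere function offset to 0.3·1) and the
  210-evaluation budget match the pipeline's own budget; random search
  with 200 evaluations is the baseline.
- Problem sizes in the test-suite and acceptance script (5–10 seeds per
  experiment, 50 optimizer/selector replicates) are the package's
  reference experiment sizes; each full pipeline run costs ≈ 30 s on one
  CPU core.
- Multiclass decoding, union-of-segments encodings, other metaheuristics,
  and artifact rejection are out of scope.
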