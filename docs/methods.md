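# Methods

## Signal model

The generator is phenomenological: it reproduces the statistical and
temporal structure that the downstream analysis relies on, not the optics
of light transport.

**Activation envelope.** Muscle activation for gesture *g* is the 0/1 phase
indicator of the protocol passed through a first-order lag,

    e(t + Δ) = e(t) + (u(t) − e(t)) · (1 − exp(−Δ/τ)),

with tissue time constant τ = 150 ms by default. The target is held over
each sample interval, so a unit step reaches `1 − exp(−t/τ)` exactly `t`
after the first active sample; rise and decay are mirror images. Envelopes
are kept per gesture, so tissue relaxation continues into the following
rest phase instead of snapping to zero.

**LMG.** Each of the five modules alternates a green and an infrared LED
every 125 ms while one photodiode is read continuously at 400 Hz (50
samples per LED state). The ADC and amplifier rates are not fixed by the
armband design and are configurable; 400 Hz is chosen so that every 200 ms
window still contains ≥ 40 fresh samples per LED colour after
demultiplexing. The sample at time *t* for module *c* is

    baseline_c + gain_colour[c, g] · e_g(t) + drift_c(t) + N(0, σ_lmg²),

with separate `[5 × gestures]` gain matrices per LED colour. Default
subject gains are drawn uniformly on [0.3, 1.0] a.u. with a rejection step
enforcing a minimum pairwise Euclidean column distance of 0.4, so distinct
gestures deform the five sensing sites in distinct patterns; the rest
column is identically zero. Drift is a single slow sinusoid (2 % of the
mean gain, 60 s period) available to exercise robustness; it is off in the
default benchmark conditions. σ_lmg defaults to 5 % of the mean active
gain.

**EMG.** Five bipolar channels at 1200 Hz are modelled as band-limited
carrier noise amplitude-modulated by the same envelope:
`emg_gain[c, g] · e_g(t) · n_c(t) + white noise`, where `n_c` is white
noise filtered to 20–450 Hz (the standard sEMG energy band) and normalized
to unit variance. The synthesis band is deliberately narrower than the
5–500 Hz analysis filter so the filtering stage does real work.

**Force sessions.** The subject ramps grip force from rest to half of
maximum clench and back over 15 s, ten times, with 15 s rest between ramps.
Force is an exact triangle (apex 0.5); the LMG deflection is
`gain · lag(force / 0.5)`, i.e. the normalized force drives the same
first-order tissue dynamics. Force and LMG share one sample grid.

All randomness flows from a single integer seed through
`numpy.random.SeedSequence`; identical inputs give bit-identical sessions.

**What the generator does not emulate.** Photon transport, skin
pigmentation, silicone mechanics, electrode lift-off, motion artifact,
inter-session electrode/armband shift, crosstalk between EMG channels, and
fatigue-induced nonstationarity. Classes are therefore separable mainly by
their per-channel deflection levels, and a passing benchmark demonstrates
that the pipeline recovers the generating structure — not that comparable
accuracy would be reached on real recordings.

## Preprocessing

- **Demultiplexing**: sample-and-hold. Each of the 10 logical channels
  (5 green + 5 IR) keeps the photodiode value while its LED is lit and
  carries the last lit value forward during the other LED's interval;
  leading samples are back-filled. This keeps every channel on the full
  sample grid so windows are dense. A per-run-mean variant
  (`method="cycle_mean"`) is available.
- **Filtering**: EMG only — causal 4th-order Butterworth bandpass,
  5–500 Hz; a high cutoff at or above Nyquist is clamped to 0.99 × Nyquist
  with a logged warning. A zero-phase variant exists for offline use. LMG
  is consumed raw, and no input normalization is applied anywhere: the deep
  models carry batch normalization instead.
- **Windowing**: 200 ms windows, 20 ms stride; window count per contiguous
  session is `floor((T − L)/S) + 1`. Per-window labels follow the
  `majority` policy by default; the `strict` policy (used in the
  benchmarks) drops windows spanning more than one trigger label, so every
  window is unambiguous. The repetition id of a window is the id at its
  final sample; a rest phase shares the id of the active phase that follows
  it, making the rest+gesture pair the unit that blocked CV separates.
  Regression targets are reduced to the window's final sample — the value a
  causal estimator would predict at decision time.
- **Balancing**: seeded uniform down-sampling of every class to the
  minimum class count, order-preserving. Force sessions are not balanced;
  instead only active-phase windows are kept.

## Features

The eight time-domain features use the common Phinyomark-style
conventions; formulas are in the `features` module docstring. Thresholds
default to ε_zc = 0, ε_wamp = 0.005 signal units, δ_log = 1e-12 (keeping
the log detector finite on silent windows); all are configurable. VAR is
the sample variance about the window mean (ddof = 1). Features are
computed per channel and concatenated, giving 8 × C columns.

## Decoders

- **RF**: scikit-learn random forest, 150 trees, over flattened inputs.
- **CNN**: three blocks of (3×3 convolution, batch normalization, dropout
  0.3), max-pooling after the first two blocks, then four fully-connected
  ReLU layers and the task head.
- **TMC-ViT**: two (3×3 convolution, max-pool) stages embed the raw
  window; 2×2 patches are flattened, linearly projected, and offset by a
  learned position embedding; a pre-norm transformer encoder of four
  multi-head-attention layers (four heads each, GELU MLP) follows; the head
  consumes the mean over tokens (no class token).

Windows enter the 2-D operators as (time × channel) single-plane images, so
kernels and patches mix temporal and cross-channel structure; EMG feature
vectors are reshaped to (channel × feature) maps. Classification heads end
in softmax with sparse cross-entropy; regression heads are a single linear
unit with MSE.

The deep models run on a compact in-package NumPy backend (`_nn`):
im2col convolution, batch-norm, dropout, layer-norm, multi-head
self-attention, Adam, seeded mini-batch training with early stopping on the
training loss (the final-epoch weights are kept — no best-of-run rollback,
so CV variance is honest). Every backward pass is verified against central
finite differences in the test suite.

**Batch-norm re-estimation.** Dropout inflates the variance of activations
feeding later batch-norm layers during training, so running statistics
accumulated under dropout are biased relative to inference conditions —
enough, on near-margin classes, to flip predictions wholesale at eval time.
After the last epoch the backend therefore recomputes every batch-norm
layer's running mean and variance exactly, in inference mode (dropout off),
over up to 16 training batches.

**Hyperparameters.** The armband study fixes the topology (tree count,
block/layer/head counts, patch size) but not layer widths or optimizer
settings. Full-size defaults: CNN filters (32, 64, 128), FC widths
(256, 128, 64, 32); ViT conv stack (16, 32), embed dim 64, MLP dim 128;
Adam lr 1e-3, batch 64, 50 epochs, patience 10. The **reduced preset**
(`ModelSpec.reduced` / `TrainConfig.reduced`) keeps the same topology with
narrower layers — CNN (8, 16, 16) / (64, 32, 16, 8); ViT (8, 16), embed 32,
MLP 64 — and trains for 12 epochs (patience 3) on a seeded,
class-stratified subsample of at most 1500 windows per fit. The 20 ms
stride makes consecutive windows 90 % redundant, so this cap discards
little information; the reduced preset is the default for the synthetic
benchmarks and is sized to run the whole suite on one CPU in minutes.

## Evaluation

- **Classification**: 5-fold CV, repetition-blocked by default — folds
  partition whole repetitions (sizes differing by at most one), because
  90 %-overlapping windows would leak between window-random folds. A
  window-random mode exists and is documented as optimistic. A leakage
  guard asserts that fold test sets are disjoint and exhaustive.
- **Regression**: 10-fold CV with exactly one held-out repetition per
  fold. Per fold, NMSE (%) and Pearson r are computed on the held-out
  repetition's concatenated, time-ordered trajectory. A constant
  prediction leaves Pearson undefined; that fold's r is recorded as NaN
  rather than failing the run.
- **ANOVA**: classical one-way F and p from explicit sums of squares, with
  the degenerate convention (0, 1) for zero within-group variance and equal
  means. The LMG-vs-EMG comparison pools the 30 per-subject × model mean
  accuracies per interface; applied to the study's printed per-subject
  table this grouping reproduces its reported p = 0.0381.
- **Results tables**: tidy per-subject rows pivot to a subject × (model,
  interface/metric) grid with arithmetic AVG and per-column MAX rows;
  aggregating the study's printed per-subject values recovers its printed
  aggregate claims (e.g. TMC-ViT LMG mean 98.24 %, max 99.11 %; force
  accuracy mean 90.46 %, max 98.09 %).
- **Sensor bench**: `I = |S̄g − S̄r| / (Φv · Rp)`, offset-invariant and
  scaling as 1/(Φv·Rp).

## Benchmark conditions and problem sizes

The default synthetic benchmark uses seed 42, one synthetic subject, four
active gestures + rest × 6 repetitions (15 s / 15 s phases), 5 % noise,
strict labels, giving 22 230 balanced LMG windows (4 446 per class) of
80 samples × 10 channels; the force benchmark gives 7 410 active windows
over 10 ramps. Under these conditions all three families exceed 90 % mean
blocked-CV accuracy (chance 20 %) and the TMC-ViT force pipeline exceeds
85 % mean NMSE. Training inside CV uses the reduced preset above; held-out
windows are always evaluated in full.

## Numerical choices and edge cases

- Windows are stored float32; network training is float32 (float64 in the
  gradient-check tests). RF seeds derive from the fit's SeedSequence, so
  end-to-end runs are reproducible bit-for-bit on a fixed BLAS.
- Majority labels break ties by `numpy.unique` order (lexicographic).
- NMSE requires a non-constant reference (zero denominator is a domain
  error); it is ≤ 100 always and 100 iff the trajectories are identical.
- `balance_classes` can only see classes that produced windows; callers
  pass `expected_labels` to get a named error for an absent class.
- Session CSVs are written at 17 significant digits and read with
  round-trip float parsing, so write/read is lossless.

## Known limitations

- The synthetic benchmark is easier than real recordings (see the
  generator's non-goals); its accuracies sit near ceiling and should not be
  read as expected real-world performance.
- The reduced preset underfits harder (e.g. lower-SNR) synthetic
  conditions; switch to the full-size spec and config for such studies.
- Per-subject subgroup averages (sex, handedness) reported for the armband
  study cannot be re-derived from its printed per-subject means; the
  aggregation stage reports descriptive means only and attempts no such
  reconstruction.
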