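# Methods

`rpfno` forecasts short horizons of wearable motion signals by encoding
3-axis gyroscope streams as sequences of small distance images (recurrence
plots), learning a frame-to-frame forecaster in the frequency domain (a
Fourier neural operator), decoding predicted frames back to raw signals
with an LSTM, and deriving an energy-based early warning for falls from the
forecasted frames.  This note records the model, its assumptions, the
parameters that matter, the numerical choices, and what the synthetic-data
experiments do and do not show.

## Recurrence-plot encoding

A stream is sampled at a fixed rate (30 Hz by default).  For each end index
`t`, the last `Tw = 5` samples of each axis are concatenated into one
vector

    X_t = [w^x_{t-4..t} ; w^y_{t-4..t} ; w^z_{t-4..t}]  (length 15),

one linear midpoint is inserted between every consecutive pair of entries
of the whole concatenated vector — crossing axis boundaries — giving
`M = 2*15 - 1 = 29` entries, and the distance-only recurrence plot

    Y_t[i, j] = |X_t[i] - X_t[j]|

is formed.  No threshold and no step function are applied: binarized
recurrence plots discard the amplitude information the forecaster and
decoder need.  Entries of the concatenated vector are scalars, so the L2
norm of the difference is the absolute difference.  Interpolating the
whole concatenated vector (rather than per axis) is the only order
consistent with the 29x29 grid; the alternative per-axis order would give
27.  Consequences the rest of the pipeline must absorb:

* `Y_t` is symmetric with zero diagonal and satisfies the reverse triangle
  bound `|Y[i,k] - Y[k,j]| <= Y[i,j]`;
* `Y_t` is invariant to a global sign flip and constant offset of the
  window (`x -> -x + c`), so raw signals are recoverable from frames only
  up to what a trained decoder's data disambiguates.

For two-sensor fusion the cross recurrence plot `C[i,j] = |x_i - y_j|`
pairs the gyroscope window with the accelerometer window ending at the
same sample; it is generally asymmetric with nonzero diagonal.

A supervised sample stacks `T = 30` consecutive frames (1 s at 30 Hz,
stride 1) as input and the next `T_hat = 20` frames (~0.6 s) as target,
together with the 3-axis raw samples at the target frames' end indices for
decoder training.  A 60 s recording (1800 samples) yields 1796 frames and
1747 samples.

## Fourier neural operator

The forecaster treats time as channels: a pointwise linear lift maps the
`T` input channels at each grid point to `width` channels, `N = 4` Fourier
layers update the state as

    v_{n+1} = sigmoid( IFFT( R_n . FFT(v_n) ) + W_n v_n + b_n ),

and a pointwise linear projection emits `T_hat` output channels.  The
spectral branch mixes channels mode-by-mode with complex weights `R_n` on
a truncated frequency set and zeroes all other modes.  Sigmoid is the
activation throughout the Fourier layers (a deliberate design choice of
the method this package implements); only the projection is unbounded.

**Mode truncation.**  With `modes = k` (default 8) the retained set is
axis-0 frequencies `{0, ±1, …, ±(k-1)}` crossed with nonnegative axis-1
frequencies `{0..k-1}` of the real-input half spectrum, one complex weight
tensor `(width, width, k, k)` per layer; negative axis-0 rows reuse the
conjugated weights, which keeps the full-spectrum multiplier
Hermitian-symmetric, so each spectral branch is an exact real-linear,
translation-equivariant operator.  Admissibility: `k <= (M + 1) // 2`;
`k = 8` keeps the 17, 23 and 29 grids of the resolution-transfer
experiment admissible.  Because weights live on frequency indices, the
parameter count is independent of the grid size M and the same trained
weights evaluate at any admissible resolution (mesh invariance).

**Numerics.**  Since only `(2k-1) x k` modes survive, the transform is
evaluated as a pair of small dense DFT matrix products restricted to the
retained frequencies instead of a full FFT; this is exact (the unit tests
compare it against an FFT-based reference) and much faster at these grid
sizes, which are small and prime.  All forward/backward passes are
hand-derived numpy, validated against central finite differences in
float64; training runs in float32.  Initialisation: lift/projection and
the pointwise linear maps use uniform fan-in scaling; `R` is drawn
uniformly in `[0, 1/width^2)`, following common neural-operator practice.

**Normalization.**  Frames are divided by the training split's global
maximum distance before entering any model; the normalizer is stored on
the model and in its checkpoint, so a checkpoint fully determines
inference.

## Convolutional baseline

Four convolution layers (kernel 5, stride 1, zero padding so the spatial
size never changes) followed by three fully connected layers mapping the
flattened feature grid to the `T_hat x M x M` output; ReLU after every
layer except the final one.  The fully connected head ties the baseline to
one grid size — it cannot evaluate at another resolution — and dominates
its parameter count: at the desk-scale profile the baseline holds ~2.1 M
parameters against the operator's ~133 k, because any dense head must
touch all `T_hat * M^2` outputs while the operator projects pointwise.
`param_count` is reported on both models so comparisons state their
capacities.

## Signal decoder

An LSTM consumes the frame sequence (each M x M frame flattened to M^2
entries per step, hidden size 128 by default) and a two-layer head
(128 -> 64 -> 3) emits the 3-axis sample at each frame's end index, so 20
frames decode to 20 samples per axis.  The decoder is trained on (true
frames -> true signals) pairs, separately from the forecaster, and applied
at inference to predicted frames.  Because of the sign/offset invariance
above, held-out recovery is scored by per-axis correlation (shape), not
absolute error.  Overlapping decoded segments are stitched first-wins;
uncovered indices are kept as NaN and reported, never silently filled.

## Training protocol and evaluation

Adam on MSE, batch 32, learning rate 1e-3 halved every 50 epochs, 200
epochs at full scale.  Splits are chronological 6:2:2 (validation and test
counts floor-allocated, remainder to train: 3600 -> 2160/720/720), because
consecutive sliding-window samples share frames and a shuffled split would
leak near-duplicates; additionally the first `T + T_hat - 1` samples of
validation and test, whose frame spans still overlap the previous
partition, are dropped (49 samples per boundary under the defaults).
Validation curves are monitored for overfitting only; no early stopping.
Training is deterministic given the seed.

One forecaster is trained per subject.  The cross-subject matrix reports,
for model i on subject j's test set, the *relative* MSE: squared error in
raw distance units divided by the test set's mean squared target.  In
model-normalized units the matrix is dominated by amplitude-scale column
effects (low-amplitude subjects look uniformly "easy"); the relative form
makes rows comparable, and personalization appears as a low diagonal
against the row's off-diagonal entries.

## Synthetic motion model

The study population (volunteers walking or running with a thigh-mounted
phone) is emulated by a harmonic gait model: each gyro axis is
`sum_h A_h sin(2 pi h f t + phi_h)` with 2-3 harmonics, subject-specific
stride frequency `f` (walking 1.4-2.0 Hz, running 2.4-3.0 Hz), per-axis
amplitudes in 0.5-3 rad/s tapered toward higher harmonics, axis-specific
phases, plus Gaussian noise (sd 0.03-0.08 rad/s).  Cohorts enforce a
pairwise stride-frequency gap of at least 0.05 Hz (redraw on collision) so
cross-subject evaluation is well posed.  Accelerometer companions for the
fusion experiments share the stride frequency, draw fresh amplitudes and
phases, and add a gravity offset on the z axis.  A fall is the simplest
out-of-distribution event for periodic gait: a 0.5 s broadband burst at
3-4x the pre-onset per-axis peak (the impact), then near-zero signal
(lying still); samples from the onset on are labelled `fall`.

What passing tests on this generator do **not** show: robustness to soft
tissue artifacts, sensor drift, orientation changes, pocket motion, gait
variability within a subject, or realistic fall biomechanics.  The
generator exists so every downstream stage is testable and so the
pipeline's qualitative claims (personalization, mesh invariance, energy
separation) can be exercised end to end.

## Fall early warning

A two-layer classifier (flattened `T_hat`-frame predicted stack -> 64 ->
2 logits) is trained by cross-entropy to discriminate the normal
activities (walking vs. running) from FNO-*predicted* stacks.  The energy
statistic `E = -log sum_i exp(logit_i)` (computed with a stable
log-sum-exp) is low in-distribution and high out-of-distribution; the
threshold `tau` is the 0.95 quantile (linear interpolation) of energies on
normal training data — one-class calibration, falls never touch `tau`.
The detector slides along a stream: at each step it forecasts ~0.6 s of
frames, scores their energy, and raises a potential-fall alert when it
exceeds `tau`; the energy of the last `T_hat` *observed* frames is tracked
the same way, and its first exceedance at or after the alert confirms the
event, so the alert lead (confirmation minus alert) is nonnegative.

Two desk-scale observations worth stating plainly.  First, a forecast
cannot flag a fall before any anomalous sample exists — the alert follows
the onset by the few tenths of a second the anomaly needs to enter the
input window.  Second, on these synthetic falls the observed-frame energy
reacts essentially as fast as the forecast-based alert (the injected burst
is violent enough that a single observed anomalous frame spikes the
energy), so measured alert leads are near zero; the asserted property is
the ordering alert <= confirmation, not a clinical lead time, and no
sensitivity/specificity claim is made beyond the calibrated false-alarm
rate on synthetic data.

## Desk-scale profile

The test suite and examples run a reduced profile chosen for a single CPU:
35 s streams per subject (~600 training samples after the split), operator
width 16 (default 32), 20 epochs, matched for the baseline (channels 6,
hidden 96/96).  At this profile the personalization matrix is decisive and
the validation curves are still monotone (no overfitting).  One honest
deviation from the full-scale expectation: at this profile the baseline's
heavily over-parameterized dense head attains *lower* diagonal MSE than
the operator on the clean, quasi-periodic synthetic frames, so the
operator-vs-baseline ordering is computed and reported by the comparison
test rather than asserted; the ordering claim originates from real
recordings, which are noisier and less interpolable than this generator's
output.

## Known limitations

* The decoder inherits the sign/offset ambiguity of distance-only frames.
* The resolution-transfer comparison aligns grids by bilinear
  downsampling; window boundaries make the correspondence approximate
  (midpoints across axis seams differ between window sizes), which is part
  of the tolerance budget of that check.
* Unit conventions are the caller's: the pipeline is unit-agnostic and
  decoded signals inherit the input's units (rad/s for the synthetic
  gyro).
* Fall detection is a demonstration of the energy mechanism on synthetic
  transients, not a validated detector.
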