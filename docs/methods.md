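# Methods

## Problem and model

Gated and tracked radiotherapy of thoracic and abdominal tumours must act
on a respiratory surrogate signal — here the anterior–posterior (AP)
displacement of a point on the chest or abdomen surface, in mm — despite
system latencies of up to 500 ms between measuring the surrogate and
acting on it.  The package predicts the surrogate 500 ms ahead so the
latency can be cancelled.

The central idea is to encode the quasi-periodicity of breathing
explicitly before learning.  Each preprocessed trace `y(t)` is written as
a modulated cosine

    y(t) = d(t) + d(t) · cos φ(t) + BL(t)

with three slowly varying, individually smooth components:

* `BL(t)` — the baseline, the piecewise-linear curve through the lower
  cycle extrema (posture and drift);
* `d(t)` — the deflection, one-half of the peak-to-trough breathing
  amplitude, from the upper and lower envelopes;
* `φ(t)` — the cycle phase, 0° at the upper extrema, 180° at the lower,
  advancing 360° per breath, obtained exactly by inverting the model:
  `φ = arccos((y − d − BL)/d)` on the way down and `360° − arccos(·)` on
  the way up.

Two recurrent predictors share one architecture (three stacked LSTM
layers and a dense head) and differ only in the output encoding:

* **signal mode** ("Model 1"): scaled signal window → scaled signal value
  one horizon ahead (one channel);
* **components mode** ("Model 2"): scaled signal window → the three
  component channels one horizon ahead, decoded and reassembled through
  the model equation into a millimetre prediction.

Because the affine per-window scaling commutes with the model equation,
training in scaled space and predicting in mm is exact (see *Scaling*).

## Preprocessing

Scanner traces arrive irregularly sampled (~13–24 Hz) and are linearly
interpolated onto a uniform 20 Hz grid.  Linear interpolation is used
because inter-sample intervals (≤ 75 ms) are short against a breathing
period and it cannot ring.  Setup artefacts are removed by user-supplied
cropping; no artefact detector is included.  Noise is removed with a
maximally flat (Butterworth) low-pass of order 8 and 1 Hz cutoff — the
breathing band (≈ 0.1–0.5 Hz) passes with unit gain, scanner noise above
1 Hz is suppressed by ≥ 40 dB.  Offline filtering is zero-phase
(forward–backward), so peak positions are not lagged.  At inference the
same zero-phase filter is applied *within* each input window (reflect
padding capped at one window length), and training windows are drawn
from the raw resampled trace and filtered the same way, so training and
inference see the same distribution.

## Peak detection

Cycle anchors are the alternating local maxima/minima of the filtered
trace.  Extrema are accepted only with prominence ≥ 55 % of the mean
peak-to-trough amplitude; since that mean itself depends on the accepted
set, the estimate is iterated (find extrema → enforce alternation → mean
amplitude → reject by prominence → re-alternate) until stable, at most 5
passes.  Of consecutive same-sign extrema the more extreme survives;
plateaus resolve to their first sample.  The 55 % rule rejects ripple
(e.g. cardiac or sensor oscillation) while keeping genuine shallow
breaths.

Residual noise above the breathing band can shift the apparent extremum
of the 1 Hz-filtered trace by one or two samples, so candidate extrema
are *localised* on an additionally smoothed copy (zero-phase low-pass at
0.6 Hz, comfortably above the ~0.25 Hz fundamental); amplitudes and
envelope values are always taken from the input trace at the detected
indices.  When the envelope slopes (amplitude change, baseline drift),
the realised extremum itself sits up to one further sample away from the
underlying cycle anchor — that displacement is physical, not a detector
error.

Samples before the first and after the last anchor of either class are
excluded (`valid_mask`); envelopes are never extrapolated.

## Decomposition numerics

The arccos argument `c = (y − d − BL)/d` is clamped to [−1, 1]; clamped
samples are flagged.  Clamping occurs where the signal genuinely leaves
the piecewise-linear envelope chords: near anchors when the envelope
slopes (amplitude change, baseline drift), and in end-exhale dwells where
the filtered waveform undershoots the chord.  On clean
constant-parameter traces the clamp fraction is ≈ 0; under realistic
amplitude/baseline modulation 1–7 % of valid samples clamp.  This is a
property of chord-interpolated envelopes, not an error state: the exact
round-trip guarantee `reassemble(decompose(y)) = y` holds on all valid,
unclamped samples to 1e-9 mm, because `cos(arccos(c)) = c` exactly.

Near the arccos branch points an imperfect envelope can also make the raw
phase retreat by a fraction of a degree; the unwrapped phase is made
monotone with a running maximum and the adjusted samples are flagged as
clamped, since they indicate the same envelope inconsistency.

## Scaling

Each input window is normalised by its own extremes:
`y_scaled = (y − y_min − y_half)/y_half` with
`y_half = (y_max − y_min)/2`, mapping the window extremes exactly to ±1.
Applied to the model equation this gives per-component channels
`d/y_half` and `(BL − y_min − y_half)/y_half`, and the scaled components
recompose to the scaled signal *exactly* (the map is affine).  The
consistency is what allows components-mode training in scaled space.
Note the plus sign in front of the cosine term of the scaled
recomposition; an affine map cannot flip it, and the package treats the
alternative sign as an erratum.

The phase is an angle, not a length; the wrapped phase is encoded
linearly onto [−1, 1) via `φ/180 − 1` so all three channels share one
numeric range.  A second encoding (`unwrapped_delta`, predicting the
phase increment) is reserved in the configuration but not implemented:
decoding it at inference would require decomposing the input window,
whose end lies beyond the window's last detectable anchor.

Scaling parameters always come from the input window only, never from
the future target, and predictions are unscaled with those same
parameters.

## Predictor and training

Architecture: three stacked LSTM layers (default 20 units each; the
model-selection grid is 40/30/20) and a dense head with 1 or 3 outputs.
The implementation is a compact NumPy one (float32, full backpropagation
through time, Adam, seeded initialisation: Glorot input kernels,
orthogonal recurrent kernels, unit forget-gate bias), with gradient
correctness pinned by numerical-derivative tests.

Input windows of 20–320 samples (1–16 s at 20 Hz) slide with stride 1 by
default; the target sits exactly `horizon` = 10 samples (500 ms) after
the window end, scaled with the window's own parameters.  Loss is MSE on
the scaled targets, channels weighted equally.  On the phase channel the
residual is wrapped to its principal value (period 2 in channel units),
i.e. the penalty is the minimal circular difference: an angle target on
a circle cannot be penalised linearly across the 0°/360° wrap without
the wrap dominating the loss — without this the phase channel plateaus
at ~3× the error of the other channels and drags the reassembled signal
with it.  Decoding is unchanged.

Datasets are split 4:1 into training/validation at subject level (all
traces of a subject on one side), deterministically under a seed.
Samples are reshuffled every epoch with the run's seeded generator; with
a fixed seed and BLAS configuration, training and prediction are
bit-reproducible, and a persisted model reloads to bit-identical
predictions.

Streaming prediction is causal: at each sample the trailing window is
filtered, scaled and fed forward, and the output is aligned to
`index + horizon`; the first `window + horizon − 1` output samples are a
gap.  A flat window yields no prediction.  Predicted deflection is
clipped at 0 before reassembly so the model equation stays valid.

## Evaluation

Per dataset: RMSE of the reassembled signal and of deflection/baseline in
mm; phase error is circular (minimal angular difference, bounded by
180°).  Datasets group into 'large' (any cycle amplitude strictly
> 12 mm peak-to-trough) and 'small'.  Cohort summaries are unweighted
mean ± sample SD (ddof = 1) over datasets, overall and per group; a
single-dataset group reports SD 0 with a flag.

## Synthetic data

The generator emulates the cohort statistics of the two surrogate sites:
'sternum' traces draw their mean amplitude from 2.4 ± 1.9 mm, 'abdomen'
from 10.7 ± 2.7 mm (between-trace), with per-cycle within-trace
variation of 12 % (amplitude) and 8 % (period, mean ~4 s — normal resting
respiratory rate).  Per-cycle deviations follow a stationary AR(1)
process (lag-1 correlation 0.7): successive breaths resemble each other,
as in real resting subjects — independent draws would make the next
cycle's envelope white noise and hence unpredictable in principle.  On
top come slow sinusoidal amplitude modulation (5–18 %, 45–90 s), baseline
wander (0.3–1.5 mm, 60–120 s), an end-exhale dwell exponent
n ∈ [1, 2.5] (waveform ∝ ((1+cos φ)/2)^n, extrema unchanged), and white
Gaussian noise (SD 0.3 mm) added last.  Anchors are quantised to the
20 Hz grid so that constant-parameter traces have exactly recoverable
ground truth; under modulation the detected peak can sit one sample off
the analytic anchor (the envelope slope shifts the extremum), so
recovery there is asserted at a looser tolerance.

What the generator does *not* emulate: coughs, talking, swallowing,
table motion, autocorrelated sensor noise, and the internal/external
correlation between surface and tumour motion.  Passing tests therefore
demonstrate the pipeline's correctness and the components-mode advantage
on quasi-periodic signals with realistic drift, not clinical performance
on disturbed breathing.

## Scaled-down study

`cyclopred.study.run_study(seed)` reproduces the method comparison at
desk scale: 12 training traces (8 abdomen, 4 sternum, 3 min each, one
subject each), 3 held-out test traces (2 abdomen, 1 sternum), window 160
(8 s), units 20/20/20, learning rate 0.01, batch 256, 30 epochs, both
models under the identical budget, plus the persistence baseline
(predict the last observed value).  Training windows are subsampled with
stride 4 (a window start every 200 ms): consecutive stride-1 windows
share 159 of 160 samples, so this prunes redundancy while keeping cycle
coverage.  Reported RMSEs are unweighted means over the held-out traces.

Two honest observations from running this study.  First, a floor
analysis: an oracle that takes the *true* decomposition components at
the window end and extrapolates them smoothly 500 ms ahead still incurs
a substantial RMSE, set by the AR(1) innovations (the next anchor is
unseen), the noise at the causal window boundary (no zero-phase filter
can denoise the most recent sample), and phase unobservability during
exhale dwells.  Learned predictors sit above that floor at this budget.
Second, at this scale the direct signal model can outperform the
components model: reassembly compounds three per-channel errors, whereas
the direct model pays the irreducible uncertainty once.  The advantage
of explicit cyclic encoding reported at full scale rests on training
across many heterogeneous subjects, where the scaled, decomposed
representation generalises better — a regime a 12-trace synthetic cohort
does not reach.  Both models beat the persistence baseline by a factor
of 2.5–4.

## Known limitations

* Envelope chords make the decomposition locally inexact near anchors
  (clamping, above); a spline envelope would trade this against
  overshoot.
* The wrapped phase channel remains hardest to learn near the wrap even
  with the circular loss; phase RMSE is dominated by those samples.
* The LSTM is CPU-bound NumPy; it is adequate for the trace lengths here
  but not for hyper-parameter sweeps over large cohorts.
* Only scalar single-point surrogates are supported, and no
  internal/external correlation model is included: predictions concern
  the surface signal, not the tumour position itself.
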