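# Methods

`sonouroflow` estimates urinary flowrate and bladder-emptying patterns from
the sound a voiding stream makes.  This note documents the models, the
parameter choices, the synthetic data the package is validated on, and the
limits of what that validation shows.

## Signal chain

**Levels and calibration.**  Recordings are mono sound-pressure signals.  If
the recording is not absolutely calibrated, a `calibration_offset` in dB maps
the digital scale to dB SPL (default 0 dB: samples are read as pascals, so a
1-Pa-RMS signal sits at 94 dB SPL).  Absolute levels measured by any given
microphone chain depend on that chain; the offset is the user's statement of
it.

**STFT.**  One-sided short-time Fourier transform, 4096-point FFT, window
length equal to the FFT size, 25% overlap (hop 3072 at the default settings),
periodic Hanning window `0.5*(1 - cos(2*pi*n/m))`.  Frames are stamped at the
window center, bins indexed from 0.  Per-bin levels are single-component RMS
levels in dB re 20 uPa: magnitudes are rescaled by `2/sum(w)` (half that for
DC/Nyquist) so a sine at a bin reads its physical RMS pressure.  An
overlap-add inverse is provided purely as a convention check: it reconstructs
the interior of the signal to < 1e-6 relative error.

**Loudness (sone).**  Stationary Zwicker-type loudness per STFT frame:

1. per-bin intensities are summed into third-octave bands (preferred base-10
   centers, 25 Hz-16 kHz);
2. each band's intensity is placed at its center's critical-band rate
   (Zwicker-Terhardt Bark formula; 1 kHz maps to ~8.5 Bark) and spread over a
   fixed 0.1-Bark grid on [0, 24] Bark with level-independent skirts of
   27 dB/Bark toward lower and 12 dB/Bark toward higher rates; component
   intensities add;
3. specific loudness per band:
   `N' = 0.08 (E_TQ/E0)^0.23 [(0.5 + 0.5 E/E_TQ)^0.23 - 1]`, clamped at 0
   (the raw expression goes negative below the threshold in quiet, where by
   definition nothing is heard).  `E_TQ` comes from Terhardt's analytic
   threshold-in-quiet approximation, `E0` corresponds to 1e-12 W/m^2;
4. total loudness `N = integral_0^24 N' dz` by the trapezoid rule.

The per-frame series is smoothed with a 50-ms exponential filter (a simple
stand-in for temporal loudness integration).  This is an ISO 532-1-style
calculation, not a certified implementation: the spreading slopes are fixed
rather than level-dependent, and no binaural stage exists.  The structural
properties that matter downstream — monotonicity in level, zero at/below
threshold, the `E^0.23` high-level power law — hold and are tested.

**Roughness (asper).**  `R = cal * 0.3 * f_mod[kHz] * integral dL(z) dz` with
the modulation frequency fixed at 70 Hz.  The signal is split into 24
one-Bark-wide Butterworth bands; each band's Hilbert envelope (decimated to
~3 kHz) is expressed in dB, band-passed around the modulation frequency
(2nd-order zero-phase Butterworth, [35, 140] Hz) and analyzed in 200-ms
blocks with 50% overlap (>= 14 modulation periods per block).  The masking
depth `dL(z)` is the peak-to-trough swing of that fluctuation per band,
capped at 50 dB so background noise cannot inflate the estimate; the cap is
interpreted as a ceiling on measured depth, not a fixed value.  The final
scalar `cal` was fitted once so that the reference signal — a 1-kHz tone at
60 dB SPL, 100% amplitude-modulated at 70 Hz, which *defines* 1 asper — yields
exactly 1, and is frozen in `ROUGHNESS_ASPER_SCALE` (`calibrate_asper_scale()`
reproduces it).  A recording's roughness is the median over blocks, robust to
filter edge transients.  Fixing `f_mod` at 70 Hz rather than estimating the
per-band modulation rate means sounds modulated far from 70 Hz are credited
less roughness than a full Daniel-Weber-style model would assign; the
envelope band-pass provides the modulation-rate selectivity.

## Flowrate ground truth and pattern labels

Flowrate is mass conservation: `V(t) = dW/dt / rho`, with the weight trace
smoothed by a 0.5-s moving average before central differencing (load cells
are noisy) and negative excursions clipped.  Urine density defaults to
1.0 g/mL and is configurable.

Voiding metrics: Qmax, trapezoid voided volume, voiding time (first to last
crossing of the span threshold), Qavg = volume/voiding time, and the number
of interruptions (sub-threshold gaps >= 1 s strictly inside the span).
Because clinical devices disagree on whether pauses count toward the
denominator, `q_avg_flowing` (volume / time above threshold) is also exposed.

The span threshold is `max(0.5 mL/s, 0.1 * Qmax)`.  A purely absolute
threshold is fragile: any additive noise that scales with the curve
amplitude — the bounded augmentation below, or sensor noise — eventually
exceeds a fixed 0.5 mL/s for strong streams and opens the detected span into
silent regions, manufacturing interruptions.  Tying the threshold to Qmax
makes span and gap detection invariant to amplitude scaling, which is what
the label rule needs.

Labels: **A** if Qmax > 15 mL/s with no interruptions and a bell-shaped
envelope; **C** if Qmax < 5 mL/s, or interrupted flow with Qmax < 7.5 mL/s;
**B** otherwise.  "Bell-shaped" is operationalized as: after 1-s smoothing,
a single peak above half maximum with prominence above 20% of the maximum,
and no interruptions.  The clinical rule leaves Qmax in [10, 15] mL/s
unassigned; such curves go to B (A additionally requires the bell shape).
All thresholds sit in `LabelThresholds` and are configurable; labels are
deterministic given the curve.

## Dataset assembly

* **Alignment**: features and flow are linearly interpolated onto a uniform
  grid over the intersection of their supports, at the coarser of the two
  native steps.
* **Normalization**: curves are mapped to [0, 1] on both axes and resampled
  to exactly 246 points.  The values are renormalized after interpolation
  (folding the factor into the stored `(t_min, t_max, v_max)` scale) so the
  peak is exactly 1, normalization is idempotent, and inversion is exact up
  to interpolation.  Classification therefore sees only curve *shape*.
* **Augmentation**: `V'(t) = |V(t) + A*rand(t)|`, `rand ~ U[-1, 1]` i.i.d.
  per sample, `A` drawn per copy uniformly from `(0, 0.05*max V)`; 100 copies
  per event.  The perturbation of any sample is strictly below `A`, so labels
  are invariant (the cohort parameter ranges keep every event at least a 5%
  margin from the clinical thresholds).  Augmentation happens before
  normalization.
* **Splitting**: patient-wise, so augmented copies of one patient never
  appear on both sides.  Regression inputs and targets are z-scored with
  train-split statistics only.

## Sequence models

One LSTM layer, gates `f, i, o` (sigmoid) and candidate `tanh`, cell update
`c_t = f*c_{t-1} + i*g`, output `h_t = o*tanh(c_t)`.  Weights act on the
concatenated `[h_{t-1}, x_t]`; initialization is seeded uniform Glorot with
zero biases except the forget gate, whose bias starts at 1 (the
mainstream-framework default).  With zero forget bias the cell state decays
with a factor ~0.5 per step, so over a 246-step sequence almost no gradient
reaches early inputs and training stalls at chance on some seeds; unit
forget bias keeps the memory pathway open at the start of training.  Forward and backward-through-time recurrences are written out
explicitly and numba-compiled; weight gradients are accumulated with batched
matrix products.  All computation is float64, single-threaded, and exactly
reproducible from the seed.

* **Regressor**: input `(loudness, roughness)` (a roughness-only 1-feature
  mode exists; using both features is the default and the more accurate
  variant), hidden size 5, one-neuron dense head on `h_t`, masked MSE over
  zero-padded batches of 3, Adam, 40 epochs.  Learning rate defaults to
  1e-2: with 40 epochs over cohort-sized data (a few hundred optimizer
  steps), 1e-3 leaves the model visibly underfit (held-out error ~6% even
  noiseless) while 1e-2 converges comfortably (<0.5% noiseless).  Predictions
  are de-standardized to mL/s and clipped at 0.
* **Classifier**: input the length-246 normalized curve, hidden size 50, the
  *last* hidden state feeds a dense 3-class softmax head,
  `y = softmax(W h_T + b)`; cross-entropy, Adam 1e-3, batch 3, 500 epochs by
  default (the synthetic benchmark below uses 50 — the classes separate long
  before that).
* **Evaluation**: the mean flowrate error rate of a predicted curve is
  `mean_t |pred - meas| / max(meas) * 100` on a shared grid.

## Synthetic voiding events

No recordings were deposited with the clinical study this pipeline is built
around, so the generator supplies events with the structure the pipeline
assumes, at 10 Hz with 2 s of silent padding:

* **bell** (label A): `s^2 (1-s)^4` on the unit interval — fast rise, slow
  decline — scaled to Qmax drawn from (16, 28) mL/s, voiding 15-35 s;
* **staccato** (B): the bell modulated by `1 - depth*sin^2(pi*n_dips*s)`,
  dips never reaching zero; Qmax in (8.0, 9.4) mL/s, 3-5 dips of depth
  0.4-0.65, voiding 30-60 s.  The lower Qmax bound keeps a >5% margin above
  the 7.5-mL/s interrupted-C boundary so augmentation cannot flip the label;
* **interrupted** (C): 2-4 `sin^2` bursts separated by >= 1.6-s zero-flow
  gaps, later bursts attenuated; Qmax in (3.0, 4.7) mL/s, voiding 50-90 s.

Weight traces are the cumulative trapezoid integral of `rho*V` plus Gaussian
sensor noise (0.5 g by default).  Sound features follow a forward model of
the observed co-variation between voiding-sound psychoacoustics and
flowrate: `loudness = 2.0 * V^0.6 * (1+eps)` sone, `roughness = 0.08 * V *
(1+eps')` asper, `eps` i.i.d. Gaussian with 5% standard deviation, negatives
clipped.  The power-law exponent reflects the compressive loudness-intensity
relationship; the gains place peak loudness/roughness in the plausible
few-sone / sub-asper range for a domestic voiding recording.  No quantitative
acoustic law for this mapping has been published, so these are the package's
own documented choices, deliberately kept in one spec object
(`ForwardModelSpec`) separate from the measurement pipeline.

**What the generator does not emulate**: actual splash acoustics, toilet and
room geometry, background noise spectra, microphone placement, inter-patient
anatomical variation, or any lag/dispersion between flow at the meatus and
sound at the bowl (a `lag` parameter exists but defaults to 0).  Passing
tests therefore demonstrate that the *pipeline* is correct and that the
models can learn the sound-to-flow association when it exists as assumed;
they do not certify clinical accuracy on real patients.

## Benchmark problem sizes

The repository's standing benchmarks use desk-scale cohorts: the classifier
benchmark trains on 10 patients/class x 100 augmented copies with an 80/20
patient-wise split for 50 epochs and reports the median held-out true-class
probability (observed ~0.9999; threshold 0.9); the regressor benchmark
trains on 48 of 60 events at 5% feature noise for 40 epochs and reports the
mean held-out flowrate error rate (observed ~1-5%, threshold 6.2%).  Both
are recomputed from scratch by `scripts/acceptance.py`.

## Known limitations

* The psychoacoustic chain approximates the standard models (fixed spreading
  slopes, fixed 70-Hz modulation frequency, no temporal masking); absolute
  sone/asper values for arbitrary real-world sounds will deviate from a
  certified analyzer, though orderings and trends are preserved.
* The classifier consumes shape-normalized curves, so it cannot distinguish
  patterns that differ only in amplitude or duration; that information lives
  in the metrics/rule-based labeler, which is also the arbiter for training
  labels.
* Qavg against span-based voiding time is systematically below devices that
  exclude pauses; both definitions are reported.
* The LSTM training loop is plain SGD-with-Adam at fixed hyperparameters; no
  early stopping, no regularization.  At the benchmark sizes this is
  sufficient and keeps runs exactly reproducible.
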