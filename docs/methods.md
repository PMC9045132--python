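# Methods

`sleepmci` implements a two-channel (C3/C4) sleep-EEG analysis pipeline
for separating mild cognitive impairment (MCI) from healthy controls
(HC): preprocessing and artifact rejection, sleep-spindle and slow-wave
detection, spectral/complexity/event feature extraction conditioned on
sleep stage, and SVM / bidirectional-GRU classification. Because the
pipeline is exercised on synthetic data, the package also contains a
first-class cohort generator whose output carries the group-level
structure the analysis is meant to pick up.

## Signal model and synthetic cohorts (`synth`)

Background EEG is modeled as spectrally shaped Gaussian noise: a white
Gaussian spectrum is multiplied by f^(−β/2) (default β = 1, the classic
1/f EEG background), inverse-transformed, and scaled to a target RMS
(default 10 μV). This is the simplest process with a controllable band
structure; autoregressive alternatives would add poles the analysis never
relies on.

Events are superimposed on (not spliced into) the background, which is
how detectors see real data:

* **Spindles** — sinusoids at a frequency drawn from 12–14 Hz under a
  raised-cosine envelope, peak amplitude 25 μV, duration 0.6–1.5 s,
  placed by a Poisson process at 2 events/min (HC) inside N2 epochs only.
* **Slow waves** — a negative half-sine followed by a positive half-sine.
  The trough takes 5/8 of the trough-to-peak (PTP) amplitude and the
  positive peak 3/8, so that over the detector's admissible PTP range
  (75–400 μV) both peaks stay inside the per-peak candidate windows
  (−40…−300 μV and 10…150 μV). Rate 4/min (HC) in N2∪N3, PTP drawn from
  100–250 μV.
* **Artifacts** — 1–3 s transients at 100× the background RMS (mV
  scale, as movement/electrode artifacts are), placed in any stage at
  2/hour and applied to all channels at once (movements are global
  events). Their intervals are recorded in the ground truth and serve as
  the synthetic stand-in for a recording's manual artifact annotations.
  The amplitude matters: transients comparable to slow waves (tens of
  μV) disappear inside the natural between-window variance and no
  outlier rule can see them.

Group effects for MCI recordings: spindle rate × 0.5, slow-wave rate and
PTP × 0.7, and a ×1.5 gain applied to a 4–8 Hz band-filtered copy of the
background added back in, which raises relative theta power without
changing event morphology. No published effect sizes exist for these
contrasts at the segment level; the defaults are configurable and were
fixed once at field-plausible magnitudes. The stage schedule defaults to
a ~35-min compressed night (wake – N1 – N2 – N3 – N2 – REM – wake) whose
N2/N3 block yields four 300-s NREM windows and whose wake blocks yield
two; real nights are hours long, but the per-segment feature
distributions, which are what the classifiers consume, do not depend on
recording length.

A fixed seed makes the whole cohort bit-identical (signals, truths,
labels). What the generator does **not** emulate: K-complexes, REM
sawtooth waves, inter-subject spectral variability, age/MMSE covariates,
channel asymmetries. Passing tests therefore demonstrate that the
pipeline recovers the structure it is pointed at, not that it would reach
any particular accuracy on clinical recordings.

## Preprocessing (`preprocess`)

Recordings are bandpassed 0.1–30 Hz with a zero-phase windowed-sinc FIR
(Hamming window, transition width 0.1× the band edge with a 0.1 Hz
floor, forward–backward application) and then downsampled to 100 Hz by a
polyphase anti-aliased resampler. Filtering happens at the native rate,
before downsampling, to prevent aliasing. Hypnograms (one stage code per
30-s epoch; W=0, N1=1, N2=2, N3=3, REM=5) are expanded to sample
resolution by repetition and must match the signal length exactly.

Segmentation tiles every maximal run of eligible stages with
non-overlapping 300-s windows, left to right. NREM windows must be 100%
N2/N3 — a window straddling any other stage is never emitted. Windows
overlapping annotated artifact intervals are dropped first; the surviving
windows' per-channel standard deviations are log-transformed and
z-scored (pooled over channels, separately per state so the systematic
NREM/wake variance difference cannot masquerade as artifact), and any
window with |z| > 3 on any channel is excluded. The threshold is the
conventional two-sided 3-SD outlier cut and is configurable; z-scoring
log-SDs makes the rule invariant to global amplitude rescaling.

The pooling scope of the z-scores matters at desk scale.
`segment_and_reject` pools within one recording — correct semantics,
but a short recording yields only a handful of windows, and with n
windows no z-score can exceed (n−1)/√n, so a 3-SD cut cannot fire below
n ≈ 11. The cohort pipeline (`extract_cohort_features`, and the
analysis scripts) therefore pools the candidate-window SDs per state
across the whole cohort, which is also how a full study population is
screened. With every simulated artifact annotated, the pooled rule acts
as a backstop for unannotated artifacts; its firing behavior is
unit-tested with targeted variance injections.

## Spectral features (`spectral`)

Welch PSD per 300-s segment: 5-s Hamming windows, 50% overlap, median
aggregation across windows (robust to residual transients). The median is
taken plainly over per-window periodograms, without a small-sample
median-bias correction — the relative powers that drive the analysis are
ratios and cancel any common factor; Parseval-style absolute checks in
the tests use mean aggregation, where the integral of the density equals
the signal variance.

Band edges (configurable): delta 0.5–4, theta 4–8, alpha 8–12, sigma
12–16, beta 16–30, gamma 30–40 Hz — conventional edges that exactly tile
the 0.5–40 Hz total range, so the six relative powers sum to 1.
Absolute powers are trapezoid integrals of the density with interpolated
fractional end bins; total power is the integral over 0.5–40 Hz;
relative power is the ratio. The spectral block is 13 features: six
absolute, the total, six relative. Note the 0.1–30 Hz front-end filter
attenuates the 30–40 Hz gamma band; gamma is still computed as the
integral of the residual density, and the upper filter edge is
configurable for users who want unattenuated gamma.

## Spindle detection (`spindles`)

Three time-resolved criteria on two filtered copies of the segment
(broadband 1–30 Hz, sigma 12–15 Hz; zero-phase FIR, 1.5 Hz transition):

1. **relative sigma power** from 2-s STFT windows at a 200-ms hop,
   threshold 0.2;
2. **moving correlation** — Pearson r between the broadband and sigma
   traces over 300-ms windows at 100-ms steps, threshold 0.65;
3. **moving RMS** of the sigma trace (same windows), threshold
   mean + 1.5 × SD of the RMS series.

All three series are linearly interpolated from window centers to the
sample grid with edge hold. The per-sample count of satisfied criteria
(0–3) is smoothed with a 100-ms moving average; runs where the smoothed
count reaches 2 seed events, whose boundaries extend across the
surrounding samples where ≥ 2 raw criteria hold. Events closer than
500 ms are merged; events outside 0.5–2.0 s are discarded (the upper
bound is the standard spindle ceiling; it is configurable).

Per-event measures: amplitude = PTP of the sigma trace in the event;
RMS; abspower = log₁₀ of the median squared sigma amplitude; relpower =
mean relative sigma power; frequency = mean instantaneous frequency from
the analytic (Hilbert) phase of the sigma trace; oscillations = count of
negative-to-positive zero crossings. Segment features are the density
(events/min) plus the means of the seven event measures — zeros when no
events, since zero density is the true value and the means are undefined
(a dense matrix keeps the classifier input well-formed).

Two behaviors worth knowing about: the threshold statistics are adaptive
(the RMS threshold is defined relative to the segment itself), so pure
background yields occasional short detections — on the synthetic
conditions used in the tests this costs nothing at the stated
recall ≥ 0.9 / precision ≥ 0.8 margins (both measure 1.0); and strong
sub-0.5-s bursts can smear past the minimum-duration rule through the
sigma filter's impulse response, which is inherent to band-limited
duration measurement.

## Slow-wave detection (`slowwaves`)

On the 0.3–2 Hz filtered trace (FIR, 0.2 Hz transition): candidate
troughs in [−300, −40] μV and positive peaks in [10, 150] μV (minimum
peak separation 0.2 s against ripple duplicates); each trough pairs with
the nearest **subsequent** positive peak (the negative-then-positive
slow-wave convention). Phase durations come from the zero crossings
bracketing each peak; slope = |trough| ÷ time from trough to the next
zero upcrossing. An event survives only if PTP ∈ [75, 400] μV, negative
phase 0.3–1.5 s, positive phase 0.1–1 s, slope > 0. Duration is the sum
of the two phase durations, frequency its reciprocal; overlapping events
are resolved in favor of the larger PTP. The amplitude windows apply to
the filtered trace, which is where the candidate peaks are found.

## Complexity features (`complexity`)

Eight measures in fixed order: permutation entropy, SVD entropy, sample
entropy, the DFA scaling exponent, Petrosian, Katz and Higuchi fractal
dimensions, and Lempel–Ziv complexity. None of their hyperparameters are
dictated by the problem; the defaults are the field-standard choices and
all are configurable and recorded in the run manifest:

* permutation / SVD entropy: order m=3, delay 1, normalized by log(3!)
  and log(3);
* sample entropy: m=2, r=0.2×SD, Chebyshev distance via a KD-tree pair
  count; evaluated on a centered 3000-sample (30-s) window of the
  segment — the estimate is stable at that length for m=2 and keeps
  cohort-scale extraction fast;
* DFA: first-order detrending, 16 window sizes log-spaced in [4, n/10],
  exponent by least squares on the log–log fluctuation curve (0.5 for
  white noise, 1.5 for Brownian motion — both verified in tests);
* Higuchi: k_max=10; Petrosian from sign changes of the first
  difference; Katz from the path length/diameter closed form;
* Lempel–Ziv: binarize at the median, LZ76 exhaustive-history phrase
  count, normalized by n/log₂(n).

A constant segment (entropy undefined) returns zeros with a QC flag
rather than raising, so one degenerate segment cannot abort a cohort run.

## Feature assembly (`features`)

Each kept time window yields one row: per-channel features are averaged
across C3/C4. Averaging is the only two-channel fusion consistent with
the 36-wide NREM vector (13 spectral + 8 complexity + 8 spindle + 7
slow-wave); concatenation would double the width. Wake rows carry
spectral + complexity only (21). The column order is a frozen contract
(`NREM_FEATURES` / `WAKE_FEATURES`). If one channel is missing the other
is used as-is with a QC flag (configurable to hard-fail).
Standardization is z-scoring with means/SDs estimated on training rows
only — computing them on all rows would leak test-set statistics into
training. A feature constant on the training rows gets SD 1 and a flag,
producing an all-zero column instead of NaNs.

## Classification (`classify`, `gru`)

**SVM** — cubic polynomial kernel (sklearn SVC, coef0 = 1). Presets:
gamma = 2.15, C = 1 for NREM features; gamma = 13.2, C = 2 for wake.
When either hyperparameter is unset, a grid search under stratified
10-fold cross-validation picks the pair (replacing Bayesian
optimization; the preset optima are shipped). Decision values are
squashed to [0, 1] MCI scores by a logistic map — rank-preserving, so
ROC and AUC are unaffected by the choice.

**Bi-GRU** — implemented from scratch in numpy: the standard
update/reset/candidate gate equations, three stacked bidirectional
layers (hidden 89 for NREM, 59 for wake), inverted dropout 0.5 between
layers, a 2-node softmax head on the concatenated final states, binary
cross-entropy loss, Adam (learning rate 10⁻³), batch size 32, up to 200
epochs. Gradients are computed by backpropagation through time and are
verified against central finite differences in the tests. Each segment's
feature vector enters as a length-1 sequence — the features are a fixed
set per segment with no natural time axis — but the implementation
supports k-step sequences for experimentation. Epoch selection follows
the stated protocol: per-epoch validation accuracy is averaged over
stratified CV folds, the best epoch is chosen, and a final model is
trained on all training rows for that many epochs. All randomness (init,
shuffling, dropout, folds) derives from one seed, making training
deterministic.

**Evaluation** — confusion counts at score threshold 0.5;
sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
accuracy = (TP+TN)/total, F1 = 2·precision·recall/(precision+recall),
all in percent; ROC by sweeping the threshold over observed scores, AUC
by the trapezoid rule.

**Splitting** — stratified random 80/20 at the segment level by default,
which mirrors the original protocol but lets segments of one subject
appear on both sides; a subject-level grouping mode is provided and is
the right choice when estimating generalization to new subjects. The
difference matters: segment-level splits are optimistic whenever
subject identity correlates with features.

## Group statistics (`stats`)

Per band and state, relative powers of the two groups are compared with
a two-sided Mann–Whitney U test (scipy; normal approximation with tie
correction at these sample sizes), marked * for p < 0.05 and ** for
p < 0.01. Observations are segments by default (matching the
segment-level analysis); a subject-mean mode exists because segments
within a subject are not independent, and no multiple-testing correction
is applied by default (a Bonferroni option is exposed).

## Problem sizes and runtime

The shipped analysis and the test suite use cohorts of 8 HC + 8 MCI
subjects with ~35-min recordings (64 NREM and 32 wake rows), ten seeded
80/20 splits for the classifier comparison, 100-epoch GRU budgets in the
scripted runs, and detector sweeps of 20–25 injected waves. These sizes
were chosen so a full run completes in minutes on one CPU while leaving
every distributional property testable; all of them scale up through
configuration without code changes.

## Known limitations

* Two channels only; no re-referencing, notch filtering, or ICA — on
  two channels ICA is ill-posed, and artifact handling rests on
  annotations plus the log-SD rule.
* The detectors' thresholds are segment-adaptive; extremely event-dense
  segments shift the RMS threshold upward and can mask weaker spindles.
* Synthetic waveforms are stylized (half-sine slow waves, enveloped
  sinusoid spindles); morphology-sensitive conclusions do not transfer
  to clinical data without validation on real recordings.
* Gamma-band features sit above the default front-end filter edge and
  are strongly attenuated unless the filter is reconfigured.
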