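# Methods

## Problem and scope

The package detects pathological tremor in 1-second windows of wearable
signals, as a binary classification (*Tremor* / *No Tremor*) meant for
tremor-triggered interventions such as closed-loop peripheral electrical
stimulation. Three input modalities are supported: the wrist
flexion–extension angle from paired hand/forearm IMUs (50 Hz), the
tremor-band surface-EMG envelope (50 Hz), and minimally processed raw EMG
(510 Hz). No features are extracted: each window's sample sequence is the
classifier input.

## Synthetic cohort generator

Clinical recordings of this kind are rarely shareable, so the package
ships a generator that emulates the recording session: by default 12
patients and 11 healthy controls, 14 repetitions of a 60-s postural trial
each, IMU quaternions at 50 Hz and bipolar FCR/ECR EMG at 2042 Hz.

**Kinematics.** The forearm sensor carries slow postural drift — a
random walk low-passed below 1 Hz, 2° RMS. The hand sensor is the forearm
orientation composed with a rotation about the forearm mediolateral (x)
axis, `q_hand = q_forearm ⊗ q_rel`; the same convention is inverted
exactly by the preprocessing. Patients receive a flexion–extension
sinusoid with per-subject frequency f_t ~ U(4, 10) Hz and amplitude
A ~ U(3, 12)°, both jittered ±5% cycle-to-cycle through a slowly varying
instantaneous frequency and amplitude (tremor is variable and
non-stationary; a pure sinusoid would be unrealistically easy). Healthy
subjects receive drift, 0.1° RMS sensor noise and a faint physiological
tremor: an 8–12 Hz oscillation at 5% of the mean pathological amplitude.

**EMG.** Interference-pattern surface EMG is surrogated by band-limited
Gaussian noise (20–450 Hz) — the standard amplitude-modulation surrogate
rather than a motor-unit-level simulation, which no downstream stage
needs. Patients: the carrier is amplitude-modulated by a non-negative
burst train, a half-wave-rectified sinusoid at f_t over a baseline, with
modulation depth d ~ U(0.5, 0.9) and FCR/ECR bursts in antiphase
(alternating flexor/extensor activity). Bursts peak at 20% MVC-equivalent
activation (`burst_mvc_fraction`), with the inter-burst baseline at
(1 − d) of that; healthy subjects produce a constant 10% MVC isometric
analog with a 3–4% physiological modulation. The two levels keep total
power comparable between classes while giving tremor bursts the larger
amplitude excursions seen in real recordings — an amplitude-free variant
(both classes equalized in RMS) makes raw-EMG windows nearly
class-uninformative for every amplitude-sensitive model, which real data
demonstrably is not. White measurement noise is added at 20 dB SNR by
default.

Generation is a pure function of the configuration: every recording's
random substream is keyed by (seed, subject, trial), so iteration order
and laziness cannot change the data. Per-subject draws are logged in the
manifest for recovery tests.

What the generator does **not** emulate: motor-unit recruitment and firing
statistics, line interference, electrode artifacts beyond hard clipping,
rest/kinetic tremor variants, intermittent tremor within a trial, and the
two distinct clinical postures. Passing tests therefore demonstrate that
the pipeline recovers the structure this model encodes — tremor-band
oscillation against realistic drift/noise — not clinical performance.

## Preprocessing

- Wrist angle: `q_rel = conj(q_forearm) ⊗ q_hand`, intrinsic X-Y′-Z″ Euler
  decomposition, first angle in degrees. Non-unit quaternions (norm error
  > 1e-6) raise; near-gimbal configurations (second angle within 1e-3 rad
  of ±π/2) warn but return. The Euler convention is fixed to match the
  generator — self-consistency over anatomical fidelity, since no
  convention is canonical.
- Tremor band-pass: 2nd-order Butterworth [4, 10] Hz applied
  forward–backward (`sosfiltfilt`), i.e. zero net phase and doubled
  effective order — the standard reading of "2nd-order zero-lag".
- EMG screening: an automated stand-in for visual quality inspection.
  SNR = 10·log10 of integrated Welch power inside the 20–450 Hz carrier
  band over power outside it (excluding the 4–10 Hz band where legitimate
  modulation lives); accept at ≥ 6 dB and no clipping run of ≥ 3 samples
  at the amplitude extreme.
- Downsampling: polyphase rational resampling, 2042 → 510 Hz with the
  exact fraction 255/1021 (decimating by 4 would give 510.5 Hz and break
  the 510-sample window length), and 510 → 50 Hz (5/51) for envelopes.
- Envelope: full-wave rectification, the shared zero-lag band-pass at the
  input rate, then the polyphase resampler to 50 Hz (tremor content sits
  far below the 25 Hz post-decimation Nyquist). In the default pipeline
  the envelope is computed from the 510 Hz stream.
- Windows: consecutive non-overlapping 1-s segments; the trailing
  remainder is dropped. Overlap is exposed for streaming-oriented use but
  defaults to 0.
- Normalization: the whole dataset is mapped affinely to [0, 1] by its
  global min/max (replicating the study protocol, which normalizes before
  splitting). This leaks test amplitude statistics by construction; a
  train-only stats mode is available via the returned (min, max).

## Labeling

Each window's Hann periodogram (density scaling; ~1 Hz resolution at
50 Hz) is reduced to its peak inside [4, 10] Hz. The global threshold is
the 99th percentile of the no-tremor (healthy-subject) peak distribution,
calibrated per modality because the statistic's units differ between the
band-passed angle and the EMG envelope. Ties go to *No Tremor* (strictly
greater ⇒ *Tremor*). Kinematic windows are labeled from the band-passed
angle; envelope windows from themselves; raw-EMG windows inherit the
label of the time-aligned envelope window. Patients can and do contribute
*No Tremor* windows.

The 99th-percentile choice fixes the healthy-side disagreement at ~1% by
construction. On the patient side, a noiseless probe
(`envelope_peak_probe`) measures the pipeline's response to a given
(f_t, depth): patients whose tremor frequency sits at the band edges lose
line power to the filter roll-off and can fall within a factor ~2 of the
threshold, where window-to-window periodogram noise produces missed
windows. This is an inherent property of band-limited PSD thresholding,
not of the generator.

## Models

Classical models are scikit-learn estimators with the protocol's fixed
settings (KNN: ball-tree, distance weights; SVM: RBF; RF: entropy,
min_samples_leaf = 2), tuned by exhaustive grid search with stratified
10-fold CV selecting on mean f1. The shipped grids are small supersets of
the per-modality optima used for final assessment (`OPTIMAL_HYPERPARAMS`).

The LSTM is implemented in numpy: two stacked LSTM layers (equal hidden
size: 20, 35 or 50), a linear readout on the last hidden state of layer 2,
sigmoid output, binary cross-entropy, Adam (grid learning rates 0.005,
0.001, 0.0001), batch size 64, parameters checkpointed whenever the
validation loss improves. Backpropagation through time is verified against
central finite differences. Numerical choices:

- float64 arithmetic. Gradients attenuate exponentially through long
  sequences; in float32 they fall into the denormal range, which both
  stalls the CPU and silently zeroes the learning signal for early
  timesteps.
- Global gradient-norm clipping at 0.25. At the protocol's largest
  learning rate (0.005) Adam steps otherwise overshoot right after the
  loss breaks from its initial plateau; clipping keeps all three grid
  learning rates usable.
- Internal input standardization: training-set mean/SD are stored and
  applied before the first layer. The [0, 1] dataset normalization leaves
  within-window fluctuations at a scale of ~0.01–0.05; at torch-style
  uniform init the recurrent state then converges to an input-independent
  fixed point over a few hundred timesteps and the readout sees a constant.
  Z-scoring is equivalent to rescaling input weights/biases and removes
  the dependence of trainability on the dataset's global amplitude range.
- Weight init U(−k, k), k = 1/√hidden; seeded init and batch shuffling
  make training bit-reproducible.
- max_epochs defaults to 150 with optional early-stopping patience;
  scaled-down runs in the tests use ≤ 50 epochs, patience 8.

## Evaluation

precision, accuracy, recall, specificity and f1 from the confusion counts
with Tremor positive. Zero-denominator ratios return 0 with an explicit
flag, so reports are total. Aggregations (mean ± SD of f1 across
modalities per model and vice versa) use population SD (ddof = 0),
recorded in the table metadata. The comparison report provides the tidy
score table, the f1 model × modality matrix and grouped-bar/heat-map
plots.

## Problem sizes used in tests and the acceptance script

Dataset-construction checks run the full default cohort (23 subjects × 14
trials): 18,000 kinematic windows (9,000 per class) and 8,000 per EMG
modality (4,000 per class), split 70/30 and 70/15/15. Classifier-recovery
checks run 2,000-window balanced datasets per modality from a 4-trial
cohort — large enough for stable scores, small enough for a desk-scale
single-CPU run. The label-shuffled leakage control averages three
independent shuffles per family; the LSTM control is scored by accuracy
(with an f1 ceiling) because a constant-output chance predictor has a
degenerate f1 of 0 or 2/3.

## Known limitations

- Band-edge tremor (f_t within ~0.5 Hz of 4 or 10 Hz) is intrinsically
  hard for the PSD-peak labeling; agreement with design labels drops for
  those subjects first.
- The LSTM's plateau-then-breakthrough training dynamics make its final
  score sensitive to the validation checkpoint at the largest learning
  rate; the checkpointing rule (keep best validation loss) is what makes
  those runs usable.
- Whole-dataset normalization replicates the protocol but leaks test-set
  amplitude statistics; use the train-only mode for honest generalization
  estimates on real data.
- Classical models are weak on raw EMG in this synthetic setting: with
  class-comparable total power, the only raw-window cues are burst-scale
  amplitude excursions, which distance-based learners exploit poorly
  (KNN with the Chebyshev metric can fall below chance because
  high-amplitude windows are far from everything, including each other).
  Random Forest and the LSTM handle the modality; mirroring the study's
  own ordering, raw EMG is the hardest input for classical models.
- The LSTM raw-EMG score is the most seed-sensitive number in the
  acceptance report: training rides a plateau, breaks through, and can
  collapse again at the largest learning rate, so the final score depends
  on which epoch the best-validation checkpoint captured.
- FCR and ECR are treated as independent instances (scalar-per-timestep
  sequences); a stacked two-channel mode is not implemented.
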