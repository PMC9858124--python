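# tremordetect

Binary detection of pathological tremor — *Tremor* vs *No Tremor* — from
1-second windows of wearable-sensor signals, using classical machine
learning (KNN, SVM, Random Forest) and a two-layer LSTM, **without any
feature extraction**: the classifiers consume the raw signal sequence of
each window.

## Who this is for

Researchers developing closed-loop peripheral electrical stimulation (PES)
or other tremor-responsive systems need a detector that decides, window by
window, whether tremor is currently present in a kinematic or
electromyographic signal. This package implements such a detection
pipeline end-to-end and, because clinical recordings are rarely shareable,
ships a statistically matched synthetic cohort generator so every stage is
testable and reproducible.

## The pipeline

Three input modalities are derived from a cohort of essential-tremor
patients and healthy controls holding a tremor-eliciting posture for 60 s:

1. **Wrist flexion–extension angle** (50 Hz). Paired hand/forearm IMUs
   stream unit quaternions; the relative orientation
   `q_rel = q_forearm* ⊗ q_hand` is decomposed into intrinsic X-Y′-Z″
   Euler angles, flexion–extension first.
2. **EMG envelope** (50 Hz). Bipolar surface EMG from the wrist flexor
   (FCR) and extensor (ECR), 2042 Hz, is downsampled to 510 Hz, full-wave
   rectified, band-passed 4–10 Hz (2nd-order zero-lag Butterworth) and
   resampled to 50 Hz.
3. **Raw EMG** (510 Hz), the minimally processed alternative.

Windows are auto-labeled by a spectral rule: the peak of the Hann
periodogram inside the tremor band [4, 10] Hz is compared with a global
threshold calibrated as the 99th percentile of the healthy-subject
(no-tremor) peak distribution; strictly greater ⇒ *Tremor*. Raw-EMG
windows inherit the label of their time-aligned envelope window. Balanced
datasets (9,000 windows per class for kinematics, 4,000 per class for
each EMG modality) are normalized to [0, 1] and split 70/30 (classical
models) or 70/15/15 (LSTM).

Models: KNN (ball-tree, distance weights), RBF-kernel SVM and
entropy-criterion Random Forest tuned by exhaustive grid search with
10-fold cross-validation on mean f1; and a two-layer LSTM whose final
hidden state feeds a linear readout with sigmoid output, trained with
Adam on binary cross-entropy, checkpointing parameters whenever the
validation loss improves. The LSTM is implemented in numpy in this
package (forward pass, backpropagation through time, Adam), verified by
finite-difference gradient checks.

Evaluation uses, with Tremor positive,

    precision = TP/(TP+FP)        recall      = TP/(TP+FN)
    accuracy  = (TP+TN)/n         specificity = TN/(TN+FP)
    f1        = 2·P·R/(P+R)

## Worked example

```python
from tremordetect import CohortConfig, build_datasets, run_experiment, compare_report

cfg = CohortConfig(n_patients=4, n_healthy=4, n_trials=3,
                   trial_duration=30.0, seed=7)
datasets = build_datasets(cfg, n_kin_per_class=300, n_emg_per_class=300)
result = run_experiment(datasets, families=("knn", "svm", "lstm"), seed=0,
                        lstm_max_epochs=30, lstm_patience=10)
print(compare_report(result.reports)["f1_matrix"].round(3))
```

prints (this is the exact output of `examples/03_train_and_evaluate.py`):

```
modality  emg-envelope  emg-raw  kinematic-angle
model
knn              0.971    0.141            0.994
lstm             0.966    0.946            0.989
svm              0.941    0.566            0.994
```

Each cell is the f1 score of one model on the held-out test windows of one
modality. The clean kinematic and envelope modalities are separated almost
perfectly by every family; raw EMG is where the models diverge — the LSTM
still reaches f1 ≈ 0.95 from the unprocessed sequence while
distance-based classical models degrade sharply, mirroring the ordering
observed on clinical data (KNN weakest on raw EMG, LSTM strongest).
`examples/` contains one short script per capability (cohort simulation,
preprocessing + labeling, training + evaluation, metrics).

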