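"""Train classifiers on labeled windows and compare them across modalities.

Classical models (here KNN and SVM) take the flat 50- or 510-sample window
as a feature vector; the LSTM reads it as a sequence and classifies from
its final hidden state. Scores are precision, recall, specificity,
accuracy and f1 on a held-out stratified test partition.
"""

from tremordetect import (CohortConfig, build_datasets, compare_report,
                          run_experiment)

cfg = CohortConfig(n_patients=4, n_healthy=4, n_trials=3,
                   trial_duration=30.0, seed=7)
datasets = build_datasets(cfg, n_kin_per_class=300, n_emg_per_class=300)

result = run_experiment(datasets, families=("knn", "svm", "lstm"), seed=0,
                        lstm_max_epochs=30, lstm_patience=10)

report = compare_report(result.reports)
print(report["scores"].round(3).to_string(index=False))
print("\nf1 by model and modality:")
print(report["f1_matrix"].round(3).to_string())
print("\nmean +- SD of f1 across modalities per model:")
print(report["by_model"].round(3).to_string())
print("\n(values near 1.0 = near-perfect separation of Tremor vs No "
      "Tremor windows on this clean synthetic cohort)")
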