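"""The five evaluation metrics from raw confusion counts.

Tremor is the positive class. With TP=8, FP=2, FN=4, TN=6:
precision = 8/10 = 0.8, recall = 8/12 = 0.667, f1 = harmonic mean = 0.727,
accuracy = 14/20 = 0.7, specificity = 6/8 = 0.75.
"""

from tremordetect import metrics
from tremordetect.types import ConfusionCounts

m = metrics(ConfusionCounts(tp=8, fp=2, fn=4, tn=6))
for name in ("precision", "recall", "f1", "accuracy", "specificity"):
    print(f"{name:12s} {getattr(m, name):.4f}")
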