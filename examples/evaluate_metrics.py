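"""Two-class evaluation statistics from a confusion matrix.

Worked example: a held-out test split of 92 candidate MK images — 53 true
CD41⁺ and 39 true CD41⁻ — with 1 false negative and 2 false positives.
"""

from mkflow import ConfusionMatrix, report

cm = ConfusionMatrix(tp=52, fp=2, tn=37, fn=1)
rep = report(cm).rounded()

print("confusion counts: TP=52  FN=1  FP=2  TN=37")
print(f"overall accuracy: {rep['accuracy_pct']}%")
for cls, m in rep["per_class"].items():
    print(f"{cls}: support={m['support']}  precision={m['precision_pct']}%  "
          f"recall={m['recall_pct']}%  F1={m['f1_pct']}%")
w = rep["weighted"]
print(f"support-weighted: precision={w['precision_pct']}%  "
      f"recall={w['recall_pct']}%  F1={w['f1_pct']}%")
print("\nRecall of the positive class is the share of true MKs retrieved; "
      "recall of the negative class is the share of platelet-adhesion "
      "false positives correctly excluded.")
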