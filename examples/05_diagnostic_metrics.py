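"""Diagnostic metric suite, ROC/AUC and the 1% index-agreement rule.

Twelve standard indicators of a binary diagnostic test follow from the
confusion counts (or from sensitivity and specificity alone when prevalence
is unknown). AUC is the Mann-Whitney rank statistic.
"""

import numpy as np

import ki67score as k

# Derived indicators from a published operating point of an IDC classifier.
suite = k.metric_suite_from_rates(sensitivity=0.8505, specificity=0.9523)
for name, value in suite.as_dict(ndigits=4).items():
    print(f"{name:>18}: {value}")
# Youden index = sens + spec - 1 summarizes the operating point in one
# number; NLR ~ 0.16 means a negative call divides the disease odds by ~6.

counts = k.ConfusionCounts(tp=182, fp=9, tn=187, fn=32)
full = k.metric_suite(counts)
print(f"\nfrom counts (n={counts.total}): accuracy {full.accuracy:.4f}, "
      f"PPV {full.ppv:.4f}, NPV {full.npv:.4f}")

rng = np.random.default_rng(0)
scores = np.concatenate([rng.normal(0.7, 0.15, 60), rng.normal(0.4, 0.15, 140)])
truth = np.array([True] * 60 + [False] * 140)
print(f"\nAUC of a noisy scorer: {k.roc_auc(scores, truth):.3f} "
      f"(1.0 = perfect ranking, 0.5 = chance)")

agree, err = k.index_agreement(29.68, 30.00, tolerance=1.0)
print(f"\nKi-67 indices 29.68% vs 30.00%: error {err:.2f} pp -> "
      f"{'agree' if agree else 'disagree'} at the 1% competition rule")
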