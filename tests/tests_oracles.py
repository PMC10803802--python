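"""Small brute-force oracles shared by test modules.

Kept independent of drgkit internals: plain-python confusion-matrix F1 and
O(n^2) concordant-pair AUC.
"""

import numpy as np


def pair_count_auc(scores, positives):
    """Concordant-pair AUC with midrank ties: P(score_pos > score_neg) + 0.5 ties."""
    pos = [s for s, p in zip(scores, positives) if p]
    neg = [s for s, p in zip(scores, positives) if not p]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def confusion_f1_macro(preds, targets, n_classes):
    """Macro F1 from an explicitly built confusion matrix; 0/0 -> 0."""
    preds = np.asarray(preds)
    targets = np.asarray(targets)
    f1s = []
    for c in range(n_classes):
        tp = int(((preds == c) & (targets == c)).sum())
        fp = int(((preds == c) & (targets != c)).sum())
        fn = int(((preds != c) & (targets == c)).sum())
        denom = tp + 0.5 * (fp + fn)
        f1s.append(tp / denom if denom > 0 else 0.0)
    return float(np.mean(f1s))
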