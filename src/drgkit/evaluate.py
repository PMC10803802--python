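"""Metric suite for DRG classifiers.

Top-k accuracy, macro/micro F1, one-vs-rest macro/micro AUC, bootstrap
standard deviations, per-class frequency analysis, and the two-label report
(base-DRG block, CC/MCC block, final-DRG accuracy after the mapping rule).

Note an identity that anchors several checks: in single-label multi-class
scoring over *all* classes, micro-averaged F1 equals top-1 accuracy, because
every misclassification is simultaneously one false positive and one false
negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score, roc_auc_score

from .catalog import CcMccLabel, DrgCatalog, LabelSpace, infer_drg


def topk_accuracy(
    ranked: Sequence[Sequence[int]], targets: Sequence[int], k: int
) -> float:
    """Fraction of records whose target appears among the first k ranked labels."""
    if k < 1:
        raise ValueError("k must be >= 1")
    hits = sum(1 for r, t in zip(ranked, targets, strict=True) if t in list(r)[:k])
    return hits / len(targets)


def f1_scores(
    top1: Sequence[int],
    targets: Sequence[int],
    averaging: str = "macro",
    class_set: Sequence[int] | None = None,
) -> float:
    """Macro or micro F1 of top-1 predictions.

    Macro averages per-class F1 over ``class_set`` (default: classes present
    in the targets); classes with no true and no predicted instances
    contribute 0.  Micro pools TP/FP/FN globally.
    """
    labels = sorted(set(targets)) if class_set is None else sorted(class_set)
    if not labels:
        raise ValueError("empty class set")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-division classes -> 0 by design
        return float(
            f1_score(targets, top1, labels=labels, average=averaging, zero_division=0)
        )


def auc_scores(
    probabilities: np.ndarray,
    targets: Sequence[int],
    averaging: str = "macro",
) -> float:
    """One-vs-rest ROC AUC from a (n_records, n_classes) probability matrix.

    Macro: unweighted mean of per-class binary AUC over classes that have at
    least one positive and one negative in the targets (degenerate classes
    are skipped with a warning).  Micro: AUC on the stacked (record, class)
    binary problem.  Ties are handled by midranks.
    """
    probs = np.asarray(probabilities, dtype=float)
    targets = np.asarray(targets)
    row_sums = probs.sum(axis=1)
    if not np.allclose(row_sums, 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    n, n_classes = probs.shape
    onehot = np.zeros_like(probs)
    onehot[np.arange(n), targets] = 1.0
    if averaging == "micro":
        return float(roc_auc_score(onehot.ravel(), probs.ravel()))
    aucs = []
    for c in range(n_classes):
        pos = onehot[:, c]
        if pos.sum() == 0 or pos.sum() == n:
            if pos.sum() > 0:  # class present but degenerate
                warnings.warn(f"class {c} has no negatives; skipped in macro AUC")
            continue
        aucs.append(roc_auc_score(pos, probs[:, c]))
    if not aucs:
        raise ValueError("no class with both positives and negatives")
    return float(np.mean(aucs))


def bootstrap_sd(
    metric: Callable[[np.ndarray], float],
    n_records: int,
    n_iter: int = 30,
    seed: int = 0,
) -> float:
    """Bootstrap standard deviation of a metric over test-set resamples.

    ``metric`` maps an index array (a with-replacement resample of
    0..n_records-1, of the full test-set size) to a scalar.  Returns the
    sample SD (ddof=1) over ``n_iter`` resamples; deterministic given seed.
    """
    if n_iter < 2:
        raise ValueError("need at least 2 bootstrap iterations")
    rng = np.random.default_rng(seed)
    values = [
        metric(rng.integers(0, n_records, size=n_records)) for _ in range(n_iter)
    ]
    return float(np.std(values, ddof=1))


@dataclass
class EvalReport:
    """Metric values with bootstrap SDs, JSON-serializable as metric -> {value, sd}."""

    metrics: dict[str, tuple[float, float | None]] = field(default_factory=dict)
    seed: int | None = None

    def add(self, name: str, value: float, sd: float | None = None) -> None:
        self.metrics[name] = (float(value), None if sd is None else float(sd))

    def value(self, name: str) -> float:
        return self.metrics[name][0]

    def to_dict(self) -> dict:
        out = {
            name: {"value": v, "sd": sd} for name, (v, sd) in self.metrics.items()
        }
        if self.seed is not None:
            out["bootstrap_seed"] = self.seed
        return out


def evaluate_single_label(
    ranked: Sequence[Sequence[int]],
    probabilities: np.ndarray,
    targets: Sequence[int],
    n_bootstrap: int = 30,
    seed: int = 0,
    ks: Sequence[int] = (1, 5, 10),
) -> EvalReport:
    """Full single-label report: ACC@k, macro/micro F1, macro/micro AUC, each
    with a bootstrap SD over resamples of the test set."""
    targets = np.asarray(targets)
    ranked_arr = [np.asarray(r) for r in ranked]
    top1 = np.asarray([r[0] for r in ranked_arr])
    n = len(targets)
    report = EvalReport(seed=seed)

    def boot(fn: Callable[[np.ndarray], float], tag: str, value: float) -> None:
        sd = bootstrap_sd(fn, n, n_iter=n_bootstrap, seed=seed)
        report.add(tag, value, sd)

    for k in ks:
        k_eff = min(k, len(ranked_arr[0]))
        hits = np.asarray(
            [t in r[:k_eff] for r, t in zip(ranked_arr, targets)], dtype=float
        )
        boot(lambda idx, h=hits: float(h[idx].mean()), f"ACC@{k}", float(hits.mean()))
    boot(
        lambda idx: f1_scores(top1[idx], targets[idx], "macro"),
        "MACRO-F1",
        f1_scores(top1, targets, "macro"),
    )
    boot(
        lambda idx: f1_scores(top1[idx], targets[idx], "micro"),
        "MICRO-F1",
        f1_scores(top1, targets, "micro"),
    )
    probs = np.asarray(probabilities)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        boot(
            lambda idx: auc_scores(probs[idx], targets[idx], "macro"),
            "MACRO-AUC",
            auc_scores(probs, targets, "macro"),
        )
        boot(
            lambda idx: auc_scores(probs[idx], targets[idx], "micro"),
            "MICRO-AUC",
            auc_scores(probs, targets, "micro"),
        )
    return report


def per_class_report(
    ranked: Sequence[Sequence[int]],
    targets: Sequence[int],
    train_counts: dict[int, int],
    k: int = 5,
    band_edges: Sequence[float] = (0.2, 0.8),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-DRG top-k accuracy against training-case counts.

    Returns (per-class table, band summary).  Bands partition [0, 1] at
    ``band_edges`` and summarize the median/IQR of training counts per band —
    the tabular form of the accuracy-vs-frequency analysis.
    """
    targets = np.asarray(targets)
    rows = []
    for label in sorted(set(targets.tolist())):
        mask = targets == label
        hits = [
            t in list(r)[:k] for r, t, m in zip(ranked, targets, mask, strict=True) if m
        ]
        rows.append(
            {
                "label": label,
                "train_count": train_counts.get(label, 0),
                "test_count": int(mask.sum()),
                f"acc_at_{k}": float(np.mean(hits)),
            }
        )
    table = pd.DataFrame(rows)
    edges = [0.0, *band_edges, 1.0 + 1e-12]
    acc = table[f"acc_at_{k}"]
    band_idx = np.digitize(acc, edges[1:-1], right=False)
    labels = [f"[{edges[i]:.1f}, {edges[i + 1]:.1f})" for i in range(len(edges) - 1)]
    table["band"] = [labels[i] for i in band_idx]
    summary = (
        table.groupby("band")["train_count"]
        .agg(n="count", median="median", q1=lambda s: s.quantile(0.25),
             q3=lambda s: s.quantile(0.75))
        .reset_index()
    )
    return table, summary


def evaluate_two_label(
    joint_logits: np.ndarray,
    base_targets: Sequence[int],
    cc_targets: Sequence[int],
    drg_targets: Sequence[int],
    catalog: DrgCatalog,
    space: LabelSpace,
    n_bootstrap: int = 30,
    seed: int = 0,
) -> EvalReport:
    """Two-label report: base-DRG block, CC/MCC block and final-DRG accuracy.

    The final DRG is derived per record by the catalog mapping rule from the
    two argmaxes; its accuracy can never exceed the base-DRG accuracy, since
    a wrong base DRG can never map to the right code.
    """
    from .model import softmax  # local import to avoid a cycle

    joint = np.asarray(joint_logits, dtype=float)
    nb = space.n_base
    base_logits, cc_logits = joint[:, :nb], joint[:, nb:]
    base_targets = np.asarray(base_targets)
    cc_targets = np.asarray(cc_targets)
    drg_targets = np.asarray(drg_targets)
    n = len(base_targets)
    report = EvalReport(seed=seed)

    base_rank = np.argsort(-base_logits, axis=1, kind="stable")
    cc_rank = np.argsort(-cc_logits, axis=1, kind="stable")
    base_probs = softmax(base_logits, axis=1)
    cc_probs = softmax(cc_logits, axis=1)

    for tag, rank, tgt, probs, ks in (
        ("BASE", base_rank, base_targets, base_probs, (1, 5, 10)),
        ("CC", cc_rank, cc_targets, cc_probs, (1,)),
    ):
        for k in ks:
            hits = np.asarray(
                [t in r[:k] for r, t in zip(rank, tgt)], dtype=float
            )
            sd = bootstrap_sd(
                lambda idx, h=hits: float(h[idx].mean()), n, n_bootstrap, seed
            )
            report.add(f"{tag}-ACC@{k}", float(hits.mean()), sd)
        top1 = rank[:, 0]
        for avg in ("macro", "micro"):
            val = f1_scores(top1, tgt, avg)
            sd = bootstrap_sd(
                lambda idx, p=top1, t=tgt, a=avg: f1_scores(p[idx], t[idx], a),
                n, n_bootstrap, seed,
            )
            report.add(f"{tag}-{avg.upper()}-F1", val, sd)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for avg in ("macro", "micro"):
                val = auc_scores(probs, tgt, avg)
                sd = bootstrap_sd(
                    lambda idx, p=probs, t=tgt, a=avg: auc_scores(p[idx], t[idx], a),
                    n, n_bootstrap, seed,
                )
                report.add(f"{tag}-{avg.upper()}-AUC", val, sd)

    final_idx = np.asarray(
        [
            space.drg_index(
                infer_drg(int(b), CcMccLabel(int(c)), catalog, space).code
            )
            for b, c in zip(base_rank[:, 0], cc_rank[:, 0])
        ]
    )
    final_hits = (final_idx == drg_targets).astype(float)
    sd = bootstrap_sd(lambda idx: float(final_hits[idx].mean()), n, n_bootstrap, seed)
    report.add("DRG-ACC@1", float(final_hits.mean()), sd)
    return report
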