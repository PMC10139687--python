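"""Agreement and classification metrics.

Cohen's kappa = (p_o - p_e) / (1 - p_e) over the full multi-class label
set; classification metrics are a confusion table with per-class
precision/recall/F1 and their unweighted (macro) means.  Reported
precision follows the printed conventions of this literature: metrics to
2 decimals, prevalence shares to 1 decimal percent.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .synth import THEMES

logger = logging.getLogger(__name__)


def cohen_kappa(labels_a: Sequence, labels_b: Sequence) -> float:
    """Chance-corrected agreement between two labelings of the same items."""
    if len(labels_a) != len(labels_b):
        raise ValueError(
            f"label sequences differ in length: {len(labels_a)} vs "
            f"{len(labels_b)}")
    if not labels_a:
        raise ValueError("label sequences are empty")
    classes = sorted(set(labels_a) | set(labels_b))
    idx = {c: i for i, c in enumerate(classes)}
    n = len(labels_a)
    table = np.zeros((len(classes), len(classes)))
    for a, b in zip(labels_a, labels_b):
        table[idx[a], idx[b]] += 1
    p_o = np.trace(table) / n
    p_e = float((table.sum(axis=1) / n) @ (table.sum(axis=0) / n))
    if abs(1.0 - p_e) < 1e-12:
        # both marginals degenerate on the same class
        return 1.0 if p_o == 1.0 else 0.0
    return float((p_o - p_e) / (1.0 - p_e))


@dataclass
class MetricsReport:
    accuracy: float
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    macro_precision: float
    macro_recall: float
    macro_f1: float
    confusion: pd.DataFrame  # rows = truth, columns = predicted
    kappa: float | None = None

    def to_dict(self) -> dict:
        out = {
            "accuracy": round(self.accuracy, 2),
            "macro_precision": round(self.macro_precision, 2),
            "macro_recall": round(self.macro_recall, 2),
            "macro_f1": round(self.macro_f1, 2),
            "per_class": {
                c: {"precision": round(self.precision[c], 2),
                    "recall": round(self.recall[c], 2),
                    "f1": round(self.f1[c], 2)}
                for c in self.precision
            },
            "confusion": self.confusion.to_dict(),
        }
        if self.kappa is not None:
            out["kappa"] = round(self.kappa, 2)
        return out

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def classification_metrics(truth: Sequence[str], predicted: Sequence[str],
                           labels: Sequence[str] = THEMES) -> MetricsReport:
    """Confusion table plus accuracy and per-class/macro precision-recall-F1.

    Per-class precision = TP/(TP+FP) and recall = TP/(TP+FN); a class
    never predicted (or never present) gets 0 for the undefined ratio,
    with a log note, so macro averages stay defined.
    """
    if len(truth) != len(predicted):
        raise ValueError("truth and predicted differ in length")
    labels = list(labels)
    known = set(labels)
    for seq, name in ((truth, "truth"), (predicted, "predicted")):
        unseen = set(seq) - known
        if unseen:
            raise ValueError(f"unknown label(s) in {name}: {sorted(unseen)}")
    confusion = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for t, p in zip(truth, predicted):
        confusion.loc[t, p] += 1
    total = int(confusion.values.sum())
    accuracy = float(np.trace(confusion.values)) / total
    precision, recall, f1 = {}, {}, {}
    for c in labels:
        tp = int(confusion.loc[c, c])
        fp = int(confusion[c].sum()) - tp
        fn = int(confusion.loc[c].sum()) - tp
        if tp + fp == 0:
            logger.info("class %s never predicted; precision set to 0", c)
            precision[c] = 0.0
        else:
            precision[c] = tp / (tp + fp)
        if tp + fn == 0:
            logger.info("class %s absent from truth; recall set to 0", c)
            recall[c] = 0.0
        else:
            recall[c] = tp / (tp + fn)
        f1[c] = f1_from_pr(precision[c], recall[c])
    return MetricsReport(
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        f1=f1,
        macro_precision=float(np.mean(list(precision.values()))),
        macro_recall=float(np.mean(list(recall.values()))),
        macro_f1=float(np.mean(list(f1.values()))),
        confusion=confusion,
    )


def f1_from_pr(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0 (logged)."""
    if not (0.0 <= precision <= 1.0 and 0.0 <= recall <= 1.0):
        raise ValueError("precision and recall must lie in [0, 1]")
    if precision == 0.0 and recall == 0.0:
        logger.info("precision and recall both 0; F1 defined as 0")
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def theme_share(predictions: Mapping[str, str] | Iterable[str],
                labels: Sequence[str] = THEMES) -> dict[str, float]:
    """Percentage of items per theme, reported to 1 decimal.

    Uses largest-remainder rounding so the reported shares sum to exactly
    100.0 (plain per-cell rounding can drift by up to 0.05 per class).
    """
    values = (list(predictions.values())
              if isinstance(predictions, Mapping) else list(predictions))
    if not values:
        raise ValueError("predictions are empty")
    n = len(values)
    raw = np.array([1000.0 * values.count(c) / n for c in labels])  # tenths
    floors = np.floor(raw)
    shortfall = int(round(1000 - floors.sum()))
    order = np.argsort(-(raw - floors), kind="stable")
    floors[order[:shortfall]] += 1
    return {c: float(f) / 10.0 for c, f in zip(labels, floors)}
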