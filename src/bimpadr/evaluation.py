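"""Evaluation metrics: ROC AUC, Precision, ACC on labeled pair sets.

AUC uses the rank-based (Mann-Whitney) formula with midrank tie handling, so
it equals the probability that a random positive outscores a random negative,
with half credit for ties.  Precision and ACC come from a confusion tally at
a fixed threshold (default 0.5, the sigmoid midpoint).  External validation
scores every (cold-start drug, ADR) pair, an extremely class-imbalanced
regime; the positive rate is carried in the report so the imbalance stays
visible.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .data import BipartiteDataset, DrugRecord, LabeledPairSet
from .model import BiMPADRModel, adr_features, score_cold_start

__all__ = ["MetricReport", "auc", "confusion_metrics", "evaluate_external",
           "roc_points"]


@dataclass
class MetricReport:
    auc: float | None  # None when only one class is present
    precision: float
    acc: float
    tp: int
    fp: int
    tn: int
    fn: int
    threshold: float
    positive_rate: float
    precision_undefined: bool = False

    @property
    def p(self) -> int:
        return self.tp + self.fn

    @property
    def n(self) -> int:
        return self.tn + self.fp

    def to_dict(self) -> dict:
        d = asdict(self)
        d["counts"] = {
            "P": self.p, "N": self.n,
            "TP": self.tp, "FP": self.fp, "TN": self.tn, "FN": self.fn,
        }
        return d


def auc(scores, labels) -> float:
    """Area under the ROC curve via midranks; errors on single-class input."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels differ in length")
    pos = labels == 1
    n_pos = int(pos.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(scores)  # midranks
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def confusion_metrics(scores, labels, threshold: float = 0.5) -> MetricReport:
    """Precision and ACC from a confusion tally; prediction positive iff
    score >= threshold.  Undefined precision (no predicted positives) is
    reported as 0.0 with ``precision_undefined`` set."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.size == 0:
        raise ValueError("empty input")
    pred = scores >= threshold
    actual = labels == 1
    tp = int(np.sum(pred & actual))
    fp = int(np.sum(pred & ~actual))
    tn = int(np.sum(~pred & ~actual))
    fn = int(np.sum(~pred & actual))
    undefined = (tp + fp) == 0
    precision = 0.0 if undefined else tp / (tp + fp)
    acc = (tp + tn) / scores.size
    return MetricReport(
        auc=auc(scores, labels) if 0 < actual.sum() < scores.size else None,
        precision=precision,
        acc=acc,
        tp=tp, fp=fp, tn=tn, fn=fn,
        threshold=threshold,
        positive_rate=float(actual.mean()),
        precision_undefined=undefined,
    )


def evaluate_external(
    model: BiMPADRModel,
    dataset: BipartiteDataset,
    external_drugs: list[DrugRecord],
    external_pairs: LabeledPairSet,
    threshold: float = 0.5,
) -> MetricReport:
    """Score the all-pairs external set in inference mode and tally metrics.

    ADR features come from the dataset's (training) graph; the external drugs
    contribute only fingerprints, never edges.
    """
    if external_pairs.provenance != "external":
        raise ValueError("expected an external-provenance pair set")
    feats = adr_features(model, dataset)
    scores = score_cold_start(model, external_drugs, feats, external_pairs)
    return confusion_metrics(scores, external_pairs.labels, threshold=threshold)


def roc_points(scores, labels) -> pd.DataFrame:
    """(FPR, TPR, threshold) points of the ROC curve, for CSV export."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels) == 1
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    tps = np.cumsum(y)
    fps = np.cumsum(~y)
    distinct = np.r_[np.flatnonzero(np.diff(s)), s.size - 1]
    p, n = max(int(labels.sum()), 1), max(int((~labels).sum()), 1)
    return pd.DataFrame({
        "threshold": s[distinct],
        "fpr": fps[distinct] / n,
        "tpr": tps[distinct] / p,
    })
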