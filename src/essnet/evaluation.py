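"""Assessment metrics for essentiality prediction.

Six measures: accuracy, precision, recall, F-measure (from thresholded
confusion counts), plus the threshold-free ROC AUC and average precision
(AP, the area under the precision-recall curve with step-wise summation).
Also the top-K candidate protocol used to compare centrality rankings:
rank all proteins by score, call the top K essential, then compute the
four confusion-based metrics.

Conventions: predicted essential iff score >= threshold (default 0.5);
ratios with zero denominators are reported as 0 and flagged; ROC ties get
half credit (the Mann-Whitney convention).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .centrality import ScoreTable, rank_candidates


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class MetricsReport:
    accuracy: float = float("nan")
    precision: float = float("nan")
    recall: float = float("nan")
    f_measure: float = float("nan")
    auc: float = float("nan")
    ap: float = float("nan")
    undefined: tuple[str, ...] = ()

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["undefined"] = list(self.undefined)
        Path(path).write_text(json.dumps(payload, indent=2))


def _check_domains(scores: ScoreTable, labels: dict[str, int]) -> list[str]:
    extra = set(scores.scores) ^ set(labels)
    if extra:
        raise ValueError(
            f"score/label domain mismatch on {sorted(extra)[:10]}")
    return sorted(scores.scores)


def confusion(scores: ScoreTable, labels: dict[str, int],
              threshold: float = 0.5) -> ConfusionCounts:
    """Threshold the scores (>=) and tally the four confusion counts."""
    ids = _check_domains(scores, labels)
    tp = tn = fp = fn = 0
    for v in ids:
        pred = scores[v] >= threshold
        if labels[v] == 1:
            tp += pred
            fn += not pred
        else:
            fp += pred
            tn += not pred
    return ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn)


def basic_metrics(c: ConfusionCounts) -> MetricsReport:
    """Accuracy, precision, recall and F-measure from confusion counts.

    Ratios whose denominator is zero are reported as 0 and named in the
    report's ``undefined`` field.
    """
    if c.total == 0:
        raise ValueError("no evaluated proteins")
    undefined: list[str] = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    accuracy = (c.TP + c.TN) / c.total
    precision = ratio(c.TP, c.TP + c.FP, "precision")
    recall = ratio(c.TP, c.TP + c.FN, "recall")
    if precision + recall == 0.0:
        undefined.append("f_measure")
        f = 0.0
    else:
        f = 2.0 * precision * recall / (precision + recall)
    return MetricsReport(accuracy=accuracy, precision=precision,
                         recall=recall, f_measure=f,
                         undefined=tuple(undefined))


def _arrays(scores: ScoreTable, labels: dict[str, int]):
    ids = _check_domains(scores, labels)
    y = np.array([labels[v] for v in ids])
    s = np.array([scores[v] for v in ids])
    return y, s


def roc_auc(scores: ScoreTable, labels: dict[str, int]) -> float:
    """Area under the ROC curve (equivalently the normalized U statistic)."""
    y, s = _arrays(scores, labels)
    if y.min() == y.max():
        raise ValueError("ROC AUC needs both classes present")
    return float(roc_auc_score(y, s))


def average_precision(scores: ScoreTable, labels: dict[str, int]) -> float:
    """Area under the precision-recall curve, step-wise summation."""
    y, s = _arrays(scores, labels)
    if y.sum() == 0:
        raise ValueError("average precision needs >=1 positive")
    return float(average_precision_score(y, s))


def full_report(scores: ScoreTable, labels: dict[str, int],
                threshold: float = 0.5) -> MetricsReport:
    """All six metrics at once."""
    report = basic_metrics(confusion(scores, labels, threshold))
    report.auc = roc_auc(scores, labels)
    report.ap = average_precision(scores, labels)
    return report


def topk_protocol(scores: ScoreTable, labels: dict[str, int],
                  K: int) -> MetricsReport:
    """Call the top-K ranked proteins essential, then Eqs.-style metrics.

    This is the protocol used for the centrality baselines: rank scores in
    descending order, take the top K as candidate essential proteins, and
    compute accuracy/precision/recall/F against the true labels.
    """
    ids = _check_domains(scores, labels)
    top = set(rank_candidates(scores, K))
    tp = sum(1 for v in top if labels[v] == 1)
    fp = K - tp
    fn = sum(labels[v] for v in ids) - tp
    tn = len(ids) - K - fn
    return basic_metrics(ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn))


def curve_points(scores: ScoreTable, labels: dict[str, int]):
    """ROC and PR curve coordinates for TSV export / plotting."""
    from sklearn.metrics import precision_recall_curve, roc_curve

    y, s = _arrays(scores, labels)
    fpr, tpr, _ = roc_curve(y, s)
    prec, rec, _ = precision_recall_curve(y, s)
    return (fpr, tpr), (rec[::-1], prec[::-1])


def write_curves(scores: ScoreTable, labels: dict[str, int],
                 roc_path: str | Path, pr_path: str | Path) -> None:
    (fpr, tpr), (rec, prec) = curve_points(scores, labels)
    with open(roc_path, "w") as fh:
        fh.write("fpr\ttpr\n")
        for a, b in zip(fpr, tpr):
            fh.write(f"{a!r}\t{b!r}\n")
    with open(pr_path, "w") as fh:
        fh.write("recall\tprecision\n")
        for a, b in zip(rec, prec):
            fh.write(f"{a!r}\t{b!r}\n")
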