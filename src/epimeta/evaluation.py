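"""Per-residue binary-classification evaluation of epitope predictions.

Predicted and annotated residue sets are compared over a residue universe
(by default all residues of the antigen; optionally surface residues only)
to give confusion counts, F1 and MCC; score tracks are evaluated by ROC-AUC
and PR-AUC; pooled %TP-at-k measures fixed-rank performance over a test set;
and Kolmogorov-Smirnov tests compare metric distributions between methods.

Zero-denominator conventions: F1 and MCC are defined as 0 whenever their
denominator vanishes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Hashable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score


@dataclass
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class KSResult:
    D: float
    pvalue: float
    kind: str                  # "one-sample" | "two-sample"
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.pvalue < self.alpha


def confusion(predicted: Iterable[Hashable], annotated: Iterable[Hashable],
              universe: Iterable[Hashable]) -> ConfusionCounts:
    """Confusion counts of a predicted residue set against an annotation."""
    pred, ann, uni = set(predicted), set(annotated), set(universe)
    if not pred <= uni or not ann <= uni:
        raise ValueError("predicted and annotated sets must be subsets of the universe")
    tp = len(pred & ann)
    return ConfusionCounts(
        TP=tp,
        FP=len(pred) - tp,
        FN=len(ann) - tp,
        TN=len(uni) - len(pred | ann),
    )


def f1(counts: ConfusionCounts) -> float:
    """F1 = 2TP / (2TP + FP + FN); 0 on an empty denominator."""
    denom = 2 * counts.TP + counts.FP + counts.FN
    return 2 * counts.TP / denom if denom else 0.0


def mcc(counts: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any marginal is empty."""
    tp, tn, fp, fn = counts.TP, counts.TN, counts.FP, counts.FN
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return (tp * tn - fp * fn) / denom if denom else 0.0


def _check_two_classes(labels: np.ndarray) -> None:
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve (Mann-Whitney concordance with ties at 1/2)."""
    labels = np.asarray(labels)
    _check_two_classes(labels)
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def pr_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the precision-recall curve by step-wise integration.

    Step interpolation (average precision) avoids the optimistic bias of
    trapezoidal interpolation between PR points.
    """
    labels = np.asarray(labels)
    _check_two_classes(labels)
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


def percent_tp_at_k(
    ranked: dict[str, Sequence[Hashable]],
    annotations: dict[str, Iterable[Hashable]],
    k: int,
) -> float:
    """Pooled %TP at fixed rank k over a test set.

    %TP = 100 * (sum over antigens of annotated residues in the top-k)
        / (total annotated residues over the test set).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    tp = 0
    total = 0
    for aid, ann in annotations.items():
        ann = set(ann)
        total += len(ann)
        tp += len(set(ranked[aid][:k]) & ann)
    return 100.0 * tp / total if total else 0.0


def ks_test(
    sample_a: Sequence[float],
    sample_b: Sequence[float] | None = None,
    reference: str = "norm",
    alpha: float = 0.05,
) -> KSResult:
    """Kolmogorov-Smirnov test.

    Two-sample when ``sample_b`` is given; otherwise a one-sample test of
    ``sample_a`` against ``reference`` (default: a normal distribution with
    the sample's mean and standard deviation, i.e. a normality check).
    """
    a = np.asarray(sample_a, dtype=float)
    if a.size == 0:
        raise ValueError("empty sample")
    if sample_b is not None:
        b = np.asarray(sample_b, dtype=float)
        if b.size == 0:
            raise ValueError("empty sample")
        res = stats.ks_2samp(a, b, method="asymp")
        return KSResult(float(res.statistic), float(res.pvalue), "two-sample", alpha)
    if reference == "norm":
        res = stats.kstest(a, "norm", args=(a.mean(), a.std(ddof=1)))
    else:
        res = stats.kstest(a, reference)
    return KSResult(float(res.statistic), float(res.pvalue), "one-sample", alpha)


def cluster_level_f1(
    clusters: Sequence[Iterable[Hashable]],
    annotated: Iterable[Hashable],
    universe: Iterable[Hashable],
) -> list[float]:
    """F1 of each cluster, treating it alone as the full predicted set.

    Because the dynamic threshold deliberately over-predicts, splitting the
    prediction into spatial clusters and scoring each independently measures
    how well individual putative epitopes match the (single-complex)
    annotation.
    """
    return [f1(confusion(c, annotated, universe)) for c in clusters]


def evaluate_antigen(
    predicted: Iterable[Hashable],
    annotated: Iterable[Hashable],
    universe: Iterable[Hashable],
    scores: Sequence[float] | None = None,
    labels: Sequence[int] | None = None,
) -> dict[str, float]:
    """F1/MCC of a predicted set, plus ROC/PR AUC when a score track is given."""
    counts = confusion(predicted, annotated, universe)
    out = {"TP": counts.TP, "TN": counts.TN, "FP": counts.FP, "FN": counts.FN,
           "f1": f1(counts), "mcc": mcc(counts)}
    if scores is not None and labels is not None:
        out["roc_auc"] = roc_auc(scores, labels)
        out["pr_auc"] = pr_auc(scores, labels)
    return out


def summarize(per_antigen: dict[str, dict[str, float]]) -> pd.DataFrame:
    """Per-antigen metric rows plus an unweighted 'mean' row."""
    df = pd.DataFrame(per_antigen).T
    if df.empty:
        warnings.warn("no antigens to summarize")
        return df
    df.loc["mean"] = df.mean(numeric_only=True)
    return df
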