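"""Per-group confusion counts, epsilon-regularized rates, and fairness gaps.

FPR and TPR are computed as FP/(FP+TN) and TP/(TP+FN), with a small epsilon
(default 0.001) added to the denominator so that groups with no negatives or
no positives — common when a demographic group is tiny — yield finite rates
of 0 instead of a division error. The alternative convention of adding
epsilon to every confusion count is available via ``epsilon_mode="counts"``.

Fairness gaps follow the equalized-odds criterion (equal TPR *and* FPR
across protected groups) and its relaxation, equal opportunity (equal TPR
only): the reported gap is the largest absolute between-group difference in
the constrained rates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.metrics import precision_recall_fscore_support

__all__ = [
    "GroupRates",
    "MulticlassGroupRates",
    "FairnessGaps",
    "compute_group_rates",
    "compute_multiclass_rates",
    "compute_performance_summary",
    "compute_fairness_gaps",
    "DEFAULT_EPSILON",
]

DEFAULT_EPSILON = 0.001


def _regularized_rate(num: float, den: float, epsilon: float, mode: str) -> float:
    if mode == "denominator":
        return num / (den + epsilon)
    if mode == "counts":
        # epsilon added to each of the two counts forming the denominator
        return (num + epsilon) / (den + 2 * epsilon)
    raise ValueError(f"unknown epsilon_mode {mode!r}")


@dataclass
class GroupRates:
    """Binary confusion counts and epsilon-regularized rates for one group."""

    group: str
    tp: int
    fp: int
    tn: int
    fn: int
    epsilon: float = DEFAULT_EPSILON
    epsilon_mode: str = "denominator"

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def fpr(self) -> float:
        return _regularized_rate(self.fp, self.fp + self.tn, self.epsilon, self.epsilon_mode)

    @property
    def tpr(self) -> float:
        return _regularized_rate(self.tp, self.tp + self.fn, self.epsilon, self.epsilon_mode)


@dataclass
class MulticlassGroupRates:
    """K x K confusion matrix (rows = true class) with one-vs-rest rates."""

    group: str
    confusion: np.ndarray
    epsilon: float = DEFAULT_EPSILON
    epsilon_mode: str = "denominator"

    @property
    def n(self) -> int:
        return int(self.confusion.sum())

    @property
    def n_classes(self) -> int:
        return self.confusion.shape[0]

    def one_vs_rest(self, cls: int) -> GroupRates:
        """Collapse to binary counts with `cls` as the positive class."""
        c = self.confusion
        tp = int(c[cls, cls])
        fn = int(c[cls, :].sum() - tp)
        fp = int(c[:, cls].sum() - tp)
        tn = int(c.sum() - tp - fn - fp)
        return GroupRates(self.group, tp, fp, tn, fn, self.epsilon, self.epsilon_mode)

    @property
    def tpr(self) -> np.ndarray:
        return np.array([self.one_vs_rest(c).tpr for c in range(self.n_classes)])

    @property
    def fpr(self) -> np.ndarray:
        return np.array([self.one_vs_rest(c).fpr for c in range(self.n_classes)])


@dataclass
class FairnessGaps:
    """Largest between-group rate differences under the two criteria.

    eq_odds_gap bounds the violation of equalized odds (max over TPR and FPR
    differences); eq_opp_gap bounds equal opportunity (TPR difference only),
    so eq_opp_gap <= eq_odds_gap always.
    """

    eq_odds_gap: float
    eq_opp_gap: float


def _require_binary(df: pd.DataFrame) -> None:
    labels = pd.concat([df["true_label"], df["predicted_label"]]).unique()
    bad = set(labels) - {0, 1}
    if bad:
        raise ValueError(
            f"non-binary labels {sorted(bad)} found; use compute_multiclass_rates for K > 2"
        )


def compute_group_rates(
    df: pd.DataFrame,
    epsilon: float = DEFAULT_EPSILON,
    epsilon_mode: str = "denominator",
    label_col: str = "predicted_label",
) -> dict[str, GroupRates]:
    """Confusion counts and regularized FPR/TPR per protected group (binary)."""
    if df.empty:
        raise ValueError("empty prediction table")
    _require_binary(df)
    out: dict[str, GroupRates] = {}
    for g, sub in df.groupby("group", sort=True):
        y = sub["true_label"].to_numpy()
        yhat = sub[label_col].to_numpy()
        out[str(g)] = GroupRates(
            group=str(g),
            tp=int(((y == 1) & (yhat == 1)).sum()),
            fp=int(((y == 0) & (yhat == 1)).sum()),
            tn=int(((y == 0) & (yhat == 0)).sum()),
            fn=int(((y == 1) & (yhat == 0)).sum()),
            epsilon=epsilon,
            epsilon_mode=epsilon_mode,
        )
    return out


def compute_multiclass_rates(
    df: pd.DataFrame,
    n_classes: int,
    epsilon: float = DEFAULT_EPSILON,
    epsilon_mode: str = "denominator",
    label_col: str = "predicted_label",
) -> dict[str, MulticlassGroupRates]:
    """Per-group K x K confusion matrices with one-vs-rest regularized rates."""
    if df.empty:
        raise ValueError("empty prediction table")
    labels = pd.concat([df["true_label"], df[label_col]]).unique()
    bad = [l for l in labels if not 0 <= l < n_classes]
    if bad:
        raise ValueError(f"labels {sorted(bad)} outside 0..{n_classes - 1}")
    out: dict[str, MulticlassGroupRates] = {}
    for g, sub in df.groupby("group", sort=True):
        conf = np.zeros((n_classes, n_classes), dtype=int)
        np.add.at(conf, (sub["true_label"].to_numpy(), sub[label_col].to_numpy()), 1)
        out[str(g)] = MulticlassGroupRates(str(g), conf, epsilon, epsilon_mode)
    return out


def compute_performance_summary(
    df: pd.DataFrame,
    n_classes: int = 2,
    label_col: str = "predicted_label",
) -> pd.DataFrame:
    """Accuracy (percent), precision, recall and F1 per group.

    Binary tasks use the positive-class convention; K > 2 uses macro
    averaging, which weighs every stage class equally regardless of
    prevalence. Empty groups are simply absent from the output.
    """
    rows = []
    average = "binary" if n_classes == 2 else "macro"
    for g, sub in df.groupby("group", sort=True):
        if sub.empty:
            continue
        y = sub["true_label"].to_numpy()
        yhat = sub[label_col].to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            prec, rec, f1, _ = precision_recall_fscore_support(
                y, yhat, average=average, labels=list(range(n_classes)), zero_division=0
            )
        rows.append(
            {
                "group": str(g),
                "n": len(sub),
                "accuracy_pct": 100.0 * float((y == yhat).mean()),
                "precision": float(prec),
                "recall": float(rec),
                "f1": float(f1),
            }
        )
    return pd.DataFrame(rows)


def compute_fairness_gaps(rates: dict[str, GroupRates]) -> FairnessGaps:
    """Equalized-odds and equal-opportunity gaps from per-group rates.

    With two groups these are the absolute rate differences; with more, the
    maximum pairwise difference. A single group trivially satisfies both
    criteria (gaps of 0, with a warning).
    """
    groups = list(rates)
    if len(groups) < 2:
        warnings.warn("fairness gaps need >= 2 groups; returning zeros", stacklevel=2)
        return FairnessGaps(eq_odds_gap=0.0, eq_opp_gap=0.0)
    tpr_gap = max(abs(rates[a].tpr - rates[b].tpr) for a, b in combinations(groups, 2))
    fpr_gap = max(abs(rates[a].fpr - rates[b].fpr) for a, b in combinations(groups, 2))
    return FairnessGaps(eq_odds_gap=max(tpr_gap, fpr_gap), eq_opp_gap=tpr_gap)
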