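"""Empirical joint distribution Pr(Ŷ, Y, A) and loss specifications.

The derived-predictor programs are fit against the empirical plug-in joint
distribution of (predicted label, true label, protected group). Zero-mass
cells are kept as exact zeros: conditionals on a zero-mass (Y = j, A = α)
cell are undefined and the corresponding fairness constraints are dropped as
vacuous rather than epsilon-inflated — the epsilon regularization belongs to
rate *reporting*, not to the optimization's probability mass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["JointDistribution", "LossSpec", "estimate_joint"]

_MASS_TOL = 1e-9


@dataclass
class JointDistribution:
    """Empirical Pr(Ŷ = k, Y = j, A = α) with group list and class count.

    `joint` has shape (n_groups, K, K) indexed [group, true, predicted].
    """

    groups: list[str]
    n_classes: int
    joint: np.ndarray  # (G, K, K), [g, y, yhat]

    def __post_init__(self) -> None:
        self.joint = np.asarray(self.joint, dtype=float)
        g, k = len(self.groups), self.n_classes
        if self.joint.shape != (g, k, k):
            raise ValueError(f"joint shape {self.joint.shape} != ({g}, {k}, {k})")
        if np.any(self.joint < 0):
            raise ValueError("joint probabilities must be non-negative")
        total = self.joint.sum()
        if abs(total - 1.0) > _MASS_TOL:
            raise ValueError(f"joint mass {total} != 1")

    def group_index(self, group: str) -> int:
        return self.groups.index(group)

    def p_group_true(self) -> np.ndarray:
        """Marginal Pr(A = α, Y = j), shape (G, K)."""
        return self.joint.sum(axis=2)

    def cond_pred_given_true(self, g: int) -> np.ndarray:
        """Pr(Ŷ = k | Y = j, A = g) as a (K, K) array [j, k]; NaN rows where undefined."""
        marg = self.joint[g].sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(marg > 0, self.joint[g] / marg, np.nan)

    def p_pred(self, g: int) -> np.ndarray:
        """Marginal Pr(Ŷ = k, A = g) within the cohort, shape (K,)."""
        return self.joint[g].sum(axis=0)


@dataclass
class LossSpec:
    """Penalty l(i, j, α) for outputting class i when the truth is j in group α.

    Stored as an array of shape (n_groups, K, K) indexed [group, output i,
    truth j]. The default is the 0-1 loss, identical across groups; group-
    dependent weights let inaccuracies be penalized differently by protected
    group membership.
    """

    groups: list[str]
    n_classes: int
    penalties: np.ndarray  # (G, K, K), [g, i, j]

    def __post_init__(self) -> None:
        self.penalties = np.asarray(self.penalties, dtype=float)
        g, k = len(self.groups), self.n_classes
        if self.penalties.shape != (g, k, k):
            raise ValueError(f"penalties shape {self.penalties.shape} != ({g}, {k}, {k})")
        if np.any(self.penalties < 0):
            raise ValueError("penalties must be non-negative")

    @classmethod
    def zero_one(cls, groups: list[str], n_classes: int) -> "LossSpec":
        pen = 1.0 - np.eye(n_classes)
        return cls(list(groups), n_classes, np.broadcast_to(pen, (len(groups), n_classes, n_classes)).copy())


def estimate_joint(df: pd.DataFrame, n_classes: int, label_col: str = "predicted_label") -> JointDistribution:
    """Empirical joint Pr(Ŷ, Y, A) from a prediction table.

    Frequencies are normalized by the total record count; groups with zero
    records are excluded with a warning; zero-mass cells stay exact zeros.
    """
    if df.empty:
        raise ValueError("empty prediction table")
    labels = pd.concat([df["true_label"], df[label_col]]).unique()
    bad = [l for l in labels if not 0 <= l < n_classes]
    if bad:
        raise ValueError(f"labels {sorted(bad)} outside 0..{n_classes - 1}")
    groups = sorted(df["group"].astype(str).unique())
    counts = np.zeros((len(groups), n_classes, n_classes))
    gidx = {g: i for i, g in enumerate(groups)}
    np.add.at(
        counts,
        (
            df["group"].astype(str).map(gidx).to_numpy(),
            df["true_label"].to_numpy(),
            df[label_col].to_numpy(),
        ),
        1.0,
    )
    return JointDistribution(groups, n_classes, counts / counts.sum())
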