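"""Multi-class fairness adjustment via protected-group confusion matrices.

For a K-class predictor, the post-processing adjustment keeps one column-
stochastic K x K matrix per protected group, W^α with
W^α[i, j] = Pr(Ŷ_adj = i | Ŷ = j, A = α): column j is the distribution of
adjusted labels handed to records the base model assigned to class j. The
expected loss of the adjusted predictor is

    E[l] = Σ_α Σ_{i,j,k} l(i, j, α) · W^α[i, k] · Pr(Ŷ = k, Y = j, A = α),

linear in the W entries, and the fairness constraints are linear too:
multi-class equalized odds ties the full adjusted conditional
Pr(Ŷ_adj = i | Y = j, A = α) = Σ_k W^α[i, k] · Pr(Ŷ = k | Y = j, A = α)
across groups for every (i, j); equal opportunity (the per-class
generalization of equal TPR) ties only the correct-classification
probabilities i = j. The minimizer is found by linear programming; ties are
broken toward the identity matrices by a second program so results are
reproducible across solver backends. Constraints on zero-mass (Y = j, A = α)
cells are vacuous and dropped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from ._rng import substream
from .binary import EQUAL_OPPORTUNITY, EQUALIZED_ODDS
from .joint import JointDistribution, LossSpec

__all__ = [
    "AdjustmentMatrixSet",
    "fit_multiclass",
    "apply_multiclass",
    "expected_loss",
]

_OBJ_SLACK = 1e-9
_COL_TOL = 1e-9


@dataclass
class AdjustmentMatrixSet:
    """Per-group adjustment matrices W^α and fit diagnostics."""

    criterion: str
    n_classes: int
    matrices: dict[str, np.ndarray]  # group -> (K, K), W[i, j] = Pr(adj=i | Ŷ=j)
    objective: float
    degenerate_cells: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        k = self.n_classes
        for g, w in self.matrices.items():
            w = np.asarray(w, dtype=float)
            if w.shape != (k, k):
                raise ValueError(f"group {g!r}: matrix shape {w.shape} != ({k}, {k})")
            if np.any(w < -_COL_TOL) or np.any(w > 1 + _COL_TOL):
                raise ValueError(f"group {g!r}: entries outside [0, 1]")
            cols = w.sum(axis=0)
            if np.any(np.abs(cols - 1.0) > 1e-6):
                raise ValueError(f"group {g!r}: columns must sum to 1, got {cols}")
            self.matrices[g] = np.clip(w, 0.0, 1.0) + 0.0  # +0.0 drops negative zeros

    def to_json(self, path=None) -> str:
        payload = {
            "criterion": self.criterion,
            "n_classes": self.n_classes,
            "matrices": {g: w.tolist() for g, w in self.matrices.items()},
            "objective": self.objective,
            "degenerate_cells": [[g, int(j)] for g, j in self.degenerate_cells],
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "AdjustmentMatrixSet":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            try:
                payload = json.loads(source)
            except (json.JSONDecodeError, TypeError):
                with open(source, encoding="utf-8") as fh:
                    payload = json.load(fh)
        return cls(
            criterion=payload["criterion"],
            n_classes=int(payload["n_classes"]),
            matrices={g: np.asarray(w, dtype=float) for g, w in payload["matrices"].items()},
            objective=float(payload["objective"]),
            degenerate_cells=[(g, int(j)) for g, j in payload.get("degenerate_cells", [])],
        )


def expected_loss(joint: JointDistribution, W: AdjustmentMatrixSet | dict, loss: LossSpec | None = None) -> float:
    """E[l] of the adjusted predictor: Σ l(i,j,α)·W^α[i,k]·Pr(Ŷ=k, Y=j, A=α)."""
    if loss is None:
        loss = LossSpec.zero_one(joint.groups, joint.n_classes)
    mats = W.matrices if isinstance(W, AdjustmentMatrixSet) else W
    total = 0.0
    for g_idx, g in enumerate(joint.groups):
        w = np.asarray(mats[g], dtype=float)
        # Σ_{i,j,k} L[i,j]·W[i,k]·P[j,k]
        total += float(np.einsum("ij,ik,jk->", loss.penalties[g_idx], w, joint.joint[g_idx]))
    return total


def _var(g: int, i: int, k: int, K: int) -> int:
    return g * K * K + i * K + k


def fit_multiclass(
    joint: JointDistribution,
    loss: LossSpec | None = None,
    criterion: str = EQUALIZED_ODDS,
) -> AdjustmentMatrixSet:
    """Fit the loss-minimal adjustment matrices under a fairness criterion.

    The program is always feasible: any constant predictor (one row of W set
    to all ones) equalizes the adjusted conditionals exactly, so a solver
    failure is surfaced as an error rather than silently repaired.
    """
    if criterion not in (EQUALIZED_ODDS, EQUAL_OPPORTUNITY):
        raise ValueError(f"unknown criterion {criterion!r}")
    K, G = joint.n_classes, len(joint.groups)
    if loss is None:
        loss = LossSpec.zero_one(joint.groups, K)
    n = G * K * K

    # objective: c[g,i,k] = Σ_j l(i,j,g)·P(g,j,k)
    c = np.zeros(n)
    for g in range(G):
        coef = loss.penalties[g] @ joint.joint[g]  # (i, k) = Σ_j L[i,j] P[j,k]
        c[g * K * K : (g + 1) * K * K] = coef.ravel()

    # column stochasticity
    rows_eq, rhs_eq = [], []
    for g in range(G):
        for k in range(K):
            row = np.zeros(n)
            for i in range(K):
                row[_var(g, i, k, K)] = 1.0
            rows_eq.append(row)
            rhs_eq.append(1.0)

    # fairness equality constraints against group 0
    conds = [joint.cond_pred_given_true(g) for g in range(G)]  # (K, K) [j, k]
    degenerate = [
        (joint.groups[g], j) for g in range(G) for j in range(K) if np.isnan(conds[g][j]).any()
    ]
    for g in range(1, G):
        for j in range(K):
            if np.isnan(conds[0][j]).any() or np.isnan(conds[g][j]).any():
                continue
            targets = range(K) if criterion == EQUALIZED_ODDS else (j,)
            for i in targets:
                row = np.zeros(n)
                for k in range(K):
                    row[_var(0, i, k, K)] = conds[0][j, k]
                    row[_var(g, i, k, K)] = -conds[g][j, k]
                rows_eq.append(row)
                rhs_eq.append(0.0)

    A_eq = np.array(rows_eq)
    b_eq = np.array(rhs_eq)
    res = linprog(c, A_eq=A_eq, b_eq=b_eq, bounds=[(0.0, 1.0)] * n, method="highs")
    if not res.success:
        raise RuntimeError(f"multi-class adjustment LP failed: {res.message}")
    opt = float(res.fun)

    # tie-break: among optima, minimize Σ |W - I| (linear surrogate for
    # distance to identity) for reproducibility across backends
    identity = np.tile(np.eye(K).ravel(), G)
    c2 = np.concatenate([np.zeros(n), np.ones(n)])
    A_ub = np.block(
        [
            [np.eye(n), -np.eye(n)],
            [-np.eye(n), -np.eye(n)],
            [c.reshape(1, -1), np.zeros((1, n))],
        ]
    )
    b_ub = np.concatenate([identity, -identity, [opt + _OBJ_SLACK]])
    A_eq2 = np.hstack([A_eq, np.zeros((A_eq.shape[0], n))])
    res2 = linprog(
        c2,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq2,
        b_eq=b_eq,
        bounds=[(0.0, 1.0)] * n + [(0.0, None)] * n,
        method="highs",
    )
    x = res2.x[:n] if res2.success else res.x
    x = np.clip(x, 0.0, 1.0)

    matrices = {}
    for g_idx, g in enumerate(joint.groups):
        w = x[g_idx * K * K : (g_idx + 1) * K * K].reshape(K, K)
        w = w / w.sum(axis=0, keepdims=True)  # renormalize solver round-off
        matrices[g] = w
    return AdjustmentMatrixSet(
        criterion=criterion,
        n_classes=K,
        matrices=matrices,
        objective=opt,
        degenerate_cells=degenerate,
    )


def apply_multiclass(df: pd.DataFrame, W: AdjustmentMatrixSet, seed: int) -> pd.DataFrame:
    """Stochastically relabel a table: adjusted label drawn from column Ŷ of W^α.

    Deterministic given seed; returns a copy with an `adjusted_label` column.
    """
    unseen = set(df["group"].astype(str)) - set(W.matrices)
    if unseen:
        raise ValueError(f"groups {sorted(unseen)} absent from the fitted adjustment")
    rng = substream(seed, "apply-multiclass")
    u = rng.random(len(df))
    K = W.n_classes
    # cumulative column distributions per (group, base label)
    cums = {g: np.cumsum(w, axis=0) for g, w in W.matrices.items()}
    col = np.stack(
        [cums[g][:, j] for g, j in zip(df["group"].astype(str), df["predicted_label"])]
    )  # (n, K)
    adjusted = (u[:, None] > col).sum(axis=1).clip(0, K - 1)
    out = df.copy()
    out["adjusted_label"] = adjusted.astype(int)
    return out
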