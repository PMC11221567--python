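"""Binary derived predictors satisfying equalized odds or equal opportunity.

A derived predictor post-processes an existing classifier without retraining
it: for each protected group α it keeps two mixing probabilities
p_α = (Pr(Ŷ_adj = 1 | Ŷ = 0, A = α), Pr(Ŷ_adj = 1 | Ŷ = 1, A = α)) and flips
predictions stochastically. Geometrically, the achievable (FPR, TPR)
operating points of such mixtures form the convex quadrilateral spanned by
(0,0), the base predictor's point, its label-flipped complement, and (1,1) —
the ROC convex hull of the available predictors. Equalized odds requires all
groups to operate at one common point inside the intersection of their
hulls; equal opportunity only aligns the TPR coordinate. The mixing
parameters minimizing expected loss subject to those (linear) equality
constraints are found by linear programming, with a secondary program that
breaks ties toward identity mixing for reproducibility across solver
backends.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog
from scipy.spatial import ConvexHull, QhullError

from ._rng import substream
from .joint import JointDistribution, LossSpec
from .metrics import GroupRates

__all__ = [
    "RocHull",
    "DerivedPredictorBinary",
    "build_roc_hull",
    "fit_equalized_odds",
    "fit_equal_opportunity",
    "apply_derived_predictor",
]

EQUALIZED_ODDS = "equalized_odds"
EQUAL_OPPORTUNITY = "equal_opportunity"

_OBJ_SLACK = 1e-9  # slack when pinning the tie-break stage to the optimum


# ---------------------------------------------------------------------------
# ROC convex hulls


@dataclass
class RocHull:
    """Convex closure of a group's achievable (FPR, TPR) operating points."""

    vertices: np.ndarray  # (m, 2) counter-clockwise
    degenerate: bool = False  # base point(s) on the chance diagonal

    def contains(self, point, tol: float = 1e-9) -> bool:
        p = np.asarray(point, dtype=float)
        if self.degenerate:
            return bool(abs(p[0] - p[1]) <= tol and -tol <= p[0] <= 1 + tol)
        hull = ConvexHull(self.vertices)
        return bool(np.all(hull.equations[:, :2] @ p + hull.equations[:, 2] <= tol))


def build_roc_hull(rates, score_points=None) -> RocHull:
    """ROC hull from a base operating point and optional score-threshold points.

    `rates` is a GroupRates or a bare (fpr, tpr) pair. Every supplied point
    contributes itself and its complement (1-FPR, 1-TPR), reachable by
    flipping the corresponding predictor's labels; (0,0) and (1,1) are the
    trivial always-negative / always-positive predictors. A base point on
    the chance diagonal collapses the hull to the diagonal segment, which is
    flagged as degenerate.
    """
    if isinstance(rates, GroupRates):
        base = (rates.fpr, rates.tpr)
    else:
        base = (float(rates[0]), float(rates[1]))
    pts = [(0.0, 0.0), (1.0, 1.0), base, (1.0 - base[0], 1.0 - base[1])]
    if score_points is not None:
        for f, t in score_points:
            pts.append((float(f), float(t)))
            pts.append((1.0 - float(f), 1.0 - float(t)))
    arr = np.asarray(pts, dtype=float)
    try:
        hull = ConvexHull(arr)
    except QhullError:
        # all points collinear on the diagonal: uninformative predictor
        return RocHull(np.array([[0.0, 0.0], [1.0, 1.0]]), degenerate=True)
    return RocHull(arr[hull.vertices], degenerate=False)


# ---------------------------------------------------------------------------
# Derived predictor


@dataclass
class DerivedPredictorBinary:
    """Fitted per-group mixing parameters and fit-time diagnostics.

    mixing[α] = (Pr(Ŷ_adj=1 | Ŷ=0, A=α), Pr(Ŷ_adj=1 | Ŷ=1, A=α));
    achieved[α] = the implied (FPR, TPR) at fit time. Under equalized odds
    the achieved points of all non-degenerate groups coincide; under equal
    opportunity only the TPRs do.
    """

    criterion: str
    mixing: dict[str, tuple[float, float]]
    achieved: dict[str, tuple[float, float]]
    objective: float
    degenerate_groups: list[str] = field(default_factory=list)
    infeasible: bool = False

    def to_json(self, path=None) -> str:
        payload = {
            "criterion": self.criterion,
            "mixing": {g: list(p) for g, p in self.mixing.items()},
            "achieved": {g: list(p) for g, p in self.achieved.items()},
            "objective": self.objective,
            "degenerate_groups": self.degenerate_groups,
            "infeasible": self.infeasible,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "DerivedPredictorBinary":
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
            mixing={g: tuple(p) for g, p in payload["mixing"].items()},
            achieved={g: tuple(p) for g, p in payload["achieved"].items()},
            objective=float(payload["objective"]),
            degenerate_groups=list(payload.get("degenerate_groups", [])),
            infeasible=bool(payload.get("infeasible", False)),
        )


def _binary_objective(joint: JointDistribution, loss: LossSpec):
    """Linear objective c·p + const over p[g,k] = Pr(adj=1 | Ŷ=k, A=g)."""
    P = joint.joint  # (G, 2, 2) [g, y, yhat]
    L = loss.penalties  # (G, 2, 2) [g, i, j]
    G = len(joint.groups)
    c = np.zeros(2 * G)
    const = 0.0
    for g in range(G):
        for k in range(2):
            c[2 * g + k] = sum(P[g, j, k] * (L[g, 1, j] - L[g, 0, j]) for j in range(2))
        const += sum(P[g, j, k] * L[g, 0, j] for j in range(2) for k in range(2))
    return c, const


def _constraint_rows(joint: JointDistribution, criterion: str):
    """Equality rows A p = 0 tying adjusted conditional rates across groups.

    Pr(Ŷ_adj=1 | Y=j, A=g) = Σ_k p[g,k]·Pr(Ŷ=k | Y=j, A=g) is linear in p;
    equalized odds ties it across groups for j ∈ {0,1} (FPR and TPR), equal
    opportunity only for j = 1. Rows involving a group with no mass at Y=j
    are dropped as vacuous; such groups are reported as degenerate.
    """
    G = len(joint.groups)
    conds = [joint.cond_pred_given_true(g) for g in range(G)]
    which_j = (0, 1) if criterion == EQUALIZED_ODDS else (1,)
    rows, degenerate = [], set()
    for g in range(G):
        for j in range(2):
            if np.isnan(conds[g][j]).any():
                degenerate.add(joint.groups[g])
    ref = 0
    for g in range(1, G):
        for j in which_j:
            if np.isnan(conds[ref][j]).any() or np.isnan(conds[g][j]).any():
                continue
            row = np.zeros(2 * G)
            for k in range(2):
                row[2 * ref + k] = conds[ref][j, k]
                row[2 * g + k] = -conds[g][j, k]
            rows.append(row)
    A = np.array(rows) if rows else np.zeros((0, 2 * G))
    return A, sorted(degenerate), conds


def _solve_with_tiebreak(c, A_eq, n_vars, identity):
    """Min c·p s.t. A_eq p = 0, 0<=p<=1; among optima, closest (L1) to `identity`."""
    b_eq = np.zeros(A_eq.shape[0]) if A_eq.size else None
    res = linprog(
        c,
        A_eq=A_eq if A_eq.size else None,
        b_eq=b_eq,
        bounds=[(0.0, 1.0)] * n_vars,
        method="highs",
    )
    if not res.success:
        return None, None
    opt = float(res.fun)
    # stage 2: minimize sum |p - identity| subject to optimality
    n = n_vars
    c2 = np.concatenate([np.zeros(n), np.ones(n)])
    A_ub = np.block(
        [
            [np.eye(n), -np.eye(n)],
            [-np.eye(n), -np.eye(n)],
            [c.reshape(1, -1), np.zeros((1, n))],
        ]
    )
    b_ub = np.concatenate([identity, -identity, [opt + _OBJ_SLACK]])
    A_eq2 = np.hstack([A_eq, np.zeros((A_eq.shape[0], n))]) if A_eq.size else None
    res2 = linprog(
        c2,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq2,
        b_eq=np.zeros(A_eq.shape[0]) if A_eq.size else None,
        bounds=[(0.0, 1.0)] * n + [(0.0, None)] * n,
        method="highs",
    )
    p = res2.x[:n] if res2.success else res.x
    return np.clip(p, 0.0, 1.0), opt


def _fit_binary(joint: JointDistribution, loss: LossSpec | None, criterion: str) -> DerivedPredictorBinary:
    if joint.n_classes != 2:
        raise ValueError("binary fit requires a 2-class joint distribution")
    if loss is None:
        loss = LossSpec.zero_one(joint.groups, 2)
    G = len(joint.groups)
    c, const = _binary_objective(joint, loss)
    A, degenerate, conds = _constraint_rows(joint, criterion)
    identity = np.tile([0.0, 1.0], G)
    p, opt = _solve_with_tiebreak(c, A, 2 * G, identity)
    infeasible = False
    if p is None:
        # Constant predictors (p_0 = p_1) always satisfy the constraints, so a
        # genuine infeasibility cannot occur; numerical failure falls back to
        # the best point on the chance diagonal, explicitly flagged.
        infeasible = True
        cand = [np.zeros(2 * G), np.ones(2 * G)]
        vals = [float(c @ x) for x in cand]
        p = cand[int(np.argmin(vals))]
        opt = min(vals)
        warnings.warn("LP solve failed; falling back to best diagonal point", stacklevel=2)
    mixing = {g: (float(p[2 * i]), float(p[2 * i + 1])) for i, g in enumerate(joint.groups)}
    achieved = {}
    for i, g in enumerate(joint.groups):
        cond = conds[i]
        fpr = float(np.nansum(cond[0] * p[2 * i : 2 * i + 2])) if not np.isnan(cond[0]).any() else float("nan")
        tpr = float(np.nansum(cond[1] * p[2 * i : 2 * i + 2])) if not np.isnan(cond[1]).any() else float("nan")
        achieved[g] = (fpr, tpr)
    return DerivedPredictorBinary(
        criterion=criterion,
        mixing=mixing,
        achieved=achieved,
        objective=float(opt + const),
        degenerate_groups=degenerate,
        infeasible=infeasible,
    )


def fit_equalized_odds(joint: JointDistribution, loss: LossSpec | None = None) -> DerivedPredictorBinary:
    """Fit the expected-loss-minimal derived predictor with equal (FPR, TPR) across groups."""
    return _fit_binary(joint, loss, EQUALIZED_ODDS)


def fit_equal_opportunity(joint: JointDistribution, loss: LossSpec | None = None) -> DerivedPredictorBinary:
    """Fit the derived predictor equalizing TPR only; never costlier than equalized odds."""
    return _fit_binary(joint, loss, EQUAL_OPPORTUNITY)


def apply_derived_predictor(
    df: pd.DataFrame, predictor: DerivedPredictorBinary, seed: int
) -> pd.DataFrame:
    """Stochastically relabel a prediction table with a fitted binary predictor.

    Each record with base prediction Ŷ = j in group α receives adjusted label
    1 with probability mixing[α][j], independently; deterministic given seed.
    Returns a copy with an `adjusted_label` column.
    """
    unseen = set(df["group"].astype(str)) - set(predictor.mixing)
    if unseen:
        raise ValueError(f"groups {sorted(unseen)} absent from the fitted predictor")
    rng = substream(seed, "apply-binary")
    u = rng.random(len(df))
    probs = np.array(
        [predictor.mixing[g][j] for g, j in zip(df["group"].astype(str), df["predicted_label"])]
    )
    out = df.copy()
    out["adjusted_label"] = (u < probs).astype(int)
    return out
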