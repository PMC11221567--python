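"""Independent oracles used by the test suite.

Everything here recomputes quantities by brute force (explicit loops, dense
grids, randomized feasible-point sampling) without touching the package's
optimized code paths, so agreement between the two routes is evidence, not
tautology.
"""

from __future__ import annotations

import numpy as np

from fairpost.joint import JointDistribution


# ---------------------------------------------------------------------------
# counting


def brute_binary_counts(df):
    """Tally (tp, fp, tn, fn) per group by iterating record by record."""
    out = {}
    for _, row in df.iterrows():
        g = str(row["group"])
        c = out.setdefault(g, {"tp": 0, "fp": 0, "tn": 0, "fn": 0})
        y, yhat = int(row["true_label"]), int(row["predicted_label"])
        if y == 1 and yhat == 1:
            c["tp"] += 1
        elif y == 0 and yhat == 1:
            c["fp"] += 1
        elif y == 0 and yhat == 0:
            c["tn"] += 1
        else:
            c["fn"] += 1
    return out


def brute_confusion(df, n_classes):
    """Per-group K x K confusion tally by explicit iteration."""
    out = {}
    for _, row in df.iterrows():
        g = str(row["group"])
        mat = out.setdefault(g, np.zeros((n_classes, n_classes), dtype=int))
        mat[int(row["true_label"]), int(row["predicted_label"])] += 1
    return out


def triple_loop_expected_loss(joint: JointDistribution, matrices, penalties) -> float:
    """E[l] = sum over alpha, i, j, k of l(i,j,alpha) W[i,k] P(yhat=k, y=j, alpha)."""
    total = 0.0
    K = joint.n_classes
    for g_idx, g in enumerate(joint.groups):
        W = np.asarray(matrices[g])
        for i in range(K):
            for j in range(K):
                for k in range(K):
                    total += penalties[g_idx, i, j] * W[i, k] * joint.joint[g_idx, j, k]
    return total


# ---------------------------------------------------------------------------
# random instances


def random_binary_joint(rng, min_count=2, max_count=40) -> JointDistribution:
    """Random two-group binary joint with every (Y, group) cell populated and
    base predictors safely away from the chance diagonal (invertible mixing map)."""
    while True:
        counts = rng.integers(min_count, max_count, size=(2, 2, 2)).astype(float)
        jd = JointDistribution(["a", "b"], 2, counts / counts.sum())
        ok = True
        for g in range(2):
            cond = jd.cond_pred_given_true(g)
            det = cond[0, 0] * cond[1, 1] - cond[0, 1] * cond[1, 0]
            if not np.isfinite(det) or abs(det) < 0.05:
                ok = False
        if ok:
            return jd


def random_multiclass_joint(rng, n_classes=3, n_groups=2, max_count=40) -> JointDistribution:
    counts = rng.integers(1, max_count, size=(n_groups, n_classes, n_classes)).astype(float)
    groups = [f"g{i}" for i in range(n_groups)]
    return JointDistribution(groups, n_classes, counts / counts.sum())


# ---------------------------------------------------------------------------
# binary grid-search oracles


def _direct_objective_terms(joint: JointDistribution):
    """0-1 loss objective E(p) = const + sum_g c_g . p_g, derived from scratch."""
    P = joint.joint
    c = np.array([[P[g, 0, k] - P[g, 1, k] for k in range(2)] for g in range(2)])
    const = P[:, 1, :].sum()
    return c, const


def grid_eq_odds_binary(joint: JointDistribution, step=1e-3) -> float:
    """Exhaustive grid over group-a mixing parameters; group-b solved exactly
    from the two equal-rate constraints. Returns the minimal 0-1 expected loss."""
    c, const = _direct_objective_terms(joint)
    Ca = joint.cond_pred_given_true(0)  # rate_j(p) = sum_k p_k Ca[j, k]
    Cb = joint.cond_pred_given_true(1)
    Cb_inv = np.linalg.inv(Cb)
    grid = np.arange(0.0, 1.0 + step / 2, step)
    p0, p1 = np.meshgrid(grid, grid, indexing="ij")
    pa = np.stack([p0.ravel(), p1.ravel()])  # (2, N)
    rates = Ca @ pa
    pb = Cb_inv @ rates
    feas = (pb >= -1e-9).all(axis=0) & (pb <= 1 + 1e-9).all(axis=0)
    obj = const + c[0] @ pa + c[1] @ np.clip(pb, 0, 1)
    return float(obj[feas].min())


def grid_eq_opp_binary(joint: JointDistribution, step=1e-3) -> float:
    """Grid over the common TPR; each group optimized exactly on the induced
    feasible segment (a linear objective attains its minimum at an endpoint)."""
    c, const = _direct_objective_terms(joint)
    taus = np.arange(0.0, 1.0 + step / 2, step)
    total = np.zeros_like(taus)
    feasible = np.ones_like(taus, dtype=bool)
    for g in range(2):
        a, b = joint.cond_pred_given_true(g)[1]  # tpr(p) = a p0 + b p1
        best = np.full_like(taus, np.inf)
        cands = []
        if b > 1e-12:
            for p0 in (0.0, 1.0):
                cands.append((np.full_like(taus, p0), (taus - a * p0) / b))
        if a > 1e-12:
            for p1 in (0.0, 1.0):
                cands.append(((taus - b * p1) / a, np.full_like(taus, p1)))
        for p0v, p1v in cands:
            ok = (p0v >= -1e-9) & (p0v <= 1 + 1e-9) & (p1v >= -1e-9) & (p1v <= 1 + 1e-9)
            val = c[g, 0] * np.clip(p0v, 0, 1) + c[g, 1] * np.clip(p1v, 0, 1)
            best = np.where(ok & (val < best), val, best)
        feasible &= np.isfinite(best)
        total = total + np.where(np.isfinite(best), best, 0.0)
    return float(const + total[feasible].min())


# ---------------------------------------------------------------------------
# multiclass feasible-point sampler


def multiclass_objective_vector(joint: JointDistribution, penalties) -> np.ndarray:
    """Flattened objective coefficients computed by an explicit loop."""
    K, G = joint.n_classes, len(joint.groups)
    c = np.zeros(G * K * K)
    for g in range(G):
        for i in range(K):
            for k in range(K):
                c[g * K * K + i * K + k] = sum(
                    penalties[g, i, j] * joint.joint[g, j, k] for j in range(K)
                )
    return c


def constant_predictor_flat(q, n_groups, n_classes) -> np.ndarray:
    """W-set outputting distribution q regardless of input: always fair."""
    W = np.tile(np.asarray(q, dtype=float).reshape(n_classes, 1), (1, n_classes))
    return np.tile(W.ravel(), n_groups)


def sample_feasible_objectives(joint, penalties, pool, n_samples, rng, chunk=100_000):
    """Objectives of Dirichlet convex combinations of feasible pool points.

    `pool` is an (m, n_vars) array of feasible flattened W-sets; any convex
    combination stays inside the (convex) constraint polytope. Returns the
    minimum sampled objective.
    """
    c = multiclass_objective_vector(joint, penalties)
    pool = np.asarray(pool)
    pool_obj = pool @ c
    best = np.inf
    k_mix = min(5, len(pool))
    done = 0
    while done < n_samples:
        m = min(chunk, n_samples - done)
        idx = rng.integers(0, len(pool), size=(m, k_mix))
        w = rng.gamma(1.0, size=(m, k_mix))
        w /= w.sum(axis=1, keepdims=True)
        # objective is linear, so the combo objective is the combo of objectives
        objs = (w * pool_obj[idx]).sum(axis=1)
        best = min(best, float(objs.min()))
        done += m
    return best
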