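"""Half-sample bootstrap of subgroup rates and between-group significance tests.

The evaluation scheme repeatedly (default 50 iterations) draws a random
subset of half the evaluation records — from the pooled table, so each
subsample preserves the natural group imbalance — and recomputes the
epsilon-regularized FPR and TPR per protected group. Replicate means,
standard deviations and confidence intervals summarize each metric, and an
independent two-sample t-test on the replicate vectors quantifies
between-group differences.

A caveat worth stating plainly: half-sample replicates from one fixed table
are not independent draws from the sampling distribution, so the t-test on
them is a descriptive disparity score, not a calibrated hypothesis test. A
permutation test on the underlying records is available as an alternative
(`permutation_pvalue`); it is a different procedure from the replicate
t-test and is labelled as such.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import substream
from .metrics import DEFAULT_EPSILON, compute_group_rates, compute_multiclass_rates

__all__ = [
    "BootstrapReport",
    "TTestResult",
    "bootstrap_rates",
    "group_difference_ttest",
    "permutation_pvalue",
    "build_comparison_report",
]


@dataclass
class BootstrapReport:
    """Replicate rate estimates and their summaries.

    `replicates` is indexed by iteration with one column per (group, metric);
    a group missing from a subsample leaves NaN for that iteration, excluded
    from summaries and counted in `missing_counts`.
    """

    replicates: pd.DataFrame
    iterations: int
    subsample_fraction: float
    subsample_size: int
    seed: int
    ci_level: float = 0.95
    ci_method: str = "normal"
    missing_counts: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        rows = []
        z = stats.norm.ppf(0.5 + self.ci_level / 2)
        for col in self.replicates.columns:
            vals = self.replicates[col].dropna().to_numpy()
            group, metric = col
            mean = float(np.mean(vals)) if len(vals) else np.nan
            # exact zero for all-equal replicates (no float-roundoff residue)
            if len(vals) < 2 or np.ptp(vals) == 0:
                sd = 0.0
            else:
                sd = float(np.std(vals, ddof=1))
            if self.ci_method == "normal":
                half = z * sd / np.sqrt(len(vals)) if len(vals) else np.nan
                lo, hi = mean - half, mean + half
            elif self.ci_method == "percentile":
                alpha = 1 - self.ci_level
                lo, hi = (
                    (float(np.quantile(vals, alpha / 2)), float(np.quantile(vals, 1 - alpha / 2)))
                    if len(vals)
                    else (np.nan, np.nan)
                )
            else:
                raise ValueError(f"unknown ci_method {self.ci_method!r}")
            rows.append(
                {
                    "group": group,
                    "metric": metric,
                    "n_replicates": len(vals),
                    "mean": mean,
                    "sd": sd,
                    "ci_low": lo,
                    "ci_high": hi,
                }
            )
        return pd.DataFrame(rows)


@dataclass
class TTestResult:
    """Two-sample t-test comparing one metric's replicates across two groups."""

    metric: str
    group_a: str
    group_b: str
    t_statistic: float
    p_value: float
    df: float
    equal_var: bool = True


def bootstrap_rates(
    df: pd.DataFrame,
    iterations: int = 50,
    fraction: float = 0.5,
    epsilon: float = DEFAULT_EPSILON,
    seed: int = 0,
    n_classes: int = 2,
    replace: bool = False,
    label_col: str = "predicted_label",
    ci_level: float = 0.95,
    ci_method: str = "normal",
) -> BootstrapReport:
    """Bootstrap per-group FPR/TPR over random half-samples of the pooled table.

    Each iteration draws ``floor(fraction * n)`` records (without replacement
    by default) and computes epsilon-regularized rates per group; metrics for
    K > 2 are one-vs-rest per class, labelled ``fpr_c`` / ``tpr_c``.
    Deterministic given seed.
    """
    n = len(df)
    size = int(np.floor(fraction * n))
    if size < 2:
        raise ValueError(f"subsample of {size} records is too small (n={n}, fraction={fraction})")
    groups = sorted(df["group"].astype(str).unique())
    if n_classes == 2:
        metrics = ["fpr", "tpr"]
    else:
        metrics = [f"{m}_{c}" for c in range(n_classes) for m in ("fpr", "tpr")]
    cols = pd.MultiIndex.from_product([groups, metrics], names=["group", "metric"])
    rep = pd.DataFrame(np.nan, index=pd.RangeIndex(iterations, name="iteration"), columns=cols)
    missing = {g: 0 for g in groups}

    rng = substream(seed, "bootstrap")
    for it in range(iterations):
        idx = rng.choice(n, size=size, replace=replace)
        sub = df.iloc[idx]
        present = set(sub["group"].astype(str))
        for g in groups:
            if g not in present:
                missing[g] += 1
        if n_classes == 2:
            rates = compute_group_rates(sub, epsilon=epsilon, label_col=label_col)
            for g, r in rates.items():
                rep.loc[it, (g, "fpr")] = r.fpr
                rep.loc[it, (g, "tpr")] = r.tpr
        else:
            rates = compute_multiclass_rates(sub, n_classes, epsilon=epsilon, label_col=label_col)
            for g, r in rates.items():
                for c in range(n_classes):
                    ovr = r.one_vs_rest(c)
                    rep.loc[it, (g, f"fpr_{c}")] = ovr.fpr
                    rep.loc[it, (g, f"tpr_{c}")] = ovr.tpr
    return BootstrapReport(
        replicates=rep,
        iterations=iterations,
        subsample_fraction=fraction,
        subsample_size=size,
        seed=seed,
        ci_level=ci_level,
        ci_method=ci_method,
        missing_counts=missing,
    )


def group_difference_ttest(
    report: BootstrapReport,
    metric: str,
    group_a: str,
    group_b: str,
    equal_var: bool = True,
) -> TTestResult:
    """Two-sided independent-samples t-test on a metric's replicate vectors.

    Student (pooled variance) by default, Welch with ``equal_var=False``.
    Two zero-variance arrays with equal means give t = 0, p = 1.
    """
    a = report.replicates[(group_a, metric)].dropna().to_numpy()
    b = report.replicates[(group_b, metric)].dropna().to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 non-missing replicates per group")
    if np.var(a) == 0 and np.var(b) == 0:
        dof = len(a) + len(b) - 2
        if np.mean(a) == np.mean(b):
            return TTestResult(metric, group_a, group_b, 0.0, 1.0, float(dof), equal_var)
        return TTestResult(metric, group_a, group_b, float("inf"), 0.0, float(dof), equal_var)
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    dof = float(res.df) if hasattr(res, "df") else float(len(a) + len(b) - 2)
    return TTestResult(metric, group_a, group_b, float(res.statistic), float(res.pvalue), dof, equal_var)


def permutation_pvalue(
    df: pd.DataFrame,
    metric: str,
    group_a: str,
    group_b: str,
    epsilon: float = DEFAULT_EPSILON,
    n_permutations: int = 1000,
    seed: int = 0,
) -> float:
    """Permutation test of a between-group rate difference on the raw records.

    Group labels are shuffled across records; the p-value is the fraction of
    permutations with an absolute rate difference at least as large as the
    observed one. This is an alternative diagnostic, not part of the
    replicate-t-test evaluation scheme.
    """
    rng = substream(seed, "permutation")
    sub = df[df["group"].astype(str).isin([group_a, group_b])].reset_index(drop=True)

    def gap(frame):
        rates = compute_group_rates(frame, epsilon=epsilon)
        if group_a not in rates or group_b not in rates:
            return np.nan
        return abs(getattr(rates[group_a], metric) - getattr(rates[group_b], metric))

    observed = gap(sub)
    labels = sub["group"].to_numpy().copy()
    count, valid = 0, 0
    for _ in range(n_permutations):
        rng.shuffle(labels)
        perm = sub.assign(group=labels)
        g = gap(perm)
        if np.isnan(g):
            continue
        valid += 1
        if g >= observed - 1e-12:
            count += 1
    return (count + 1) / (valid + 1)


def build_comparison_report(
    pre_df: pd.DataFrame,
    post_by_criterion: dict[str, pd.DataFrame],
    loss_values: dict[str, float] | None = None,
    epsilon: float = DEFAULT_EPSILON,
    n_classes: int = 2,
    model: str = "model",
) -> pd.DataFrame:
    """Pre- vs post-adjustment rate table, one row per group (x class for K > 2).

    `post_by_criterion` maps a criterion name to the adjusted table (with an
    `adjusted_label` column) on the same record ids; `loss_values` maps
    'pre' and each criterion to the scalar expected loss, reported once per
    model row set (constant across groups).
    """
    pre_ids = pre_df["record_id"].sort_values().to_numpy()
    for name, post in post_by_criterion.items():
        post_ids = post["record_id"].sort_values().to_numpy()
        if len(post_ids) != len(pre_ids) or not (post_ids == pre_ids).all():
            raise ValueError(f"record ids of post table {name!r} do not match the pre table")
        if "adjusted_label" not in post.columns:
            raise ValueError(f"post table {name!r} lacks an adjusted_label column")

    def rate_frame(frame, label_col):
        out = []
        if n_classes == 2:
            rates = compute_group_rates(frame, epsilon=epsilon, label_col=label_col)
            for g, r in rates.items():
                out.append({"group": g, "class": None, "fpr": r.fpr, "tpr": r.tpr})
        else:
            rates = compute_multiclass_rates(frame, n_classes, epsilon=epsilon, label_col=label_col)
            for g, r in rates.items():
                for c in range(n_classes):
                    ovr = r.one_vs_rest(c)
                    out.append({"group": g, "class": c, "fpr": ovr.fpr, "tpr": ovr.tpr})
        return pd.DataFrame(out)

    base = rate_frame(pre_df, "predicted_label").rename(
        columns={"fpr": "fpr_pre", "tpr": "tpr_pre"}
    )
    for name, post in post_by_criterion.items():
        rf = rate_frame(post, "adjusted_label").rename(
            columns={"fpr": f"fpr_{name}", "tpr": f"tpr_{name}"}
        )
        base = base.merge(rf, on=["group", "class"], how="left")
    base.insert(0, "model", model)
    if loss_values:
        for key, val in loss_values.items():
            base[f"loss_{key}"] = float(val)
    if n_classes == 2:
        base = base.drop(columns=["class"])
    return base
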