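"""Synthetic prediction-table generator with controllable group disparity.

Emulates the prediction-level structure of a clinical classifier evaluated on
an imbalanced two-group cohort: a protected attribute A (e.g. White /
non-White), a true class label Y (binary cancer stage 0 vs III/IV, or the
3-class 0 / I-II / III-IV split), a predicted label Ŷ, and for the binary
task a continuous score in [0, 1].

Binary scores follow a binormal model: class-0 scores are standard normal,
class-1 scores are shifted by d' = sqrt(2) * Phi^-1(AUC), then squashed to
[0, 1] by the logistic function (monotone, hence AUC-preserving). This gives
closed-form control of each group's discrimination and of the operating
point (FPR, TPR) at any score threshold, so disparities of a chosen size can
be injected and recovered analytically.

The multi-class generator is parameterized directly by per-group conditional
confusion tendencies Pr(Ŷ | Y), the exact conditionals the multi-class
fairness adjustment consumes, which makes parameter recovery testable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit, ndtr, ndtri

from ._rng import substream

__all__ = [
    "CohortConfig",
    "COHORT_COLUMNS",
    "generate_binary_cohort",
    "generate_multiclass_cohort",
    "dprime_for_auc",
    "auc_for_tpr_at_threshold",
    "binormal_operating_point",
    "read_cohort",
    "write_cohort",
    "group_sizes",
]

COHORT_COLUMNS = ["record_id", "group", "true_label", "predicted_label", "score"]

_SUM_TOL = 1e-9


def dprime_for_auc(auc: float) -> float:
    """Binormal separation d' giving the requested AUC: AUC = Phi(d'/sqrt(2))."""
    return math.sqrt(2.0) * float(ndtri(auc))


def auc_for_tpr_at_threshold(threshold: float, tpr: float) -> float:
    """AUC whose binormal score model attains `tpr` at score cutoff `threshold`.

    The logistic squash maps latent z to score expit(z), so the cutoff in
    latent space is z* = logit(threshold) and TPR = Phi(d' - z*). Inverting
    gives d' = z* + Phi^-1(tpr), hence AUC = Phi(d'/sqrt(2)).
    """
    dprime = float(logit(threshold)) + float(ndtri(tpr))
    return float(ndtr(dprime / math.sqrt(2.0)))


def binormal_operating_point(auc: float, threshold: float) -> tuple[float, float]:
    """Population (FPR, TPR) of the binormal model at a score threshold."""
    zstar = float(logit(threshold))
    dprime = dprime_for_auc(auc)
    fpr = float(ndtr(-zstar))
    tpr = float(ndtr(dprime - zstar))
    return fpr, tpr


@dataclass
class CohortConfig:
    """Design of a synthetic cohort.

    Parameters
    ----------
    n_total:
        Number of prediction records.
    group_fractions:
        Mapping group -> fraction of the cohort; must sum to 1. Group sizes
        are assigned deterministically by largest-remainder rounding so that
        fixed designs (e.g. 32/41 and 9/41) reproduce exactly.
    prevalence_per_group:
        Mapping group -> class-probability vector (length K, sums to 1).
    auc_per_group:
        Binary task only: mapping group -> target AUC in [0.5, 1.0).
    confusion_per_group:
        Multi-class task: mapping group -> K x K row-stochastic matrix of
        conditional confusion tendencies Pr(Ŷ = col | Y = row).
    threshold:
        Binary score cutoff in (0, 1); predicted_label = 1 iff score > threshold.
    seed:
        Root seed; all randomness flows through named substreams of it.
    """

    n_total: int
    group_fractions: Mapping[str, float]
    prevalence_per_group: Mapping[str, Sequence[float]]
    auc_per_group: Mapping[str, float] | None = None
    confusion_per_group: Mapping[str, Sequence[Sequence[float]]] | None = None
    threshold: float = 0.5
    seed: int = 0

    @property
    def groups(self) -> list[str]:
        return list(self.group_fractions)

    @property
    def n_classes(self) -> int:
        return len(next(iter(self.prevalence_per_group.values())))

    def validate(self) -> None:
        if self.n_total < 2:
            raise ValueError(f"n_total must be >= 2, got {self.n_total}")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError(f"threshold must lie in (0, 1), got {self.threshold}")
        frac_sum = sum(self.group_fractions.values())
        if abs(frac_sum - 1.0) > _SUM_TOL:
            raise ValueError(f"group_fractions sum to {frac_sum}, expected 1")
        if set(self.prevalence_per_group) != set(self.group_fractions):
            raise ValueError("prevalence_per_group groups do not match group_fractions")
        k = self.n_classes
        if k not in (2, 3):
            raise ValueError(f"prevalence vectors must have length 2 or 3, got {k}")
        for g, prev in self.prevalence_per_group.items():
            if len(prev) != k:
                raise ValueError(f"group {g!r}: prevalence length {len(prev)} != {k}")
            if abs(sum(prev) - 1.0) > _SUM_TOL:
                raise ValueError(f"group {g!r}: prevalence sums to {sum(prev)}")
            if any(p < 0 for p in prev):
                raise ValueError(f"group {g!r}: negative prevalence entry")
        if self.auc_per_group is not None:
            for g, auc in self.auc_per_group.items():
                if not 0.5 <= auc < 1.0:
                    raise ValueError(f"group {g!r}: AUC {auc} outside [0.5, 1.0)")
        if self.confusion_per_group is not None:
            for g, mat in self.confusion_per_group.items():
                arr = np.asarray(mat, dtype=float)
                if arr.shape != (k, k):
                    raise ValueError(f"group {g!r}: confusion shape {arr.shape} != ({k},{k})")
                if np.any(arr < 0):
                    raise ValueError(f"group {g!r}: negative confusion entry")
                rows = arr.sum(axis=1)
                if np.any(np.abs(rows - 1.0) > 1e-6):
                    raise ValueError(
                        f"group {g!r}: confusion rows must sum to 1 within 1e-6, got {rows}"
                    )


def group_sizes(n_total: int, group_fractions: Mapping[str, float]) -> dict[str, int]:
    """Deterministic group sizes by largest-remainder rounding (exact for fixed designs)."""
    names = list(group_fractions)
    raw = np.array([group_fractions[g] * n_total for g in names])
    base = np.floor(raw).astype(int)
    shortfall = int(round(n_total - base.sum()))
    # Hand remaining units to the largest fractional parts; ties broken by order.
    order = np.argsort(-(raw - base), kind="stable")
    for i in order[:shortfall]:
        base[i] += 1
    return dict(zip(names, base.tolist()))


def _record_ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i:07d}" for i in range(n)]


def generate_binary_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate a binary prediction table under the binormal score model.

    Returns a DataFrame with columns record_id, group, true_label,
    predicted_label, score; deterministic given `config.seed`.
    """
    config.validate()
    if config.n_classes != 2:
        raise ValueError("generate_binary_cohort requires 2-class prevalence vectors")
    if config.auc_per_group is None:
        raise ValueError("binary cohorts require auc_per_group")
    if set(config.auc_per_group) != set(config.groups):
        raise ValueError("auc_per_group groups do not match group_fractions")

    sizes = group_sizes(config.n_total, config.group_fractions)
    frames = []
    offset = 0
    for g in config.groups:
        n_g = sizes[g]
        if n_g == 0:
            raise ValueError(f"group {g!r} received 0 records; its metrics would be undefined")
        rng = substream(config.seed, f"binary:{g}")
        prev1 = float(config.prevalence_per_group[g][1])
        y = (rng.random(n_g) < prev1).astype(int)
        dprime = dprime_for_auc(float(config.auc_per_group[g]))
        z = rng.standard_normal(n_g) + dprime * y
        score = expit(z)
        yhat = (score > config.threshold).astype(int)
        frames.append(
            pd.DataFrame(
                {
                    "record_id": _record_ids(f"r{offset:02d}-", n_g),
                    "group": g,
                    "true_label": y,
                    "predicted_label": yhat,
                    "score": score,
                }
            )
        )
        offset += 1
    return pd.concat(frames, ignore_index=True)


def generate_multiclass_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate a K-class prediction table from per-group confusion tendencies.

    For each record, Y is drawn from the group's prevalence vector and Ŷ from
    row Y of the group's Pr(Ŷ | Y) matrix. The score column is absent (NaN).
    """
    config.validate()
    k = config.n_classes
    if config.confusion_per_group is None:
        raise ValueError("multi-class cohorts require confusion_per_group")
    if set(config.confusion_per_group) != set(config.groups):
        raise ValueError("confusion_per_group groups do not match group_fractions")

    sizes = group_sizes(config.n_total, config.group_fractions)
    frames = []
    offset = 0
    for g in config.groups:
        n_g = sizes[g]
        if n_g == 0:
            raise ValueError(f"group {g!r} received 0 records; its metrics would be undefined")
        rng = substream(config.seed, f"multiclass:{g}")
        prev = np.asarray(config.prevalence_per_group[g], dtype=float)
        conf = np.asarray(config.confusion_per_group[g], dtype=float)
        conf = conf / conf.sum(axis=1, keepdims=True)
        # Inverse-CDF draws keep each record's (Y, Ŷ) a pure function of the stream.
        y = np.searchsorted(np.cumsum(prev), rng.random(n_g), side="right").clip(0, k - 1)
        u = rng.random(n_g)
        cum = np.cumsum(conf, axis=1)
        yhat = (u[:, None] > cum[y]).sum(axis=1).clip(0, k - 1)
        frames.append(
            pd.DataFrame(
                {
                    "record_id": _record_ids(f"r{offset:02d}-", n_g),
                    "group": g,
                    "true_label": y,
                    "predicted_label": yhat,
                    "score": np.nan,
                }
            )
        )
        offset += 1
    return pd.concat(frames, ignore_index=True)


def write_cohort(df: pd.DataFrame, path) -> None:
    """Write a prediction table as UTF-8 CSV with the canonical column order."""
    out = df.loc[:, [c for c in COHORT_COLUMNS if c in df.columns]
                 + [c for c in df.columns if c not in COHORT_COLUMNS]]
    out.to_csv(path, index=False, encoding="utf-8")


def read_cohort(path) -> pd.DataFrame:
    """Read a prediction-table CSV, validating the required columns."""
    df = pd.read_csv(path, dtype={"record_id": str, "group": str})
    missing = [c for c in COHORT_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV missing required columns: {missing}")
    if "score" not in df.columns:
        df["score"] = np.nan
    df["true_label"] = df["true_label"].astype(int)
    df["predicted_label"] = df["predicted_label"].astype(int)
    return df
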