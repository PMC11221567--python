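"""End-to-end orchestration: simulate -> metrics -> adjust -> evaluate.

A run is a pure function of its RunConfig: one root seed feeds named
substreams per stage, and every artifact (cohort CSV, adjusted CSVs,
predictor JSONs, metric and comparison reports, manifest) is regenerated
bit-identically from the same config.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .binary import (
    EQUAL_OPPORTUNITY,
    EQUALIZED_ODDS,
    apply_derived_predictor,
    fit_equal_opportunity,
    fit_equalized_odds,
)
from .cohort import CohortConfig, generate_binary_cohort, generate_multiclass_cohort, write_cohort
from .evaluate import bootstrap_rates, build_comparison_report, group_difference_ttest
from .joint import estimate_joint
from .metrics import (
    DEFAULT_EPSILON,
    compute_fairness_gaps,
    compute_group_rates,
    compute_performance_summary,
)
from .multiclass import apply_multiclass, expected_loss, fit_multiclass

__all__ = ["RunConfig", "run_pipeline", "make_fixture", "FIXTURE_NAMES"]

try:
    _VERSION = version("fairpost")
except PackageNotFoundError:  # pragma: no cover - running from a source tree
    _VERSION = "unknown"


@dataclass
class RunConfig:
    """Fully serializable description of one pipeline run."""

    cohort: CohortConfig
    epsilon: float = DEFAULT_EPSILON
    criteria: tuple[str, ...] = (EQUALIZED_ODDS, EQUAL_OPPORTUNITY)
    n_classes: int = 2
    bootstrap_iterations: int = 50
    bootstrap_fraction: float = 0.5
    seed: int = 0
    output_dir: str = "fairpost_run"

    def to_dict(self, exclude_output: bool = False) -> dict:
        d = asdict(self)
        d["criteria"] = list(self.criteria)
        if exclude_output:
            d.pop("output_dir", None)
        cohort = d["cohort"]
        for key in ("group_fractions", "prevalence_per_group", "auc_per_group", "confusion_per_group"):
            if cohort.get(key) is not None:
                cohort[key] = {
                    g: (list(np.asarray(v).ravel()) if np.ndim(v) else float(v))
                    if not isinstance(v, (int, float))
                    else float(v)
                    for g, v in cohort[key].items()
                }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        cohort = d.pop("cohort")
        if isinstance(cohort, dict):
            conf = cohort.get("confusion_per_group")
            if conf is not None:
                k = len(cohort["prevalence_per_group"][next(iter(cohort["prevalence_per_group"]))])
                cohort["confusion_per_group"] = {
                    g: np.asarray(v, dtype=float).reshape(k, k) for g, v in conf.items()
                }
            cohort = CohortConfig(**cohort)
        d["criteria"] = tuple(d.get("criteria", (EQUALIZED_ODDS, EQUAL_OPPORTUNITY)))
        return cls(cohort=cohort, **{k: v for k, v in d.items() if k != "cohort"} )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        # the hash identifies the analysis, not where its files land
        blob = json.dumps(self.to_dict(exclude_output=True), sort_keys=True).encode("utf-8")
        return hashlib.sha256(blob).hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis and write all artifacts to the output directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        if config.n_classes == 2:
            cohort = generate_binary_cohort(config.cohort)
        else:
            cohort = generate_multiclass_cohort(config.cohort)
        write_cohort(cohort, out / "cohort.csv")

        stage = "metrics"
        summary = compute_performance_summary(cohort, n_classes=config.n_classes)
        summary.to_csv(out / "performance.csv", index=False)
        if config.n_classes == 2:
            rates = compute_group_rates(cohort, epsilon=config.epsilon)
            gaps = compute_fairness_gaps(rates)
            with open(out / "fairness_gaps.json", "w", encoding="utf-8") as fh:
                json.dump(
                    {"eq_odds_gap": gaps.eq_odds_gap, "eq_opp_gap": gaps.eq_opp_gap},
                    fh,
                    indent=2,
                    sort_keys=True,
                )

        stage = "adjust"
        joint = estimate_joint(cohort, config.n_classes)
        post_tables: dict[str, pd.DataFrame] = {}
        losses = {"pre": _identity_loss(joint)}
        for criterion in config.criteria:
            if config.n_classes == 2:
                fit = fit_equalized_odds(joint) if criterion == EQUALIZED_ODDS else fit_equal_opportunity(joint)
                fit.to_json(out / f"predictor_{criterion}.json")
                adjusted = apply_derived_predictor(cohort, fit, config.seed)
            else:
                fit = fit_multiclass(joint, criterion=criterion)
                fit.to_json(out / f"predictor_{criterion}.json")
                adjusted = apply_multiclass(cohort, fit, config.seed)
            write_cohort(adjusted, out / f"adjusted_{criterion}.csv")
            post_tables[criterion] = adjusted
            losses[criterion] = float(fit.objective)

        stage = "evaluate"
        report = bootstrap_rates(
            cohort,
            iterations=config.bootstrap_iterations,
            fraction=config.bootstrap_fraction,
            epsilon=config.epsilon,
            seed=config.seed,
            n_classes=config.n_classes,
        )
        report.summary().to_csv(out / "bootstrap_summary.csv", index=False)
        groups = sorted(cohort["group"].astype(str).unique())
        if len(groups) == 2:
            tt_rows = []
            for metric in report.replicates.columns.get_level_values("metric").unique():
                tt = group_difference_ttest(report, metric, groups[0], groups[1])
                tt_rows.append(
                    {
                        "metric": metric,
                        "group_a": tt.group_a,
                        "group_b": tt.group_b,
                        "t_statistic": tt.t_statistic,
                        "p_value": tt.p_value,
                        "df": tt.df,
                    }
                )
            pd.DataFrame(tt_rows).to_csv(out / "ttests.csv", index=False)
        comparison = build_comparison_report(
            cohort, post_tables, losses, epsilon=config.epsilon, n_classes=config.n_classes
        )
        comparison.to_csv(out / "comparison.csv", index=False)

        stage = "manifest"
        manifest = {
            "config": config.to_dict(exclude_output=True),
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "version": _VERSION,
        }
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out


def _identity_loss(joint) -> float:
    """Misclassification mass of the unadjusted predictor (0-1 loss)."""
    total = 0.0
    for g in range(len(joint.groups)):
        total += float(joint.joint[g].sum() - np.trace(joint.joint[g]))
    return total


# ---------------------------------------------------------------------------
# Deterministic toy fixtures with hand-countable confusion matrices

FIXTURE_NAMES = ("binary_perfect", "binary_biased", "binary_mixed", "multiclass_identity")


def make_fixture(name: str) -> pd.DataFrame:
    """Small deterministic prediction tables used across tests and examples.

    binary_perfect: 20 all-correct records, two groups.
    binary_biased: group a has TPR 0.9 / FPR 0.1 (10 positives, 10 negatives);
        group b has TPR 0.6 / FPR 0.3 (10 positives, 10 negatives).
    binary_mixed: 40 records with a known, hand-countable confusion per group.
    multiclass_identity: 30 all-correct 3-class records.
    """
    if name == "binary_perfect":
        rows = [(g, y, y) for g in ("a", "b") for y in (0, 1) for _ in range(5)]
    elif name == "binary_biased":
        rows = []
        rows += [("a", 1, 1)] * 9 + [("a", 1, 0)] * 1      # TPR a = 0.9
        rows += [("a", 0, 1)] * 1 + [("a", 0, 0)] * 9      # FPR a = 0.1
        rows += [("b", 1, 1)] * 6 + [("b", 1, 0)] * 4      # TPR b = 0.6
        rows += [("b", 0, 1)] * 3 + [("b", 0, 0)] * 7      # FPR b = 0.3
    elif name == "binary_mixed":
        rows = []
        rows += [("a", 1, 1)] * 7 + [("a", 1, 0)] * 3
        rows += [("a", 0, 1)] * 2 + [("a", 0, 0)] * 8
        rows += [("b", 1, 1)] * 4 + [("b", 1, 0)] * 6
        rows += [("b", 0, 1)] * 5 + [("b", 0, 0)] * 5
    elif name == "multiclass_identity":
        rows = [(g, y, y) for g in ("a", "b") for y in (0, 1, 2) for _ in range(5)]
    else:
        raise KeyError(f"unknown fixture {name!r}; known: {FIXTURE_NAMES}")
    return pd.DataFrame(
        {
            "record_id": [f"f{i:04d}" for i in range(len(rows))],
            "group": [r[0] for r in rows],
            "true_label": [r[1] for r in rows],
            "predicted_label": [r[2] for r in rows],
            "score": np.nan,
        }
    )
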