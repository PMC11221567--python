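"""Simulate a biased binary classifier over an imbalanced two-group cohort.

The generator plays the role of a trained model evaluated on a held-out set:
group AUCs of 0.80 vs 0.65 at a shared score threshold mimic a classifier
that discriminates cancer stage well for the majority group and poorly for
the minority group.
"""

from fairpost import (
    CohortConfig,
    compute_fairness_gaps,
    compute_group_rates,
    compute_performance_summary,
    generate_binary_cohort,
)

config = CohortConfig(
    n_total=20000,
    group_fractions={"White": 0.78, "nonWhite": 0.22},
    prevalence_per_group={"White": [0.61, 0.39], "nonWhite": [0.61, 0.39]},
    auc_per_group={"White": 0.80, "nonWhite": 0.65},
    threshold=0.7,
    seed=11,
)
cohort = generate_binary_cohort(config)

print("group sizes:", cohort["group"].value_counts().to_dict())
print(compute_performance_summary(cohort).to_string(index=False))

rates = compute_group_rates(cohort)
for g, r in rates.items():
    print(f"{g:>9}: FPR={r.fpr:.3f} TPR={r.tpr:.3f}  (tp={r.tp} fp={r.fp} tn={r.tn} fn={r.fn})")

gaps = compute_fairness_gaps(rates)
print(f"equalized-odds gap = {gaps.eq_odds_gap:.3f}, equal-opportunity gap = {gaps.eq_opp_gap:.3f}")
print("A gap near zero would mean the classifier treats both groups alike; here the")
print("minority group's true positives are detected far less often.")
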