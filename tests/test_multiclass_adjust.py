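"""Multi-class adjustment: joint estimation, expected loss, LP fit, stochastic apply."""

import numpy as np
import pandas as pd
import pytest

from _oracles import (
    constant_predictor_flat,
    multiclass_objective_vector,
    random_binary_joint,
    random_multiclass_joint,
    sample_feasible_objectives,
    triple_loop_expected_loss,
)
from fairpost import (
    EQUAL_OPPORTUNITY,
    EQUALIZED_ODDS,
    AdjustmentMatrixSet,
    JointDistribution,
    LossSpec,
    apply_multiclass,
    estimate_joint,
    expected_loss,
    fit_equal_opportunity,
    fit_equalized_odds,
    fit_multiclass,
    generate_multiclass_cohort,
    make_fixture,
)


def random_column_stochastic(rng, k):
    w = rng.random((k, k))
    return w / w.sum(axis=0, keepdims=True)


class TestEstimateJoint:
    def test_even_spread_quarter_cells(self):
        df = pd.DataFrame(
            {
                "record_id": list("abcd"),
                "group": "g",
                "true_label": [0, 0, 1, 1],
                "predicted_label": [0, 1, 0, 1],
            }
        )
        joint = estimate_joint(df, 2)
        assert np.allclose(joint.joint, 0.25)

    def test_marginal_conservation(self, multiclass_config):
        df = generate_multiclass_cohort(multiclass_config(n_total=600))
        joint = estimate_joint(df, 3)
        marg = joint.p_group_true()
        for g_idx, g in enumerate(joint.groups):
            sub = df[df["group"] == g]
            for j in range(3):
                expected = ((sub["true_label"] == j).sum()) / len(df)
                assert marg[g_idx, j] == pytest.approx(expected, abs=1e-12)

    def test_matches_brute_tally(self, rng):
        df = pd.DataFrame(
            {
                "record_id": [f"r{i}" for i in range(60)],
                "group": rng.choice(["a", "b"], 60),
                "true_label": rng.integers(0, 3, 60),
                "predicted_label": rng.integers(0, 3, 60),
            }
        )
        joint = estimate_joint(df, 3)
        for g_idx, g in enumerate(joint.groups):
            tally = np.zeros((3, 3))
            for _, row in df[df["group"] == g].iterrows():
                tally[row["true_label"], row["predicted_label"]] += 1
            assert np.allclose(joint.joint[g_idx], tally / 60)

    def test_total_mass_one(self, rng):
        joint = random_multiclass_joint(rng)
        assert joint.joint.sum() == pytest.approx(1.0, abs=1e-12)


class TestExpectedLoss:
    def test_perfect_predictor_identity_zero(self):
        df = make_fixture("multiclass_identity")
        joint = estimate_joint(df, 3)
        mats = {g: np.eye(3) for g in joint.groups}
        assert expected_loss(joint, mats) == pytest.approx(0.0, abs=1e-15)

    def test_constant_predictor_closed_form(self, rng):
        joint = random_multiclass_joint(rng)
        for c in range(3):
            w = np.zeros((3, 3))
            w[c, :] = 1.0
            mats = {g: w for g in joint.groups}
            p_y_c = joint.joint[:, c, :].sum()
            assert expected_loss(joint, mats) == pytest.approx(1 - p_y_c, abs=1e-12)

    def test_matches_triple_loop_oracle(self, rng):
        for _ in range(20):
            joint = random_multiclass_joint(rng)
            loss_spec = LossSpec.zero_one(joint.groups, 3)
            mats = {g: random_column_stochastic(rng, 3) for g in joint.groups}
            oracle = triple_loop_expected_loss(joint, mats, loss_spec.penalties)
            assert abs(expected_loss(joint, mats, loss_spec) - oracle) <= 1e-12

    def test_group_weighted_loss(self, rng):
        joint = random_multiclass_joint(rng)
        pen = np.stack([2.0 * (1 - np.eye(3)), 0.5 * (1 - np.eye(3))])
        loss_spec = LossSpec(joint.groups, 3, pen)
        mats = {g: random_column_stochastic(rng, 3) for g in joint.groups}
        oracle = triple_loop_expected_loss(joint, mats, pen)
        assert expected_loss(joint, mats, loss_spec) == pytest.approx(oracle, abs=1e-12)


class TestFit:
    def test_single_group_identity_optimal(self, rng):
        counts = rng.integers(1, 40, size=(1, 3, 3)).astype(float)
        counts += 50 * np.eye(3)  # make the base predictor clearly better than chance
        joint = JointDistribution(["a"], 3, counts / counts.sum())
        fit = fit_multiclass(joint, criterion=EQUALIZED_ODDS)
        base_rate = joint.joint[0].sum() - np.trace(joint.joint[0])
        assert fit.objective == pytest.approx(base_rate, abs=1e-9)
        assert np.allclose(fit.matrices["a"], np.eye(3), atol=1e-6)

    def test_k2_reduction_matches_binary(self, rng):
        for _ in range(20):
            joint = random_binary_joint(rng)
            b = fit_equalized_odds(joint)
            m = fit_multiclass(joint, criterion=EQUALIZED_ODDS)
            assert abs(b.objective - m.objective) <= 1e-6

    def test_k2_equal_opportunity_collapses_to_odds(self, rng):
        """Tying every correct-classification probability at K=2 fixes both the
        TPR and 1-FPR, so the per-class relaxation coincides with equalized odds
        and is never cheaper than the binary TPR-only constraint."""
        for _ in range(10):
            joint = random_binary_joint(rng)
            mo = fit_multiclass(joint, criterion=EQUAL_OPPORTUNITY)
            modds = fit_multiclass(joint, criterion=EQUALIZED_ODDS)
            bo = fit_equal_opportunity(joint)
            assert abs(mo.objective - modds.objective) <= 1e-6
            assert bo.objective <= mo.objective + 1e-9

    def test_column_stochastic_and_residuals(self, rng):
        for _ in range(5):
            joint = random_multiclass_joint(rng)
            fit = fit_multiclass(joint, criterion=EQUALIZED_ODDS)
            for g_idx, g in enumerate(joint.groups):
                w = fit.matrices[g]
                assert np.all(w >= -1e-9) and np.all(w <= 1 + 1e-9)
                assert np.allclose(w.sum(axis=0), 1.0, atol=1e-6)
            # adjusted conditionals Pr(adj=i | Y=j, g) coincide across groups
            adj = [
                fit.matrices[g] @ joint.cond_pred_given_true(i).T
                for i, g in enumerate(joint.groups)
            ]
            assert np.abs(adj[0] - adj[1]).max() <= 1e-6

    def test_equal_opportunity_relaxation_cheaper(self, rng):
        for _ in range(10):
            joint = random_multiclass_joint(rng)
            odds = fit_multiclass(joint, criterion=EQUALIZED_ODDS)
            opp = fit_multiclass(joint, criterion=EQUAL_OPPORTUNITY)
            assert opp.objective <= odds.objective + 1e-9
            # diagonal conditionals equalized under equal opportunity
            adj = [
                fit_multiclass(joint, criterion=EQUAL_OPPORTUNITY).matrices[g]
                @ joint.cond_pred_given_true(i).T
                for i, g in enumerate(joint.groups)
            ]
            assert np.abs(np.diag(adj[0]) - np.diag(adj[1])).max() <= 1e-6

    def test_dominates_sampled_feasible_points(self, rng):
        """LP optimum is <= the objective of every sampled feasible W-set."""
        from scipy.optimize import linprog

        for _ in range(2):
            joint = random_multiclass_joint(rng)
            loss_spec = LossSpec.zero_one(joint.groups, 3)
            fit = fit_multiclass(joint, loss_spec, criterion=EQUALIZED_ODDS)
            pool = [constant_predictor_flat(q, 2, 3) for q in rng.dirichlet(np.ones(3), 50)]
            pool.append(np.concatenate([fit.matrices[g].ravel() for g in joint.groups]))
            best = sample_feasible_objectives(
                joint, loss_spec.penalties, np.array(pool), 20000, rng
            )
            assert fit.objective <= best + 1e-9

    def test_unknown_criterion_rejected(self, rng):
        with pytest.raises(ValueError, match="criterion"):
            fit_multiclass(random_multiclass_joint(rng), criterion="parity")


class TestApply:
    def test_identity_keeps_labels(self, multiclass_config):
        df = generate_multiclass_cohort(multiclass_config(n_total=300))
        W = AdjustmentMatrixSet(
            criterion=EQUALIZED_ODDS, n_classes=3,
            matrices={g: np.eye(3) for g in ("White", "nonWhite")}, objective=0.0,
        )
        out = apply_multiclass(df, W, seed=3)
        assert (out["adjusted_label"] == out["predicted_label"]).all()

    def test_point_mass_column(self, multiclass_config):
        df = generate_multiclass_cohort(multiclass_config(n_total=300))
        w = np.zeros((3, 3))
        w[2, :] = 1.0
        W = AdjustmentMatrixSet(
            criterion=EQUALIZED_ODDS, n_classes=3,
            matrices={g: w for g in ("White", "nonWhite")}, objective=0.0,
        )
        out = apply_multiclass(df, W, seed=3)
        assert (out["adjusted_label"] == 2).all()

    def test_multinomial_sampling_frequencies(self):
        n = 60000
        df = pd.DataFrame(
            {
                "record_id": [f"r{i}" for i in range(n)],
                "group": "a",
                "true_label": 0,
                "predicted_label": 1,
            }
        )
        w = np.zeros((3, 3))
        w[:, 1] = [0.2, 0.3, 0.5]
        w[:, 0] = w[:, 2] = [1.0, 0.0, 0.0]
        W = AdjustmentMatrixSet(
            criterion=EQUALIZED_ODDS, n_classes=3, matrices={"a": w}, objective=0.0
        )
        out = apply_multiclass(df, W, seed=3)
        for cls, p in enumerate([0.2, 0.3, 0.5]):
            se = np.sqrt(p * (1 - p) / n)
            assert abs((out["adjusted_label"] == cls).mean() - p) <= 3 * se

    def test_deterministic_and_unseen_group(self, multiclass_config):
        df = generate_multiclass_cohort(multiclass_config(n_total=300))
        W = AdjustmentMatrixSet(
            criterion=EQUALIZED_ODDS, n_classes=3,
            matrices={"White": np.eye(3)}, objective=0.0,
        )
        with pytest.raises(ValueError, match="absent"):
            apply_multiclass(df, W, seed=1)

    def test_json_roundtrip(self, tmp_path, rng):
        joint = random_multiclass_joint(rng)
        fit = fit_multiclass(joint, criterion=EQUALIZED_ODDS)
        path = tmp_path / "w.json"
        fit.to_json(path)
        back = AdjustmentMatrixSet.from_json(path)
        for g in fit.matrices:
            assert np.allclose(back.matrices[g], fit.matrices[g])
        assert back.objective == pytest.approx(fit.objective)


class TestPopulationConstraint:
    def test_fresh_sample_conditional_gap_small(self, multiclass_config):
        fit_df = generate_multiclass_cohort(multiclass_config(n_total=60000, seed=31))
        fit = fit_multiclass(estimate_joint(fit_df, 3), criterion=EQUALIZED_ODDS)
        fresh = generate_multiclass_cohort(multiclass_config(n_total=60000, seed=32))
        adj = apply_multiclass(fresh, fit, seed=33)
        worst = 0.0
        for j in range(3):
            for i in range(3):
                probs = [
                    (adj[(adj.group == g) & (adj.true_label == j)]["adjusted_label"] == i).mean()
                    for g in ("White", "nonWhite")
                ]
                worst = max(worst, abs(probs[0] - probs[1]))
        assert worst <= 0.025
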