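"""Validation machinery: splits, ROC, metrics, holdout, permutation test."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from breathdiscrim import validate as vd
from breathdiscrim.validate import HoldoutConfig

from conftest import null_cohort, small_cohort


@pytest.fixture
def paper_shaped():
    """34 CIR / 87 CLD cohort on the modelling scale."""
    return small_cohort(n_per_class={"CIR": 34, "CLD": 87}, n_compounds=60,
                        seed=12).features.restrict_classes(["CIR", "CLD"]) \
        .log_abundances()


class TestSplits:
    def test_paper_default_sizes(self, paper_shaped):
        conf = HoldoutConfig(n_repeats=10)
        plan = vd.make_splits(paper_shaped, conf, seed=1)
        y = paper_shaped.y
        assert len(plan.val2) == 53            # 87 - 27 - 7 remaining CLD
        assert set(y.loc[plan.val2]) == {"CLD"}
        for rep in plan.repeats:
            train, val1 = rep["train"], rep["val1"]
            assert (y.loc[train] == "CIR").sum() == 27
            assert (y.loc[train] == "CLD").sum() == 27
            assert (y.loc[val1] == "CIR").sum() == 7
            assert (y.loc[val1] == "CLD").sum() == 7
            assert not (set(train) | set(val1)) & set(plan.val2)
            assert not set(train) & set(val1)

    def test_seed_reproducibility_and_repeat_count(self, paper_shaped):
        conf = HoldoutConfig(n_repeats=25)
        p1 = vd.make_splits(paper_shaped, conf, seed=9)
        p2 = vd.make_splits(paper_shaped, conf, seed=9)
        assert p1.repeats == p2.repeats and p1.val2 == p2.val2
        assert p1.n_repeats == 25
        distinct = {tuple(sorted(r["train"])) for r in p1.repeats}
        assert len(distinct) > 1

    def test_insufficient_class_count_rejected(self, paper_shaped):
        conf = HoldoutConfig(n_train_per_class=30, n_val_per_class=7)
        with pytest.raises(ValueError, match="CIR"):
            vd.make_splits(paper_shaped, conf, seed=0)


class TestROC:
    def test_probabilities_equal_to_labels_give_perfect_curve(self):
        labels = np.array(["CIR", "CLD", "CIR", "CLD", "CIR"])
        probs = (labels == "CIR").astype(float)
        r = vd.roc_curve(probs, labels)
        assert r.auc == 1.0
        assert r.sensitivity == 1.0 and r.specificity == 1.0

    def test_identical_probabilities_give_half(self):
        labels = np.array(["CIR"] * 4 + ["CLD"] * 6)
        r = vd.roc_curve(np.full(10, 0.3), labels)
        assert r.auc == pytest.approx(0.5)

    def test_endpoints(self):
        rng = np.random.default_rng(0)
        labels = np.array(["CIR", "CLD"] * 10)
        r = vd.roc_curve(rng.random(20), labels)
        assert (r.points.iloc[0][["FPR", "TPR"]] == 0).all()
        assert (r.points.iloc[-1][["FPR", "TPR"]] == 1).all()
        assert r.points["FPR"].is_monotonic_increasing
        assert r.points["TPR"].is_monotonic_increasing

    def test_auc_equals_mann_whitney_u_identity(self):
        # AUC = U / (n1 n2), cross-checked on 100 random instances (with ties)
        rng = np.random.default_rng(42)
        for _ in range(100):
            n1, n2 = rng.integers(3, 15, size=2)
            labels = np.array(["CIR"] * n1 + ["CLD"] * n2)
            probs = rng.choice(np.round(rng.random(8), 2), size=n1 + n2)
            auc = vd.roc_curve(probs, labels).auc
            pos, neg = probs[:n1], probs[n1:]
            u = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            assert auc == pytest.approx(u / (n1 * n2), abs=1e-12)

    def test_auc_matches_sklearn(self):
        rng = np.random.default_rng(3)
        labels = np.array(["CIR", "CLD"] * 25)
        probs = rng.random(50)
        ours = vd.roc_curve(probs, labels).auc
        ref = roc_auc_score((labels == "CIR").astype(int), probs)
        assert ours == pytest.approx(ref, abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(7)
        labels = np.array(["CIR", "CLD"] * 15)
        probs = rng.random(30)
        a = vd.roc_curve(probs, labels)
        b = vd.roc_curve(1 / (1 + np.exp(-5 * (probs - 0.5))), labels)
        assert a.auc == pytest.approx(b.auc, abs=1e-12)
        pd.testing.assert_frame_equal(a.points[["FPR", "TPR"]],
                                      b.points[["FPR", "TPR"]])

    def test_one_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            vd.roc_curve([0.2, 0.8], ["CIR", "CIR"])


class TestMetrics:
    def test_confusion_arithmetic(self):
        pred = ["CIR"] * 5 + ["CLD"] * 1 + ["CLD"] * 8 + ["CIR"] * 2
        true = ["CIR"] * 6 + ["CLD"] * 10
        m = vd.classification_metrics(pred, true)
        assert m["sensitivity"] == pytest.approx(5 / 6)
        assert m["specificity"] == pytest.approx(0.8)
        assert m["ppv"] == pytest.approx(5 / 7)
        assert m["npv"] == pytest.approx(8 / 9)

    def test_all_positive_predictions_leave_npv_undefined(self):
        m = vd.classification_metrics(["CIR"] * 4, ["CIR", "CIR", "CLD", "CLD"])
        assert m["specificity"] == 0.0
        assert np.isnan(m["npv"])

    def test_perfect_prediction(self):
        m = vd.classification_metrics(["CIR", "CLD"], ["CIR", "CLD"])
        assert all(v == 1.0 for v in m.values())

    def test_foreign_label_rejected(self):
        with pytest.raises(ValueError, match="HC"):
            vd.classification_metrics(["CIR", "HC"], ["CIR", "CLD"])


class TestHoldout:
    def test_separable_cohort_is_perfect(self):
        fm = small_cohort(n_per_class={"CIR": 30, "CLD": 30}, n_compounds=30,
                          effect=4.0, seed=5).features \
            .restrict_classes(["CIR", "CLD"]).log_abundances()
        conf = HoldoutConfig(n_train_per_class=20, n_val_per_class=7, n_repeats=15)
        rep = vd.run_holdout(fm, vd.make_splits(fm, conf, seed=2), conf)
        assert rep.auc == pytest.approx(1.0, abs=1e-12)
        assert rep.sensitivity == 1.0 and rep.specificity == 1.0

    def test_null_cohort_auc_near_half(self):
        fm = null_cohort(n_per_class={"CIR": 30, "CLD": 30},
                         n_compounds=40, seed=8).features \
            .restrict_classes(["CIR", "CLD"]).log_abundances()
        conf = HoldoutConfig(n_train_per_class=20, n_val_per_class=7, n_repeats=200)
        rep = vd.run_holdout(fm, vd.make_splits(fm, conf, seed=3), conf)
        assert abs(rep.auc - 0.5) < 0.06

    def test_planted_effect_beats_null(self):
        conf = HoldoutConfig(n_train_per_class=18, n_val_per_class=6, n_repeats=20)
        for seed in range(3):
            fm_eff = small_cohort(n_per_class={"CIR": 25, "CLD": 25}, n_compounds=60,
                                  effect=1.5, seed=60 + seed).features \
                .restrict_classes(["CIR", "CLD"]).log_abundances()
            fm_null = null_cohort(n_per_class={"CIR": 25, "CLD": 25},
                                  n_compounds=60, seed=60 + seed).features \
                .restrict_classes(["CIR", "CLD"]).log_abundances()
            auc_eff = vd.run_holdout(fm_eff, vd.make_splits(fm_eff, conf, seed=1), conf).auc
            auc_null = vd.run_holdout(fm_null, vd.make_splits(fm_null, conf, seed=1), conf).auc
            assert auc_eff > auc_null

    def test_monotone_in_effect_size(self):
        # aggregated AUC is non-decreasing in the planted effect (median of 3 seeds)
        conf = HoldoutConfig(n_train_per_class=18, n_val_per_class=6, n_repeats=10)
        medians = []
        for effect in [0.0, 0.5, 1.0, 1.5, 2.0]:
            aucs = []
            for seed in range(3):
                fm = small_cohort(n_per_class={"CIR": 25, "CLD": 25}, n_compounds=60,
                                  effect=effect, seed=200 + seed).features \
                    .restrict_classes(["CIR", "CLD"]).log_abundances()
                aucs.append(vd.run_holdout(fm, vd.make_splits(fm, conf, seed=4),
                                           conf).auc)
            medians.append(np.median(aucs))
        assert all(b >= a - 0.02 for a, b in zip(medians, medians[1:]))
        assert medians[-1] > medians[0]

    def test_report_is_deterministic(self, paper_shaped):
        conf = HoldoutConfig(n_repeats=5)
        r1 = vd.run_holdout(paper_shaped, vd.make_splits(paper_shaped, conf, 11), conf)
        r2 = vd.run_holdout(paper_shaped, vd.make_splits(paper_shaped, conf, 11), conf)
        assert r1.auc == r2.auc
        pd.testing.assert_frame_equal(r1.per_repeat, r2.per_repeat)
        assert r1.val2_accuracy == r2.val2_accuracy

    def test_val2_accuracy_high_on_planted_cohort(self, paper_shaped):
        conf = HoldoutConfig(n_repeats=5)
        rep = vd.run_holdout(paper_shaped, vd.make_splits(paper_shaped, conf, 2), conf)
        assert rep.val2_accuracy > 0.8
        assert rep.auc_ci[0] <= rep.auc_ci[1]


class TestPermutation:
    def test_boundary_single_permutation(self):
        fm = null_cohort(n_per_class={"CIR": 20, "CLD": 20},
                         n_compounds=20, seed=1).features \
            .restrict_classes(["CIR", "CLD"]).log_abundances()
        conf = HoldoutConfig(n_train_per_class=12, n_val_per_class=5, n_repeats=2)
        out = vd.permutation_test(fm, conf, n_perm=1, seed=0, observed=0.0)
        assert out["p_value"] == 1.0       # null >= observed with a single draw

    def test_floor_when_observed_beats_every_permutation(self):
        fm = small_cohort(n_per_class={"CIR": 25, "CLD": 25}, n_compounds=40,
                          effect=4.0, seed=2).features \
            .restrict_classes(["CIR", "CLD"]).log_abundances()
        conf = HoldoutConfig(n_train_per_class=15, n_val_per_class=7, n_repeats=5)
        out = vd.permutation_test(fm, conf, n_perm=50, seed=0)
        assert out["observed"] == 1.0
        assert out["p_value"] == 1 / 50
        assert len(out["null"]) == 50

    def test_statistic_config_error_rate(self):
        fm = small_cohort(n_per_class={"CIR": 20, "CLD": 20}, n_compounds=30,
                          effect=3.0, seed=3).features \
            .restrict_classes(["CIR", "CLD"]).log_abundances()
        conf = HoldoutConfig(n_train_per_class=12, n_val_per_class=5,
                             n_repeats=3, statistic="error")
        out = vd.permutation_test(fm, conf, n_perm=20, seed=1, observed=0.0)
        assert 0 < out["p_value"] <= 1
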