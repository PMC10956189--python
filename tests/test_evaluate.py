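"""Top-k recall, averaged curves, fold plans, permutation importance."""

import numpy as np
import pandas as pd
import pytest

from varprio.evaluate import (
    FoldPlan,
    PatientOutcome,
    averaged_curves,
    cohort_topk,
    make_folds,
    mda_importance,
    topk_recall,
)
from varprio.models import RankedVariant, VariantPrioritizer, train_model


def outcome(pid, ranked_ids, causative):
    ranked = tuple(
        RankedVariant(v, score=1.0 - 0.01 * i, rank=i + 1, best_disease="D")
        for i, v in enumerate(ranked_ids)
    )
    return PatientOutcome(pid, ranked, frozenset(causative))


class TestTopkRecall:
    def test_one_of_two_causatives_in_top5(self):
        """Revised denominator: 1 hit, 1 miss at k=5 gives exactly 0.5."""
        o = outcome("p", [f"v{i}" for i in range(10)], {"v2", "v9"})
        assert topk_recall(o, 5) == 0.5

    def test_perfect_ranking_reaches_one_at_every_k(self):
        o = outcome("p", ["a", "b", "c", "d"], {"a", "b", "c"})
        for k in (1, 2, 3, 4, 10):
            assert topk_recall(o, k) == 1.0

    def test_more_causatives_than_cutoff(self):
        # 3 causatives at ranks 1-3, k=2: 2 hits / min(3, 2) = 1.0
        o = outcome("p", ["a", "b", "c", "d"], {"a", "b", "c"})
        assert topk_recall(o, 2) == 1.0

    def test_nondecreasing_in_k_where_metric_is_ordered(self):
        """Monotone in k for single-causative patients, and for k >= the
        causative count in general.  (Below that, the revised denominator
        min(c, k) grows with k and can shrink the ratio: a patient with
        causatives at ranks 1 and 100 scores 1.0 at k=1 but 0.5 at k=2.)"""
        rng = np.random.default_rng(0)
        for _ in range(20):
            ids = [f"v{i}" for i in range(30)]
            c = int(rng.integers(1, 4))
            caus = set(rng.choice(ids, size=c, replace=False))
            o = outcome("p", ids, caus)
            recalls = {k: topk_recall(o, k) for k in range(1, 31)}
            assert all(recalls[k] <= recalls[k + 1] for k in range(max(c, 1), 30))
            if c == 1:
                assert all(recalls[k] <= recalls[k + 1] for k in range(1, 30))
            assert recalls[30] == 1.0  # k = all candidates, none dropped
        # documented counterexample below k = c
        o = outcome("p", [f"v{i}" for i in range(10)], {"v0", "v9"})
        assert topk_recall(o, 1) == 1.0 and topk_recall(o, 2) == 0.5

    def test_unranked_causative_counts_as_miss(self, caplog):
        o = outcome("p", ["a", "b"], {"a", "zz"})
        assert "zz" in caplog.text
        assert topk_recall(o, 2) == 0.5

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            topk_recall(outcome("p", ["a"], {"a"}), 0)


class TestCohortTopk:
    def test_mean_of_per_patient_recalls(self):
        o1 = outcome("p1", ["a", "b"], {"a"})          # recall 1.0 at k=1
        o2 = outcome("p2", ["a", "b"], {"a", "b"})     # 1/min(2,1) = 1 hit -> 1.0? no:
        # at k=5 p2 has both in top 5 -> 1.0; construct 0.5 case instead
        o2 = outcome("p2", [f"v{i}" for i in range(10)], {"v0", "v9"})
        assert cohort_topk([o1, o2], 5) == pytest.approx((1.0 + 0.5) / 2)

    def test_all_perfect(self):
        outs = [outcome(f"p{i}", ["a", "b"], {"a"}) for i in range(5)]
        assert cohort_topk(outs, 1) == 1.0

    def test_ten_patient_hand_tally(self):
        """Causative rank r_i per patient; top-3 recall = mean(r_i <= 3)."""
        ranks = [1, 2, 3, 4, 1, 7, 2, 9, 3, 5]
        outs = []
        for i, r in enumerate(ranks):
            ids = [f"v{j}" for j in range(10)]
            outs.append(outcome(f"p{i}", ids, {ids[r - 1]}))
        hand = sum(1 for r in ranks if r <= 3) / 10  # = 0.6
        assert cohort_topk(outs, 3) == pytest.approx(hand)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            cohort_topk([], 1)


class TestAveragedCurves:
    def test_identical_folds_average_to_themselves(self):
        y = np.array([0, 0, 1, 1, 0, 1])
        s = np.array([0.1, 0.4, 0.35, 0.8, 0.2, 0.9])
        one = averaged_curves([s], [y])
        three = averaged_curves([s, s, s], [y, y, y])
        assert np.allclose(one["mean_tpr"], three["mean_tpr"])
        assert one["auroc"] == pytest.approx(three["auroc"])

    def test_perfect_classifier_auroc_one(self):
        y = np.array([0, 0, 1, 1])
        s = np.array([0.1, 0.2, 0.8, 0.9])
        res = averaged_curves([s, s], [y, y])
        assert res["auroc"] == pytest.approx(1.0, abs=1e-9)

    def test_two_fold_hand_interpolation(self):
        """Averaged TPR equals the hand-computed mean of interpolated folds."""
        y1, s1 = np.array([0, 1, 0, 1]), np.array([0.2, 0.9, 0.6, 0.8])
        y2, s2 = np.array([1, 0, 1, 0]), np.array([0.7, 0.1, 0.3, 0.5])
        from sklearn.metrics import roc_curve

        grid = np.linspace(0, 1, 1001)
        manual = []
        for s, y in [(s1, y1), (s2, y2)]:
            fpr, tpr, _ = roc_curve(y, s)
            manual.append(np.interp(grid, fpr, tpr))
        res = averaged_curves([s1, s2], [y1, y2], grid_size=1001)
        assert np.allclose(res["mean_tpr"], np.mean(manual, axis=0))

    def test_single_class_fold_skipped_with_warning(self):
        y1, s1 = np.array([0, 1]), np.array([0.1, 0.9])
        y2, s2 = np.array([1, 1]), np.array([0.5, 0.6])
        with pytest.warns(UserWarning, match="single class"):
            res = averaged_curves([s1, s2], [y1, y2])
        assert res["n_folds"] == 1


class TestMakeFolds:
    def test_random_scheme_deterministic_and_balanced(self):
        pats = [f"p{i}" for i in range(10)]
        plan1 = make_folds(pats, "random_patient", seed=42)
        plan2 = make_folds(pats, "random_patient", seed=42)
        assert plan1.assignments == plan2.assignments
        sizes = sorted(len(plan1.test_patients(f)) for f in range(5))
        assert sizes == [2, 2, 2, 2, 2]

    def test_date_split_separates_external_set(self):
        pats = ["p1", "p2", "p3", "p4"]
        dates = {"p1": "2021-10-01", "p2": "2022-08-31",
                 "p3": "2022-09-01", "p4": "2023-01-15"}
        plan = make_folds(pats, "date_split", seed=0, dates=dates)
        assert plan.external == {"p3", "p4"}
        assert set(plan.assignments) == {"p1", "p2"}

    def test_gene_based_keeps_shared_genes_together(self):
        pats = [f"p{i}" for i in range(8)]
        genes = {
            "p0": frozenset({"G1"}), "p1": frozenset({"G1", "G2"}),
            "p2": frozenset({"G2"}), "p3": frozenset({"G3"}),
            "p4": frozenset({"G4"}), "p5": frozenset({"G5"}),
            "p6": frozenset({"G6"}), "p7": frozenset({"G7"}),
        }
        plan = make_folds(pats, "gene_based", seed=0, genes=genes)
        # p0, p1, p2 share genes transitively: one fold
        assert plan.assignments["p0"] == plan.assignments["p1"] == plan.assignments["p2"]
        by_fold = {}
        for p, f in plan.assignments.items():
            for g in genes[p]:
                assert by_fold.setdefault(g, f) == f  # no gene spans folds

    def test_gene_based_giant_component_warns(self):
        pats = [f"p{i}" for i in range(5)]
        genes = {p: frozenset({"G1"}) for p in pats}
        with pytest.warns(UserWarning, match="component"):
            make_folds(pats, "gene_based", seed=0, genes=genes)

    def test_leakage_removed_is_exact_intersection(self):
        """Fixture shares 3 variant ids between train and test patients."""
        pats = [f"p{i}" for i in range(5)]
        vids = {
            "p0": frozenset({"s1", "s2", "a0"}),
            "p1": frozenset({"s1", "a1"}),
            "p2": frozenset({"s2", "a2"}),
            "p3": frozenset({"s3", "a3"}),
            "p4": frozenset({"s3", "a4"}),
        }
        plan = make_folds(pats, "random_patient", n_folds=5, seed=1,
                          variant_ids=vids)
        for fold in range(5):
            test_vars = set().union(*(vids[p] for p in plan.test_patients(fold)))
            train_vars = set().union(*(vids[p] for p in plan.train_patients(fold)))
            assert plan.leakage_removed[fold] == frozenset(test_vars & train_vars)
            # after exclusion no shared id remains in training
            assert not (train_vars - plan.leakage_removed[fold]) & test_vars


class TestMdaImportance:
    def _fit(self, seed=0):
        rng = np.random.default_rng(seed)
        n = 500
        y = (rng.random(n) < 0.4).astype(int)
        df = pd.DataFrame(
            {
                "bayes": np.clip(0.2 + 0.6 * y + rng.normal(0, 0.05, n), 0, 1),
                "symsim": rng.normal(2, 1, n),            # pure noise
                "insilico": np.full(n, 0.206),            # constant column
                "vaf": rng.random(n),
                "qual": rng.uniform(0, 150, n),
                "inh_mismatch": rng.integers(0, 2, n),
                "label": y,
            }
        )
        return train_model("rf_all", df, seed=0), df

    def test_constant_column_importance_exactly_zero(self):
        model, df = self._fit()
        mda = mda_importance(model, df, df["label"], n_repeats=5, seed=0)
        assert mda["insilico"] == 0.0

    def test_noise_feature_near_zero_and_planted_dominant(self):
        model, df = self._fit()
        mda = mda_importance(model, df, df["label"], n_repeats=50, seed=0)
        assert abs(mda["symsim"]) <= 0.02
        assert mda["bayes"] == max(mda.values())
        assert mda["bayes"] > 0.1
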