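"""Baseline multiplicative score, trained models, per-patient ranking."""

import math

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from varprio.features import FEATURE_NAMES
from varprio.models import (
    MODEL_SPECS,
    VariantPrioritizer,
    baseline_score,
    score_and_rank,
    sigmoid,
    train_model,
)


def make_table(rng, n=400, seed_signal=2.0):
    """Labeled pair table with a planted signal in bayes and symsim."""
    y = rng.random(n) < 0.25
    df = pd.DataFrame(
        {
            "patient_id": "P0",
            "variant_id": [f"v{i}" for i in range(n)],
            "disease_id": "D0",
            "bayes": np.clip(rng.normal(0.3 + 0.5 * y, 0.2), 0.001, 0.999),
            "symsim": np.clip(rng.normal(1.0 + seed_signal * y, 0.8), 0, None),
            "insilico": rng.random(n),
            "vaf": rng.random(n),
            "qual": rng.uniform(0, 150, n),
            "inh_mismatch": rng.integers(0, 2, n),
            "label": y.astype(int),
        }
    )
    return df


class TestSigmoidAndBaseline:
    def test_sigmoid_values(self):
        assert sigmoid(0) == 0.5
        assert sigmoid(2) == pytest.approx(0.880797, abs=1e-6)
        for x in (-3.5, -1.0, 0.7, 4.2):
            assert sigmoid(x) + sigmoid(-x) == pytest.approx(1.0)

    def test_baseline_zero_bayes_kills_score(self):
        assert baseline_score(0.0, 5.0, 1.0) == 0.0

    def test_baseline_forced_sigmoids(self):
        # symsim = 2 and insilico = 0 pin both sigmoids at 0.5
        assert baseline_score(1.0, 2.0, 0.0) == pytest.approx(0.25)

    def test_baseline_worked_example(self):
        got = baseline_score(0.9, 4.0, 0.8)
        assert got == pytest.approx(0.9 * sigmoid(2.0) * sigmoid(0.8))
        assert got == pytest.approx(0.9 * 0.880797 * 0.689974, abs=1e-5)  # 0.5470

    def test_baseline_strictly_increasing_in_each_input(self):
        base = baseline_score(0.5, 2.0, 0.5)
        assert baseline_score(0.6, 2.0, 0.5) > base
        assert baseline_score(0.5, 2.5, 0.5) > base
        assert baseline_score(0.5, 2.0, 0.6) > base

    def test_baseline_bounded_below_one(self):
        rng = np.random.default_rng(0)
        b, s, i = rng.random(100), rng.uniform(0, 10, 100), rng.random(100)
        scores = baseline_score(b, s, i)
        assert np.all((scores >= 0) & (scores < 1))


class TestModelRegistry:
    def test_table4_feature_subsets(self):
        core = ("bayes", "symsim", "insilico")
        assert MODEL_SPECS["baseline"].features == core
        assert MODEL_SPECS["lr"].features == core
        assert MODEL_SPECS["rf_qc"].features == core + ("vaf", "qual")
        assert MODEL_SPECS["lr_all"].features == FEATURE_NAMES
        assert MODEL_SPECS["rf_all"].features == FEATURE_NAMES
        algos = {MODEL_SPECS[m].algorithm for m in ("lr", "lr_qc", "lr_all")}
        assert algos == {"logistic_regression"}

    def test_sklearn_protocol(self):
        est = VariantPrioritizer(model="lr", random_state=7)
        assert est.get_params() == {"model": "lr", "random_state": 7}
        cloned = clone(est).set_params(model="rf")
        assert cloned.get_params()["model"] == "rf"

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError, match="unknown model"):
            VariantPrioritizer(model="xgboost").fit(make_table(np.random.default_rng(0)))


class TestTraining:
    def test_separable_table_ranks_perfectly(self):
        rng = np.random.default_rng(1)
        df = make_table(rng)
        df["bayes"] = np.where(df["label"] == 1, 0.95, 0.05)  # force separability
        est = train_model("lr", df, seed=0)
        auc = roc_auc_score(df["label"], est.score_pairs(df))
        assert auc == 1.0

    def test_same_seed_reproduces_scores(self):
        rng = np.random.default_rng(2)
        df = make_table(rng)
        s1 = train_model("rf", df, seed=5).score_pairs(df)
        s2 = train_model("rf", df, seed=5).score_pairs(df)
        assert np.array_equal(s1, s2)

    def test_single_class_table_rejected(self):
        rng = np.random.default_rng(3)
        df = make_table(rng)
        df["label"] = 0
        with pytest.raises(ValueError, match="single class"):
            train_model("lr", df, seed=0)

    def test_baseline_requires_no_labels(self):
        rng = np.random.default_rng(4)
        df = make_table(rng).drop(columns="label")
        est = VariantPrioritizer(model="baseline").fit(df)
        scores = est.score_pairs(df)
        assert np.allclose(
            scores, baseline_score(df["bayes"], df["symsim"], df["insilico"])
        )

    def test_balanced_weights_invariant_to_duplicating_negatives(self):
        """Inverse-frequency class weighting cancels negative-row duplication.

        With near-zero regularization the weighted log-loss of the duplicated
        table is a positive multiple of the original, so the optimum is
        unchanged.
        """
        rng = np.random.default_rng(5)
        df = make_table(rng, n=300)
        X = df[["bayes", "symsim", "insilico"]].to_numpy()
        y = df["label"].to_numpy()
        dup_X = np.vstack([X, X[y == 0]])
        dup_y = np.concatenate([y, y[y == 0]])
        kw = dict(class_weight="balanced", C=1e6, max_iter=5000, tol=1e-12)
        a = LogisticRegression(**kw).fit(X, y)
        b = LogisticRegression(**kw).fit(dup_X, dup_y)
        assert np.allclose(a.coef_, b.coef_, atol=1e-6)
        assert np.allclose(a.intercept_, b.intercept_, atol=1e-6)

    def test_paper_hyperparameters_applied(self):
        rng = np.random.default_rng(6)
        df = make_table(rng)
        lr = train_model("lr_all", df, seed=0).estimator_
        assert lr.class_weight == "balanced" and lr.max_iter == 500
        rf = train_model("rf_qc", df, seed=0).estimator_
        assert rf.n_estimators == 500 and rf.class_weight == "balanced"


class TestScoreAndRank:
    def _pairs(self, rows):
        return pd.DataFrame(
            rows,
            columns=["variant_id", "disease_id", "bayes", "symsim", "insilico",
                     "vaf", "qual", "inh_mismatch"],
        )

    def test_max_over_diseases_with_argmax(self):
        pairs = self._pairs(
            [
                ("v1", "D1", 0.2, 2.0, 0.5, 0.5, 80, 0),
                ("v1", "D2", 0.9, 2.0, 0.5, 0.5, 80, 0),
                ("v1", "D3", 0.4, 2.0, 0.5, 0.5, 80, 0),
            ]
        )
        model = VariantPrioritizer(model="baseline").fit(pairs)
        (rv,) = score_and_rank(model, pairs)
        assert rv.best_disease == "D2"
        assert rv.score == pytest.approx(float(baseline_score(0.9, 2.0, 0.5)))

    def test_rank_order_and_consistency(self):
        pairs = self._pairs(
            [
                ("v1", "D1", 0.9, 4.0, 0.9, 0.5, 80, 0),
                ("v2", "D1", 0.1, 1.0, 0.1, 0.5, 80, 0),
                ("v3", "D1", 0.5, 2.0, 0.5, 0.5, 80, 0),
            ]
        )
        model = VariantPrioritizer(model="baseline").fit(pairs)
        ranked = score_and_rank(model, pairs)
        assert [r.variant_id for r in ranked] == ["v1", "v3", "v2"]
        assert [r.rank for r in ranked] == [1, 2, 3]
        assert all(
            ranked[i].score >= ranked[i + 1].score for i in range(len(ranked) - 1)
        )

    def test_ties_break_by_ascending_variant_id(self):
        pairs = self._pairs(
            [
                ("vc", "D1", 0.0, 0.0, 0.0, 0.5, 80, 0),
                ("va", "D1", 0.0, 0.0, 0.0, 0.5, 80, 0),
                ("vb", "D1", 0.0, 0.0, 0.0, 0.5, 80, 0),
            ]
        )
        model = VariantPrioritizer(model="baseline").fit(pairs)
        ranked = score_and_rank(model, pairs)
        assert [r.variant_id for r in ranked] == ["va", "vb", "vc"]

    def test_empty_pairs_give_empty_ranking(self):
        model = VariantPrioritizer(model="baseline").fit(self._pairs(
            [("v", "D", 0.5, 1.0, 0.5, 0.5, 80, 0)]))
        assert score_and_rank(model, self._pairs([]).iloc[:0]) == []


def test_model_roundtrip_bit_identical_scores(tmp_path):
    rng = np.random.default_rng(8)
    df = make_table(rng)
    est = train_model("rf_all", df, seed=3)
    est.save(tmp_path / "m.joblib")
    back = VariantPrioritizer.load(tmp_path / "m.joblib")
    assert np.array_equal(est.score_pairs(df), back.score_pairs(df))
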