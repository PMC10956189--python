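"""Prioritization models: rule-based baseline and trained classifiers.

Seven model variants are registered, differing in algorithm and feature
subset:

    ========  ====================  =====================================
    name      algorithm             features
    ========  ====================  =====================================
    baseline  multiplication        bayes, symsim, insilico
    lr        logistic regression   bayes, symsim, insilico
    lr_qc     logistic regression   + vaf, qual
    lr_all    logistic regression   + inh_mismatch
    rf        random forest         bayes, symsim, insilico
    rf_qc     random forest         + vaf, qual
    rf_all    random forest         + inh_mismatch
    ========  ====================  =====================================

The baseline is an untrained multiplicative score,

    score = bayes * sigmoid(symsim - 2) * sigmoid(insilico),

where the shift of 2 soft-gates dissimilar diseases.  Trained models use
scikit-learn's LogisticRegression (class_weight="balanced", max_iter=500)
and RandomForestClassifier (n_estimators=500, class_weight="balanced"),
other options at their defaults.

Per-variant scores are the maximum over the variant's candidate diseases;
variants are ranked by descending score with ties broken by ascending
variant id.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.utils.validation import check_is_fitted

from .features import FEATURE_NAMES

__all__ = [
    "ModelSpec",
    "MODEL_SPECS",
    "RankedVariant",
    "VariantPrioritizer",
    "sigmoid",
    "baseline_score",
    "train_model",
    "score_and_rank",
]

_CORE = ("bayes", "symsim", "insilico")
_QC = _CORE + ("vaf", "qual")
_ALL = _QC + ("inh_mismatch",)


@dataclass(frozen=True)
class ModelSpec:
    name: str
    algorithm: str  # multiplication | logistic_regression | random_forest
    features: tuple[str, ...]


MODEL_SPECS: dict[str, ModelSpec] = {
    "baseline": ModelSpec("baseline", "multiplication", _CORE),
    "lr": ModelSpec("lr", "logistic_regression", _CORE),
    "lr_qc": ModelSpec("lr_qc", "logistic_regression", _QC),
    "lr_all": ModelSpec("lr_all", "logistic_regression", _ALL),
    "rf": ModelSpec("rf", "random_forest", _CORE),
    "rf_qc": ModelSpec("rf_qc", "random_forest", _QC),
    "rf_all": ModelSpec("rf_all", "random_forest", _ALL),
}


def sigmoid(x):
    """Standard logistic function 1 / (1 + exp(-x))."""
    return expit(x)


def baseline_score(bayes, symsim, insilico):
    """Untrained multiplicative score: bayes * σ(symsim - 2) * σ(insilico)."""
    return np.asarray(bayes) * sigmoid(np.asarray(symsim) - 2.0) * sigmoid(
        np.asarray(insilico)
    )


@dataclass(frozen=True)
class RankedVariant:
    """One variant in a patient's ranking."""

    variant_id: str
    score: float
    rank: int
    best_disease: str


class VariantPrioritizer(ClassifierMixin, BaseEstimator):
    """Scikit-learn estimator scoring (variant, disease) feature rows.

    Parameters
    ----------
    model : str
        One of the registered model names (see MODEL_SPECS).
    random_state : int
        Seed for the stochastic learners; mandatory for reproducible
        rankings.

    Attributes
    ----------
    estimator_ : fitted scikit-learn classifier, or None for the baseline.
    feature_names_ : tuple of feature columns the model consumes.
    classes_ : array([0, 1]).
    """

    def __init__(self, model: str = "rf_all", random_state: int = 0):
        self.model = model
        self.random_state = random_state

    @property
    def spec(self) -> ModelSpec:
        try:
            return MODEL_SPECS[self.model]
        except KeyError:
            raise ValueError(
                f"unknown model {self.model!r}; choose from {sorted(MODEL_SPECS)}"
            ) from None

    def _select(self, X) -> np.ndarray:
        names = self.spec.features
        if isinstance(X, pd.DataFrame):
            missing = [c for c in names if c not in X.columns]
            if missing:
                raise ValueError(f"feature table lacks columns {missing}")
            return X.loc[:, list(names)].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] not in (len(names), len(FEATURE_NAMES)):
            raise ValueError(
                f"expected {len(names)} or {len(FEATURE_NAMES)} feature "
                f"columns in canonical order, got shape {X.shape}"
            )
        if X.shape[1] == len(FEATURE_NAMES):
            idx = [FEATURE_NAMES.index(n) for n in names]
            X = X[:, idx]
        return X

    def fit(self, X, y=None):
        """Fit the underlying classifier (no-op for the baseline model)."""
        spec = self.spec
        Xs = self._select(X)
        if not np.all(np.isfinite(Xs)):
            raise ValueError("feature matrix contains non-finite values")
        self.feature_names_ = spec.features
        self.classes_ = np.array([0, 1])
        if spec.algorithm == "multiplication":
            self.estimator_ = None
            return self
        if y is None:
            raise ValueError(f"model {spec.name!r} requires labels to train")
        y = np.asarray(y).astype(int)
        if len(np.unique(y)) < 2:
            raise ValueError("training table contains a single class")
        if spec.algorithm == "logistic_regression":
            est = LogisticRegression(
                class_weight="balanced",
                max_iter=500,
                random_state=self.random_state,
            )
        elif spec.algorithm == "random_forest":
            est = RandomForestClassifier(
                n_estimators=500,
                class_weight="balanced",
                random_state=self.random_state,
                n_jobs=1,
            )
        else:  # pragma: no cover - registry is closed
            raise ValueError(f"unknown algorithm {spec.algorithm!r}")
        self.estimator_ = est.fit(Xs, y)
        return self

    def score_pairs(self, X) -> np.ndarray:
        """Probability-like score in [0, 1) for each (variant, disease) row."""
        check_is_fitted(self, "feature_names_")
        Xs = self._select(X)
        if self.estimator_ is None:
            return baseline_score(Xs[:, 0], Xs[:, 1], Xs[:, 2])
        proba = self.estimator_.predict_proba(Xs)
        return proba[:, list(self.estimator_.classes_).index(1)]

    def predict_proba(self, X) -> np.ndarray:
        s = self.score_pairs(X)
        return np.column_stack([1.0 - s, s])

    def predict(self, X) -> np.ndarray:
        return (self.score_pairs(X) >= 0.5).astype(int)

    def save(self, path) -> None:
        check_is_fitted(self, "feature_names_")
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "VariantPrioritizer":
        obj = joblib.load(path)
        if not isinstance(obj, VariantPrioritizer):
            raise TypeError(f"{path} does not contain a VariantPrioritizer")
        return obj


def train_model(
    spec: ModelSpec | str,
    table: pd.DataFrame,
    seed: int = 0,
    label_col: str = "label",
) -> VariantPrioritizer:
    """Fit a registered model on a labeled pair-level feature table."""
    name = spec if isinstance(spec, str) else spec.name
    est = VariantPrioritizer(model=name, random_state=seed)
    return est.fit(table, table[label_col].to_numpy())


def score_and_rank(
    model: VariantPrioritizer,
    pairs: pd.DataFrame,
) -> list[RankedVariant]:
    """Rank one patient's candidate variants.

    ``pairs`` holds one row per (variant, disease) with columns
    ``variant_id``, ``disease_id`` and the feature columns.  The per-variant
    score is the maximum over its candidate diseases; ties in disease score
    resolve to the lexicographically smallest disease id, and ties in
    variant score to ascending variant id.
    """
    if pairs.empty:
        return []
    df = pairs.copy()
    df["_score"] = model.score_pairs(df)
    per_variant = (
        df.sort_values(["_score", "disease_id"], ascending=[False, True])
        .groupby("variant_id", sort=False)
        .first()
        .reset_index()
    )
    per_variant = per_variant.sort_values(
        ["_score", "variant_id"], ascending=[False, True]
    ).reset_index(drop=True)
    return [
        RankedVariant(variant_id=vid, score=float(s), rank=i + 1, best_disease=did)
        for i, (vid, s, did) in enumerate(
            zip(per_variant["variant_id"], per_variant["_score"], per_variant["disease_id"])
        )
    ]
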