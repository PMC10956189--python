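"""Ranking evaluation: revised top-k recall, fold-averaged curves,
fold construction with variant-leakage exclusion, and permutation
importance (mean decrease in accuracy).

Top-k recall uses a revised denominator so that patients with more
causative variants than the cutoff can still reach 1.0:

    recall_k = |causative variants ranked <= k| / min(#causative, k)

and is averaged unweighted across patients.  Fold-averaged ROC/PR curves
interpolate each fold's curve onto a common grid before averaging, so
folds with different score distributions remain comparable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import precision_recall_curve, roc_curve

from .models import RankedVariant

__all__ = [
    "PatientOutcome",
    "FoldPlan",
    "topk_recall",
    "cohort_topk",
    "averaged_curves",
    "make_folds",
    "mda_importance",
]

logger = logging.getLogger(__name__)

DEFAULT_K_GRID = (1, 3, 5, 10, 20, 30, 100)


@dataclass(frozen=True)
class PatientOutcome:
    """One patient's ranked candidates plus the confirmed causative ids."""

    patient_id: str
    ranked: tuple[RankedVariant, ...]
    causative_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.causative_ids:
            raise ValueError("causative_ids must be non-empty")
        ranked_ids = {r.variant_id for r in self.ranked}
        missing = self.causative_ids - ranked_ids
        if missing:
            # counted as misses at infinite rank (e.g. removed by filters)
            logger.warning(
                "patient %s: causative variant(s) %s absent from ranking; "
                "counted as misses",
                self.patient_id,
                sorted(missing),
            )


def topk_recall(outcome: PatientOutcome, k: int) -> float:
    """Revised-denominator top-k recall for one patient."""
    if k < 1:
        raise ValueError("k must be a positive integer")
    hits = sum(
        1 for r in outcome.ranked if r.rank <= k and r.variant_id in outcome.causative_ids
    )
    return hits / min(len(outcome.causative_ids), k)


def cohort_topk(outcomes: Sequence[PatientOutcome], k: int) -> float:
    """Unweighted mean of per-patient top-k recall."""
    if not outcomes:
        raise ValueError("cohort is empty")
    return float(np.mean([topk_recall(o, k) for o in outcomes]))


def averaged_curves(
    fold_scores: Sequence[np.ndarray],
    fold_labels: Sequence[np.ndarray],
    grid_size: int = 1001,
) -> dict:
    """Average per-fold ROC and PR curves on a common interpolation grid.

    TPR is interpolated onto a uniform FPR grid and precision onto a uniform
    recall grid; areas use the trapezoid rule.  Folds containing a single
    class are skipped with a warning.
    """
    if len(fold_scores) != len(fold_labels):
        raise ValueError("fold_scores and fold_labels differ in length")
    grid = np.linspace(0.0, 1.0, grid_size)
    tprs, precs, aurocs, auprcs = [], [], [], []
    for i, (s, y) in enumerate(zip(fold_scores, fold_labels)):
        y = np.asarray(y).astype(int)
        if len(np.unique(y)) < 2:
            warnings.warn(f"fold {i} has a single class; skipped", stacklevel=2)
            continue
        fpr, tpr, _ = roc_curve(y, s)
        tprs.append(np.interp(grid, fpr, tpr))
        prec, rec, _ = precision_recall_curve(y, s)
        # precision_recall_curve returns recall descending; flip for interp
        precs.append(np.interp(grid, rec[::-1], prec[::-1]))
    if not tprs:
        raise ValueError("no fold with both classes")
    mean_tpr = np.mean(tprs, axis=0)
    mean_prec = np.mean(precs, axis=0)
    return {
        "fpr_grid": grid,
        "mean_tpr": mean_tpr,
        "recall_grid": grid,
        "mean_precision": mean_prec,
        "auroc": float(np.trapezoid(mean_tpr, grid)),
        "auprc": float(np.trapezoid(mean_prec, grid)),
        "n_folds": len(tprs),
        "grid_size": grid_size,
    }


@dataclass
class FoldPlan:
    """Patient-to-fold assignment plus the leakage-excluded variant ids."""

    scheme: str
    assignments: dict[str, int]
    leakage_removed: dict[int, frozenset[str]] = field(default_factory=dict)
    external: frozenset[str] = frozenset()

    def test_patients(self, fold: int) -> list[str]:
        return sorted(p for p, f in self.assignments.items() if f == fold)

    def train_patients(self, fold: int) -> list[str]:
        return sorted(p for p, f in self.assignments.items() if f != fold)


def make_folds(
    patients: Sequence[str],
    scheme: str = "random_patient",
    n_folds: int = 5,
    seed: int = 0,
    variant_ids: Mapping[str, frozenset[str]] | None = None,
    dates: Mapping[str, str] | None = None,
    genes: Mapping[str, frozenset[str]] | None = None,
    split_date: str = "2022-09-01",
) -> FoldPlan:
    """Build a cross-validation plan under one of three schemes.

    random_patient
        Seeded shuffle into ``n_folds`` near-equal folds.
    date_split
        Patients analysed on/after ``split_date`` form an external
        validation set; the rest are folded as in random_patient.
    gene_based
        Connected components of the patient-gene bipartite graph are packed
        greedily (largest first) into folds so no causal gene spans folds.

    When ``variant_ids`` maps each patient to its candidate-variant ids,
    variants shared between a fold's training patients and its test patients
    are recorded in ``leakage_removed[fold]``; training tables must drop
    those rows.
    """
    patients = sorted(set(patients))
    rng = np.random.default_rng(seed)
    plan = FoldPlan(scheme=scheme, assignments={})
    if scheme == "date_split":
        if dates is None:
            raise ValueError("date_split scheme requires per-patient dates")
        external = frozenset(p for p in patients if dates[p] >= split_date)
        plan.external = external
        pool = [p for p in patients if p not in external]
    elif scheme in ("random_patient", "gene_based"):
        pool = list(patients)
    else:
        raise ValueError(f"unknown fold scheme: {scheme!r}")

    if scheme == "gene_based":
        if genes is None:
            raise ValueError("gene_based scheme requires per-patient causal genes")
        # union-find over patients joined by shared causal genes
        parent = {p: p for p in pool}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        by_gene: dict[str, list[str]] = {}
        for p in pool:
            for g in genes[p]:
                by_gene.setdefault(g, []).append(p)
        for members in by_gene.values():
            for other in members[1:]:
                ra, rb = find(members[0]), find(other)
                if ra != rb:
                    parent[rb] = ra
        components: dict[str, list[str]] = {}
        for p in pool:
            components.setdefault(find(p), []).append(p)
        comps = sorted(components.values(), key=lambda c: (-len(c), c[0]))
        if comps and len(comps[0]) > 0.2 * len(pool):
            warnings.warn(
                f"largest patient-gene component holds {len(comps[0])} of "
                f"{len(pool)} patients; fold balance will be "
                f"{[len(c) for c in comps[:n_folds]]}-skewed",
                stacklevel=2,
            )
        sizes = [0] * n_folds
        for comp in comps:
            tgt = int(np.argmin(sizes))
            for p in comp:
                plan.assignments[p] = tgt
            sizes[tgt] += len(comp)
    else:
        order = list(rng.permutation(pool))
        for i, p in enumerate(order):
            plan.assignments[p] = i % n_folds

    if variant_ids is not None:
        for fold in range(n_folds):
            test_vars: set[str] = set()
            for p in plan.test_patients(fold):
                test_vars |= variant_ids[p]
            if scheme == "date_split":
                for p in plan.external:
                    test_vars |= variant_ids[p]
            train_vars: set[str] = set()
            for p in plan.train_patients(fold):
                train_vars |= variant_ids[p]
            plan.leakage_removed[fold] = frozenset(train_vars & test_vars)
    return plan


def mda_importance(
    model,
    X: pd.DataFrame,
    y,
    n_repeats: int = 10,
    seed: int = 0,
    metric: str = "accuracy",
) -> dict[str, float]:
    """Permutation importance: mean decrease in accuracy per feature.

    Each feature column is shuffled in place (others untouched) and the
    drop in classification accuracy (probability threshold 0.5), or AUROC
    with ``metric="auroc"``, is averaged over ``n_repeats`` seeded shuffles.
    """
    from sklearn.metrics import accuracy_score, roc_auc_score

    y = np.asarray(y).astype(int)

    def score(frame) -> float:
        if metric == "accuracy":
            return accuracy_score(y, model.predict(frame))
        if metric == "auroc":
            return roc_auc_score(y, model.score_pairs(frame))
        raise ValueError(f"unknown metric {metric!r}")

    rng = np.random.default_rng(seed)
    base = score(X)
    out: dict[str, float] = {}
    for col in model.feature_names_:
        drops = []
        for _ in range(n_repeats):
            perm = X.copy()
            perm[col] = rng.permutation(perm[col].to_numpy())
            drops.append(base - score(perm))
        out[col] = float(np.mean(drops))
    return out
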