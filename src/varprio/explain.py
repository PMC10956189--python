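"""Per-prediction additive feature attribution (Shapley values).

With only six model features, exact Shapley values are computed by full
coalition enumeration rather than sampling.  The value of a coalition S for
a row x is the interventional expectation

    v(S) = mean over background rows b of f(x restricted to S, b elsewhere)

and the attribution of feature i is the Shapley-weighted average of its
marginal contributions over all 2^(n-1) coalitions excluding i.  This
satisfies the efficiency axiom exactly: the attributions of a row sum to
f(x) - base_value, where base_value is the mean model output over the
background set.
"""

from __future__ import annotations

from itertools import combinations
from math import factorial

import numpy as np
import pandas as pd

__all__ = ["shap_attribution"]

_MAX_EXACT_FEATURES = 12


def _positive_scores(model, X: np.ndarray, columns) -> np.ndarray:
    frame = pd.DataFrame(X, columns=list(columns))
    if hasattr(model, "score_pairs"):
        return np.asarray(model.score_pairs(frame), dtype=float)
    if hasattr(model, "predict_proba"):
        return np.asarray(model.predict_proba(frame), dtype=float)[:, -1]
    raise TypeError(
        f"{type(model).__name__} exposes neither score_pairs nor "
        "predict_proba; use mda_importance for global importance instead"
    )


def shap_attribution(
    model,
    rows: pd.DataFrame,
    background: pd.DataFrame | None = None,
    max_background: int = 64,
    seed: int = 0,
):
    """Exact Shapley attributions for each row of a feature table.

    Parameters
    ----------
    model : fitted estimator with ``score_pairs`` or ``predict_proba``.
    rows : feature rows to explain (must contain the model's features).
    background : reference rows defining the interventional expectation;
        defaults to ``rows`` itself, subsampled to ``max_background``.
    Returns
    -------
    (attributions, base_value) : DataFrame of per-row per-feature signed
        contributions, and the scalar mean model output over the background.
    """
    names = list(getattr(model, "feature_names_", rows.columns))
    X = rows.loc[:, names].to_numpy(dtype=float)
    if background is None:
        background = rows
    B = background.loc[:, names].to_numpy(dtype=float)
    if len(B) > max_background:
        rng = np.random.default_rng(seed)
        B = B[rng.choice(len(B), size=max_background, replace=False)]
    n = len(names)
    if n > _MAX_EXACT_FEATURES:
        raise ValueError(
            f"exact enumeration supports at most {_MAX_EXACT_FEATURES} "
            f"features, got {n}"
        )
    n_rows, n_bg = len(X), len(B)

    # v[S] for every coalition S, for every explained row:
    # mean over background of f(x on S, b off S)
    coalitions = [frozenset(s) for k in range(n + 1) for s in combinations(range(n), k)]
    v: dict[frozenset, np.ndarray] = {}
    for S in coalitions:
        mask = np.zeros(n, dtype=bool)
        mask[list(S)] = True
        # hybrid matrix: tile background, overwrite coalition columns per row
        hybrid = np.repeat(B[None, :, :], n_rows, axis=0)  # (rows, bg, n)
        hybrid[:, :, mask] = X[:, None, mask]
        scores = _positive_scores(model, hybrid.reshape(-1, n), names)
        v[S] = scores.reshape(n_rows, n_bg).mean(axis=1)

    fact = [factorial(k) for k in range(n + 1)]
    phi = np.zeros((n_rows, n))
    for i in range(n):
        others = [j for j in range(n) if j != i]
        for k in range(n):
            w = fact[k] * fact[n - k - 1] / fact[n]
            for S in combinations(others, k):
                S = frozenset(S)
                phi[:, i] += w * (v[S | {i}] - v[S])

    base_value = float(v[frozenset()].mean())
    # efficiency check: sum phi = f(x) - v(empty) per row (exact up to fp error)
    attributions = pd.DataFrame(phi, columns=names, index=rows.index)
    return attributions, base_value
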