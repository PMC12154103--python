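"""Shapley-value feature importance for probability models.

Contributions are estimated with sampled-permutation Shapley values
under marginal-expectation imputation: absent features are filled in
from a background sample, so a feature's contribution is its average
marginal effect on the predicted probability over random orderings.
For four or fewer features the exact enumeration over all subsets is
used instead of sampling; on that path the per-row contributions
satisfy local accuracy,

    sum_j phi_j(x) = f(x) - E_b[f(b)],

to floating precision.  Importance is the mean absolute contribution
over the evaluated rows, one column per outcome in the report table.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

EXACT_MAX_FEATURES = 4


@dataclass
class ImportanceTable:
    """Mean |contribution| per feature (rows) and outcome (columns)."""

    scores: pd.DataFrame
    metadata: dict

    def ranking(self, outcome: str) -> list:
        return list(self.scores[outcome].sort_values(ascending=False).index)

    def to_csv(self, path) -> None:
        self.scores.rename_axis("Features").reset_index().to_csv(path, index=False)


def _as_predict(model):
    if hasattr(model, "predict_probability"):
        return model.predict_probability
    if hasattr(model, "predict_proba"):
        return lambda X: model.predict_proba(X)[:, 1]
    return model.predict


def shapley_contributions_exact(model, X, background) -> np.ndarray:
    """Exact Shapley contributions by subset enumeration (small p only)."""
    f = _as_predict(model)
    X = np.asarray(X, dtype=float)
    B = np.asarray(background, dtype=float)
    n, p = X.shape
    if p == 0:
        raise ValidationError("at least one feature is required")

    # value of coalition S for every row: mean_b f(x_S, b_{~S})
    def value(S: tuple) -> np.ndarray:
        vals = np.empty(n)
        mixed = np.repeat(B, n, axis=0)  # (n_b * n, p): background base
        xs = np.tile(X, (len(B), 1))
        for j in S:
            mixed[:, j] = xs[:, j]
        preds = f(mixed).reshape(len(B), n)
        vals[:] = preds.mean(axis=0)
        return vals

    cache = {(): value(())}
    for size in range(1, p + 1):
        for S in itertools.combinations(range(p), size):
            cache[S] = value(S)

    phi = np.zeros((n, p))
    for j in range(p):
        others = [k for k in range(p) if k != j]
        for size in range(0, p):
            w = math.factorial(size) * math.factorial(p - size - 1) / math.factorial(p)
            for S in itertools.combinations(others, size):
                Sj = tuple(sorted(S + (j,)))
                phi[:, j] += w * (cache[Sj] - cache[S])
    return phi


def shapley_contributions_sampled(
    model, X, background, n_permutations: int = 200, seed: int = 0
) -> np.ndarray:
    """Sampled-permutation Shapley contributions.

    Per permutation one background row is drawn per evaluated row and
    features are switched in one at a time in permutation order; each
    feature is credited with the resulting change in prediction.
    """
    f = _as_predict(model)
    X = np.asarray(X, dtype=float)
    B = np.asarray(background, dtype=float)
    n, p = X.shape
    if p == 0:
        raise ValidationError("at least one feature is required")
    rng = np.random.default_rng(seed)
    phi = np.zeros((n, p))
    for _ in range(n_permutations):
        order = rng.permutation(p)
        b = B[rng.integers(0, len(B), size=n)]
        # prefix k uses x for order[:k], background otherwise
        steps = np.empty((p + 1, n, p))
        current = b.copy()
        steps[0] = current
        for k, j in enumerate(order, start=1):
            current = current.copy()
            current[:, j] = X[:, j]
            steps[k] = current
        preds = f(steps.reshape(-1, p)).reshape(p + 1, n)
        for k, j in enumerate(order, start=1):
            phi[:, j] += preds[k] - preds[k - 1]
    return phi / n_permutations


def shapley_importance(
    model,
    data,
    background_size: int = 100,
    n_permutations: int = 200,
    seed: int = 0,
    feature_names=None,
    eval_rows: int | None = None,
) -> pd.Series:
    """Mean absolute Shapley contribution per feature.

    The background is drawn from ``data`` (clipped with a warning if
    ``background_size`` exceeds the available rows); ``eval_rows``
    optionally subsamples the rows whose contributions are averaged.
    Exact enumeration is used for up to four features.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2 or X.shape[1] == 0:
        raise ValidationError("data must be 2-D with at least one feature")
    if background_size < 1 or n_permutations < 1:
        raise ValidationError("background_size and n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    if background_size > len(X):
        warnings.warn(
            f"background_size {background_size} exceeds data rows {len(X)}; clipping",
            stacklevel=2,
        )
        background_size = len(X)
    bg = X[rng.choice(len(X), size=background_size, replace=False)]
    rows = X
    if eval_rows is not None and eval_rows < len(X):
        rows = X[rng.choice(len(X), size=eval_rows, replace=False)]

    if X.shape[1] <= EXACT_MAX_FEATURES:
        phi = shapley_contributions_exact(model, rows, bg)
    else:
        phi = shapley_contributions_sampled(
            model, rows, bg, n_permutations=n_permutations, seed=seed
        )
    scores = np.abs(phi).mean(axis=0)
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(X.shape[1])]
    return pd.Series(scores, index=list(feature_names), name="importance")


def importance_table(
    models: dict,
    data,
    feature_names,
    background_size: int = 100,
    n_permutations: int = 200,
    seed: int = 0,
    eval_rows: int | None = 200,
    column_names: dict | None = None,
) -> ImportanceTable:
    """Per-outcome importance columns from a dict outcome -> fitted model."""
    cols = {}
    for outcome, model in models.items():
        name = (column_names or {}).get(outcome, outcome)
        cols[name] = shapley_importance(
            model,
            data,
            background_size=background_size,
            n_permutations=n_permutations,
            seed=seed,
            feature_names=feature_names,
            eval_rows=eval_rows,
        )
    scores = pd.DataFrame(cols)
    meta = {
        "background_size": background_size,
        "n_permutations": n_permutations,
        "seed": seed,
        "eval_rows": eval_rows,
    }
    return ImportanceTable(scores=scores, metadata=meta)


def plot_importance(table: ImportanceTable, outcome: str, ax=None):
    """Simple horizontal bar chart of one outcome's importance ranking."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    s = table.scores[outcome].sort_values()
    ax.barh(s.index, s.to_numpy())
    ax.set_xlabel("mean |Shapley contribution|")
    ax.set_title(outcome)
    return ax
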