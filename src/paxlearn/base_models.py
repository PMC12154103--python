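"""Interchangeable probability-output base learners and the
three-metric model-selection harness.

Candidates are registered by string tag.  The tuned feed-forward
network configuration (three hidden layers of 256/128/64 rectified
units, batch size 64, learning rate 1e-3, 50 epochs) ships as the
default :class:`NetworkConfig`.  The scikit-learn multilayer perceptron
realises it; the dropout and batch-normalisation fields are recorded in
the configuration and the backend applies L2 weight decay as its
regulariser.

Model selection scores every candidate on a held-out set by accuracy,
rank-based AUC and positive-class F1 (threshold 0.5) and picks the
candidate with the best mean rank across the three metrics, ties broken
by AUC and then by candidate order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import GradientBoostingRegressor, RandomForestClassifier, \
    RandomForestRegressor, GradientBoostingClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LinearRegression, LogisticRegression
from sklearn.metrics import accuracy_score, f1_score, roc_auc_score
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier, MLPRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, SVR

from .errors import DegenerateDataError, MetricError, ValidationError

PROB_EPS = 1e-6

#: Fixed candidate order; also the final tie-break in model selection.
CANDIDATE_TAGS = (
    "logistic",
    "naive_bayes",
    "random_forest",
    "gradient_boosting",
    "svm",
    "mlp",
)


@dataclass(frozen=True)
class NetworkConfig:
    """Tuned feed-forward architecture for the neural candidate."""

    hidden: tuple = (256, 128, 64)
    activation: str = "relu"
    dropout: float = 0.5
    batch_norm: bool = True
    batch_size: int = 64
    learning_rate: float = 0.001
    epochs: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if any(h <= 0 for h in self.hidden):
            raise ValidationError("hidden layer sizes must be positive")
        if not 0 <= self.dropout < 1:
            raise ValidationError("dropout must lie in [0, 1)")
        if self.learning_rate <= 0:
            raise ValidationError("learning rate must be positive")


def _mlp_kwargs(config: NetworkConfig, seed: int) -> dict:
    return dict(
        hidden_layer_sizes=tuple(config.hidden),
        activation=config.activation,
        batch_size=config.batch_size,
        learning_rate_init=config.learning_rate,
        max_iter=config.epochs,
        solver="adam",
        alpha=1e-4,
        random_state=seed,
    )


def build_classifier(tag: str, seed: int = 0, network_config: NetworkConfig | None = None):
    """Unfitted scikit-learn estimator (with scaling where it matters)."""
    if tag == "logistic":
        return make_pipeline(
            StandardScaler(), LogisticRegression(max_iter=2000, random_state=seed)
        )
    if tag == "naive_bayes":
        return GaussianNB()
    if tag == "random_forest":
        return RandomForestClassifier(n_estimators=200, random_state=seed)
    if tag == "gradient_boosting":
        return GradientBoostingClassifier(random_state=seed)
    if tag == "svm":
        return make_pipeline(
            StandardScaler(), SVC(probability=True, random_state=seed)
        )
    if tag == "mlp":
        cfg = network_config or NetworkConfig(seed=seed)
        return make_pipeline(StandardScaler(), MLPClassifier(**_mlp_kwargs(cfg, seed)))
    raise ValidationError(f"unknown model tag {tag!r}")


def build_regressor(tag: str, seed: int = 0, network_config: NetworkConfig | None = None):
    """Same-family regressor used for the effect (stage-2) models."""
    if tag in ("logistic", "naive_bayes"):
        return LinearRegression()
    if tag == "random_forest":
        return RandomForestRegressor(n_estimators=200, random_state=seed)
    if tag == "gradient_boosting":
        return GradientBoostingRegressor(random_state=seed)
    if tag == "svm":
        return make_pipeline(StandardScaler(), SVR())
    if tag == "mlp":
        cfg = network_config or NetworkConfig(seed=seed)
        return make_pipeline(StandardScaler(), MLPRegressor(**_mlp_kwargs(cfg, seed)))
    raise ValidationError(f"unknown model tag {tag!r}")


class OutcomeModel:
    """Fitted probability predictor with clipped outputs.

    Predictions are always inside [PROB_EPS, 1 - PROB_EPS].
    """

    def __init__(self, estimator, model_tag: str, fit_metadata: dict | None = None):
        self._estimator = estimator
        self.model_tag = model_tag
        self.fit_metadata = fit_metadata or {}

    def predict_probability(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        p = self._estimator.predict_proba(X)[:, 1]
        return np.clip(p, PROB_EPS, 1.0 - PROB_EPS)


class ConstantModel:
    """Fallback when one arm's outcome is single-class."""

    def __init__(self, p: float, model_tag: str = "constant"):
        self.p = float(np.clip(p, PROB_EPS, 1.0 - PROB_EPS))
        self.model_tag = model_tag
        self.fit_metadata = {"constant": self.p}

    def predict_probability(self, X) -> np.ndarray:
        return np.full(len(X), self.p)


def fit_outcome_model(
    X,
    y,
    tag: str = "logistic",
    seed: int = 0,
    network_config: NetworkConfig | None = None,
    fallback_constant: bool = False,
):
    """Fit one arm's outcome model; seed-deterministic.

    Single-class data raise :class:`DegenerateDataError` unless
    ``fallback_constant`` is set, in which case an epsilon-clipped
    constant predictor is returned.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    classes = np.unique(y)
    if classes.size < 2:
        if fallback_constant:
            return ConstantModel(float(y.mean()) if y.size else 0.0)
        raise DegenerateDataError(
            "outcome is single-class in this arm; refit with "
            "fallback_constant=True to use a constant predictor"
        )
    est = build_classifier(tag, seed=seed, network_config=network_config)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(X, y)
    meta = {"seed": seed, "n": int(len(y))}
    if tag == "mlp":
        meta["network"] = asdict(network_config or NetworkConfig(seed=seed))
    return OutcomeModel(est, tag, meta)


# ---------------------------------------------------------------------------
# model selection


@dataclass
class MetricReport:
    """Per-candidate holdout metrics plus the selected tag."""

    metrics: pd.DataFrame  # index = candidate tag; columns Accuracy, AUC, F1-Score
    selected_tag: str

    def to_csv(self, path) -> None:
        out = self.metrics.rename_axis("Model").reset_index()
        out.to_csv(path, index=False)


def compute_metrics(y_true, scores, threshold: float = 0.5) -> dict:
    """Accuracy, rank-based AUC and positive-class F1 at the threshold."""
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if np.unique(y_true).size < 2:
        raise MetricError("holdout contains a single class; AUC is undefined")
    pred = (scores >= threshold).astype(int)
    return {
        "Accuracy": float(accuracy_score(y_true, pred)),
        "AUC": float(roc_auc_score(y_true, scores)),
        "F1-Score": float(f1_score(y_true, pred, pos_label=1, zero_division=0)),
    }


def select_model(metrics: pd.DataFrame, candidate_order=None) -> str:
    """Pure selection rule: best (lowest) mean rank across the three
    metrics; ties by higher AUC, then by candidate order."""
    order = list(candidate_order) if candidate_order is not None else list(metrics.index)
    ranks = pd.DataFrame(index=metrics.index)
    for col in ("Accuracy", "AUC", "F1-Score"):
        ranks[col] = rankdata(-metrics[col].to_numpy(), method="average")
    mean_rank = ranks.mean(axis=1)
    best = mean_rank.min()
    tied = [t for t in order if np.isclose(mean_rank[t], best)]
    if len(tied) > 1:
        best_auc = metrics.loc[tied, "AUC"].max()
        tied = [t for t in tied if np.isclose(metrics.loc[t, "AUC"], best_auc)]
    return tied[0]


def evaluate_candidates(
    X_train,
    y_train,
    X_holdout,
    y_holdout,
    candidates=CANDIDATE_TAGS,
    seed: int = 0,
    network_config: NetworkConfig | None = None,
) -> MetricReport:
    """Fit every candidate on the training split and score it on the
    holdout; requires both classes present in the holdout."""
    y_holdout = np.asarray(y_holdout, dtype=int)
    if np.unique(y_holdout).size < 2:
        raise MetricError("holdout contains a single class; AUC is undefined")
    rows = {}
    for tag in candidates:
        model = fit_outcome_model(
            X_train, y_train, tag=tag, seed=seed, network_config=network_config
        )
        rows[tag] = compute_metrics(y_holdout, model.predict_probability(X_holdout))
    metrics = pd.DataFrame.from_dict(rows, orient="index")[
        ["Accuracy", "AUC", "F1-Score"]
    ]
    return MetricReport(metrics=metrics, selected_tag=select_model(metrics, candidates))
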