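"""Three-stage X-Learner for binary outcomes.

Stage 1 fits arm-specific outcome models mu1 (treated) and mu0
(control).  Stage 2 imputes the missing counterfactual for every unit
and forms pseudo-outcomes

    D1_i = Y_i - mu0(x_i)      for treated i,
    D0_j = mu1(x_j) - Y_j      for control j,

then regresses them on covariates to obtain effect models tau1 and
tau0.  Stage 3 combines the two with a propensity weight,

    tau(x) = g(x) * tau0(x) + (1 - g(x)) * tau1(x),

a convex combination that leans on the effect model trained on the
*larger* arm where assignment is imbalanced.  Positive tau here means
the treatment raises the outcome probability (the raw convention); the
reporting layer flips sign for outcomes reported as reductions.

Effect estimates are evaluated on a held-out test split so that the
per-unit CATEs entering the effect summary are out-of-sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .base_models import (
    NetworkConfig,
    build_regressor,
    fit_outcome_model,
)
from .errors import PositivityError, ValidationError

PROPENSITY_CLIP = (0.01, 0.99)


@dataclass
class OutcomeModelPair:
    """Arm-specific outcome models fitted on disjoint row sets."""

    mu1: object  # fitted on treated rows
    mu0: object  # fitted on control rows
    n_treated: int = 0
    n_control: int = 0


@dataclass
class PseudoOutcomeSet:
    """Imputed per-unit effects; every value lies in [-1, 1] for binary
    outcomes with clipped predictions."""

    D1: np.ndarray
    D0: np.ndarray
    treated_idx: np.ndarray
    control_idx: np.ndarray


class PropensityModel:
    """Clipped probability of treatment given covariates."""

    def __init__(self, estimator, clip=PROPENSITY_CLIP, constant: float | None = None):
        self._estimator = estimator
        self.clip = clip
        self.constant = constant

    def predict(self, X) -> np.ndarray:
        if self.constant is not None:
            g = np.full(len(X), self.constant)
        else:
            g = self._estimator.predict_proba(np.asarray(X, dtype=float))[:, 1]
        return np.clip(g, self.clip[0], self.clip[1])


@dataclass
class CateEstimates:
    """Per-unit effect estimates with their audit components."""

    tau_hat: np.ndarray
    tau1: np.ndarray
    tau0: np.ndarray
    g: np.ndarray
    treatment: str = ""
    outcome: str = ""
    index: np.ndarray | None = None
    extra: dict = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        idx = self.index if self.index is not None else np.arange(len(self.tau_hat))
        return pd.DataFrame(
            {"id": idx, "tau_hat": self.tau_hat, "tau1": self.tau1,
             "tau0": self.tau0, "g": self.g}
        )


def _check_arms(t: np.ndarray, context: str) -> None:
    if t.sum() == 0 or t.sum() == len(t):
        raise PositivityError(f"{context}: one treatment arm is empty")


def fit_stage1(
    X,
    t,
    y,
    tag: str = "logistic",
    seed: int = 0,
    network_config: NetworkConfig | None = None,
) -> OutcomeModelPair:
    """Fit mu1 on the treated arm and mu0 on the control arm.

    A single-class arm falls back to a constant predictor.
    """
    X = np.asarray(X, dtype=float)
    t = np.asarray(t, dtype=int)
    y = np.asarray(y, dtype=int)
    _check_arms(t, "stage 1")
    mu1 = fit_outcome_model(
        X[t == 1], y[t == 1], tag=tag, seed=seed,
        network_config=network_config, fallback_constant=True,
    )
    mu0 = fit_outcome_model(
        X[t == 0], y[t == 0], tag=tag, seed=seed,
        network_config=network_config, fallback_constant=True,
    )
    return OutcomeModelPair(
        mu1=mu1, mu0=mu0, n_treated=int(t.sum()), n_control=int((1 - t).sum())
    )


def compute_pseudo_outcomes(pair: OutcomeModelPair, X, t, y) -> PseudoOutcomeSet:
    """Counterfactual-imputed effects for every unit (raw sign convention)."""
    X = np.asarray(X, dtype=float)
    t = np.asarray(t)
    y = np.asarray(y, dtype=float)
    if not np.isin(t, (0, 1)).all():
        raise ValidationError("every row needs a 0/1 arm label")
    t = t.astype(int)
    ti = np.flatnonzero(t == 1)
    ci = np.flatnonzero(t == 0)
    D1 = y[ti] - pair.mu0.predict_probability(X[ti])
    D0 = pair.mu1.predict_probability(X[ci]) - y[ci]
    return PseudoOutcomeSet(D1=D1, D0=D0, treated_idx=ti, control_idx=ci)


def fit_stage2(
    pseudo: PseudoOutcomeSet,
    X,
    tag: str = "logistic",
    seed: int = 0,
    network_config: NetworkConfig | None = None,
):
    """Effect regressors: tau1 on the treated rows' D1, tau0 on the
    control rows' D0.  Returns the two fitted regressors; predictions
    should be clipped to [-1, 1] (combine_cate does this)."""
    if len(pseudo.D1) == 0 or len(pseudo.D0) == 0:
        raise PositivityError("stage 2 requires both pseudo-outcome sets nonempty")
    X = np.asarray(X, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tau1 = build_regressor(tag, seed=seed, network_config=network_config)
        tau1.fit(X[pseudo.treated_idx], pseudo.D1)
        tau0 = build_regressor(tag, seed=seed, network_config=network_config)
        tau0.fit(X[pseudo.control_idx], pseudo.D0)
    return tau1, tau0


def fit_propensity(
    X, t, clip=PROPENSITY_CLIP, seed: int = 0
) -> PropensityModel:
    """Logistic propensity model with clipped outputs.

    Perfect separation (holdout-free in-sample AUC of 1) triggers a
    fall-back to the constant arm share, with a warning.
    """
    X = np.asarray(X, dtype=float)
    t = np.asarray(t, dtype=int)
    _check_arms(t, "propensity fit")
    est = make_pipeline(
        StandardScaler(), LogisticRegression(max_iter=2000, random_state=seed)
    )
    est.fit(X, t)
    score = est.predict_proba(X)[:, 1]
    if roc_auc_score(t, score) >= 1.0 - 1e-12:
        warnings.warn(
            "propensity model separates the arms perfectly; "
            "falling back to the constant arm share",
            stacklevel=2,
        )
        return PropensityModel(None, clip=clip, constant=float(t.mean()))
    return PropensityModel(est, clip=clip)


def combine_cate(tau1_model, tau0_model, propensity: PropensityModel, X,
                 treatment: str = "", outcome: str = "",
                 index=None) -> CateEstimates:
    """Propensity-weighted convex combination of the two effect models."""
    X = np.asarray(X, dtype=float)
    g = propensity.predict(X)
    t1 = np.clip(np.asarray(tau1_model.predict(X), dtype=float), -1.0, 1.0)
    t0 = np.clip(np.asarray(tau0_model.predict(X), dtype=float), -1.0, 1.0)
    tau_hat = g * t0 + (1.0 - g) * t1
    return CateEstimates(
        tau_hat=tau_hat, tau1=t1, tau0=t0, g=g,
        treatment=treatment, outcome=outcome, index=index,
    )


def estimate_cate(
    X,
    t,
    y,
    base_model: str = "logistic",
    seed: int = 0,
    split: float = 0.2,
    network_config: NetworkConfig | None = None,
    propensity_clip=PROPENSITY_CLIP,
    treatment: str = "",
    outcome: str = "",
) -> CateEstimates:
    """Full pipeline: train on a (1 - split) fraction stratified by
    treatment x outcome, return out-of-sample CATE on the held-out rows.

    With ``split=0`` everything is both trained and evaluated in-sample.
    """
    X = np.asarray(X, dtype=float)
    t = np.asarray(t, dtype=int)
    y = np.asarray(y, dtype=int)
    _check_arms(t, "estimate_cate")
    idx = np.arange(len(t))
    if split and split > 0:
        strata = t * 2 + y
        # fall back to stratifying on treatment alone when a stratum is
        # too small to split
        if np.bincount(strata).min() < 2:
            strata = t
        train_idx, test_idx = train_test_split(
            idx, test_size=split, random_state=seed, stratify=strata
        )
    else:
        train_idx = test_idx = idx

    Xtr, ttr, ytr = X[train_idx], t[train_idx], y[train_idx]
    pair = fit_stage1(Xtr, ttr, ytr, tag=base_model, seed=seed,
                      network_config=network_config)
    pseudo = compute_pseudo_outcomes(pair, Xtr, ttr, ytr)
    tau1_m, tau0_m = fit_stage2(pseudo, Xtr, tag=base_model, seed=seed,
                                network_config=network_config)
    prop = fit_propensity(Xtr, ttr, clip=propensity_clip, seed=seed)
    est = combine_cate(
        tau1_m, tau0_m, prop, X[test_idx],
        treatment=treatment, outcome=outcome, index=test_idx,
    )
    est.extra = {
        "n_train": int(len(train_idx)),
        "n_test": int(len(test_idx)),
        "n_treated_train": int(ttr.sum()),
        "propensity_model": prop,
        "outcome_pair": pair,
    }
    return est
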