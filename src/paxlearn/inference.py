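"""Effect-size inference over per-unit CATE estimates.

The average treatment effect is the mean of the per-unit CATE estimates
on the test split; its standard error divides the sample standard
deviation of those estimates by sqrt(n); the 95% confidence interval
and two-sided p-value use the t distribution with n - 1 degrees of
freedom.  All effects are risk differences for binary outcomes.

Note this standard error reflects only the spread of the fitted
per-unit effects across test units, not the training noise of the
stage-1/stage-2 models; see the methods note for the coverage
diagnostic quantifying the consequences.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InferenceError, PositivityError
from .preprocessing import TreatmentDefinition, assign_treatment
from .xlearner import CateEstimates, estimate_cate

OVERLAP_BOUNDS = (0.05, 0.95)

REPORT_COLUMNS = [
    "Mental Health Indicators",
    "ATE",
    "Lower Bound (95% CI)",
    "Upper Bound (95% CI)",
    "p-Value",
    "Significant",
]

#: Display names used in the report tables.
OUTCOME_DISPLAY = {
    "depression": "Depression",
    "suicidal_ideation": "Suicidal Ideation",
    "stress": "Heavy Stress",
}


@dataclass(frozen=True)
class EffectSummary:
    """One report row: ATE with t-based interval and test."""

    outcome: str
    treatment: str
    n_test: int
    ate: float
    se: float
    ci_lower: float
    ci_upper: float
    p_value: float
    significant: bool
    sign_convention: str = "raw"  # raw: positive = raises outcome probability
    alpha: float = 0.05


def summarize_effect(
    cate: CateEstimates | np.ndarray,
    alpha: float = 0.05,
    outcome: str = "",
    treatment: str = "",
) -> EffectSummary:
    """Aggregate per-unit effects into ATE / SE / CI / p-value."""
    if isinstance(cate, CateEstimates):
        tau = np.asarray(cate.tau_hat, dtype=float)
        outcome = outcome or cate.outcome
        treatment = treatment or cate.treatment
    else:
        tau = np.asarray(cate, dtype=float)
    n = tau.size
    if n < 2:
        raise InferenceError("effect summarisation needs at least 2 estimates")
    ate = float(tau.mean())
    se = float(tau.std(ddof=1) / np.sqrt(n))
    if se == 0.0:
        ci_lo = ci_hi = ate
        p = 0.0 if ate != 0.0 else 1.0
    else:
        tcrit = float(stats.t.ppf(1.0 - alpha / 2.0, n - 1))
        ci_lo, ci_hi = ate - tcrit * se, ate + tcrit * se
        p = float(2.0 * stats.t.sf(abs(ate / se), n - 1))
    return EffectSummary(
        outcome=outcome,
        treatment=treatment,
        n_test=int(n),
        ate=ate,
        se=se,
        ci_lower=float(ci_lo),
        ci_upper=float(ci_hi),
        p_value=p,
        significant=bool(p < alpha),
        alpha=alpha,
    )


def apply_sign_convention(summary: EffectSummary,
                          direction: str = "reduction") -> EffectSummary:
    """Report harm-outcome effects as probability reductions.

    Under the raw convention a beneficial treatment has a negative risk
    difference; the reduction convention negates the estimate (and swaps
    the interval bounds) so that a positive entry reads as a reduction.
    Idempotent: an already-converted summary is returned unchanged.
    """
    if direction == "raw" or summary.sign_convention == direction:
        return summary
    if direction != "reduction":
        raise ValueError(f"unknown sign convention {direction!r}")
    return replace(
        summary,
        ate=-summary.ate,
        ci_lower=-summary.ci_upper,
        ci_upper=-summary.ci_lower,
        sign_convention="reduction",
    )


# ---------------------------------------------------------------------------
# overlap diagnostics


@dataclass
class OverlapReport:
    """Distributional check of the positivity assumption."""

    g_min: float
    g_max: float
    share_outside: float
    warn: bool
    bounds: tuple
    histogram_treated: list
    histogram_control: list
    bin_edges: list

    def to_dict(self) -> dict:
        return {
            "g_min": self.g_min,
            "g_max": self.g_max,
            "share_outside": self.share_outside,
            "warn": self.warn,
            "bounds": list(self.bounds),
            "histogram_treated": self.histogram_treated,
            "histogram_control": self.histogram_control,
            "bin_edges": self.bin_edges,
        }


def check_overlap(propensity, X, t, bounds=OVERLAP_BOUNDS,
                  warn_share: float = 0.10) -> OverlapReport:
    """Report the propensity distribution per arm and flag poor overlap
    (more than ``warn_share`` of units outside ``bounds``)."""
    g = propensity.predict(X)
    t = np.asarray(t, dtype=int)
    outside = float(((g < bounds[0]) | (g > bounds[1])).mean())
    edges = np.linspace(0.0, 1.0, 21)
    h1, _ = np.histogram(g[t == 1], bins=edges)
    h0, _ = np.histogram(g[t == 0], bins=edges)
    return OverlapReport(
        g_min=float(g.min()),
        g_max=float(g.max()),
        share_outside=outside,
        warn=bool(outside > warn_share),
        bounds=tuple(bounds),
        histogram_treated=h1.tolist(),
        histogram_control=h0.tolist(),
        bin_edges=edges.tolist(),
    )


# ---------------------------------------------------------------------------
# report assembly


def effect_table(summaries, by_threshold: bool = False) -> pd.DataFrame:
    """Rows shaped like the published effect tables.

    ``by_threshold`` adds the 'Sedentary Hours' column for sweep
    reports.  Flagged (failed) rows appear with NaN statistics.
    """
    rows = []
    for item in summaries:
        if isinstance(item, dict) and "error" in item:
            row = {
                "Mental Health Indicators": OUTCOME_DISPLAY.get(
                    item.get("outcome", ""), item.get("outcome", "")
                ),
                "ATE": np.nan,
                "Lower Bound (95% CI)": np.nan,
                "Upper Bound (95% CI)": np.nan,
                "p-Value": np.nan,
                "Significant": "flagged: " + item["error"],
            }
            if by_threshold:
                row["Sedentary Hours"] = item.get("threshold")
            rows.append(row)
            continue
        s = item
        row = {
            "Mental Health Indicators": OUTCOME_DISPLAY.get(s.outcome, s.outcome),
            "ATE": s.ate,
            "Lower Bound (95% CI)": s.ci_lower,
            "Upper Bound (95% CI)": s.ci_upper,
            "p-Value": s.p_value,
            "Significant": bool(s.significant),
        }
        if by_threshold:
            row["Sedentary Hours"] = _threshold_of(s.treatment)
        rows.append(row)
    cols = list(REPORT_COLUMNS)
    if by_threshold:
        cols.insert(1, "Sedentary Hours")
    return pd.DataFrame(rows)[cols]


def _threshold_of(label: str):
    if "(" in label:
        return label.split("(", 1)[1].rstrip(")")
    return None


def run_sedentary_sweep(
    features,
    outcome_labels,
    data,
    thresholds=(4, 6, 8, 10, 12),
    outcome: str = "depression",
    base_model: str = "logistic",
    seed: int = 0,
    split: float = 0.2,
    sign: str = "reduction",
) -> list:
    """Independent full X-Learner run per sitting-hours threshold.

    Returns a list of :class:`EffectSummary` (one per threshold); a
    threshold that leaves an arm empty yields a flagged dict instead of
    aborting the sweep.
    """
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    results = []
    X = np.asarray(features, dtype=float)
    y = np.asarray(outcome_labels, dtype=int)
    for h in thresholds:
        definition = TreatmentDefinition("sedentary_threshold", float(h))
        try:
            t = assign_treatment(data, definition)
            est = estimate_cate(
                X, t, y, base_model=base_model, seed=seed, split=split,
                treatment=definition.label, outcome=outcome,
            )
            summary = summarize_effect(est)
            results.append(apply_sign_convention(summary, sign))
        except PositivityError as exc:
            results.append(
                {"outcome": outcome, "threshold": h, "error": str(exc)}
            )
    return results
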