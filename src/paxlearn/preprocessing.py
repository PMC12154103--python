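"""Screening and recoding of elderly health-survey extracts.

The raw extract is one row per respondent with survey-coded fields:
Likert labels for perceived health and stress, yes/no strings for the
two depression-related items, integer category codes for the
socio-demographic features, and continuous age / BMI / daily sitting
hours.  Any field may instead hold a sentinel code (``no_response``,
``do_not_know``, ``missing``).  This module applies the study rules:

* keep respondents aged ``min_age`` and above (default 60);
* drop any row with a sentinel in an analysis variable (no imputation);
* recode outcomes and health perception to binary;
* dichotomise the three intervention variables into treated/control arms.

Label-wise (not code-wise) mappings are used throughout so the
direction of the Likert scales is unambiguous; the mapping tables below
are module-level and can be overridden by callers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    EmptyCohortError,
    PositivityError,
    ValidationError,
)

SENTINELS = ("no_response", "do_not_know", "missing")

# "Do you consider yourself healthy?" — five-point scale, positive =
# top three agreement categories.
HEALTH_LABELS = ("strongly_agree", "agree", "neutral", "disagree", "strongly_disagree")
HEALTH_POSITIVE = frozenset(HEALTH_LABELS[:3])

# "Do you experience stress in your daily life?" — five-point scale,
# high stress = top two severity categories.
STRESS_LABELS = ("very_much", "a_lot", "a_little", "not_much", "hardly_any")
STRESS_HIGH = frozenset(STRESS_LABELS[:2])

YESNO = ("yes", "no")

#: The 13 input features, in the reporting order of the study tables.
FEATURE_COLUMNS = [
    "sex",
    "age",
    "education",
    "income",
    "household_income",
    "occupation",
    "bmi",
    "obesity_status",
    "health_perception",
    "hypertension",
    "dyslipidemia",
    "diabetes",
    "alcohol_habits",
]

OUTCOME_COLUMNS = ["depression", "suicidal_ideation", "stress"]

TREATMENT_COLUMNS = ["high_pa_sessions", "moderate_pa_sessions", "sedentary_hours"]

#: Variables whose sentinel values trigger row removal: exactly the
#: input-feature, outcome and intervention fields; other columns are ignored.
ANALYSIS_COLUMNS = FEATURE_COLUMNS + OUTCOME_COLUMNS + TREATMENT_COLUMNS

#: Fields eligible for sentinel codes in raw extracts (interview items);
#: the intervention fields are recorded separately and stay numeric.
SENTINEL_ELIGIBLE_COLUMNS = FEATURE_COLUMNS + OUTCOME_COLUMNS

_NUMERIC_COLUMNS = [
    c for c in ANALYSIS_COLUMNS
    if c not in ("health_perception", "depression", "suicidal_ideation", "stress")
]

SEDENTARY_THRESHOLDS = (4, 6, 8, 10, 12)

TREATMENT_DEFINITIONS = ("high_pa", "moderate_pa", "sedentary_mean", "sedentary_threshold")


@dataclass(frozen=True)
class TreatmentDefinition:
    """One of the study's treated/control dichotomisations.

    ``high_pa`` / ``moderate_pa``: treated = at least one session per week.
    ``sedentary_threshold``: treated = sitting strictly less than
    ``threshold_hours`` per day (the beneficial low-sitting condition).
    ``sedentary_mean``: treated = sitting below the within-cohort mean.
    """

    name: str
    threshold_hours: float | None = None

    def __post_init__(self) -> None:
        if self.name not in TREATMENT_DEFINITIONS:
            raise ValidationError(f"unknown treatment definition {self.name!r}")
        if (self.name == "sedentary_threshold") != (self.threshold_hours is not None):
            raise ValidationError(
                "threshold_hours must be given exactly for the "
                "'sedentary_threshold' definition"
            )

    @property
    def label(self) -> str:
        if self.name == "sedentary_threshold":
            return f"sedentary_threshold({self.threshold_hours:g}h)"
        return self.name


@dataclass
class ProcessedCohort:
    """Model-ready arrays plus the audit trail of the screening rules."""

    data: pd.DataFrame
    features: pd.DataFrame
    outcomes: pd.DataFrame
    audit: dict = field(default_factory=dict)


def _sentinel_mask(df: pd.DataFrame, columns: list[str]) -> pd.Series:
    cols = [c for c in columns if c in df.columns]
    if not cols:
        return pd.Series(False, index=df.index)
    return df[cols].isin(SENTINELS).any(axis=1)


def _restore_numeric(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for c in _NUMERIC_COLUMNS:
        if c in out.columns and out[c].dtype == object:
            out[c] = pd.to_numeric(out[c])
    return out


def screen_cohort(
    raw: pd.DataFrame, min_age: float = 60.0
) -> tuple[pd.DataFrame, dict]:
    """Apply the age floor and the sentinel-removal rule.

    Returns the surviving rows (numeric dtypes restored) and an audit
    dict with per-rule drop counts satisfying
    ``rows_read == rows_kept + dropped_age + dropped_sentinel``.
    """
    if min_age < 0:
        raise ConfigurationError("min_age must be non-negative")
    if "age" not in raw.columns:
        raise ValidationError("cohort has no 'age' column")

    age = pd.to_numeric(raw["age"], errors="coerce")
    age_ok = age >= min_age
    sent = _sentinel_mask(raw, ANALYSIS_COLUMNS)
    kept_mask = age_ok & ~sent

    audit = {
        "rows_read": int(len(raw)),
        "dropped_age": int((~age_ok).sum()),
        "dropped_sentinel": int((age_ok & sent).sum()),
        "rows_kept": int(kept_mask.sum()),
    }
    if audit["rows_kept"] == 0:
        raise EmptyCohortError(
            f"no respondents remain after screening (age >= {min_age}, "
            "sentinel removal)"
        )
    return _restore_numeric(raw.loc[kept_mask]), audit


def _recode_binary_labels(values: pd.Series, positive: frozenset, allowed) -> pd.Series:
    bad = set(values.unique()) - set(allowed)
    if bad:
        raise ValidationError(
            f"unexpected response labels {sorted(map(str, bad))!r} in "
            f"column {values.name!r}"
        )
    return values.isin(positive).astype(int)


def recode_outcomes(df: pd.DataFrame) -> pd.DataFrame:
    """Binary labels for the three mental-health outcomes.

    depression = 1 iff the respondent reported feeling depressed for two
    consecutive weeks or more; suicidal_ideation = 1 iff past-year
    ideation was affirmed; stress = 1 iff the perceived-stress response
    falls in the top two severity categories.
    """
    return pd.DataFrame(
        {
            "depression": _recode_binary_labels(
                df["depression"], frozenset({"yes"}), YESNO
            ),
            "suicidal_ideation": _recode_binary_labels(
                df["suicidal_ideation"], frozenset({"yes"}), YESNO
            ),
            "stress": _recode_binary_labels(df["stress"], STRESS_HIGH, STRESS_LABELS),
        },
        index=df.index,
    )


def recode_health_perception(values: pd.Series) -> pd.Series:
    """1 iff self-rated health is in the top three agreement categories."""
    return _recode_binary_labels(values, HEALTH_POSITIVE, HEALTH_LABELS)


def recode_features(df: pd.DataFrame) -> pd.DataFrame:
    """Numeric 13-column feature matrix in the study's reporting order."""
    out = pd.DataFrame(index=df.index)
    for c in FEATURE_COLUMNS:
        if c == "health_perception":
            out[c] = recode_health_perception(df[c])
        else:
            out[c] = pd.to_numeric(df[c])
    return out


def assign_treatment(
    df: pd.DataFrame, definition: TreatmentDefinition | str, threshold_hours=None
) -> np.ndarray:
    """Per-row treated (1) / control (0) labels for one definition.

    Raises :class:`PositivityError` when either arm is empty.
    """
    if isinstance(definition, str):
        definition = TreatmentDefinition(definition, threshold_hours)

    if definition.name == "high_pa":
        t = (pd.to_numeric(df["high_pa_sessions"]) >= 1).to_numpy()
    elif definition.name == "moderate_pa":
        t = (pd.to_numeric(df["moderate_pa_sessions"]) >= 1).to_numpy()
    else:
        hours = pd.to_numeric(df["sedentary_hours"]).to_numpy(dtype=float)
        if definition.name == "sedentary_mean":
            cut = hours.mean()
        else:
            cut = float(definition.threshold_hours)
        # strict '<': treated is the low-sitting (beneficial) condition
        t = hours < cut

    t = t.astype(int)
    if t.all() or not t.any():
        raise PositivityError(
            f"treatment definition {definition.label!r} leaves an empty arm "
            f"({int(t.sum())} treated of {len(t)})"
        )
    return t


def preprocess(raw: pd.DataFrame, min_age: float = 60.0) -> ProcessedCohort:
    """Screen then recode: the full preparation path used by every analysis."""
    kept, audit = screen_cohort(raw, min_age=min_age)
    return ProcessedCohort(
        data=kept,
        features=recode_features(kept),
        outcomes=recode_outcomes(kept),
        audit=audit,
    )
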