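"""Synthetic elderly-cohort generator with known causal ground truth.

Emulates the structure of a national health-survey extract for
respondents aged 60+: thirteen covariates with configurable marginals,
three binary mental-health outcomes (depressed mood, suicidal ideation,
high perceived stress), two weekly physical-activity indicators and
continuous daily sitting hours.  One intervention is designated the
*causal treatment*: assignment follows a logistic model on the recoded
covariates (confounded by default through health perception and age),
and potential outcomes are parameterised on the probability scale,

    p0(x) = expit(a + gamma . z(x)),      p1(x) = clip(p0(x) - tau(x), 0, 1),

so the true conditional average treatment effect is exactly the risk
difference tau*(x) = p0(x) - p1(x).  The sign convention is that
positive tau means the treatment *reduces* the outcome probability.

Covariates are drawn with independent marginals; the only built-in
dependence is the confounding path covariates -> treatment and
covariates -> outcome, plus the deterministic link between the binary
outcome and its raw Likert/yes-no survey form.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import truncnorm

from .errors import ConfigurationError
from .preprocessing import (
    FEATURE_COLUMNS,
    SENTINELS,
    SENTINEL_ELIGIBLE_COLUMNS,
)

# ---------------------------------------------------------------------------
# default marginals (survey-table shares of the target elderly cohort)

_N_TABLE = 7066.0

DEFAULT_COVARIATE_SPEC = {
    "sex": {"probs": [3141 / _N_TABLE, 3925 / _N_TABLE]},          # 0 male, 1 female
    "age": {"mean": 69.65, "sd": 6.43},
    "education": {"probs": [c / _N_TABLE for c in (3403, 1541, 1215, 907)]},
    "income": {"probs": [c / _N_TABLE for c in (1687, 1752, 1816, 1811)]},
    "household_income": {"probs": [c / _N_TABLE for c in (2603, 2069, 1404, 990)]},
    "occupation": {
        "probs": [c / _N_TABLE for c in (235, 152, 535, 621, 481, 1010, 4032)]
    },
    "bmi": {"mean": 24.22, "sd": 3.2},
    "obesity_status": {
        "probs": [c / _N_TABLE for c in (182, 2745, 2060, 1831, 220, 28)]
    },
    # binary positive self-rated health share (top-three Likert categories)
    "health_perception": {"probs": [0.2611, 0.7389]},
    "hypertension": {"probs": [3458 / _N_TABLE, 3608 / _N_TABLE]},
    "dyslipidemia": {"probs": [4536 / _N_TABLE, 2530 / _N_TABLE]},
    "diabetes": {"probs": [5656 / _N_TABLE, 1410 / _N_TABLE]},
    "alcohol_habits": {
        "probs": [c / _N_TABLE for c in (3199, 1114, 543, 934, 728, 548)]
    },
}

DEFAULT_OUTCOME_BASE_RATES = {
    "depression": 0.1402,
    "suicidal_ideation": 0.0609,
    "stress": 0.1875,
}

# Coefficients act on the recoded design: binary/ordinal codes as-is,
# age and bmi standardised by their configured mean/sd.  Health
# perception is the dominant driver of every outcome by construction.
DEFAULT_OUTCOME_COEFFICIENTS = {
    "depression": {
        "health_perception": -1.5,
        "sex": 0.5,
        "age": 0.2,
        "education": -0.1,
        "household_income": -0.15,
        "dyslipidemia": 0.3,
    },
    "suicidal_ideation": {
        "health_perception": -1.3,
        "education": -0.2,
        "household_income": -0.2,
        "age": 0.15,
    },
    "stress": {
        "health_perception": -1.6,
        "sex": 0.6,
        "occupation": 0.08,
        "education": -0.15,
        "alcohol_habits": 0.08,
    },
}

#: healthier-feeling and younger respondents exercise more: the default
#: confounders of the treatment assignment.
DEFAULT_TREATMENT_COEFFICIENTS = {"health_perception": 1.0, "age": -0.5}

DEFAULT_TREATMENT_PREVALENCES = {"high_pa": 0.03, "moderate_pa": 0.1473}

# Conditional Likert splits used to expand binary latents into raw
# survey labels; any split preserves the binary marginal.
_HEALTH_SPLIT_POS = (("strongly_agree", 0.08), ("agree", 0.44), ("neutral", 0.48))
_HEALTH_SPLIT_NEG = (("disagree", 0.77), ("strongly_disagree", 0.23))
_STRESS_SPLIT_HIGH = (("very_much", 0.3), ("a_lot", 0.7))
_STRESS_SPLIT_LOW = (("a_little", 0.45), ("not_much", 0.35), ("hardly_any", 0.2))

CAUSAL_TREATMENTS = ("high_pa", "moderate_pa", "sedentary_threshold")


@dataclass(frozen=True)
class EffectSpec:
    """Ground-truth CATE function on the risk-difference scale.

    kind 'zero': tau = 0; 'constant': tau = value; 'linear': tau =
    value + slope * z_feature (standardised for age/bmi), clipped to
    [-1, 1].  Positive tau reduces the outcome probability.
    """

    kind: str = "constant"
    value: float = 0.2
    slope: float = 0.0
    feature: str = "age"

    def tau(self, design: pd.DataFrame) -> np.ndarray:
        n = len(design)
        if self.kind == "zero":
            return np.zeros(n)
        if self.kind == "constant":
            return np.full(n, float(self.value))
        if self.kind == "linear":
            z = design[self.feature].to_numpy(dtype=float)
            return np.clip(self.value + self.slope * z, -1.0, 1.0)
        raise ConfigurationError(f"true_effect.kind: unknown kind {self.kind!r}")


@dataclass
class SimulationConfig:
    """Everything the generator needs; defaults reproduce the target
    cohort's marginals with a confounded 3%-prevalence high-intensity
    physical-activity treatment and a constant 0.2 risk reduction."""

    n_respondents: int = 21508
    seed: int = 0
    covariate_spec: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_COVARIATE_SPEC.items()}
    )
    outcome_base_rates: dict = field(
        default_factory=lambda: dict(DEFAULT_OUTCOME_BASE_RATES)
    )
    outcome_coefficients: dict = field(
        default_factory=lambda: {
            k: dict(v) for k, v in DEFAULT_OUTCOME_COEFFICIENTS.items()
        }
    )
    treatment_coefficients: dict = field(
        default_factory=lambda: dict(DEFAULT_TREATMENT_COEFFICIENTS)
    )
    treatment_prevalence: float = DEFAULT_TREATMENT_PREVALENCES["high_pa"]
    causal_treatment: str = "high_pa"
    causal_threshold_hours: float | None = None
    true_effect: EffectSpec = field(default_factory=EffectSpec)
    # least-squares fit of the truncated normal to the five
    # threshold shares 19.8/38.3/43.6/75.3/86.1% (the 8 h share is not
    # jointly attainable with its neighbours under any normal)
    sedentary_mean: float = 7.43
    sedentary_sd: float = 4.36
    missingness_rate: float = 0.0

    def validate(self) -> None:
        if self.n_respondents < 2:
            raise ConfigurationError("n_respondents must be at least 2")
        for name, spec in self.covariate_spec.items():
            if "probs" in spec:
                p = np.asarray(spec["probs"], dtype=float)
                if (p < 0).any() or (p > 1).any():
                    raise ConfigurationError(
                        f"covariate_spec[{name!r}]: probabilities outside [0, 1]"
                    )
                if abs(p.sum() - 1.0) > 1e-9:
                    raise ConfigurationError(
                        f"covariate_spec[{name!r}]: probabilities sum to "
                        f"{p.sum():.12g}, expected 1"
                    )
            elif "mean" in spec:
                if not np.isfinite(spec["mean"]) or spec.get("sd", 0) <= 0:
                    raise ConfigurationError(
                        f"covariate_spec[{name!r}]: mean/sd invalid"
                    )
            else:
                raise ConfigurationError(
                    f"covariate_spec[{name!r}]: needs 'probs' or 'mean'/'sd'"
                )
        missing = set(DEFAULT_OUTCOME_BASE_RATES) - set(self.outcome_base_rates)
        if missing:
            raise ConfigurationError(
                f"outcome_base_rates: missing outcomes {sorted(missing)}"
            )
        for name, r in self.outcome_base_rates.items():
            if not 0 < r < 1:
                raise ConfigurationError(
                    f"outcome_base_rates[{name!r}]: must lie in (0, 1)"
                )
        if not 0 < self.treatment_prevalence < 1:
            raise ConfigurationError("treatment_prevalence must lie in (0, 1)")
        if self.causal_treatment not in CAUSAL_TREATMENTS:
            raise ConfigurationError(
                f"causal_treatment: unknown value {self.causal_treatment!r}"
            )
        if (self.causal_treatment == "sedentary_threshold") != (
            self.causal_threshold_hours is not None
        ):
            raise ConfigurationError(
                "causal_threshold_hours must be set exactly when "
                "causal_treatment == 'sedentary_threshold'"
            )
        if self.sedentary_sd <= 0:
            raise ConfigurationError("sedentary_sd must be positive")
        if not 0 <= self.missingness_rate <= 1:
            raise ConfigurationError("missingness_rate must lie in [0, 1]")
        if self.true_effect.kind not in ("zero", "constant", "linear"):
            raise ConfigurationError(
                f"true_effect.kind: unknown kind {self.true_effect.kind!r}"
            )

    def to_dict(self) -> dict:
        return asdict(self)

    def save(self, path) -> None:
        path = str(path)
        with open(path, "w") as fh:
            if path.endswith(".json"):
                json.dump(self.to_dict(), fh, indent=2)
            else:
                yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def recovery_config(
    tau: float,
    seed: int = 0,
    n: int = 20000,
    confounded: bool = True,
    treated_share: float = 0.5,
) -> SimulationConfig:
    """Benchmark conditions for parameter-recovery studies: a constant
    risk-difference tau with an outcome base rate of 0.5 and moderate
    covariate effects, so p0 stays far enough from the boundaries that
    the configured tau is realised (essentially) unclipped."""
    coefs = {"health_perception": -0.8, "sex": 0.3, "age": 0.2}
    return SimulationConfig(
        n_respondents=n,
        seed=seed,
        outcome_base_rates={k: 0.5 for k in DEFAULT_OUTCOME_BASE_RATES},
        outcome_coefficients={k: dict(coefs) for k in DEFAULT_OUTCOME_BASE_RATES},
        treatment_coefficients=(
            {"health_perception": 0.8, "age": -0.4} if confounded else {}
        ),
        treatment_prevalence=treated_share,
        true_effect=EffectSpec("zero") if tau == 0 else EffectSpec("constant", tau),
    )


def study_config(seed: int = 0) -> SimulationConfig:
    """The full study-emulation conditions: raw extract of 21,508
    age-screened respondents with a per-field sentinel rate of 0.067,
    chosen so that complete-case screening retains roughly a third of
    rows, matching the source survey's attrition."""
    return SimulationConfig(seed=seed, missingness_rate=0.067)


@dataclass
class SimulationTruth:
    """Row-aligned ground truth: propensity, potential-outcome
    probabilities and realised CATE per outcome."""

    g: np.ndarray
    treated: np.ndarray
    outcomes: dict  # name -> {"p0": array, "p1": array, "tau": array}

    @property
    def ate(self) -> dict:
        return {k: float(v["tau"].mean()) for k, v in self.outcomes.items()}

    def frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"id": np.arange(len(self.g)), "g": self.g,
                            "treated": self.treated})
        for name, d in self.outcomes.items():
            out[f"p0_{name}"] = d["p0"]
            out[f"p1_{name}"] = d["p1"]
            out[f"tau_{name}"] = d["tau"]
        return out

    def save(self, path) -> None:
        self.frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------


def _calibrate_intercept(eta: np.ndarray, target: float) -> float:
    """Intercept a such that mean(expit(a + eta)) == target."""
    return brentq(lambda a: expit(a + eta).mean() - target, -40.0, 40.0)


def _design(covariates: pd.DataFrame, spec: dict) -> pd.DataFrame:
    """Numeric design frame used by the structural models: category
    codes as-is, age and bmi standardised by their configured moments."""
    z = covariates[FEATURE_COLUMNS].astype(float).copy()
    for c in ("age", "bmi"):
        z[c] = (z[c] - spec[c]["mean"]) / spec[c]["sd"]
    return z


def _linear_predictor(design: pd.DataFrame, coefs: dict) -> np.ndarray:
    eta = np.zeros(len(design))
    for name, b in coefs.items():
        if name not in design.columns:
            raise ConfigurationError(f"coefficient on unknown feature {name!r}")
        eta += float(b) * design[name].to_numpy(dtype=float)
    return eta


def _draw_categorical(rng, probs, n, start=0):
    return rng.choice(len(probs), size=n, p=np.asarray(probs) / np.sum(probs)) + start


def _expand_labels(rng, binary: np.ndarray, split_pos, split_neg) -> np.ndarray:
    out = np.empty(len(binary), dtype=object)
    for value, split in ((1, split_pos), (0, split_neg)):
        mask = binary == value
        labels = [lab for lab, _ in split]
        probs = np.array([p for _, p in split])
        out[mask] = rng.choice(labels, size=int(mask.sum()), p=probs / probs.sum())
    return out


def generate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, SimulationTruth]:
    """Draw a cohort and its aligned ground truth.

    Deterministic for a fixed config+seed.  The returned table holds the
    raw survey forms (Likert labels, yes/no strings, session counts);
    the truth holds true propensity, p0/p1 and realised tau per outcome.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_respondents
    spec = config.covariate_spec

    cov = pd.DataFrame(index=pd.RangeIndex(n))
    cov["sex"] = _draw_categorical(rng, spec["sex"]["probs"], n)
    cov["age"] = rng.normal(spec["age"]["mean"], spec["age"]["sd"], n)
    for c, start in (
        ("education", 1), ("income", 1), ("household_income", 1),
        ("occupation", 1), ("obesity_status", 1), ("alcohol_habits", 1),
    ):
        cov[c] = _draw_categorical(rng, spec[c]["probs"], n, start=start)
    cov["bmi"] = np.clip(rng.normal(spec["bmi"]["mean"], spec["bmi"]["sd"], n), 10.0, None)
    for c in ("health_perception", "hypertension", "dyslipidemia", "diabetes"):
        cov[c] = _draw_categorical(rng, spec[c]["probs"], n)

    z = _design(cov, spec)

    # sitting hours: truncated-at-zero normal, inverse-CDF for determinism
    a = (0.0 - config.sedentary_mean) / config.sedentary_sd
    sedentary = truncnorm.ppf(
        rng.random(n), a, np.inf, loc=config.sedentary_mean, scale=config.sedentary_sd
    )

    # causal treatment assignment
    if config.causal_treatment == "sedentary_threshold":
        treated = (sedentary < config.causal_threshold_hours).astype(int)
        g = np.full(
            n,
            truncnorm.cdf(
                config.causal_threshold_hours, a, np.inf,
                loc=config.sedentary_mean, scale=config.sedentary_sd,
            ),
        )
    else:
        eta_t = _linear_predictor(z, config.treatment_coefficients)
        a_t = _calibrate_intercept(eta_t, config.treatment_prevalence)
        g = expit(a_t + eta_t)
        treated = (rng.random(n) < g).astype(int)

    # physical-activity session counts (>=1 session/week iff in the arm)
    pa_sessions = {}
    for pa in ("high_pa", "moderate_pa"):
        if config.causal_treatment == pa:
            arm = treated
        else:
            arm = (rng.random(n) < DEFAULT_TREATMENT_PREVALENCES[pa]).astype(int)
        sessions = np.zeros(n, dtype=int)
        k = int(arm.sum())
        sessions[arm == 1] = 1 + rng.poisson(1.5, size=k)
        pa_sessions[pa] = sessions

    # potential outcomes per outcome
    tau_config = config.true_effect.tau(z)
    truth_outcomes = {}
    y_binary = {}
    for name, base in config.outcome_base_rates.items():
        eta_y = _linear_predictor(z, config.outcome_coefficients.get(name, {}))
        a_y = _calibrate_intercept(eta_y, base)
        p0 = expit(a_y + eta_y)
        p1 = np.clip(p0 - tau_config, 0.0, 1.0)
        tau = p0 - p1  # realised CATE; equals tau_config where unclipped
        p_real = np.where(treated == 1, p1, p0)
        y_binary[name] = (rng.random(n) < p_real).astype(int)
        truth_outcomes[name] = {"p0": p0, "p1": p1, "tau": tau}

    cohort = pd.DataFrame({"id": np.arange(n)})
    for c in FEATURE_COLUMNS:
        if c == "health_perception":
            cohort[c] = _expand_labels(
                rng, cov[c].to_numpy(), _HEALTH_SPLIT_POS, _HEALTH_SPLIT_NEG
            )
        else:
            cohort[c] = cov[c].to_numpy()
    cohort["depression"] = np.where(y_binary["depression"] == 1, "yes", "no")
    cohort["suicidal_ideation"] = np.where(
        y_binary["suicidal_ideation"] == 1, "yes", "no"
    )
    cohort["stress"] = _expand_labels(
        rng, y_binary["stress"], _STRESS_SPLIT_HIGH, _STRESS_SPLIT_LOW
    )
    cohort["high_pa_sessions"] = pa_sessions["high_pa"]
    cohort["moderate_pa_sessions"] = pa_sessions["moderate_pa"]
    cohort["sedentary_hours"] = sedentary

    if config.missingness_rate > 0:
        cohort, _ = _inject(cohort, config.missingness_rate, rng)

    truth = SimulationTruth(g=g, treated=treated, outcomes=truth_outcomes)
    return cohort, truth


def _inject(cohort: pd.DataFrame, rate: float, rng) -> tuple[pd.DataFrame, dict]:
    out = cohort.copy()
    cols = [c for c in SENTINEL_ELIGIBLE_COLUMNS if c in out.columns]
    n = len(out)
    hit = rng.random((n, len(cols))) < rate
    codes = rng.choice(len(SENTINELS), size=(n, len(cols)))
    for j, c in enumerate(cols):
        rows = np.flatnonzero(hit[:, j])
        if rows.size:
            col = out[c].astype(object)
            col.iloc[rows] = [SENTINELS[k] for k in codes[rows, j]]
            out[c] = col
    info = {
        "affected_fields": int(hit.sum()),
        "affected_rows": int(hit.any(axis=1).sum()),
        "eligible_fields": len(cols),
    }
    return out, info


def inject_sentinels(
    cohort: pd.DataFrame, rate: float, seed: int
) -> tuple[pd.DataFrame, dict]:
    """Independently replace each eligible field with a sentinel code
    with probability ``rate``; returns the modified table and counts of
    affected fields/rows."""
    if not 0 <= rate <= 1:
        raise ConfigurationError("rate must lie in [0, 1]")
    if rate == 0:
        return cohort.copy(), {
            "affected_fields": 0,
            "affected_rows": 0,
            "eligible_fields": len(
                [c for c in SENTINEL_ELIGIBLE_COLUMNS if c in cohort.columns]
            ),
        }
    return _inject(cohort, rate, np.random.default_rng(seed))
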