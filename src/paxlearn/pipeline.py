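"""End-to-end orchestration: simulate -> preprocess -> select model ->
estimate effects -> report -> importance, with a manifest for
reproducibility.

Each (outcome x treatment) cell is an independent X-Learner run; a
failure in one cell (for example a positivity violation at one sitting
threshold) is recorded and does not abort the others.  Every output
file is listed in ``manifest.json`` with a content hash, alongside the
seeds and library versions of the run.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .base_models import evaluate_candidates, fit_outcome_model
from .errors import ConfigurationError, PaxlearnError
from .importance import importance_table
from .inference import (
    apply_sign_convention,
    check_overlap,
    effect_table,
    run_sedentary_sweep,
    summarize_effect,
)
from .preprocessing import FEATURE_COLUMNS, assign_treatment, preprocess
from .synthetic import SimulationConfig, generate_cohort
from .xlearner import estimate_cate, fit_propensity

IMPORTANCE_COLUMNS = {
    "depression": "Depression",
    "suicidal_ideation": "Suicide Ideation",
    "stress": "Heavy Stress",
}

DEFAULT_CANDIDATES = (
    "logistic",
    "naive_bayes",
    "random_forest",
    "gradient_boosting",
    "mlp",
)


@dataclass
class RunConfig:
    """Configuration of a full analysis run."""

    out_dir: str = "results/run"
    input_csv: str | None = None
    simulation: dict = field(default_factory=dict)
    outcomes: tuple = ("depression", "suicidal_ideation", "stress")
    pa_treatments: tuple = ("high_pa", "moderate_pa")
    sedentary_thresholds: tuple = (4, 6, 8, 10, 12)
    base_model: str = "logistic"
    candidates: tuple = DEFAULT_CANDIDATES
    selection_outcome: str = "depression"
    run_selection: bool = True
    run_importance: bool = True
    importance_background: int = 100
    importance_permutations: int = 200
    importance_eval_rows: int = 200
    split: float = 0.2
    min_age: float = 60.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ConfigurationError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)

    def validate(self) -> None:
        for o in self.outcomes:
            if o not in IMPORTANCE_COLUMNS:
                raise ConfigurationError(f"unknown outcome {o!r}")
        for t in self.pa_treatments:
            if t not in ("high_pa", "moderate_pa"):
                raise ConfigurationError(f"unknown treatment {t!r}")
        if self.input_csv is not None and not Path(self.input_csv).exists():
            raise ConfigurationError(f"input_csv not found: {self.input_csv}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_cohort(config: RunConfig, out: Path):
    if config.input_csv is not None:
        return pd.read_csv(config.input_csv), None
    sim_kwargs = dict(config.simulation)
    sim_kwargs.setdefault("seed", config.seed)
    sim = SimulationConfig(**sim_kwargs)
    cohort, truth = generate_cohort(sim)
    cohort.to_csv(out / "cohort.csv", index=False)
    truth.save(out / "truth.csv")
    sim.save(out / "simulation_config.yaml")
    return cohort, truth


def run_full_analysis(config: RunConfig) -> dict:
    """Run every stage and return the manifest (also written to disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "errors": [],
        "files": {},
    }
    import sklearn

    manifest["versions"] = {
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
    }

    cohort, _ = _load_cohort(config, out)
    processed = preprocess(cohort, min_age=config.min_age)
    X = processed.features.to_numpy(dtype=float)
    manifest["rows"] = processed.audit

    with open(out / "audit.json", "w") as fh:
        json.dump(processed.audit, fh, indent=2)

    # --- model selection -------------------------------------------------
    if config.run_selection:
        from sklearn.model_selection import train_test_split

        y_sel = processed.outcomes[config.selection_outcome].to_numpy()
        tr, ho = train_test_split(
            np.arange(len(y_sel)), test_size=0.2,
            random_state=config.seed, stratify=y_sel,
        )
        report = evaluate_candidates(
            X[tr], y_sel[tr], X[ho], y_sel[ho],
            candidates=config.candidates, seed=config.seed,
        )
        report.to_csv(out / "metric_report.csv")
        manifest["selected_model"] = report.selected_tag

    # --- effect estimation ----------------------------------------------
    tidy_rows = []
    pa_summaries: dict = {t: [] for t in config.pa_treatments}
    overlap: dict = {}
    for treatment in config.pa_treatments:
        try:
            t_arr = assign_treatment(processed.data, treatment)
            prop = fit_propensity(X, t_arr, seed=config.seed)
            overlap[treatment] = check_overlap(prop, X, t_arr).to_dict()
        except PaxlearnError as exc:
            manifest["errors"].append({"stage": "overlap", "cell": treatment,
                                       "error": str(exc)})
        for outcome in config.outcomes:
            try:
                t_arr = assign_treatment(processed.data, treatment)
                est = estimate_cate(
                    X, t_arr, processed.outcomes[outcome].to_numpy(),
                    base_model=config.base_model, seed=config.seed,
                    split=config.split, treatment=treatment, outcome=outcome,
                )
                s = apply_sign_convention(summarize_effect(est))
                pa_summaries[treatment].append(s)
                tidy_rows.append(_tidy(s))
            except PaxlearnError as exc:
                manifest["errors"].append(
                    {"stage": "estimate", "cell": f"{outcome}|{treatment}",
                     "error": str(exc)}
                )
                pa_summaries[treatment].append(
                    {"outcome": outcome, "error": str(exc)}
                )

    for treatment, summaries in pa_summaries.items():
        effect_table(summaries).to_csv(out / f"effects_{treatment}.csv", index=False)

    sweep_all = []
    for outcome in config.outcomes:
        res = run_sedentary_sweep(
            processed.features, processed.outcomes[outcome], processed.data,
            thresholds=config.sedentary_thresholds, outcome=outcome,
            base_model=config.base_model, seed=config.seed, split=config.split,
        )
        sweep_all.extend(res)
        for item in res:
            if isinstance(item, dict):
                manifest["errors"].append(
                    {"stage": "sweep", "cell": f"{outcome}|{item['threshold']}h",
                     "error": item["error"]}
                )
            else:
                tidy_rows.append(_tidy(item))
    effect_table(sweep_all, by_threshold=True).to_csv(
        out / "effects_sedentary.csv", index=False
    )

    pd.DataFrame(tidy_rows).to_csv(out / "effects.csv", index=False)
    with open(out / "overlap.json", "w") as fh:
        json.dump(overlap, fh, indent=2)

    # --- feature importance ----------------------------------------------
    if config.run_importance:
        tag = manifest.get("selected_model", config.base_model)
        models = {}
        for outcome in config.outcomes:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                models[outcome] = fit_outcome_model(
                    X, processed.outcomes[outcome].to_numpy(),
                    tag=tag, seed=config.seed,
                )
        table = importance_table(
            models, X, FEATURE_COLUMNS,
            background_size=config.importance_background,
            n_permutations=config.importance_permutations,
            seed=config.seed, eval_rows=config.importance_eval_rows,
            column_names=IMPORTANCE_COLUMNS,
        )
        table.to_csv(out / "importance.csv")
        manifest["importance_model"] = tag

    for p in sorted(out.iterdir()):
        if p.name != "manifest.json" and p.is_file():
            manifest["files"][p.name] = _sha256(p)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _tidy(s) -> dict:
    return {
        "outcome": s.outcome,
        "treatment": s.treatment,
        "n_test": s.n_test,
        "ate": s.ate,
        "se": s.se,
        "ci_lower": s.ci_lower,
        "ci_upper": s.ci_upper,
        "p_value": s.p_value,
        "significant": s.significant,
        "sign_convention": s.sign_convention,
    }
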