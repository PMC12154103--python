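"""Step 6 — Shapley feature importance of the outcome models.

Fits the selected base learner to each outcome on the full analysis
cohort and computes sampled-permutation Shapley contributions for the
13 features, averaged in absolute value over a subsample of rows.

Writes importance.csv and one bar chart per outcome into the results
directory.
"""

import argparse
import json
import warnings
from pathlib import Path

import pandas as pd

from paxlearn import fit_outcome_model, importance_table, plot_importance, preprocess
from paxlearn.pipeline import IMPORTANCE_COLUMNS
from paxlearn.preprocessing import FEATURE_COLUMNS


def _selected_model(out: Path) -> str:
    path = out / "selected_model.json"
    if path.exists():
        with open(path) as fh:
            return json.load(fh)["selected"]
    return "logistic"


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--results", default="results")
    args = ap.parse_args()

    out = Path(args.results)
    cohort = pd.read_csv(out / "cohort.csv")
    processed = preprocess(cohort, min_age=60)
    X = processed.features.to_numpy(dtype=float)
    tag = _selected_model(out)

    models = {}
    for outcome in processed.outcomes.columns:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            models[outcome] = fit_outcome_model(
                X, processed.outcomes[outcome].to_numpy(),
                tag=tag, seed=args.seed,
            )
    table = importance_table(
        models, X, FEATURE_COLUMNS,
        background_size=100, n_permutations=200,
        eval_rows=200, seed=args.seed, column_names=IMPORTANCE_COLUMNS,
    )
    table.to_csv(out / "importance.csv")
    print(table.scores.round(4).to_string())

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for column in table.scores.columns:
        ax = plot_importance(table, column)
        slug = column.lower().replace(" ", "_")
        ax.figure.tight_layout()
        ax.figure.savefig(out / f"importance_{slug}.png", dpi=120)
        plt.close(ax.figure)
    print(f"wrote {out / 'importance.csv'} and per-outcome charts")


if __name__ == "__main__":
    main()
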