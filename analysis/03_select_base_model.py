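"""Step 3 — choose the base learner for the outcome models.

Fits each candidate classifier (logistic regression, naive Bayes,
random forest, gradient boosting, feed-forward network) on an 80/20
split of the depression outcome and scores the holdout on Accuracy,
AUC and F1.  The candidate with the best mean rank across the three
metrics is carried into the effect-estimation steps.

Writes metric_report.csv into the results directory.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from paxlearn import evaluate_candidates, preprocess
from paxlearn.pipeline import DEFAULT_CANDIDATES


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--results", default="results")
    ap.add_argument("--outcome", default="depression")
    args = ap.parse_args()

    out = Path(args.results)
    cohort = pd.read_csv(out / "cohort.csv")
    processed = preprocess(cohort, min_age=60)
    X = processed.features.to_numpy(dtype=float)
    y = processed.outcomes[args.outcome].to_numpy()

    tr, ho = train_test_split(
        np.arange(len(y)), test_size=0.2, random_state=args.seed, stratify=y
    )
    report = evaluate_candidates(
        X[tr], y[tr], X[ho], y[ho],
        candidates=DEFAULT_CANDIDATES, seed=args.seed,
    )
    report.to_csv(out / "metric_report.csv")
    with open(out / "selected_model.json", "w") as fh:
        json.dump({"selected": report.selected_tag,
                   "outcome": args.outcome}, fh, indent=2)

    print(report.metrics.round(4).to_string())
    print(f"selected base learner: {report.selected_tag}")


if __name__ == "__main__":
    main()
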