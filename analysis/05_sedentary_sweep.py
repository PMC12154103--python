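"""Step 5 — sitting-time threshold sweep.

Repeats the full X-Learner analysis with treatment redefined as
"sits fewer than h hours per day" for h in {4, 6, 8, 10, 12}.  Each
threshold is an independent run; a threshold that empties an arm is
flagged in the table rather than aborting the sweep.

Writes effects_sedentary.csv into the results directory.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from paxlearn import effect_table, preprocess, run_sedentary_sweep


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
    base_model = _selected_model(out)

    all_rows = []
    for outcome in processed.outcomes.columns:
        all_rows.extend(
            run_sedentary_sweep(
                processed.features, processed.outcomes[outcome],
                processed.data, outcome=outcome,
                base_model=base_model, seed=args.seed,
            )
        )
    table = effect_table(all_rows, by_threshold=True)
    table.to_csv(out / "effects_sedentary.csv", index=False)
    print(table.round(4).to_string(index=False))


if __name__ == "__main__":
    main()
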