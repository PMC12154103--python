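"""Step 2 — screen and recode the cohort.

Applies the published eligibility pipeline to the raw extract: keep
respondents aged 60+, drop any row carrying a sentinel response
(no_response / do_not_know / missing) in an analysis column, recode the
Likert and yes/no survey items to binary indicators, and assemble the
13-column feature matrix.

Writes the screening audit (audit.json) and the processed analysis
table (processed.csv) into the results directory.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from paxlearn import preprocess


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", default="results")
    args = ap.parse_args()

    out = Path(args.results)
    cohort_path = out / "cohort.csv"
    if not cohort_path.exists():
        raise SystemExit(
            f"{cohort_path} not found - run analysis/01_simulate_cohort.py first"
        )
    cohort = pd.read_csv(cohort_path)
    processed = preprocess(cohort, min_age=60)

    with open(out / "audit.json", "w") as fh:
        json.dump(processed.audit, fh, indent=2)
    processed.data.to_csv(out / "processed.csv", index=False)

    a = processed.audit
    print(f"read {a['rows_read']} rows")
    print(f"  dropped (age < 60):        {a['dropped_age']}")
    print(f"  dropped (sentinel answer): {a['dropped_sentinel']}")
    print(f"  analysis cohort:           {a['rows_kept']}")
    for outcome in processed.outcomes.columns:
        print(f"  {outcome:18s} prevalence: "
              f"{processed.outcomes[outcome].mean():.4f}")
    print(f"wrote {out / 'audit.json'} and {out / 'processed.csv'}")


if __name__ == "__main__":
    main()
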