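#!/usr/bin/env python
"""Driver 1: generate the default synthetic registry-like cohort.

Writes visits, characteristics and ground-truth CSVs to results/cohort/.
"""

from pathlib import Path

import pandas as pd

from sletraj.io import write_cohort
from sletraj.simulate import SimConfig, simulate_cohort

OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"
SEED = 0


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cohort, truth = simulate_cohort(SimConfig(seed=SEED))
    write_cohort(cohort, OUT / "visits.csv", OUT / "characteristics.csv")
    pd.DataFrame({
        "patient_id": list(truth.labels),
        "group": [truth.labels[p] for p in truth.labels],
        "tempo": [truth.tempo[p] for p in truth.labels],
    }).to_csv(OUT / "truth.csv", index=False, float_format="%.12g")
    print(f"{cohort.n_patients} patients / {cohort.n_visits} visits -> {OUT}")


if __name__ == "__main__":
    main()
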