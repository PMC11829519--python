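#!/usr/bin/env python
"""Score the simulated proprioception sessions.

Computes joint position sense (mean absolute reproduction error, deg) and
movement detection sense (excursion/10 + direction response, averaged over
trials, 0-2) per joint and pooled per participant, and summarizes the group
contrast.  Writes results/proprioception_scores.csv.
"""

import sys
from pathlib import Path

import pandas as pd

from limbpoint.proprioception import score_sessions

DATA_DIR = Path("scratch/cohort_data")
RESULTS = Path("results")


def main() -> None:
    trials = pd.read_csv(DATA_DIR / "proprioception_trials.csv")
    scores = score_sessions(trials)
    RESULTS.mkdir(exist_ok=True)
    scores.to_csv(RESULTS / "proprioception_scores.csv", index=False)
    pooled = scores[scores["joint"] == "pooled"].copy()
    pooled["group"] = pooled["participant"].str[0].map({"C": "control", "S": "SCI"})
    summary = pooled.groupby(["group", "test"])["score"].agg(["mean", "min", "max"]).round(2)
    print(summary.to_string())


if __name__ == "__main__":
    sys.exit(main())
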