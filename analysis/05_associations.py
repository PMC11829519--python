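#!/usr/bin/env python
"""Crude associations within the SCI group.

Two families of single-predictor random-intercept models, mirroring the
follow-up to the group comparisons: (1) mean muscle torque at the classes
showing group differences vs end-point performance, per trial; and
(2) those torques vs the per-participant proprioception scores (MDS, JPS).
Writes results/associations.csv.
"""

import sys
from pathlib import Path

import pandas as pd

from limbpoint.stats import crude_association

RESULTS = Path("results")

#: (target class, torque column) pairs probed for associations.
TORQUE_AT_CLASS = [
    ("KA", "torque_hip"),
    ("HKA", "torque_knee"),
    ("HA", "torque_knee"),
    ("HKA", "torque_ankle"),
]


def main() -> None:
    table = pd.read_csv(Path("scratch") / "cohort_metrics.csv")
    sci = table[(table["group"] == "SCI") & (table["target"] != "uncollapsed")]
    rows = []
    for target, torque in TORQUE_AT_CLASS:
        sub = sci[sci["target"] == target]
        for outcome in ("h_error", "v_error", "log_area"):
            a = crude_association(sub, outcome, torque)
            rows.append(dict(family="torque-performance", target=target,
                             predictor=torque, outcome=outcome, slope=a.slope,
                             ci_low=a.ci_low, ci_high=a.ci_high, p=a.p,
                             marginal_r2=a.marginal_r2, f2=a.f2, n=a.n_obs))
        for sense in ("mds", "jps"):
            a = crude_association(sub, torque, sense)
            rows.append(dict(family="torque-proprioception", target=target,
                             predictor=sense, outcome=torque, slope=a.slope,
                             ci_low=a.ci_low, ci_high=a.ci_high, p=a.p,
                             marginal_r2=a.marginal_r2, f2=a.f2, n=a.n_obs))
    out = pd.DataFrame(rows)
    out.to_csv(RESULTS / "associations.csv", index=False)
    show = out[out["family"] == "torque-proprioception"][
        ["target", "outcome", "predictor", "slope", "p", "marginal_r2", "f2"]
    ].round(4)
    print(show.to_string(index=False))


if __name__ == "__main__":
    sys.exit(main())
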