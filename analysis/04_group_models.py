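#!/usr/bin/env python
"""Fit the group-comparison mixed models on the cohort metric table.

For each outcome (end-point errors, log foot-path area, per-joint mean muscle
torque) fits the random-intercept model with the interaction selection rule
(group x target and group x vision first, three-way only if both are
significant), controlling for maximum joint ROM and movement time, then runs
SCI-vs-control contrasts per target with Sidak adjustment and Cohen's d.
Writes results/model_summary.csv and results/group_contrasts.csv.
"""

import sys
from pathlib import Path

import pandas as pd

from limbpoint.stats import cohens_f2, fit_group_model, posthoc_group_contrasts

RESULTS = Path("results")
OUTCOMES = ("h_error", "v_error", "log_area", "torque_hip", "torque_knee", "torque_ankle")


def main() -> None:
    table = pd.read_csv(Path("scratch") / "cohort_metrics.csv")
    model_rows, contrast_rows = [], []
    for outcome in OUTCOMES:
        res = fit_group_model(table, outcome)
        f2 = cohens_f2(res.marginal_r2)
        model_rows.append(dict(outcome=outcome, structure=res.structure,
                               marginal_r2=round(res.marginal_r2, 3), f2=round(f2, 3),
                               p_group_target=res.interaction_pvalues["group:target"],
                               p_group_vision=res.interaction_pvalues["group:vision"],
                               aic=round(res.aic, 1)))
        print(f"{outcome}: structure={res.structure}, marginal R^2={res.marginal_r2:.3f}, "
              f"f^2={f2:.3f}, p(group x target)={res.interaction_pvalues['group:target']:.2g}")
        for c in posthoc_group_contrasts(res):
            contrast_rows.append(dict(outcome=outcome, target=c.target,
                                      estimate=c.estimate, ci_low=c.ci_low,
                                      ci_high=c.ci_high, p_adjusted=c.p_adjusted,
                                      d=c.cohens_d))
            flag = "*" if c.p_adjusted < 0.05 else " "
            print(f"  SCI-control @ {c.target}: {c.estimate:+.3f} "
                  f"[{c.ci_low:.3f}, {c.ci_high:.3f}] p_adj={c.p_adjusted:.3g} "
                  f"d={c.cohens_d:.2f} {flag}")
    pd.DataFrame(model_rows).to_csv(RESULTS / "model_summary.csv", index=False)
    pd.DataFrame(contrast_rows).to_csv(RESULTS / "group_contrasts.csv", index=False)


if __name__ == "__main__":
    sys.exit(main())
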