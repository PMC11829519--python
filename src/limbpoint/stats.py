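"""Mixed-effects group comparisons, post-hoc contrasts, effect sizes, associations.

All models are random-intercept linear mixed-effects models (participant as
the grouping factor) estimated by maximum likelihood.  The group-comparison
model follows a fixed selection rule: start from the two two-way interactions
(group x target, group x vision) plus covariates, drop interactions whose
Wald test is not significant, and assess the three-way interaction only when
both two-way interactions are significant (kept when its Wald test is
significant and it lowers the AIC).  Referent levels are the HKA target,
full vision, and the control group.

Effect sizes: Cohen's f^2 = R^2 / (1 - R^2) from the marginal R^2 (variance
explained by the fixed effects over total variance), and Cohen's d for group
contrasts using the total SD, sqrt(random-intercept + residual variance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sps

TARGET_CLASSES = ("HKA", "KA", "HA")
REFERENTS = dict(target="HKA", vision="full", group="control")

_GROUP_T = "C(group, Treatment('control'))"
_TARGET_T = "C(target, Treatment('HKA'))"
_VISION_T = "C(vision, Treatment('full'))"


@dataclass
class ModelResult:
    """Selected mixed-model fit with the quantities downstream stages need."""

    outcome: str
    formula: str
    structure: str                     # e.g. "group:target", "additive", ...
    params: pd.Series
    cov_params: pd.DataFrame
    conf_int: pd.DataFrame
    pvalues: pd.Series
    random_intercept_var: float
    residual_var: float
    marginal_r2: float
    aic: float
    n_obs: int
    n_participants: int
    interaction_pvalues: dict = field(default_factory=dict)
    converged: bool = True
    singular: bool = False
    fit: object = None                 # underlying statsmodels results

    @property
    def total_sd(self) -> float:
        return float(np.sqrt(self.random_intercept_var + self.residual_var))


def cohens_f2(marginal_r2: float) -> float:
    """Cohen's f^2 effect size of the variance explained: R^2 / (1 - R^2)."""
    r2 = float(marginal_r2)
    if not (0.0 <= r2 < 1.0):
        raise ValueError("marginal R^2 must lie in [0, 1)")
    return r2 / (1.0 - r2)


def _ml_aic(res) -> float:
    # statsmodels MixedLM reports likelihood without the constant; its aic is
    # consistent across nested fits, which is all the selection rule needs
    k = res.params.shape[0] + 1
    return float(-2 * res.llf + 2 * k)


def marginal_r2_from_fit(res, data: pd.DataFrame) -> float:
    """Variance-partition marginal R^2: var(fixed-effect prediction) / total."""
    fixed = np.asarray(res.model.exog @ res.fe_params)
    var_f = float(np.var(fixed, ddof=0))
    var_u = float(res.cov_re.iloc[0, 0]) if res.cov_re.size else 0.0
    var_e = float(res.scale)
    return var_f / (var_f + var_u + var_e)


def _fit_lmm(formula: str, data: pd.DataFrame):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data=data, groups=data["participant"])
        res = model.fit(reml=False, maxiter=200)
    return res


def _wald_interaction_p(res, token: str, df_denom: int) -> float:
    """Wald test of all fixed-effect terms containing ``token``.

    The chi-square statistic is referred to an F distribution with a
    between-within denominator df (participants minus group means): every
    tested interaction contains the between-participant group factor, and
    the asymptotic chi-square reference is anticonservative at cohort sizes
    of a few dozen participants.
    """
    names = [n for n in res.fe_params.index if token in n]
    if not names:
        return float("nan")
    k = len(res.params)
    L = np.zeros((len(names), k))
    all_names = list(res.params.index)
    for i, n in enumerate(names):
        L[i, all_names.index(n)] = 1.0
    w = res.wald_test(L, scalar=True)
    r = len(names)
    return float(sps.f.sf(float(w.statistic) / r, r, max(df_denom, 1)))


def _result_from_fit(res, outcome, formula, structure, data, interaction_ps) -> ModelResult:
    var_u = float(res.cov_re.iloc[0, 0]) if res.cov_re.size else 0.0
    var_e = float(res.scale)
    singular = var_u < 1e-8 * var_e or not res.converged
    return ModelResult(
        outcome=outcome,
        formula=formula,
        structure=structure,
        params=res.fe_params,
        cov_params=res.cov_params().loc[res.fe_params.index, res.fe_params.index],
        conf_int=res.conf_int().loc[res.fe_params.index],
        pvalues=res.pvalues.loc[res.fe_params.index],
        random_intercept_var=var_u,
        residual_var=var_e,
        marginal_r2=marginal_r2_from_fit(res, data),
        aic=_ml_aic(res),
        n_obs=int(res.nobs),
        n_participants=int(data["participant"].nunique()),
        interaction_pvalues=interaction_ps,
        converged=bool(res.converged),
        singular=singular,
        fit=res,
    )


def fit_group_model(
    table: pd.DataFrame,
    outcome: str,
    covariates: tuple[str, ...] = ("max_rom", "movement_time"),
    alpha: float = 0.05,
) -> ModelResult:
    """Fit the group-comparison mixed model for one outcome with model selection.

    ``table`` is the long cohort table (one row per trial) with columns
    participant, group, target, vision, the outcome, and the covariates.
    Rows with target classes outside HKA/KA/HA are dropped.
    """
    data = table[table["target"].isin(TARGET_CLASSES)].copy()
    if data["participant"].nunique() < 4 or data.groupby("group")["participant"].nunique().min() < 2:
        raise ValueError("need at least two participants per group")
    if outcome not in data.columns:
        raise KeyError(f"outcome {outcome!r} not in table")
    cov = " + ".join(c for c in covariates if c in data.columns)
    cov = f" + {cov}" if cov else ""
    base = f"{outcome} ~ {_GROUP_T}*{_TARGET_T} + {_GROUP_T}*{_VISION_T}{cov}"
    df_bw = int(data["participant"].nunique()) - 2
    res2 = _fit_lmm(base, data)
    p_gt = _wald_interaction_p(res2, f"{_GROUP_T}[T.SCI]:{_TARGET_T}", df_bw)
    p_gv = _wald_interaction_p(res2, f"{_GROUP_T}[T.SCI]:{_VISION_T}", df_bw)
    interaction_ps = {"group:target": p_gt, "group:vision": p_gv}

    if p_gt < alpha and p_gv < alpha:
        f3 = f"{outcome} ~ {_GROUP_T}*{_TARGET_T}*{_VISION_T}{cov}"
        res3 = _fit_lmm(f3, data)
        # three-way terms contain both target and vision tokens
        names3 = [n for n in res3.fe_params.index
                  if ":" in n and _TARGET_T in n and _VISION_T in n]
        p3 = np.nan
        if names3:
            k = len(res3.params)
            L = np.zeros((len(names3), k))
            alln = list(res3.params.index)
            for i, n in enumerate(names3):
                L[i, alln.index(n)] = 1.0
            w3 = res3.wald_test(L, scalar=True)
            p3 = float(sps.f.sf(float(w3.statistic) / len(names3), len(names3),
                                max(df_bw, 1)))
        interaction_ps["group:target:vision"] = p3
        if p3 < alpha and _ml_aic(res3) < _ml_aic(res2):
            return _result_from_fit(res3, outcome, f3, "group:target:vision", data, interaction_ps)
        return _result_from_fit(res2, outcome, base, "group:target+group:vision", data, interaction_ps)

    keep = []
    if p_gt < alpha:
        keep.append(f"{_GROUP_T}*{_TARGET_T}")
    else:
        keep.append(f"{_GROUP_T} + {_TARGET_T}")
    if p_gv < alpha:
        keep.append(f"{_GROUP_T}*{_VISION_T}")
    else:
        keep.append(f"{_VISION_T}")
    formula = f"{outcome} ~ {' + '.join(keep)}{cov}"
    structure = ("group:target" if p_gt < alpha else "") + (
        "+group:vision" if p_gv < alpha else ""
    ) or "additive"
    res = _fit_lmm(formula, data)
    return _result_from_fit(res, outcome, formula, structure.strip("+"), data, interaction_ps)


@dataclass
class Contrast:
    target: str
    estimate: float
    se: float
    df: float
    ci_low: float
    ci_high: float
    p: float
    p_adjusted: float
    cohens_d: float


def posthoc_group_contrasts(
    result: ModelResult,
    adjust: str = "sidak",
    d_scale: str = "total",
) -> list[Contrast]:
    """SCI-minus-control contrast per target class, marginal over vision.

    Degrees of freedom use a containment approximation (participants minus
    the two group means), appropriate because the group contrast is a
    between-participant comparison.  ``adjust`` is ``"sidak"`` (default,
    a Tukey-style familywise correction over the three targets) or ``"none"``.
    ``d_scale`` picks the SD used for Cohen's d: "total" (default) or
    "residual".
    """
    names = list(result.params.index)
    k = len(names)
    group_main = f"{_GROUP_T}[T.SCI]"
    contrasts = []
    df = max(result.n_participants - 2, 1)
    sd = result.total_sd if d_scale == "total" else float(np.sqrt(result.residual_var))
    for target in TARGET_CLASSES:
        L = np.zeros(k)
        if group_main in names:
            L[names.index(group_main)] = 1.0
        gt = f"{group_main}:{_TARGET_T}[T.{target}]"
        if gt in names:
            L[names.index(gt)] = 1.0
        gv = f"{group_main}:{_VISION_T}[T.obstructed]"
        if gv in names:
            L[names.index(gv)] = 0.5  # marginal over the two vision conditions
        # three-way terms, marginal over vision
        gtv = f"{group_main}:{_TARGET_T}[T.{target}]:{_VISION_T}[T.obstructed]"
        if gtv in names:
            L[names.index(gtv)] = 0.5
        est = float(L @ result.params.values)
        se = float(np.sqrt(L @ result.cov_params.values @ L))
        tval = est / se if se > 0 else np.nan
        p = float(2 * sps.t.sf(abs(tval), df))
        tcrit = sps.t.ppf(0.975, df)
        contrasts.append(Contrast(
            target=target, estimate=est, se=se, df=df,
            ci_low=est - tcrit * se, ci_high=est + tcrit * se,
            p=p, p_adjusted=p, cohens_d=est / sd if sd > 0 else np.nan,
        ))
    if adjust == "sidak":
        m = len(contrasts)
        for c in contrasts:
            c.p_adjusted = float(1.0 - (1.0 - min(c.p, 1.0)) ** m)
    return contrasts


@dataclass
class Association:
    outcome: str
    predictor: str
    slope: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    marginal_r2: float
    f2: float
    n_obs: int


def crude_association(table: pd.DataFrame, outcome: str, predictor: str) -> Association:
    """Random-intercept model of ``outcome`` on a single fixed ``predictor``.

    Used for torque vs end-point performance (per-trial predictor) and for
    torque vs proprioceptive sense (per-participant predictor).
    """
    data = table.dropna(subset=[outcome, predictor]).copy()
    res = _fit_lmm(f"{outcome} ~ {predictor}", data)
    est = float(res.fe_params[predictor])
    se = float(np.sqrt(res.cov_params().loc[predictor, predictor]))
    df = max(data["participant"].nunique() - 2, 1)
    tcrit = sps.t.ppf(0.975, df)
    r2 = marginal_r2_from_fit(res, data)
    return Association(
        outcome=outcome, predictor=predictor,
        slope=est, se=se,
        ci_low=est - tcrit * se, ci_high=est + tcrit * se,
        p=float(2 * sps.t.sf(abs(est / se), df)) if se > 0 else np.nan,
        marginal_r2=r2, f2=cohens_f2(r2), n_obs=int(res.nobs),
    )


# ---------------------------------------------------------------------------
# lightweight metric-table generator for statistical Monte Carlo

def simulate_metric_table(
    seed: int,
    n_control: int = 12,
    n_sci: int = 16,
    trials_per_cell: int = 4,
    group_target_effects: dict | None = None,
    group_effect: float = 0.0,
    participant_sd: float = 1.0,
    noise_sd: float = 1.0,
    outcome: str = "y",
) -> pd.DataFrame:
    """Generate a cohort metric table directly at the trial-metric level.

    The generative model is the fitted model's own structure -- participant
    random intercepts plus i.i.d. trial noise around cell means -- which makes
    it the right null/alternative machine for calibration and coverage checks
    of the statistics stage without paying for forward dynamics.
    ``group_target_effects`` maps target class to an SCI-minus-control shift.
    """
    rng = np.random.default_rng(seed)
    effects = group_target_effects or {}
    rows = []
    target_means = {"HKA": 0.0, "KA": 0.5, "HA": -0.5}
    for g, n in (("control", n_control), ("SCI", n_sci)):
        for i in range(n):
            pid = f"{g[0]}{i:02d}"
            b = rng.normal(0.0, participant_sd)
            max_rom = rng.normal(100.0 if g == "control" else 85.0, 10.0)
            for target in TARGET_CLASSES:
                for vision in ("full", "obstructed"):
                    mt = rng.normal(0.64, 0.1, trials_per_cell)
                    mu = target_means[target] + b
                    if g == "SCI":
                        mu += group_effect + effects.get(target, 0.0)
                    y = mu + rng.normal(0.0, noise_sd, trials_per_cell)
                    for k in range(trials_per_cell):
                        rows.append(dict(
                            participant=pid, group=g, target=target, vision=vision,
                            max_rom=max_rom, movement_time=mt[k], **{outcome: y[k]},
                        ))
    return pd.DataFrame(rows)
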