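"""Weighted intervention-effect models and the two-stage analysis.

Follow-up composition proportions are analyzed with baseline-adjusted
weighted linear regression (follow-up measure ~ arm + baseline measure);
relationship-change, structure, and turnover counts with weighted Poisson
regression (count ~ arm + baseline network size), whose arm coefficients are
exponentiated to incidence rate ratios (IRR).  Cross-wave density, though
reported alongside the counts, is fitted as a linear model.  All models use
sandwich (HC1) standard errors under the nonresponse weights — linear models
with a t reference, Poisson models with a normal reference — with
model-based variance available behind a flag.  Effect sizes are Cohen's d:
the arm effect on the response scale divided by the pooled weighted baseline
standard deviation.

The two-stage procedure fits every outcome twice — once restricted to the
primary site, once on the full sample — re-estimating nonresponse weights
within each analysis sample, intent-to-treat throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .composition import PROPORTION_MEASURES, composition_table
from .crosswave import CHANGE_FAMILIES, crosswave_table
from .model import (
    DegenerateOutcomeError,
    DomainError,
    InsufficientDataError,
)
from .weights import BoostingParams, weights_for_sample

__all__ = [
    "COUNT_MEASURES",
    "ModelResult",
    "fit_proportion_model",
    "fit_count_model",
    "cohens_d",
    "run_two_stage",
]

#: The 14 count-style outcomes (density is fitted linear but reported here).
COUNT_MEASURES = tuple(
    [f"{kind}_{fam}" for kind in ("stop", "start") for fam in CHANGE_FAMILIES]
    + [
        "total_unique_alters",
        "crosswave_density",
        "crosswave_components",
        "n_dropped",
        "n_added",
        "n_retained",
    ]
)


@dataclass
class ModelResult:
    """One fitted intervention-effect model."""

    outcome_name: str
    sample: str  # {"primary_site_only", "full"}
    family: str  # {"linear", "poisson"}
    estimate: float  # arm coefficient (response scale for linear, log for poisson)
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    n_egos: int
    n_control: int
    n_intervention: int
    irr: float | None = None
    irr_low: float | None = None
    irr_high: float | None = None
    cohens_d: float | None = None

    def __post_init__(self) -> None:
        assert self.ci_low <= self.estimate <= self.ci_high
        assert 0.0 <= self.p_value <= 1.0

    def to_dict(self) -> dict:
        return asdict(self)


def _design(arm: np.ndarray, baseline: np.ndarray | None, name: str) -> pd.DataFrame:
    """Intercept + arm + baseline covariate; a zero-variance baseline
    covariate carries no information and is dropped to keep the design
    full-rank (it would otherwise be collinear with the intercept)."""
    cols = {"const": np.ones_like(arm), "arm": arm}
    if baseline is not None and np.ptp(baseline) > 0:
        cols[name] = baseline
    return pd.DataFrame(cols)


def _check_arms(arm: np.ndarray, minimum: int = 3) -> tuple[int, int]:
    n1 = int(arm.sum())
    n0 = int(len(arm) - n1)
    if min(n0, n1) < minimum:
        raise InsufficientDataError(
            f"need at least {minimum} responders per arm, got control={n0}, intervention={n1}"
        )
    return n0, n1


def fit_proportion_model(
    outcome: np.ndarray,
    baseline: np.ndarray,
    arm: np.ndarray,
    weight: np.ndarray,
    outcome_name: str = "",
    sample: str = "full",
    robust: bool = True,
) -> ModelResult:
    """Weighted linear regression of a follow-up proportion on arm plus its
    baseline measure, with HC1 sandwich errors (t reference)."""
    arm = np.asarray(arm, dtype=float)
    n0, n1 = _check_arms(arm)
    X = _design(arm, np.asarray(baseline, dtype=float), "baseline")
    model = sm.WLS(np.asarray(outcome, dtype=float), X, weights=np.asarray(weight, dtype=float))
    res = model.fit(cov_type="HC1", use_t=True) if robust else model.fit()
    ci = res.conf_int()
    return ModelResult(
        outcome_name=outcome_name,
        sample=sample,
        family="linear",
        estimate=float(res.params["arm"]),
        se=float(res.bse["arm"]),
        ci_low=float(ci.loc["arm", 0]),
        ci_high=float(ci.loc["arm", 1]),
        p_value=float(res.pvalues["arm"]),
        n_egos=len(arm),
        n_control=n0,
        n_intervention=n1,
    )


def fit_count_model(
    outcome: np.ndarray,
    baseline_size: np.ndarray,
    arm: np.ndarray,
    weight: np.ndarray,
    outcome_name: str = "",
    sample: str = "full",
    robust: bool = True,
) -> ModelResult:
    """Weighted Poisson (log link) regression of a count on arm plus the
    baseline network size; the arm coefficient exponentiates to an IRR."""
    y = np.asarray(outcome, dtype=float)
    if np.any(y < 0):
        raise DomainError(f"{outcome_name}: count outcome must be nonnegative")
    if not np.any(y > 0):
        raise DegenerateOutcomeError(f"{outcome_name}: all-zero count outcome")
    arm = np.asarray(arm, dtype=float)
    n0, n1 = _check_arms(arm)
    X = _design(arm, np.asarray(baseline_size, dtype=float), "baseline_size")
    model = sm.GLM(y, X, family=sm.families.Poisson(), var_weights=np.asarray(weight, dtype=float))
    res = model.fit(cov_type="HC1") if robust else model.fit()
    ci = res.conf_int()
    est = float(res.params["arm"])
    lo, hi = float(ci.loc["arm", 0]), float(ci.loc["arm", 1])
    return ModelResult(
        outcome_name=outcome_name,
        sample=sample,
        family="poisson",
        estimate=est,
        se=float(res.bse["arm"]),
        ci_low=lo,
        ci_high=hi,
        p_value=float(res.pvalues["arm"]),
        n_egos=len(arm),
        n_control=n0,
        n_intervention=n1,
        irr=math.exp(est),
        irr_low=math.exp(lo),
        irr_high=math.exp(hi),
    )


def cohens_d(
    estimate: float,
    sd_control_baseline: float,
    sd_intervention_baseline: float,
    n_control: int,
    n_intervention: int,
) -> float:
    """|arm effect| standardized by the pooled baseline SD.

    pooled_sd = sqrt(((n1-1) s1^2 + (n2-1) s2^2) / (n1 + n2 - 2)).  For
    Poisson models pass a response-scale mean difference as ``estimate``.
    """
    s1, s2 = sd_control_baseline, sd_intervention_baseline
    n1, n2 = n_control, n_intervention
    if s1 < 0 or s2 < 0:
        raise DomainError("standard deviations must be nonnegative")
    if n1 < 2 or n2 < 2:
        raise DomainError("need at least 2 egos per arm for a pooled SD")
    pooled = math.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2))
    if pooled == 0:
        raise DomainError("pooled baseline SD is zero; d undefined")
    return abs(estimate) / pooled


def _wmean(x: np.ndarray, w: np.ndarray) -> float:
    return float(np.average(x, weights=w)) if len(x) else float("nan")


def _wsd(x: np.ndarray, w: np.ndarray) -> float:
    """Weighted SD with frequency-style normalization (weights sum ~ n)."""
    if len(x) < 2:
        return float("nan")
    m = np.average(x, weights=w)
    denom = w.sum() - 1.0
    if denom <= 0:
        return float("nan")
    return float(np.sqrt(np.sum(w * (x - m) ** 2) / denom))


def _poisson_response_scale_effect(res_est: float, intercept: float, b_size: float, size_mean: float) -> float:
    mu0 = math.exp(intercept + b_size * size_mean)
    mu1 = math.exp(intercept + res_est + b_size * size_mean)
    return mu1 - mu0


def run_two_stage(
    ego_df: pd.DataFrame,
    alter_df: pd.DataFrame,
    tie_df: pd.DataFrame,
    weight_method: str = "boosting",
    boosting_params: BoostingParams | None = None,
    flag_version: str = "ever",
    seed: int = 0,
    robust: bool = True,
    stages: tuple[str, ...] = ("primary_site_only", "full"),
) -> pd.DataFrame:
    """Fit all 16 proportion and 14 count models per analysis stage.

    Stage ``primary_site_only`` restricts to primary-site egos; ``full``
    uses everyone.  Nonresponse weights are re-estimated within each stage's
    intent-to-treat sample.  Returns one tidy row per outcome x stage with
    estimates, sandwich CIs, p-values, IRRs where applicable, Cohen's d, and
    the weighted descriptive means/SDs behind the report tables.
    """
    rows: list[dict] = []
    for stage in stages:
        if stage == "primary_site_only":
            sub = ego_df[ego_df["site"] == "primary_site"].reset_index(drop=True)
        elif stage == "full":
            sub = ego_df.reset_index(drop=True)
        else:
            raise DomainError(f"unknown stage {stage!r}")
        if sub.empty:
            raise InsufficientDataError(f"stage {stage}: empty analysis sample")
        ids = set(sub["ego_id"])
        a_sub = alter_df[alter_df["ego_id"].isin(ids)]
        t_sub = tie_df[tie_df["ego_id"].isin(ids)]
        wt, _bal = weights_for_sample(
            sub, a_sub, t_sub, method=weight_method, params=boosting_params, seed=seed
        )
        info = sub.merge(wt[["ego_id", "weight"]], on="ego_id")
        responders = info[info["weight"].notna()].copy()
        resp_ids = set(responders["ego_id"])

        comp = composition_table(a_sub)
        base = comp[comp["wave"] == "baseline"].set_index("ego_id")
        fu = comp[comp["wave"] == "followup"].set_index("ego_id")
        cross = crosswave_table(
            a_sub[a_sub["ego_id"].isin(resp_ids)],
            t_sub[t_sub["ego_id"].isin(resp_ids)],
            flag_version=flag_version,
        ).set_index("ego_id")

        r_ids = responders["ego_id"].to_numpy()
        arm = (responders["arm"] == "intervention").to_numpy(float)
        w = responders["weight"].to_numpy(float)
        is_int = arm == 1.0
        base_size = base.loc[r_ids, "n_alters"].to_numpy(float)

        for outcome in PROPORTION_MEASURES:
            yb = base.loc[r_ids, outcome].to_numpy(float)
            yf = fu.loc[r_ids, outcome].to_numpy(float)
            res = fit_proportion_model(
                yf, yb, arm, w, outcome_name=outcome, sample=stage, robust=robust
            )
            sd_c, sd_i = _wsd(yb[~is_int], w[~is_int]), _wsd(yb[is_int], w[is_int])
            try:
                res.cohens_d = cohens_d(res.estimate, sd_c, sd_i, res.n_control, res.n_intervention)
            except DomainError:
                res.cohens_d = float("nan")
            row = res.to_dict()
            row.update(
                mean_b_ctrl=_wmean(yb[~is_int], w[~is_int]), sd_b_ctrl=sd_c,
                mean_f_ctrl=_wmean(yf[~is_int], w[~is_int]), sd_f_ctrl=_wsd(yf[~is_int], w[~is_int]),
                mean_b_int=_wmean(yb[is_int], w[is_int]), sd_b_int=sd_i,
                mean_f_int=_wmean(yf[is_int], w[is_int]), sd_f_int=_wsd(yf[is_int], w[is_int]),
            )
            rows.append(row)

        for outcome in COUNT_MEASURES:
            y = cross.loc[r_ids, outcome].to_numpy(float)
            sd_c, sd_i = _wsd(y[~is_int], w[~is_int]), _wsd(y[is_int], w[is_int])
            if outcome == "crosswave_density":
                res = fit_proportion_model(
                    y, base_size, arm, w, outcome_name=outcome, sample=stage, robust=robust
                )
                effect = res.estimate
            else:
                try:
                    res = fit_count_model(
                        y, base_size, arm, w, outcome_name=outcome, sample=stage, robust=robust
                    )
                except DegenerateOutcomeError:
                    # keep the row inventory intact: report the outcome with
                    # no estimable effect rather than dropping it
                    rows.append(
                        dict(
                            outcome_name=outcome, sample=stage, family="poisson",
                            estimate=np.nan, se=np.nan, ci_low=np.nan, ci_high=np.nan,
                            p_value=np.nan, n_egos=len(arm), n_control=int((arm == 0).sum()),
                            n_intervention=int(arm.sum()), irr=np.nan, irr_low=np.nan,
                            irr_high=np.nan, cohens_d=np.nan,
                            mean_ctrl=_wmean(y[~is_int], w[~is_int]), sd_ctrl=sd_c,
                            mean_int=_wmean(y[is_int], w[is_int]), sd_int=sd_i,
                        )
                    )
                    continue
                # response-scale mean difference at the mean baseline size
                X = _design(arm, base_size, "baseline_size")
                glm = sm.GLM(y, X, family=sm.families.Poisson(), var_weights=w).fit()
                effect = _poisson_response_scale_effect(
                    float(glm.params["arm"]), float(glm.params["const"]),
                    float(glm.params.get("baseline_size", 0.0)), float(base_size.mean()),
                )
            try:
                res.cohens_d = cohens_d(effect, sd_c, sd_i, res.n_control, res.n_intervention)
            except DomainError:
                res.cohens_d = float("nan")
            row = res.to_dict()
            row.update(
                mean_ctrl=_wmean(y[~is_int], w[~is_int]), sd_ctrl=sd_c,
                mean_int=_wmean(y[is_int], w[is_int]), sd_int=sd_i,
            )
            rows.append(row)

    out = pd.DataFrame(rows)
    out["sig"] = np.where(
        out["p_value"] < 0.05, "*", np.where(out["p_value"] < 0.10, "~", "")
    )
    return out
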