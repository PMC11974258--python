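"""Linear-trend and group-by-time models for two-visit speech cohorts.

Each variable's change over visits is estimated with a linear mixed-effects
model: fixed effects for visit (0 = baseline, 1 = follow-up) plus age, sex,
education and the subject's inter-visit interval, and a random intercept per
subject, fit by REML.  The visit coefficient is the predicted per-interval
delta; its Wald test is the test for linear trend.  The group-by-time
interaction model adds group and group x visit fixed effects and reports the
omnibus Wald test of the interaction block.

The inter-visit interval enters as a subject-level covariate (the subject's
gap in months, constant across that subject's rows): coding it as
months-since-baseline would duplicate the visit indicator almost exactly.

When the random-intercept fit fails to converge or is singular, the model
falls back to ordinary least squares with cluster-robust (by subject)
standard errors, flagged in the result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "TrendResult",
    "InteractionResult",
    "fit_linear_trend",
    "fit_group_time_interaction",
    "trend_table",
]

DEFAULT_COVARIATES = ("age", "sex", "education", "interval")


@dataclass
class TrendResult:
    variable: str
    group: str
    delta: float
    se: float
    raw_p: float
    adj_p: float
    n_subjects: int
    converged: bool
    method: str  # "mixed" or "ols_cluster"


@dataclass
class InteractionResult:
    variable: str
    interaction_p: float
    group_slopes: dict[str, float]
    converged: bool
    method: str


def _with_interval(records: pd.DataFrame) -> pd.DataFrame:
    d = records.copy()
    iv = d.groupby("subject_id")["months_since_baseline"].transform("max")
    d["interval"] = iv
    return d


def _check_two_visits(d: pd.DataFrame, min_subjects: int) -> int:
    per_subject = d.groupby("subject_id")["visit"].nunique()
    complete = int((per_subject >= 2).sum())
    if complete < min_subjects:
        raise ValueError(
            f"need >= {min_subjects} subjects with both visits, have {complete}"
        )
    return complete


def _fit_mixed(formula: str, d: pd.DataFrame):
    """REML random-intercept fit with an OLS cluster-robust fallback."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = smf.mixedlm(formula, data=d, groups=d["subject_id"])
            fit = model.fit(reml=True, method="lbfgs")
            converged = bool(getattr(fit, "converged", True))
            singular = not np.isfinite(fit.bse).all()
            if converged and not singular:
                return fit, True, "mixed"
        except (np.linalg.LinAlgError, ValueError):
            pass
        fit = smf.ols(formula, data=d).fit(
            cov_type="cluster", cov_kwds={"groups": d["subject_id"]}
        )
        return fit, False, "ols_cluster"


def fit_linear_trend(
    records: pd.DataFrame,
    variable: str,
    group: str,
    *,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    n_groups_correction: int = 3,
    min_subjects: int = 5,
) -> TrendResult:
    """Per-group test for linear trend of ``variable`` across two visits.

    ``delta`` is the visit coefficient (units of the variable per follow-up
    interval); ``adj_p`` is Bonferroni over ``n_groups_correction`` groups.
    """
    d = _with_interval(records[records["group"] == group]).dropna(
        subset=[variable, *covariates]
    )
    n_subjects = _check_two_visits(d, min_subjects)
    rhs = " + ".join(["visit", *covariates])
    fit, mixed_ok, method = _fit_mixed(f"Q('{variable}') ~ {rhs}", d)
    delta = float(fit.params["visit"])
    se = float(fit.bse["visit"])
    raw_p = float(fit.pvalues["visit"])
    return TrendResult(
        variable=variable,
        group=group,
        delta=delta,
        se=se,
        raw_p=raw_p,
        adj_p=min(1.0, raw_p * n_groups_correction),
        n_subjects=n_subjects,
        converged=mixed_ok,
        method=method,
    )


def fit_group_time_interaction(
    records: pd.DataFrame,
    variable: str,
    *,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    min_subjects: int = 5,
) -> InteractionResult:
    """Omnibus group-by-time interaction across all groups with follow-up."""
    d = _with_interval(records).dropna(subset=[variable, *covariates])
    groups = sorted(d["group"].unique())
    if len(groups) < 2:
        raise ValueError("need >= 2 groups with longitudinal data")
    _check_two_visits(d, min_subjects)
    rhs = " + ".join(["C(group) * visit", *covariates])
    fit, mixed_ok, method = _fit_mixed(f"Q('{variable}') ~ {rhs}", d)
    inter_terms = [
        name for name in fit.params.index if ":visit" in name and "C(group)" in name
    ]
    if not inter_terms:
        raise RuntimeError("no interaction terms in fitted model")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        wt = fit.wald_test(
            [f"{t} = 0" for t in inter_terms], scalar=True, use_f=False
        )
    slopes = {groups[0]: float(fit.params["visit"])}
    for g in groups[1:]:
        term = next((t for t in inter_terms if f"[T.{g}]" in t), None)
        slopes[g] = float(fit.params["visit"] + (fit.params[term] if term else 0.0))
    return InteractionResult(
        variable=variable,
        interaction_p=float(wt.pvalue),
        group_slopes=slopes,
        converged=mixed_ok,
        method=method,
    )


def trend_table(
    records: pd.DataFrame,
    variables: list[str],
    *,
    groups: list[str] | None = None,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """Tidy per-variable x per-group trend summary with interaction p.

    One row per variable: per-group delta +/- SE and adjusted p, plus the
    omnibus group-by-time interaction p (the published table's layout).
    """
    gs = groups or sorted(records["group"].unique())
    rows = []
    for var in variables:
        row: dict[str, object] = {"variable": var}
        for g in gs:
            try:
                tr = fit_linear_trend(
                    records, var, g, covariates=covariates,
                    n_groups_correction=len(gs),
                )
                row[f"{g}_delta"] = tr.delta
                row[f"{g}_se"] = tr.se
                row[f"{g}_adj_p"] = tr.adj_p
            except ValueError:
                row[f"{g}_delta"] = np.nan
                row[f"{g}_se"] = np.nan
                row[f"{g}_adj_p"] = np.nan
        try:
            row["interaction_p"] = fit_group_time_interaction(
                records, var, covariates=covariates
            ).interaction_p
        except (ValueError, RuntimeError):
            row["interaction_p"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
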