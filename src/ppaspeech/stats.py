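"""Baseline group comparisons and SFS candidate preparation.

Covers the cross-sectional statistics: covariate-adjusted group comparisons
(ANCOVA with Bonferroni post hocs), the exact conditional test for 2 x k
category tables, robust outlier flagging, and the three-step variable
preparation (outlier audit -> group-difference screen -> multicollinearity
pruning) that defines the candidate set for the classification models.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.formula.api import ols

__all__ = [
    "GroupComparisonResult",
    "CandidateSet",
    "ancova_group_comparison",
    "fisher_exact_2xk",
    "flag_outliers",
    "select_candidates",
]

DEFAULT_COVARIATES = ("age", "sex", "education")


@dataclass
class GroupComparisonResult:
    variable: str
    omnibus_p: float
    omnibus_f: float
    pairwise: pd.DataFrame  # columns: group_a, group_b, raw_p, adj_p
    covariates: tuple[str, ...]
    n_groups: int


@dataclass
class CandidateSet:
    retained: list[str]
    dropped: dict[str, str]  # variable -> reason
    outlier_audit: dict[str, int] = field(default_factory=dict)
    provenance: dict[str, object] = field(default_factory=dict)

    def __post_init__(self):
        overlap = set(self.retained) & set(self.dropped)
        if overlap:
            raise ValueError(f"variables both retained and dropped: {sorted(overlap)}")


def _bonferroni_factor(n_groups: int, n_pairs: int, mode: str) -> int:
    # the published rule multiplies by the number of groups; the conventional
    # alternative multiplies by the number of pairwise contrasts
    if mode == "n_groups":
        return n_groups
    if mode == "n_pairs":
        return n_pairs
    raise ValueError(f"unknown bonferroni mode {mode!r}")


def ancova_group_comparison(
    table: pd.DataFrame,
    variable: str,
    group_col: str = "group",
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    *,
    bonferroni: str = "n_groups",
) -> GroupComparisonResult:
    """Linear model ``variable ~ group + covariates`` with pairwise post hocs.

    The omnibus p is the type-II F test for the group factor; pairwise
    contrasts use the full model's pooled error and are Bonferroni-adjusted
    by the number of groups (the published rule; ``bonferroni="n_pairs"``
    selects the conventional contrast-count rule).
    """
    d = table[[variable, group_col, *covariates]].dropna()
    groups = sorted(d[group_col].astype(str).unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    counts = d.groupby(group_col).size()
    if (counts < 3).any():
        small = counts[counts < 3].index.tolist()
        raise ValueError(f"groups with fewer than 3 subjects: {small}")
    constant = [c for c in covariates if d[c].nunique() <= 1]
    if constant:
        raise ValueError(f"rank-deficient design: constant covariates {constant}")

    cov_terms = " + ".join(covariates)
    formula = f"Q('{variable}') ~ C(Q('{group_col}'))"
    if cov_terms:
        formula += f" + {cov_terms}"
    fit = ols(formula, data=d).fit()
    aov = sm.stats.anova_lm(fit, typ=2)
    grp_row = next(ix for ix in aov.index if group_col in ix)
    omnibus_p = float(aov.loc[grp_row, "PR(>F)"])
    omnibus_f = float(aov.loc[grp_row, "F"])

    # pairwise contrasts on the group coefficients (treatment coding)
    param_names = list(fit.params.index)

    def coef_vector(g: str) -> np.ndarray:
        v = np.zeros(len(param_names))
        for i, name in enumerate(param_names):
            if name.endswith(f"[T.{g}]"):
                v[i] = 1.0
        return v

    pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1:]]
    factor = _bonferroni_factor(len(groups), len(pairs), bonferroni)
    rows = []
    for a, b in pairs:
        contrast = coef_vector(b) - coef_vector(a)
        raw = float(fit.t_test(contrast).pvalue)
        rows.append(
            {"group_a": a, "group_b": b, "raw_p": raw, "adj_p": min(1.0, raw * factor)}
        )
    return GroupComparisonResult(
        variable=variable,
        omnibus_p=omnibus_p,
        omnibus_f=omnibus_f,
        pairwise=pd.DataFrame(rows),
        covariates=tuple(covariates),
        n_groups=len(groups),
    )


def fisher_exact_2xk(counts) -> float:
    """Exact conditional p-value for a 2 x k table of non-negative counts.

    Delegates to scipy for 2 x 2; larger k uses full enumeration over tables
    with the observed margins (probability mass below or at the observed
    table's, the standard two-sided convention).
    """
    c = np.asarray(counts, dtype=np.int64)
    if c.ndim != 2 or c.shape[0] != 2:
        raise ValueError("expected a 2 x k table")
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    if (c.sum(axis=0) == 0).any() or (c.sum(axis=1) == 0).any():
        raise ValueError("empty margin")
    if c.shape[1] == 2:
        return float(sps.fisher_exact(c)[1])

    col = c.sum(axis=0)
    r1 = int(c.sum(axis=1)[0])
    n = int(c.sum())
    lgam = math.lgamma

    def log_comb(a: int, b: int) -> float:
        return lgam(a + 1) - lgam(b + 1) - lgam(a - b + 1)

    denom = log_comb(n, r1)

    def table_logp(x: tuple[int, ...]) -> float:
        return sum(log_comb(col[j], x[j]) for j in range(len(col))) - denom

    obs_logp = table_logp(tuple(int(v) for v in c[0]))
    total = 0.0
    k = len(col)

    def rec(j: int, remaining: int, acc: float):
        nonlocal total
        if j == k - 1:
            if 0 <= remaining <= col[j]:
                lp = acc + log_comb(col[j], remaining)
                if lp <= obs_logp + 1e-9:
                    total += math.exp(lp)
            return
        lo = max(0, remaining - int(col[j + 1:].sum()))
        hi = min(col[j], remaining)
        for x in range(lo, hi + 1):
            rec(j + 1, remaining - x, acc + log_comb(col[j], x))

    rec(0, r1, -denom)
    return min(1.0, total)


def flag_outliers(
    table: pd.DataFrame, variable: str, threshold: float = 3.0
) -> pd.Series:
    """Robust-z outlier flags (median/MAD, normal-consistent scale).

    Falls back to SD-based z with a warning when the MAD is zero; a constant
    column yields no flags (with a warning).  Never mutates the input.
    """
    x = table[variable]
    vals = x.dropna()
    if len(vals) < 5:
        raise ValueError(f"need >= 5 observations for outlier audit of {variable!r}")
    if vals.nunique() <= 1:
        warnings.warn(f"{variable}: constant column, no outliers flagged", stacklevel=2)
        return pd.Series(False, index=x.index)
    center = vals.median()
    scale = sps.median_abs_deviation(vals, scale="normal")
    if scale == 0:
        warnings.warn(
            f"{variable}: zero MAD, falling back to SD-based z", stacklevel=2
        )
        scale = vals.std(ddof=1)
    z = (x - center).abs() / scale
    return (z > threshold).fillna(False)


def select_candidates(
    table: pd.DataFrame,
    variables: list[str],
    *,
    group_col: str = "group",
    hc_group: str = "HC",
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    alpha: float = 0.05,
    r_threshold: float = 0.8,
    outlier_threshold: float = 3.0,
    bonferroni: str = "n_groups",
) -> CandidateSet:
    """Three-step candidate preparation for the classification models.

    1. Outlier audit per variable (robust z > threshold) — reported, never
       removed.
    2. Keep variables whose covariate-adjusted omnibus group effect is
       significant either patients-vs-controls or among the patient groups.
    3. Within each highly correlated pair (|Pearson r| >= ``r_threshold``
       among controls), drop the member with the smaller between-group
       omnibus F, recording the partner and r.

    Deterministic and invariant to row order; ties in step 3 break by the
    order of ``variables``.
    """
    hc = table[table[group_col] == hc_group]
    if len(hc) < 3:
        raise ValueError(f"fewer than 3 {hc_group!r} subjects")
    patients = table[table[group_col] != hc_group]

    audit: dict[str, int] = {}
    for v in variables:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                audit[v] = int(flag_outliers(table, v, outlier_threshold).sum())
        except ValueError:
            audit[v] = -1

    pv_table = table.copy()
    pv_table["_cohort"] = np.where(pv_table[group_col] == hc_group, "control", "patient")

    dropped: dict[str, str] = {}
    omnibus_f: dict[str, float] = {}
    survivors: list[str] = []
    for v in variables:
        sig = False
        try:
            r_all = ancova_group_comparison(
                pv_table, v, "_cohort", covariates, bonferroni=bonferroni
            )
            sig = sig or (np.isfinite(r_all.omnibus_p) and r_all.omnibus_p < alpha)
        except ValueError:
            pass
        f_between = np.nan
        try:
            r_pat = ancova_group_comparison(
                patients, v, group_col, covariates, bonferroni=bonferroni
            )
            sig = sig or (np.isfinite(r_pat.omnibus_p) and r_pat.omnibus_p < alpha)
            f_between = r_pat.omnibus_f
        except ValueError:
            pass
        try:
            f_full = ancova_group_comparison(
                table, v, group_col, covariates, bonferroni=bonferroni
            ).omnibus_f
        except ValueError:
            f_full = f_between
        omnibus_f[v] = f_full if np.isfinite(f_full) else 0.0
        if sig:
            survivors.append(v)
        else:
            dropped[v] = "no group difference"

    # step 3: multicollinearity among controls
    retained = list(survivors)
    if len(retained) > 1:
        corr = hc[retained].corr(method="pearson")
        pairs: list[tuple[float, str, str]] = []
        for i, a in enumerate(retained):
            for b in retained[i + 1:]:
                r = corr.loc[a, b]
                if np.isfinite(r) and abs(r) >= r_threshold:
                    pairs.append((abs(r), a, b))
        for _, a, b in sorted(pairs, reverse=True, key=lambda t: t[0]):
            if a not in retained or b not in retained:
                continue
            loser, keeper = (
                (a, b) if omnibus_f[a] < omnibus_f[b] else (b, a)
            )
            r = corr.loc[a, b]
            retained.remove(loser)
            dropped[loser] = f"multicollinear({keeper}, r={r:.3f})"

    return CandidateSet(
        retained=retained,
        dropped=dropped,
        outlier_audit=audit,
        provenance={
            "alpha": alpha,
            "r_threshold": r_threshold,
            "outlier_threshold": outlier_threshold,
            "bonferroni": bonferroni,
            "collinearity_group": hc_group,
            "tie_break": "larger omnibus F retained",
        },
    )
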