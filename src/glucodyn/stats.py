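"""Cohort-level statistics over the joined subject table.

Group comparisons (one-way ANOVA plus pairwise t-tests with Holm
adjustment), Spearman correlation matrices across the variability domains,
standardized multiple regression with collinearity diagnostics (VIF,
Durbin-Watson), TIR models over the covariate core model, and the paired
before/after comparison for therapy-change subgroups. The numerics are
delegated to scipy and statsmodels; this module fixes the conventions
(coding of sex and therapy, z-scoring, which family the Holm adjustment
spans) and the report shapes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.outliers_influence import variance_inflation_factor
from statsmodels.stats.stattools import durbin_watson

from glucodyn.errors import ComputationError, ParameterError

#: Covariates of the regression core model, in reporting order. ``sex`` is
#: coded 0/1 (M=1), ``therapy_code`` enters as a single ordinal numeric 1-4.
CORE_MODEL_TERMS = (
    "age",
    "sex",
    "diabetes_duration",
    "bmi",
    "carb_intake",
    "therapy_code",
)

DEFAULT_P_ENTER = 0.05


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupComparison:
    metric: str
    anova_f: float
    anova_p: float
    pairwise: pd.DataFrame  # columns: group_a, group_b, t_stat, p_raw, p_holm


def holm_adjust(p_values: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values (family-wise error control)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="holm")[1]


def compare_groups(
    table: pd.DataFrame, metric: str, group_col: str = "group"
) -> GroupComparison:
    """One-way ANOVA across groups plus Holm-adjusted pairwise t-tests.

    The Holm family spans all pairwise comparisons of the given metric.
    """
    groups = {g: sub[metric].dropna().to_numpy(dtype=float) for g, sub in table.groupby(group_col)}
    if len(groups) < 2:
        raise ParameterError("need at least 2 groups")
    for g, v in groups.items():
        if v.size < 2:
            raise ParameterError(f"group {g!r} has fewer than 2 subjects")
    f_stat, f_p = sps.f_oneway(*groups.values())
    rows = []
    for ga, gb in combinations(sorted(groups), 2):
        t_stat, p = sps.ttest_ind(groups[ga], groups[gb])
        rows.append({"group_a": ga, "group_b": gb, "t_stat": float(t_stat), "p_raw": float(p)})
    pairwise = pd.DataFrame(rows)
    pairwise["p_holm"] = holm_adjust(pairwise["p_raw"].to_numpy())
    return GroupComparison(
        metric=metric, anova_f=float(f_stat), anova_p=float(f_p), pairwise=pairwise
    )


def spearman_matrix(
    table: pd.DataFrame, columns: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman rank correlations (ties mid-ranked) with p-values.

    Returns ``(rho, p)`` as symmetric DataFrames with unit diagonal.
    """
    sub = table[columns].dropna()
    if len(sub) < 3:
        raise ParameterError("need at least 3 complete rows")
    k = len(columns)
    rho = np.eye(k)
    pmat = np.zeros((k, k))
    for i, j in combinations(range(k), 2):
        r, p = sps.spearmanr(sub[columns[i]], sub[columns[j]])
        rho[i, j] = rho[j, i] = r
        pmat[i, j] = pmat[j, i] = p
    return (
        pd.DataFrame(rho, index=columns, columns=columns),
        pd.DataFrame(pmat, index=columns, columns=columns),
    )


# ---------------------------------------------------------------------------
# regression
# ---------------------------------------------------------------------------

@dataclass
class RegressionReport:
    response: str
    terms: dict[str, tuple[float, float]]  # term -> (standardized beta, p)
    r2_adj: float
    vif: dict[str, float]
    durbin_watson: float
    n: int
    negative_r2_adj: bool = False
    notes: list[str] = field(default_factory=list)


def _encode_term(table: pd.DataFrame, term: str) -> pd.Series:
    col = table[term]
    if term == "sex":
        if col.dtype == object:
            return (col == "M").astype(float)
        return col.astype(float)
    if term == "therapy_code":
        return col.astype(float)
    s = col.astype(float)
    sd = s.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ParameterError(f"term {term!r} is constant")
    return (s - s.mean()) / sd


def standardized_regression(
    table: pd.DataFrame, response: str, terms: list[str]
) -> RegressionReport:
    """OLS of the z-scored response on z-scored continuous terms.

    Sex enters as 0/1 and therapy as the ordinal code 1-4 (not z-scored);
    all other terms and the response are z-scored, so a single continuous
    term's coefficient is its Pearson correlation with the response.
    Reports standardized betas, two-sided p-values, adjusted R^2, VIF per
    term, and the Durbin-Watson statistic of the residuals in table row
    order.
    """
    data = table.dropna(subset=[response, *terms])
    n = len(data)
    if n <= len(terms) + 2:
        raise ParameterError(f"need n > #terms + 2, got n={n} for {len(terms)} terms")
    y = data[response].astype(float)
    y_sd = y.std(ddof=1)
    if y_sd == 0:
        raise ComputationError(f"response {response!r} is constant")
    y = (y - y.mean()) / y_sd
    X = pd.DataFrame({t: _encode_term(data, t) for t in terms}, index=data.index)

    # perfect collinearity: name the offending terms rather than let OLS
    # silently drop rank
    corr = X.corr().to_numpy()
    for i, j in combinations(range(len(terms)), 2):
        if abs(corr[i, j]) > 1.0 - 1e-10:
            raise ParameterError(
                f"terms {terms[i]!r} and {terms[j]!r} are perfectly collinear"
            )
    exog = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(exog.to_numpy()) < exog.shape[1]:
        raise ParameterError(f"design matrix is rank deficient for terms {terms}")

    fit = sm.OLS(y.to_numpy(), exog.to_numpy()).fit()
    betas = dict(zip(exog.columns, fit.params))
    pvals = dict(zip(exog.columns, fit.pvalues))
    vif = {}
    if len(terms) == 1:
        vif[terms[0]] = 1.0
    else:
        arr = exog.to_numpy()
        for k, t in enumerate(terms, start=1):
            vif[t] = float(variance_inflation_factor(arr, k))
    r2_adj = float(fit.rsquared_adj)
    report = RegressionReport(
        response=response,
        terms={t: (float(betas[t]), float(pvals[t])) for t in terms},
        r2_adj=max(r2_adj, 0.0),
        vif=vif,
        durbin_watson=float(durbin_watson(fit.resid)),
        n=n,
        negative_r2_adj=r2_adj < 0,
    )
    if r2_adj < 0:
        report.notes.append(f"adjusted R^2 was negative ({r2_adj:.4f}); reported as 0")
    return report


def stepwise_forward(
    table: pd.DataFrame,
    response: str,
    candidates: list[str],
    keep: list[str] | None = None,
    p_enter: float = DEFAULT_P_ENTER,
) -> list[str]:
    """Forward selection: add the candidate with the smallest p < p_enter."""
    selected = list(keep or [])
    remaining = [c for c in candidates if c not in selected]
    while remaining:
        best, best_p = None, p_enter
        for cand in remaining:
            try:
                rep = standardized_regression(table, response, selected + [cand])
            except ParameterError:
                continue
            p = rep.terms[cand][1]
            if p < best_p:
                best, best_p = cand, p
        if best is None:
            break
        selected.append(best)
        remaining.remove(best)
    return selected


def tir_models(
    table: pd.DataFrame,
    index_column: str,
    subjects: str = "all",
    stepwise: bool = False,
    p_enter: float = DEFAULT_P_ENTER,
) -> RegressionReport:
    """TIR regressed on the covariate core model plus %CV and one index.

    ``subjects='patients'`` drops the non-diabetic group (relevant whenever
    diabetes duration is a term). With ``stepwise=True``, the core-model
    covariates are admitted by forward selection (p-to-enter ``p_enter``)
    while %CV and the index column are always kept.
    """
    data = table
    if subjects == "patients":
        data = table[table["group"] != "ND"]
    elif subjects != "all":
        raise ParameterError("subjects must be 'all' or 'patients'")
    if index_column == "cv_percent":
        raise ParameterError("index column coincides with %CV (perfect collinearity)")
    keep = ["cv_percent", index_column]
    if stepwise:
        terms = stepwise_forward(
            data, "tir_hours_per_day", list(CORE_MODEL_TERMS), keep=keep, p_enter=p_enter
        )
    else:
        terms = [*CORE_MODEL_TERMS, *keep]
    return standardized_regression(data, "tir_hours_per_day", terms)


# ---------------------------------------------------------------------------
# paired comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairedComparison:
    metric: str
    mean_difference: float  # mean(after - before)
    t_stat: float  # nan when the differences have zero variance
    p_value: float
    n: int
    zero_variance: bool = False


def paired_before_after(
    before: pd.DataFrame, after: pd.DataFrame, metric: str
) -> PairedComparison:
    """Two-sided paired t-test of ``metric`` between matched tables.

    Tables are aligned on ``subject_id`` and must contain the same subjects.
    Zero-variance differences (including degenerate single-row inputs) are
    flagged rather than raising; the mean difference is always reported.
    """
    b = before.set_index("subject_id")[metric].astype(float)
    a = after.set_index("subject_id")[metric].astype(float)
    if set(b.index) != set(a.index):
        raise ParameterError("before/after tables must contain the same subject ids")
    a = a.reindex(b.index)
    diff = (a - b).to_numpy()
    mean_diff = float(diff.mean())
    if diff.size < 2 or float(np.std(diff, ddof=1)) == 0.0:
        return PairedComparison(
            metric=metric,
            mean_difference=mean_diff,
            t_stat=float("nan"),
            p_value=float("nan"),
            n=diff.size,
            zero_variance=True,
        )
    t_stat, p = sps.ttest_rel(a.to_numpy(), b.to_numpy())
    return PairedComparison(
        metric=metric,
        mean_difference=mean_diff,
        t_stat=float(t_stat),
        p_value=float(p),
        n=diff.size,
    )
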