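"""Study design utilities: 1:1 propensity matching and baseline comparisons.

``propensity_match`` pairs each case with one distinct control by greedy
nearest-neighbour matching on the fitted propensity score (logistic
probability of case status given the matching covariates, e.g. age and
blood-collection time), processing cases in descending propensity order —
the hardest-to-match cases pick first.

``baseline_table`` reproduces the usual "Table 1": per continuous variable a
normality screen (Shapiro-Wilk at alpha = 0.05) selects an independent
t-test, a t-test on log-transformed values, or a Mann-Whitney U-test;
nominal variables get a chi-square test; an optional covariate-adjusted
p-value comes from a linear model of the (possibly log) variable on group
plus covariate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
import statsmodels.api as sm

EXACT_MW_MAX = 8  # exact Mann-Whitney enumeration up to this per-group size


def fit_propensity(covariates: pd.DataFrame, is_case: np.ndarray) -> np.ndarray:
    """Fitted probability of case status from a plain logistic regression."""
    X = np.asarray(covariates, dtype=float)
    if np.isnan(X).all(axis=0).any():
        raise ValueError("a matching covariate is entirely missing")
    col_mean = np.nanmean(X, axis=0)
    X = np.where(np.isnan(X), col_mean, X)
    model = LogisticRegression(C=1e12, max_iter=2000)  # effectively unpenalised
    model.fit(X, np.asarray(is_case, dtype=int))
    return model.predict_proba(X)[:, 1]


def propensity_match(cases: pd.DataFrame, pool: pd.DataFrame,
                     covariates: list[str], caliper: float | None = None
                     ) -> pd.DataFrame:
    """Greedy 1:1 nearest-neighbour matching without replacement.

    Parameters
    ----------
    cases, pool
        Sample metadata frames indexed by sample id, containing ``covariates``.
    covariates
        Column names used to fit the propensity model.
    caliper
        Optional maximum propensity distance; pairs beyond it are not formed
        (no caliper by default).

    Returns
    -------
    DataFrame with one row per matched pair: case_id, control_id,
    case_propensity, control_propensity, distance.
    """
    if len(pool) == 0:
        raise ValueError("control pool is empty")
    if len(pool) < len(cases):
        raise ValueError("control pool smaller than the case list")
    both = pd.concat([cases[covariates], pool[covariates]], axis=0)
    is_case = np.r_[np.ones(len(cases)), np.zeros(len(pool))]
    ps = fit_propensity(both, is_case)
    ps_case = pd.Series(ps[: len(cases)], index=cases.index)
    ps_pool = pd.Series(ps[len(cases):], index=pool.index)

    available = ps_pool.copy()
    rows = []
    for case_id in ps_case.sort_values(ascending=False, kind="stable").index:
        d = (available - ps_case[case_id]).abs()
        ctrl_id = d.idxmin()
        dist = float(d[ctrl_id])
        if caliper is not None and dist > caliper:
            continue
        rows.append({"case_id": case_id, "control_id": ctrl_id,
                     "case_propensity": float(ps_case[case_id]),
                     "control_propensity": float(available[ctrl_id]),
                     "distance": dist})
        available = available.drop(ctrl_id)
    return pd.DataFrame(rows)


def standardized_mean_difference(x_case, x_control) -> float:
    """SMD with pooled SD, the usual covariate-balance diagnostic."""
    x_case = np.asarray(x_case, dtype=float)
    x_control = np.asarray(x_control, dtype=float)
    pooled = np.sqrt((x_case.var(ddof=1) + x_control.var(ddof=1)) / 2.0)
    if pooled == 0:
        return 0.0
    return float((x_case.mean() - x_control.mean()) / pooled)


def mann_whitney_exact_or_normal(x, y) -> float:
    """Two-sided Mann-Whitney p: exact for small tie-free samples, else
    normal approximation with tie correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ties = len(np.unique(np.r_[x, y])) < len(x) + len(y)
    if min(len(x), len(y)) <= EXACT_MW_MAX and not ties:
        return float(stats.mannwhitneyu(x, y, alternative="two-sided",
                                        method="exact").pvalue)
    return float(stats.mannwhitneyu(x, y, alternative="two-sided",
                                    method="asymptotic").pvalue)


@dataclass
class BaselineRow:
    variable: str
    test: str                       # t | t_on_log | mann_whitney | chi_square | skipped
    summary_group1: str
    summary_group2: str
    p_value: float
    adjusted_p: float | None = None
    note: str = ""


def _mean_se(x: np.ndarray) -> str:
    return f"{x.mean():.2f} ± {x.std(ddof=1) / np.sqrt(len(x)):.2f}"


def _shapiro_normal(x: np.ndarray, alpha: float) -> bool:
    if len(np.unique(x)) < 3:
        return False
    return stats.shapiro(x).pvalue >= alpha


def baseline_table(data: pd.DataFrame, group_col: str,
                   continuous: list[str], nominal: list[str] | None = None,
                   adjust_for: str | None = None,
                   shapiro_alpha: float = 0.05) -> pd.DataFrame:
    """Per-variable two-group comparison report (mean ± SE / counts, p, test).

    Group means ± SE are always reported on the raw scale even when the test
    ran on log values.  With ``adjust_for`` set, an additional p-value for the
    group term from a linear model ``variable ~ group + covariate`` is added
    (the variable enters on the same scale the primary test used).
    """
    nominal = nominal or []
    levels = sorted(pd.unique(data[group_col]))
    if len(levels) != 2:
        raise ValueError("baseline_table requires exactly two groups")
    g1 = data[data[group_col] == levels[0]]
    g2 = data[data[group_col] == levels[1]]
    rows: list[BaselineRow] = []

    for var in continuous:
        x1 = g1[var].dropna().to_numpy(dtype=float)
        x2 = g2[var].dropna().to_numpy(dtype=float)
        if len(x1) < 2 or len(x2) < 2:
            rows.append(BaselineRow(var, "skipped", "", "", np.nan,
                                    note="fewer than 2 samples in a group"))
            continue
        if x1.var(ddof=1) == 0 and x2.var(ddof=1) == 0:
            rows.append(BaselineRow(var, "skipped", _mean_se(x1), _mean_se(x2),
                                    np.nan, note="zero variance"))
            continue
        positive = (x1 > 0).all() and (x2 > 0).all()
        use_scale = None
        if _shapiro_normal(x1, shapiro_alpha) and _shapiro_normal(x2, shapiro_alpha):
            test, use_scale = "t", "raw"
        elif positive and _shapiro_normal(np.log(x1), shapiro_alpha) \
                and _shapiro_normal(np.log(x2), shapiro_alpha):
            test, use_scale = "t_on_log", "log"
        else:
            test, use_scale = "mann_whitney", "log" if positive else "raw"

        if test == "t":
            p = float(stats.ttest_ind(x1, x2, equal_var=True).pvalue)
        elif test == "t_on_log":
            p = float(stats.ttest_ind(np.log(x1), np.log(x2), equal_var=True).pvalue)
        else:
            p = mann_whitney_exact_or_normal(x1, x2)

        adj = None
        if adjust_for is not None and adjust_for != var:
            sub = data[[var, group_col, adjust_for]].dropna()
            yv = sub[var].to_numpy(dtype=float)
            if use_scale == "log" and (yv > 0).all():
                yv = np.log(yv)
            X = sm.add_constant(np.column_stack([
                (sub[group_col] == levels[1]).to_numpy(dtype=float),
                sub[adjust_for].to_numpy(dtype=float)]))
            fit = sm.OLS(yv, X).fit()
            adj = float(fit.pvalues[1])
        rows.append(BaselineRow(var, test, _mean_se(x1), _mean_se(x2), p, adj))

    for var in nominal:
        tab = pd.crosstab(data[group_col], data[var])
        if tab.shape[1] < 2:
            rows.append(BaselineRow(var, "skipped", "", "", np.nan,
                                    note="single category"))
            continue
        chi2 = stats.chi2_contingency(tab.to_numpy())
        cnt = lambda g: ", ".join(f"{c}:{n}" for c, n in
                                  pd.crosstab(g[group_col], g[var]).iloc[0].items())
        rows.append(BaselineRow(var, "chi_square", cnt(g1), cnt(g2),
                                float(chi2.pvalue)))

    out = pd.DataFrame([r.__dict__ for r in rows])
    bad = out["p_value"].dropna()
    assert ((bad >= 0) & (bad <= 1)).all()
    return out
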