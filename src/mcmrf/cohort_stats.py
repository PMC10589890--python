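"""Cohort-level statistics on regional fraction volumes.

Group comparisons use an ordinary least-squares linear model (Gaussian
family, identity link) of the form

    volume ~ group + age + sex,

with group coded control = 0, patient = 1, so a positive group coefficient
means a larger volume in patients.  Severity associations use a partial
Spearman correlation (rank-transform both variables and the covariates, then
correlate OLS rank residuals) with a Fisher-z confidence interval.  Method
agreement between the fraction-derived and lesion-map volumes uses a paired
t-test.  No multiple-testing correction is applied (tests are reported at
alpha = 0.05 individually).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "glm_group",
    "partial_spearman",
    "paired_volumes_test",
    "secondary_regressions",
]


def _design_matrix(table: pd.DataFrame, columns: list[str]) -> np.ndarray:
    """Numeric design columns; two-level categoricals become 0/1 indicators."""
    cols = []
    for name in columns:
        col = table[name]
        if col.dtype == object or str(col.dtype) == "category":
            levels = sorted(col.dropna().unique())
            if len(levels) > 2:
                raise ValueError(f"column {name!r} has more than two levels")
            cols.append((col == levels[-1]).astype(float).to_numpy())
        else:
            cols.append(col.astype(float).to_numpy())
    return np.column_stack(cols)


def _check_full_rank(x: np.ndarray, names: list[str]) -> None:
    if np.linalg.matrix_rank(x) < x.shape[1]:
        # name the first column whose removal restores full column rank
        for j in range(x.shape[1]):
            reduced = np.delete(x, j, axis=1)
            if np.linalg.matrix_rank(reduced) == np.linalg.matrix_rank(x):
                raise ValueError(f"design matrix is rank deficient: column {names[j]!r} is collinear")
        raise ValueError("design matrix is rank deficient")


def glm_group(
    table: pd.DataFrame,
    region: str,
    covariates: tuple[str, ...] = ("age_years", "sex"),
    group_col: str = "group",
) -> dict[str, float]:
    """Group difference in a region's volume, adjusted for covariates.

    ``table`` needs the volume column ``region``, a two-level ``group``
    column with values 'control'/'patient', and the covariate columns.
    Returns the group coefficient b (patient minus control, on the volume
    scale), its Wald 95% CI and p-value.
    """
    data = table.dropna(subset=[region, group_col, *covariates])
    groups = data[group_col]
    n_per = groups.value_counts()
    if len(n_per) != 2 or n_per.min() < 3:
        raise ValueError("need at least 3 subjects in each of two groups")
    g = (groups == "patient").astype(float).to_numpy()
    covs = _design_matrix(data, list(covariates))
    # constant covariates carry no information and drop out (so the model
    # degenerates gracefully to a two-sample comparison)
    keep = [j for j in range(covs.shape[1]) if np.ptp(covs[:, j]) > 0]
    covs = covs[:, keep]
    kept_names = [covariates[j] for j in keep]
    x = np.column_stack([np.ones(len(data)), g, covs])
    _check_full_rank(x, ["intercept", "group", *kept_names])
    fit = sm.OLS(data[region].astype(float).to_numpy(), x).fit()
    ci = fit.conf_int(alpha=0.05)
    return {
        "b": float(fit.params[1]),
        "ci95": (float(ci[1][0]), float(ci[1][1])),
        "p": float(fit.pvalues[1]),
        "n": int(len(data)),
    }


def partial_spearman(
    table: pd.DataFrame,
    x: str,
    y: str,
    covariates: tuple[str, ...] = ("site",),
) -> dict[str, float]:
    """Partial Spearman correlation of x and y given covariates.

    All variables are rank-transformed (average ranks for ties); x and y
    ranks are residualized on the covariate ranks by OLS and the Pearson
    correlation of the residuals is reported, with a Fisher-z 95% CI and
    p-value on n - 2 - k degrees of freedom.  Constant covariates drop out,
    so with a single-level covariate this is ordinary Spearman correlation.
    """
    data = table.dropna(subset=[x, y, *covariates])
    n = len(data)
    if n < 5:
        raise ValueError("need at least 5 complete cases")
    xv = data[x].astype(float).to_numpy()
    yv = data[y].astype(float).to_numpy()
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise ValueError("x and y must not be constant")
    rx = stats.rankdata(xv)
    ry = stats.rankdata(yv)
    cov_cols = _design_matrix(data, list(covariates))
    cov_ranks = np.column_stack([stats.rankdata(c) for c in cov_cols.T])
    keep = [j for j in range(cov_ranks.shape[1]) if np.ptp(cov_ranks[:, j]) > 0]
    k = len(keep)
    z = np.column_stack([np.ones(n)] + [cov_ranks[:, j] for j in keep])
    res_x = rx - z @ np.linalg.lstsq(z, rx, rcond=None)[0]
    res_y = ry - z @ np.linalg.lstsq(z, ry, rcond=None)[0]
    rho = float(np.corrcoef(res_x, res_y)[0, 1])
    dof = n - 2 - k
    rho_c = np.clip(rho, -1 + 1e-15, 1 - 1e-15)
    if abs(rho_c) >= 1:
        p = 0.0
    else:
        t = rho_c * np.sqrt(dof / (1 - rho_c**2))
        p = float(2 * stats.t.sf(abs(t), dof))
    se = 1.0 / np.sqrt(max(n - 3 - k, 1))
    zr = np.arctanh(rho_c)
    ci = (float(np.tanh(zr - 1.959963984540054 * se)), float(np.tanh(zr + 1.959963984540054 * se)))
    return {"rho": rho, "ci95": ci, "p": p, "n": n}


def paired_volumes_test(
    table: pd.DataFrame, a: str, b: str
) -> dict[str, float]:
    """Two-sided paired t-test of volume columns a - b.

    Identically zero differences return t = p = NaN with mean_diff 0 (the
    degenerate "methods agree exactly" convention); constant non-zero
    differences have no sampling variance and raise instead.
    """
    data = table.dropna(subset=[a, b])
    if len(data) < 3:
        raise ValueError("need at least 3 paired complete cases")
    diff = data[a].astype(float).to_numpy() - data[b].astype(float).to_numpy()
    if np.ptp(diff) == 0:
        if diff[0] == 0:
            return {"t": np.nan, "p": np.nan, "mean_diff": 0.0, "n": len(diff)}
        raise ValueError("paired differences have zero variance")
    t, p = stats.ttest_rel(data[a].astype(float), data[b].astype(float))
    return {"t": float(t), "p": float(p), "mean_diff": float(diff.mean()), "n": len(diff)}


def secondary_regressions(
    table: pd.DataFrame,
    outcome: str,
    predictors: tuple[str, ...] = ("edss", "disease_duration_years", "age_years", "sex"),
) -> pd.DataFrame:
    """One-at-a-time linear regressions of the outcome on each predictor.

    Returns a tidy coefficient table (predictor, b, ci_low, ci_high, p, n,
    r_squared); rows for predictors with too few complete cases are omitted.
    """
    rows = []
    for pred in predictors:
        data = table.dropna(subset=[outcome, pred])
        if len(data) < 3:
            continue
        xp = _design_matrix(data, [pred])
        x = np.column_stack([np.ones(len(data)), xp])
        _check_full_rank(x, ["intercept", pred])
        fit = sm.OLS(data[outcome].astype(float).to_numpy(), x).fit()
        ci = fit.conf_int(alpha=0.05)
        rows.append(
            {
                "predictor": pred,
                "b": float(fit.params[1]),
                "ci_low": float(ci[1][0]),
                "ci_high": float(ci[1][1]),
                "p": float(fit.pvalues[1]),
                "n": int(len(data)),
                "r_squared": float(fit.rsquared),
            }
        )
    return pd.DataFrame(rows)
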