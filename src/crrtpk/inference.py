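"""Statistical layer: group comparisons, factorial ANOVA, stepwise regression.

Fits are delegated to statsmodels OLS.  ANOVA tables use Type II sums of
squares (identical to Type I/III on the balanced bench design, robust to the
one unbalanced comparison where the dilution split is only varied at 2 L/h).
Estimated marginal means average model predictions over an equal-weight grid
of the off-factors' levels, with t-based intervals on the residual df.
Tukey's HSD uses the studentized-range distribution with the fitted model's
residual mean square as the error term.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

__all__ = [
    "FactorialDesign",
    "RegressionFit",
    "AnovaResult",
    "two_sample_t",
    "factorial_anova",
    "tukey_hsd",
    "backward_stepwise",
]


@dataclass
class FactorialDesign:
    """Response + coded circuit factors for one analysis.

    ``data`` must contain the response column and every factor column.
    Factors used categorically are handled via patsy ``C()`` in the ANOVA;
    the stepwise regression treats them as the numeric codes supplied.
    """

    data: pd.DataFrame
    response: str = "cl_tm"
    factors: Sequence[str] = ("mode", "filter", "flow", "dilution")

    def __post_init__(self) -> None:
        missing = [c for c in (self.response, *self.factors) if c not in self.data]
        if missing:
            raise ValueError(f"design data missing columns: {missing}")

    def is_balanced(self, factors: Optional[Sequence[str]] = None) -> bool:
        factors = list(factors or self.factors)
        counts = self.data.groupby(factors, dropna=False).size()
        return counts.nunique() == 1


@dataclass
class RegressionFit:
    """Final model of a backward-stepwise multiple linear regression."""

    params: pd.Series
    conf_int: pd.DataFrame  # columns [lower, upper]
    pvalues: pd.Series
    r2: float
    adjusted_r2: float
    retained: list[str]
    dropped: list[str]  # in removal order
    vif: pd.Series  # variance inflation factors of retained covariates
    tolerance: pd.Series
    nobs: int
    results: object = field(repr=False, default=None)  # statsmodels results

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        Xd = sm.add_constant(X[self.retained], has_constant="add")
        return np.asarray(Xd @ self.params.reindex(Xd.columns))


@dataclass
class AnovaResult:
    table: pd.DataFrame  # term, sum_sq, df, F, PR(>F)
    marginal_means: pd.DataFrame
    tukey: Optional[pd.DataFrame]
    r2: float
    adjusted_r2: float
    residual_df: float
    results: object = field(repr=False, default=None)


def two_sample_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Classical two-sided pooled-variance (Student) t-test.

    Degenerate zero-variance input: p = 1 when the means agree, p → 0
    otherwise (t = ±inf).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 values")
    n1, n2 = len(x), len(y)
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    diff = x.mean() - y.mean()
    if sp2 == 0:
        if diff == 0:
            return 0.0, 1.0
        return float(np.sign(diff) * np.inf), 0.0
    t = diff / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2 * stats.t.sf(abs(t), n1 + n2 - 2)
    return float(t), float(p)


def _anova_formula(response: str, factors: Sequence[str], interactions: int) -> str:
    terms = [f"C({f})" for f in factors]
    rhs = " + ".join(terms)
    if interactions >= 2:
        for order in range(2, min(interactions, len(factors)) + 1):
            for combo in itertools.combinations(terms, order):
                rhs += " + " + ":".join(combo)
    return f"{response} ~ {rhs}"


def factorial_anova(
    design: FactorialDesign,
    factors: Optional[Sequence[str]] = None,
    interactions: int = 1,
    emm_factors: Optional[Sequence[str]] = None,
    tukey_factor: Optional[str] = None,
    alpha: float = 0.05,
) -> AnovaResult:
    """Factorial ANOVA with estimated marginal means and optional Tukey HSD.

    Parameters
    ----------
    factors
        Subset of design factors to model (default: all).
    interactions
        Highest interaction order to include (1 = main effects only).
    emm_factors
        Factors defining the marginal-mean cells (default: the modeled
        factors jointly).
    tukey_factor
        Single factor for Tukey HSD pairwise comparisons, using the model's
        residual mean square as error term.
    """
    factors = list(factors or design.factors)
    df = design.data.dropna(subset=[design.response]).copy()
    degenerate_response = df[design.response].astype(float).var() == 0.0
    formula = _anova_formula(design.response, factors, interactions)
    model = smf.ols(formula, data=df).fit()
    if model.df_resid < 1:
        raise ValueError(
            f"saturated model (no residual df) — drop an interaction: {formula}"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = anova_lm(model, typ=2)
    # degenerate zero-variance responses: define F = 0, p = 1, R² = 0
    degenerate = table["F"].isna() & (table.index != "Residual")
    if degenerate_response:
        degenerate |= table.index != "Residual"
    table.loc[degenerate, "F"] = 0.0
    table.loc[degenerate, "PR(>F)"] = 1.0

    n = int(model.nobs)
    p = int(model.df_model)
    r2 = 0.0 if degenerate_response else float(model.rsquared)
    adj = float(model.rsquared_adj) if n - p - 1 > 0 and not degenerate_response else 0.0
    if not np.isfinite(adj):
        adj = 0.0

    emm = _marginal_means(model, df, factors, list(emm_factors or factors), alpha)

    tk = None
    if tukey_factor is not None:
        tk = tukey_hsd(
            df[design.response].to_numpy(),
            df[tukey_factor].to_numpy(),
            mse=float(model.mse_resid),
            df_resid=float(model.df_resid),
        )
    return AnovaResult(
        table=table,
        marginal_means=emm,
        tukey=tk,
        r2=r2,
        adjusted_r2=adj,
        residual_df=float(model.df_resid),
        results=model,
    )


def _marginal_means(
    model, df: pd.DataFrame, factors: list[str], emm_factors: list[str], alpha: float
) -> pd.DataFrame:
    """emmeans-style cell means: average prediction over the equal-weight
    grid of off-factor levels; SE from the coefficient covariance."""
    from patsy import build_design_matrices

    levels = {f: sorted(df[f].dropna().unique()) for f in factors}
    off = [f for f in factors if f not in emm_factors]
    design_info = model.model.data.design_info
    cov = np.asarray(model.cov_params())
    params = np.asarray(model.params)
    tcrit = stats.t.ppf(1 - alpha / 2, model.df_resid)

    rows = []
    for cell in itertools.product(*(levels[f] for f in emm_factors)):
        grid = pd.DataFrame(
            [
                {**dict(zip(emm_factors, cell)), **dict(zip(off, offvals))}
                for offvals in itertools.product(*(levels[f] for f in off))
            ]
            or [dict(zip(emm_factors, cell))]
        )
        (X,) = build_design_matrices([design_info], grid)
        L = np.asarray(X).mean(axis=0)
        mean = float(L @ params)
        se = float(np.sqrt(L @ cov @ L))
        rows.append(
            {
                **dict(zip(emm_factors, cell)),
                "emmean": mean,
                "se": se,
                "ci_lower": mean - tcrit * se,
                "ci_upper": mean + tcrit * se,
            }
        )
    return pd.DataFrame(rows)


def tukey_hsd(
    values: np.ndarray,
    groups: np.ndarray,
    mse: Optional[float] = None,
    df_resid: Optional[float] = None,
) -> pd.DataFrame:
    """Tukey(-Kramer) HSD pairwise comparisons.

    By default the error term is the one-way residual mean square; pass
    ``mse``/``df_resid`` from a fitted factorial model to use its residual
    instead (the convention adopted for the mixed 2 L/h-only comparisons).
    """
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    labels = sorted(pd.unique(groups).tolist())
    k = len(labels)
    if k < 2:
        raise ValueError("need at least two groups")
    by = {g: values[groups == g] for g in labels}
    if mse is None or df_resid is None:
        n_tot = len(values)
        df_resid = n_tot - k
        mse = sum(((v - v.mean()) ** 2).sum() for v in by.values()) / df_resid
    rows = []
    for g1, g2 in itertools.combinations(labels, 2):
        m1, m2 = by[g1].mean(), by[g2].mean()
        se = np.sqrt(mse / 2 * (1 / len(by[g1]) + 1 / len(by[g2])))
        q = abs(m1 - m2) / se if se > 0 else np.inf
        p = float(stats.studentized_range.sf(q, k, df_resid))
        rows.append(
            {"group1": g1, "group2": g2, "diff": m1 - m2, "q": float(q), "p": p}
        )
    return pd.DataFrame(rows)


def backward_stepwise(
    design: FactorialDesign,
    candidates: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
) -> RegressionFit:
    """Backward-stepwise multiple linear regression.

    Starting from all candidate covariates, iteratively removes the one with
    the largest p-value above ``alpha`` (ties broken toward the covariate
    listed last) and refits, until every retained covariate has p ≤ alpha.
    Reports 95% CIs, adjusted R² and collinearity diagnostics (VIF and
    tolerance) of the final model.
    """
    candidates = list(candidates or design.factors)
    df = design.data.dropna(subset=[design.response]).copy()
    if len(df) < len(candidates) + 2:
        raise ValueError("need at least candidates + 2 observations")
    y = df[design.response].astype(float)

    retained = list(candidates)
    dropped: list[str] = []
    while retained:
        X = sm.add_constant(df[retained].astype(float), has_constant="add")
        res = sm.OLS(y, X).fit()
        pvals = res.pvalues.drop("const")
        worst_p = pvals.max()
        if worst_p <= alpha or not np.isfinite(worst_p):
            if not np.isfinite(worst_p):
                # perfectly collinear leftovers: drop the last-listed one
                worst = [c for c in retained if not np.isfinite(pvals[c])][-1]
                retained.remove(worst)
                dropped.append(worst)
                continue
            break
        # ties: remove the covariate listed last in candidate order
        worst_set = [c for c in retained if pvals[c] >= worst_p - 1e-12]
        worst = worst_set[-1]
        retained.remove(worst)
        dropped.append(worst)

    if not retained:
        warnings.warn("all candidates removed; returning intercept-only fit", stacklevel=2)
    X = sm.add_constant(df[retained].astype(float) if retained else pd.DataFrame(index=df.index), has_constant="add")
    res = sm.OLS(y, X).fit()

    if retained:
        from statsmodels.stats.outliers_influence import variance_inflation_factor

        Xv = np.asarray(X)
        vif = pd.Series(
            [
                variance_inflation_factor(Xv, i)
                for i in range(1, Xv.shape[1])
            ]
            if Xv.shape[1] > 2
            else [1.0] * len(retained),
            index=retained,
            dtype=float,
        )
    else:
        vif = pd.Series(dtype=float)
    tol = 1.0 / vif if len(vif) else pd.Series(dtype=float)

    ci = res.conf_int()
    ci.columns = ["lower", "upper"]
    n, p = int(res.nobs), len(retained)
    adj = 1 - (1 - res.rsquared) * (n - 1) / (n - p - 1) if n - p - 1 > 0 else np.nan
    return RegressionFit(
        params=res.params,
        conf_int=ci,
        pvalues=res.pvalues,
        r2=float(res.rsquared),
        adjusted_r2=float(adj),
        retained=retained,
        dropped=dropped,
        vif=vif,
        tolerance=tol,
        nobs=n,
        results=res,
    )
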