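"""Univariable screen, multicollinearity filter and multivariable logistic
regression for membership in the high-risk class.

Conventions: the screen keeps variables with p < 0.1 (configurable); pairs
with |Pearson r| > 0.7 (continuous) or Cramer's V > 0.7 (categorical) are
resolved by dropping the later-listed member; continuous variables enter the
models untransformed (per-unit odds ratios).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

SCREEN_P = 0.1
COLLINEARITY_THRESHOLD = 0.7
_Z95 = 1.959963984540054


@dataclass
class VariableFit:
    variable: str
    kind: str                      # "continuous" | "categorical"
    coef: float | None
    se: float | None
    odds_ratio: float | None
    ci_low: float | None
    ci_high: float | None
    p: float | None                # Wald p (continuous/binary) or LR p (categorical)
    n: int
    converged: bool
    flag: str | None = None        # "zero_variance" | "separation" | None


@dataclass
class LogisticFit:
    """Multivariable fit: one row per model term, Table-3 conventions."""

    terms: pd.DataFrame            # variable, coef, se, odds_ratio, ci_low, ci_high, p
    converged: bool
    n: int
    warnings: list[str] = field(default_factory=list)


def _is_categorical(series: pd.Series) -> bool:
    return series.dtype == object or isinstance(series.dtype, pd.CategoricalDtype)


def _fit_logit(y: np.ndarray, X: np.ndarray):
    """MLE logistic fit; returns (result, separation_flag)."""
    model = sm.Logit(y, X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(disp=0, maxiter=200)
        except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError):
            return None, True
    separated = (not res.mle_retvals.get("converged", False)) or bool(
        np.any(np.abs(res.params) > 30) or np.any(~np.isfinite(res.bse))
    )
    return res, separated


def univariate_screen(
    data: pd.DataFrame, target: str, variables: list[str]
) -> pd.DataFrame:
    """One single-predictor non-conditional logistic fit per variable.

    Categorical variables are reference-coded and summarized by a
    likelihood-ratio p-value; zero-variance predictors are flagged rather
    than fitted.  Returns a table with one row per variable.
    """
    y_all = data[target]
    rows = []
    for var in variables:
        sub = data[[var, target]].dropna()
        y = sub[target].to_numpy(dtype=float)
        x = sub[var]
        n = len(sub)
        kind = "categorical" if _is_categorical(x) else "continuous"
        base = VariableFit(var, kind, None, None, None, None, None, None, n, False)
        if n == 0 or x.nunique() < 2 or y_all.nunique() < 2 or len(np.unique(y)) < 2:
            base.flag = "zero_variance"
            rows.append(base)
            continue
        if kind == "categorical":
            dummies = pd.get_dummies(x, drop_first=True, dtype=float)
            X = sm.add_constant(dummies.to_numpy())
            res, separated = _fit_logit(y, X)
            if res is None or separated:
                base.flag = "separation"
                rows.append(base)
                continue
            null = sm.Logit(y, np.ones((n, 1))).fit(disp=0)
            lr = 2 * (res.llf - null.llf)
            base.p = float(stats.chi2.sf(lr, dummies.shape[1]))
            base.converged = True
        else:
            X = sm.add_constant(x.to_numpy(dtype=float))
            res, separated = _fit_logit(y, X)
            if res is None or separated:
                base.flag = "separation"
                rows.append(base)
                continue
            coef, se = float(res.params[1]), float(res.bse[1])
            base.coef = coef
            base.se = se
            base.odds_ratio = float(np.exp(coef))
            base.ci_low = float(np.exp(coef - _Z95 * se))
            base.ci_high = float(np.exp(coef + _Z95 * se))
            base.p = float(res.pvalues[1])
            base.converged = True
        rows.append(base)
    return pd.DataFrame([r.__dict__ for r in rows])


def cramers_v(x: pd.Series, y: pd.Series) -> float:
    """Cramer's V association between two categorical series."""
    table = pd.crosstab(x, y)
    if table.size == 0 or min(table.shape) < 2:
        return 0.0
    chi2 = stats.chi2_contingency(table, correction=False)[0]
    n = table.to_numpy().sum()
    return float(np.sqrt(chi2 / (n * (min(table.shape) - 1))))


def multicollinearity_filter(
    data: pd.DataFrame,
    variables: list[str],
    threshold: float = COLLINEARITY_THRESHOLD,
) -> tuple[list[str], list[tuple[str, str, float]]]:
    """Greedy collinearity pruning in listed order.

    For each pair (earlier, later) of retained variables with association
    above ``threshold`` (|Pearson r| for continuous pairs, Cramer's V for
    categorical pairs; mixed pairs are not tested), the later-listed member
    is dropped.  Returns (retained, [(kept, dropped, association), ...]).
    """
    retained: list[str] = []
    dropped: list[tuple[str, str, float]] = []
    for var in variables:
        clash = None
        for kept in retained:
            sub = data[[kept, var]].dropna()
            if len(sub) < 3:
                continue
            a_cat = _is_categorical(sub[kept])
            b_cat = _is_categorical(sub[var])
            if a_cat and b_cat:
                assoc = cramers_v(sub[kept], sub[var])
            elif not a_cat and not b_cat:
                assoc = abs(
                    float(np.corrcoef(sub[kept].astype(float), sub[var].astype(float))[0, 1])
                )
            else:
                continue
            if np.isfinite(assoc) and assoc > threshold:
                clash = (kept, var, assoc)
                break
        if clash is None:
            retained.append(var)
        else:
            dropped.append(clash)
    return retained, dropped


def multivariable_logistic(
    data: pd.DataFrame, target: str, variables: list[str]
) -> LogisticFit:
    """Maximum-likelihood multivariable logistic fit with per-term odds
    ratios, Wald 95% CIs and p-values.  Emits a sample-size warning when
    n <= 10 x number of predictors."""
    if not variables:
        raise ValueError("retained variable set is empty")
    sub = data[variables + [target]].dropna()
    y = sub[target].to_numpy(dtype=float)
    design_cols: list[str] = []
    pieces = []
    for var in variables:
        if _is_categorical(sub[var]):
            dummies = pd.get_dummies(sub[var], prefix=var, drop_first=True, dtype=float)
            pieces.append(dummies)
            design_cols.extend(dummies.columns)
        else:
            pieces.append(sub[[var]].astype(float))
            design_cols.append(var)
    X = pd.concat(pieces, axis=1).to_numpy(dtype=float)
    n, k = X.shape
    warns: list[str] = []
    if n <= 10 * k:
        msg = f"n={n} with {k} predictors: fewer than 10 observations per predictor"
        warns.append(msg)
        warnings.warn(msg)
    res, separated = _fit_logit(y, sm.add_constant(X))
    if res is None:
        raise RuntimeError("logistic fit failed (singular or separated design)")
    if separated:
        warns.append("possible separation / non-convergence; estimates unreliable")
    coefs = np.asarray(res.params[1:], dtype=float)
    ses = np.asarray(res.bse[1:], dtype=float)
    terms = pd.DataFrame(
        {
            "variable": design_cols,
            "coef": coefs,
            "se": ses,
            "odds_ratio": np.exp(coefs),
            "ci_low": np.exp(coefs - _Z95 * ses),
            "ci_high": np.exp(coefs + _Z95 * ses),
            "p": np.asarray(res.pvalues[1:], dtype=float),
        }
    )
    return LogisticFit(terms=terms, converged=not separated, n=n, warnings=warns)


def screen_then_fit(
    data: pd.DataFrame,
    target: str,
    variables: list[str],
    screen_p: float = SCREEN_P,
    collinearity_threshold: float = COLLINEARITY_THRESHOLD,
) -> tuple[pd.DataFrame, list[str], LogisticFit | None]:
    """The study's screening pipeline: univariable p < ``screen_p``, then
    collinearity pruning, then the multivariable fit (None when no variable
    survives)."""
    screen = univariate_screen(data, target, variables)
    candidates = [
        r.variable
        for r in screen.itertuples()
        if r.p is not None and np.isfinite(r.p) and r.p < screen_p
    ]
    retained, _dropped = multicollinearity_filter(
        data, candidates, threshold=collinearity_threshold
    )
    fit = multivariable_logistic(data, target, retained) if retained else None
    return screen, retained, fit
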