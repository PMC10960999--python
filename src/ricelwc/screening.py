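"""Covariate screening and regression diagnostics.

Pearson correlation matrices with per-cell significance stars (uncorrected,
two-sided t tests), descriptive statistics, mean +/- 3 SD outlier flags,
Shapiro-Wilk normality checks, collinearity (tolerance and VIF from
auxiliary regressions) and the Durbin-Watson statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .records import ValidationError

logger = logging.getLogger("ricelwc")

DEFAULT_SCREEN_VARIABLES = ["LWC", "biomass", "LAI", "CWSI", "SPAD", "Fo",
                            "FvFm", "YII"]


def pcc_matrix(obs: pd.DataFrame, variables: list[str] | None = None
               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Pearson correlation matrix plus significance marks.

    Returns ``(r, sig)`` frames; ``sig`` holds '' / '*' / '**' for two-sided
    p below 5% / 1%.  Zero-variance variables are masked (NaN row/column)
    and logged.
    """
    variables = variables or [v for v in DEFAULT_SCREEN_VARIABLES if v in obs.columns]
    k = len(variables)
    r = pd.DataFrame(np.eye(k), index=variables, columns=variables)
    sig = pd.DataFrame("", index=variables, columns=variables)
    for i, a in enumerate(variables):
        for j, b in enumerate(variables):
            if j <= i:
                continue
            pair = obs[[a, b]].dropna()
            if len(pair) < 3:
                raise ValidationError(f"fewer than 3 complete rows for ({a}, {b})")
            x, y = pair[a].to_numpy(float), pair[b].to_numpy(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                logger.info("pcc_matrix: zero-variance variable in pair (%s, %s); masked", a, b)
                r.loc[a, b] = r.loc[b, a] = np.nan
                continue
            rv, p = stats.pearsonr(x, y)
            r.loc[a, b] = r.loc[b, a] = rv
            mark = "**" if p < 0.01 else ("*" if p < 0.05 else "")
            sig.loc[a, b] = sig.loc[b, a] = mark
    return r, sig


def select_covariates(obs: pd.DataFrame, covariates: list[str],
                      k: int = 3, target: str = "LWC",
                      stage_column: str = "stage") -> pd.DataFrame:
    """Rank covariates by |Pearson r| with the target, averaged over stages.

    Returns the top-k covariates with their per-stage and mean correlations;
    the sign of r is preserved in the report.  Ties are broken by name.
    """
    stages = obs[stage_column].unique()
    rows = []
    for cov in covariates:
        per_stage = {}
        for st in stages:
            sub = obs[obs[stage_column] == st][[target, cov]].dropna()
            rv, _ = stats.pearsonr(sub[target], sub[cov])
            per_stage[st] = rv
        rows.append({"covariate": cov, **{f"r_{s}": v for s, v in per_stage.items()},
                     "mean_abs_r": np.mean([abs(v) for v in per_stage.values()]),
                     "mean_r": np.mean(list(per_stage.values()))})
    ranked = (pd.DataFrame(rows)
              .sort_values(["mean_abs_r", "covariate"], ascending=[False, True])
              .reset_index(drop=True))
    return ranked.head(k) if k is not None else ranked


def descriptive_stats(obs: pd.DataFrame, variables: list[str]) -> pd.DataFrame:
    """Max/min/mean/SD (n-1 denominator) and CV = SD/mean per variable.

    CV is NaN (masked) when the mean is zero.
    """
    rows = []
    for v in variables:
        x = obs[v].dropna().to_numpy(float)
        if x.size == 0:
            raise ValidationError(f"no data for {v}")
        sd = x.std(ddof=1) if x.size > 1 else 0.0
        mean = x.mean()
        rows.append({"variable": v, "max": x.max(), "min": x.min(),
                     "mean": mean, "sd": sd,
                     "cv": sd / mean if mean != 0 else np.nan})
    return pd.DataFrame(rows)


def flag_outliers(obs: pd.DataFrame, variables: list[str], n_sd: float = 3.0,
                  rule: str = "sd") -> pd.Series:
    """Flag rows with any variable beyond mean +/- n_sd SD (default) or,
    with ``rule='iqr'``, outside 1.5*IQR of the quartiles."""
    flags = pd.Series(False, index=obs.index)
    for v in variables:
        x = obs[v].astype(float)
        if rule == "sd":
            mu, sd = x.mean(), x.std(ddof=1)
            if sd == 0 or np.isnan(sd):
                continue
            flags |= (x - mu).abs() > n_sd * sd
        elif rule == "iqr":
            q1, q3 = x.quantile([0.25, 0.75])
            iqr = q3 - q1
            flags |= (x < q1 - 1.5 * iqr) | (x > q3 + 1.5 * iqr)
        else:
            raise ValueError(f"unknown outlier rule {rule!r}")
    return flags


def normality_check(values) -> tuple[float, float]:
    """Shapiro-Wilk statistic and p-value (reported, never enforced)."""
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 3:
        raise ValidationError("normality check needs n >= 3")
    if np.ptp(x) == 0:
        raise ValidationError("normality check undefined for constant input")
    stat, p = stats.shapiro(x)
    return float(stat), float(p)


@dataclass(frozen=True)
class CollinearityRow:
    predictor: str
    tolerance: float
    vif: float
    perfect: bool  # exactly collinear with the other predictors


def collinearity(X: pd.DataFrame) -> list[CollinearityRow]:
    """Tolerance (1 - R^2_j) and VIF (1/tolerance) for each predictor,
    where R^2_j comes from regressing predictor j on the others plus an
    intercept.  Perfect collinearity yields VIF = inf with a flag."""
    cols = list(X.columns)
    if len(cols) < 2:
        raise ValidationError("collinearity needs >= 2 predictors")
    if len(X) <= len(cols):
        raise ValidationError("need more rows than predictors")
    out = []
    A = X.to_numpy(float)
    for j, name in enumerate(cols):
        y = A[:, j]
        others = np.column_stack([np.ones(len(X)), np.delete(A, j, axis=1)])
        coef, _, _, _ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ coef
        sst = np.sum((y - y.mean()) ** 2)
        r2j = 1.0 - np.sum(resid ** 2) / sst if sst > 0 else 1.0
        tol = 1.0 - r2j
        if tol <= 1e-12:
            out.append(CollinearityRow(name, 0.0, np.inf, True))
        else:
            out.append(CollinearityRow(name, tol, 1.0 / tol, False))
    return out


def durbin_watson(residuals) -> float:
    """Durbin-Watson statistic sum((e_t - e_{t-1})^2)/sum(e_t^2); approx 2
    for independent residuals.  Ordering is the caller's responsibility
    (the pipeline sorts rows by year, site, plot_id)."""
    e = np.asarray(residuals, dtype=float)
    if e.size < 2:
        raise ValidationError("Durbin-Watson needs >= 2 residuals")
    denom = np.sum(e ** 2)
    if denom == 0:
        raise ValidationError("Durbin-Watson undefined for all-zero residuals")
    return float(np.sum(np.diff(e) ** 2) / denom)
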