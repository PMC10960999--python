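"""Stage-wise ND-LWC lines, the quadratic slope/intercept analysis, and the
coupled two-predictor multiple linear regression models.

The coupled model is LWC = b0 + b1*ND + b2*cov + e for one physiological
covariate (CWSI, Fv/Fm or SPAD), fit per growth stage on one year and
validated on the other year.  The stage-line slope a and intercept b of the
single-index model are additionally regressed (quadratically) on stage-mean
covariates, the descriptive analysis that motivates the coupling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .metrics import metrics
from .records import ValidationError


@dataclass
class StageLinearModel:
    """Single-index model LWC = a*ND + b for one growth stage."""

    stage: str
    a: float
    b: float
    r2_fit: float
    rmse_fit: float
    n_train: int
    r2_pred: float | None = None
    rmse_pred: float | None = None
    n_valid: int = 0

    def predict(self, nd) -> np.ndarray:
        return self.a * np.asarray(nd, dtype=float) + self.b


@dataclass(frozen=True)
class QuadraticRelation:
    """Quadratic trend of a stage-line parameter against a stage-mean covariate."""

    target: str      # "slope_a" | "intercept_b"
    covariate: str
    c2: float
    c1: float
    c0: float
    r2: float
    saturated: bool  # True when points == parameters (r2 = 1 trivially)


@dataclass
class CoupledModel:
    """Two-predictor MLR: LWC = b0 + b1*ND + b2*covariate."""

    stage: str
    covariate: str
    coefficients: dict[str, float]      # const, ND, <covariate>
    model_r2: float
    rmse_fit: float
    n_train: int
    prediction_r2: float | None = None
    rmse_pred: float | None = None
    n_valid: int = 0
    conf_int: dict[str, tuple[float, float]] = field(default_factory=dict)

    def predict(self, nd, cov) -> np.ndarray:
        return (self.coefficients["const"]
                + self.coefficients["ND"] * np.asarray(nd, dtype=float)
                + self.coefficients[self.covariate] * np.asarray(cov, dtype=float))


def fit_stage_line(nd, lwc, stage: str = "", nd_valid=None, lwc_valid=None
                   ) -> StageLinearModel:
    """OLS of LWC on ND; validation metrics (against the 1:1 line) are
    computed when a held-out set is supplied."""
    nd = np.asarray(nd, dtype=float)
    lwc = np.asarray(lwc, dtype=float)
    if nd.size < 3:
        raise ValidationError(f"need >= 3 training samples, got {nd.size}")
    if np.ptp(nd) == 0:
        raise ValidationError("ND constant across training samples")
    a, b = np.polyfit(nd, lwc, 1)
    fit = metrics(lwc, a * nd + b)
    model = StageLinearModel(stage=stage, a=float(a), b=float(b),
                             r2_fit=fit["r2"], rmse_fit=fit["rmse"], n_train=nd.size)
    if nd_valid is not None:
        pred = metrics(np.asarray(lwc_valid, float), model.predict(nd_valid))
        model.r2_pred, model.rmse_pred = pred["r2"], pred["rmse"]
        model.n_valid = np.asarray(nd_valid).size
    return model


def slope_intercept_analysis(stage_models: list[StageLinearModel],
                             stage_covariates: pd.DataFrame
                             ) -> list[QuadraticRelation]:
    """Least-squares quadratic of each of {slope a, intercept b} on each
    stage-mean covariate column of ``stage_covariates`` (indexed by stage).

    With three stages the fit is saturated (r2 = 1 by construction); with
    four there is a single residual degree of freedom, so no significance
    claim is attached in either case.
    """
    if len(stage_models) < 3:
        raise ValidationError("need >= 3 stages for the quadratic analysis")
    stages = [m.stage for m in stage_models]
    a_vals = np.array([m.a for m in stage_models])
    b_vals = np.array([m.b for m in stage_models])
    out = []
    for cov in stage_covariates.columns:
        x = stage_covariates.loc[stages, cov].to_numpy(float)
        for target, y in [("slope_a", a_vals), ("intercept_b", b_vals)]:
            c2, c1, c0 = np.polyfit(x, y, 2)
            pred = np.polyval([c2, c1, c0], x)
            ss_tot = np.sum((y - y.mean()) ** 2)
            r2 = 1.0 if ss_tot == 0 else 1.0 - np.sum((y - pred) ** 2) / ss_tot
            out.append(QuadraticRelation(target=target, covariate=cov,
                                         c2=float(c2), c1=float(c1), c0=float(c0),
                                         r2=float(r2), saturated=len(stages) == 3))
    return out


def fit_coupled(train: pd.DataFrame, valid: pd.DataFrame | None,
                covariate: str, stage: str = "",
                nd_column: str = "ND", target: str = "LWC") -> CoupledModel:
    """Fit LWC = b0 + b1*ND + b2*covariate on ``train`` and validate on
    ``valid`` (typically the other study year).  Coefficient 95% confidence
    intervals come from the OLS fit."""
    for df, name in [(train, "training"), (valid, "validation")]:
        if df is not None and len(df) == 0:
            raise ValidationError(f"{name} partition is empty; with single-year data "
                                  "use a random split instead of the year rule")
    X = sm.add_constant(train[[nd_column, covariate]].to_numpy(float))
    fit = sm.OLS(train[target].to_numpy(float), X).fit()
    names = ["const", "ND", covariate]
    coefs = dict(zip(names, fit.params))
    ci = fit.conf_int(alpha=0.05)
    model = CoupledModel(
        stage=stage, covariate=covariate, coefficients=coefs,
        model_r2=float(fit.rsquared),
        rmse_fit=float(np.sqrt(np.mean(fit.resid ** 2))),
        n_train=len(train),
        conf_int={n: (float(lo), float(hi)) for n, (lo, hi) in zip(names, ci)})
    if valid is not None:
        pred = model.predict(valid[nd_column], valid[covariate])
        m = metrics(valid[target].to_numpy(float), pred)
        model.prediction_r2, model.rmse_pred = m["r2"], m["rmse"]
        model.n_valid = len(valid)
    return model


def year_split(obs: pd.DataFrame, train_year: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition observations into (train_year rows, all other years)."""
    train = obs[obs["year"] == train_year]
    valid = obs[obs["year"] != train_year]
    if len(train) == 0 or len(valid) == 0:
        raise ValidationError(
            f"year split {train_year} leaves an empty partition; "
            "use a random split for single-year data")
    return train, valid


def compare_models(single: StageLinearModel, coupled: list[CoupledModel]
                   ) -> pd.DataFrame:
    """Delta R^2 and relative improvement of each coupled model over the
    single-index line, for both the model fit and the validation."""
    rows = []
    for cm in coupled:
        if cm.stage != single.stage or cm.n_train != single.n_train:
            raise ValidationError("compared models must share stage and samples")
        row = {"stage": cm.stage, "covariate": cm.covariate,
               "r2_single": single.r2_fit, "r2_coupled": cm.model_r2,
               "delta_r2_model": cm.model_r2 - single.r2_fit,
               "rel_improvement_model_pct":
                   100.0 * (cm.model_r2 - single.r2_fit) / single.r2_fit
                   if single.r2_fit else np.nan}
        if single.r2_pred is not None and cm.prediction_r2 is not None:
            row["delta_r2_pred"] = cm.prediction_r2 - single.r2_pred
            row["rel_improvement_pred_pct"] = (
                100.0 * (cm.prediction_r2 - single.r2_pred) / single.r2_pred
                if single.r2_pred else np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
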