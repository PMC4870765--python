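"""Outcome-model fitting and the change-in-estimate statistic.

For each outcome family the exposure effect is estimated by maximum
likelihood — least squares for continuous outcomes, logistic regression for
binary, and the Cox partial likelihood for censored survival times — with
Wald standard errors and p-values.  Coefficients are converted to the
reporting scale theta: the raw coefficient for continuous outcomes, the
hazard ratio exp(b) for survival, and the odds ratio exp(b) for binary,
with an optional odds-ratio-to-risk-ratio conversion

    RR = OR / (1 - p0 + p0 * OR)

given a baseline risk p0.  The change in estimate when a covariate enters
the model is Delta = |(theta_0 - theta_Z) / theta_0|.

The Cox fit is a bespoke Newton-Raphson solver on the Breslow partial
likelihood.  The simulation harness performs tens of thousands of fits per
calibration, so the solver is written directly on cumulative sums over the
risk sets; it is validated against lifelines in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit

from .config import FAMILIES
from .cohort_sim import Cohort
from .exceptions import (
    DegenerateOutcomeError,
    InvalidParameterError,
    MissingParameterError,
    UndefinedCIEError,
    UnsupportedFamilyError,
)


@dataclass
class EffectEstimate:
    """Fitted exposure effect from an adjusted or unadjusted model."""

    family: str
    adjusted: bool
    beta_hat: float
    se_beta: float
    p_exposure: float
    theta_hat: float
    converged: bool = True
    p_confounder: Optional[float] = None
    beta_confounder: Optional[float] = None
    intercept: Optional[float] = None
    n: int = 0

    @property
    def baseline_risk(self) -> Optional[float]:
        """Model-implied baseline risk expit(intercept); binary family only."""
        if self.family != "binary" or self.intercept is None:
            return None
        return float(expit(self.intercept))

    def theta(self, scale: Optional[str] = None) -> float:
        """Effect on a requested reporting scale.

        ``scale`` defaults to the family's native scale (coefficient / OR /
        HR); ``"rr"`` converts the binary odds ratio to a risk ratio at the
        model-implied baseline risk.
        """
        if scale is None or scale in ("coef", "or", "hr"):
            return self.theta_hat
        if scale == "rr":
            if self.family != "binary":
                raise InvalidParameterError("rr scale applies to the binary family only")
            return effect_scale(self.beta_hat, "binary", baseline_risk=self.baseline_risk)
        raise InvalidParameterError(f"unknown effect scale {scale!r}")


def _fit_cox_newton(time, event, X, max_iter=50, tol=1e-9):
    """Newton-Raphson on the Breslow partial likelihood.

    Subjects are sorted by descending time so each risk set is a prefix;
    ties (e.g. all administratively censored subjects) share risk sets via
    a right-side search over the sorted times.
    """
    n, p = X.shape
    order = np.argsort(-time, kind="stable")
    t = time[order]
    d = event[order].astype(bool)
    Xs = X[order]
    idx = np.searchsorted(-t, -t, side="right") - 1
    ii = idx[d]
    Xd = Xs[d]
    beta = np.zeros(p)
    converged = False
    info = np.eye(p)
    for _ in range(max_iter):
        eta = Xs @ beta
        eta -= eta.max()
        w = np.exp(eta)
        S0 = np.cumsum(w)
        S1 = np.cumsum(w[:, None] * Xs, axis=0)
        S2 = np.cumsum(w[:, None, None] * (Xs[:, :, None] * Xs[:, None, :]), axis=0)
        xbar = S1[ii] / S0[ii, None]
        grad = (Xd - xbar).sum(axis=0)
        info = (S2[ii] / S0[ii, None, None] - xbar[:, :, None] * xbar[:, None, :]).sum(axis=0)
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if not np.all(np.isfinite(beta)):
            converged = False
            break
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
        converged = False
    return beta, se, converged


def fit_exposure_model(
    outcome,
    exposure,
    covariate=None,
    family: str = "continuous",
) -> EffectEstimate:
    """Fit the outcome model with the exposure and an optional covariate.

    Returns the exposure coefficient, its Wald p-value and the effect on the
    family's native reporting scale; when a covariate is supplied its Wald
    p-value is recorded as ``p_confounder``.
    """
    if family not in FAMILIES:
        raise UnsupportedFamilyError(f"unknown outcome family {family!r}")
    exposure = np.asarray(exposure, dtype=float)
    n = len(exposure)
    adjusted = covariate is not None
    if adjusted:
        covariate = np.asarray(covariate, dtype=float)
        if len(covariate) != n:
            raise InvalidParameterError("exposure and covariate lengths differ")

    if family == "survival":
        outcome = np.asarray(outcome, dtype=float)
        time, event = outcome[:, 0], outcome[:, 1]
        X = np.column_stack([exposure, covariate]) if adjusted else exposure[:, None]
        beta, se, converged = _fit_cox_newton(time, event, X)
        zstat = beta / se
        pvals = 2.0 * stats.norm.sf(np.abs(zstat))
        return EffectEstimate(
            family=family, adjusted=adjusted,
            beta_hat=float(beta[0]), se_beta=float(se[0]),
            p_exposure=float(pvals[0]),
            theta_hat=float(np.exp(beta[0])),
            converged=bool(converged),
            p_confounder=float(pvals[1]) if adjusted else None,
            beta_confounder=float(beta[1]) if adjusted else None,
            n=n,
        )

    y = np.asarray(outcome, dtype=float)
    if len(y) != n:
        raise InvalidParameterError("outcome and exposure lengths differ")
    cols = [np.ones(n), exposure]
    if adjusted:
        cols.append(covariate)
    X = np.column_stack(cols)

    if family == "continuous":
        res = sm.OLS(y, X).fit()
        converged = True
    else:
        classes = np.unique(y)
        if len(classes) < 2:
            raise DegenerateOutcomeError("binary outcome has a single class")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=100)
            converged = bool(res.mle_retvals.get("converged", True))
        except Exception:
            return EffectEstimate(
                family=family, adjusted=adjusted,
                beta_hat=float("nan"), se_beta=float("nan"),
                p_exposure=float("nan"), theta_hat=float("nan"),
                converged=False,
                p_confounder=float("nan") if adjusted else None,
                n=n,
            )
        if not np.all(np.isfinite(res.bse)):
            converged = False

    beta_x = float(res.params[1])
    theta = beta_x if family == "continuous" else float(np.exp(beta_x))
    return EffectEstimate(
        family=family, adjusted=adjusted,
        beta_hat=beta_x, se_beta=float(res.bse[1]),
        p_exposure=float(res.pvalues[1]),
        theta_hat=theta,
        converged=converged,
        p_confounder=float(res.pvalues[2]) if adjusted else None,
        beta_confounder=float(res.params[2]) if adjusted else None,
        intercept=float(res.params[0]),
        n=n,
    )


def fit_cohort_models(cohort: Cohort):
    """Convenience: (unadjusted, adjusted) fits on the observed variables."""
    unadj = fit_exposure_model(cohort.outcome, cohort.x_obs, None, cohort.family)
    adj = fit_exposure_model(cohort.outcome, cohort.x_obs, cohort.z_obs, cohort.family)
    return unadj, adj


def effect_scale(
    beta_hat: float,
    family: str,
    baseline_risk: Optional[float] = None,
) -> float:
    """Convert a linear-predictor coefficient to the reporting effect theta.

    Identity for continuous; exp(beta) for survival (hazard ratio) and for
    binary (odds ratio) — unless ``baseline_risk`` p0 is given for the
    binary family, in which case the odds ratio is converted to a risk
    ratio via RR = OR / (1 - p0 + p0*OR).
    """
    if family not in FAMILIES:
        raise UnsupportedFamilyError(f"unknown outcome family {family!r}")
    if family == "continuous":
        return float(beta_hat)
    theta = float(math.exp(beta_hat))
    if family == "binary" and baseline_risk is not None:
        if not 0 < baseline_risk < 1:
            raise InvalidParameterError("baseline risk must be in (0,1)")
        theta = theta / (1.0 - baseline_risk + baseline_risk * theta)
    return theta


def odds_to_risk_ratio(odds_ratio: float, baseline_risk: Optional[float]) -> float:
    """RR corresponding to an OR at baseline risk p0."""
    if baseline_risk is None:
        raise MissingParameterError("baseline risk required for the OR -> RR conversion")
    if not 0 < baseline_risk < 1:
        raise InvalidParameterError("baseline risk must be in (0,1)")
    return odds_ratio / (1.0 - baseline_risk + baseline_risk * odds_ratio)


def change_in_estimate(theta_unadjusted: float, theta_adjusted: float) -> float:
    """Delta = |(theta_0 - theta_Z) / theta_0|, the relative CIE."""
    if theta_unadjusted == 0:
        raise UndefinedCIEError("change in estimate undefined: unadjusted effect is zero")
    return abs((theta_unadjusted - theta_adjusted) / theta_unadjusted)


def reporting_theta(est: EffectEstimate, binary_scale: str = "rr") -> float:
    """Effect on the scale used for CIE and RMSE summaries.

    Continuous: coefficient.  Survival: hazard ratio.  Binary: risk ratio by
    default (converted at the model-implied baseline risk), or the odds
    ratio when ``binary_scale="or"``.
    """
    if est.family == "binary" and binary_scale == "rr":
        return est.theta("rr")
    return est.theta_hat
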