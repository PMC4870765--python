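"""The decision layer: screening plus the five identification strategies.

A pure risk factor (associated with the outcome, independent of the
exposure in the population) can move the exposure estimate in a finite
sample — confounding by chance — and simulated CIE rules flag such
covariates at high rates.  The two-stage procedure first screens the
observed exposure-covariate correlation with a Pearson test and only
evaluates a covariate further (by any of the five strategies) when the
no-correlation hypothesis is rejected:

* ``p05`` / ``p20``   adjust when the covariate's Wald p-value <= 0.05 / 0.20
* ``cie10``           adjust when Delta >= 0.10
* ``cie_sim_type1``   adjust when Delta >= simulated type-I cutoff
* ``cie_sim_type2``   adjust when Delta >= simulated type-II cutoff

Thresholds are boundary-inclusive (adjust when Delta >= delta_c, p <= cutoff).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import stats

from .cie_calibration import CutoffResult, delta_from_estimates
from .cohort_sim import Cohort
from .config import STRATEGIES
from .effect_models import EffectEstimate, fit_cohort_models, reporting_theta
from .exceptions import (
    DegenerateInputError,
    InvalidParameterError,
    MissingParameterError,
    UndefinedCIEError,
)

_P_CUTOFFS = {"p05": 0.05, "p20": 0.20}


@dataclass
class Decision:
    """Outcome of one confounder-identification run for one candidate."""

    strategy: str
    screened_out: bool
    adjust: bool
    final_theta: float
    delta_observed: Optional[float] = None
    cutoff_used: Optional[float] = None
    screen_r: Optional[float] = None
    screen_p: Optional[float] = None

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "strategy", "screened_out", "adjust", "final_theta",
            "delta_observed", "cutoff_used", "screen_r", "screen_p",
        )}


def screen_correlation(
    x_obs, z_obs, alpha: float = 0.05
) -> Tuple[bool, float, float]:
    """Pearson-correlation pre-test between observed exposure and covariate.

    Returns ``(keep, r, p)`` where ``keep`` is True when the two-sided
    t-test rejects zero correlation at ``alpha`` (boundary inclusive) —
    i.e. the covariate stays in contention as a structural confounder.
    """
    x_obs = np.asarray(x_obs, dtype=float)
    z_obs = np.asarray(z_obs, dtype=float)
    if len(x_obs) != len(z_obs) or len(x_obs) < 3:
        raise InvalidParameterError("inputs must have equal length >= 3")
    if not 0 < alpha < 1:
        raise InvalidParameterError(f"alpha must be in (0,1), got {alpha}")
    if np.ptp(x_obs) == 0 or np.ptp(z_obs) == 0:
        raise DegenerateInputError("zero-variance input in correlation screen")
    r, p = stats.pearsonr(x_obs, z_obs)
    return bool(p <= alpha), float(r), float(p)


def apply_strategy(
    strategy: str,
    unadj: EffectEstimate,
    adj: EffectEstimate,
    cutoff: Optional[CutoffResult] = None,
    binary_scale: str = "rr",
) -> Decision:
    """Apply one identification rule to a fitted model pair."""
    if strategy not in STRATEGIES:
        raise InvalidParameterError(f"unknown strategy {strategy!r}")

    theta0 = reporting_theta(unadj, binary_scale)
    thetaz = reporting_theta(adj, binary_scale)

    delta: Optional[float] = None
    cutoff_used: Optional[float] = None
    if strategy in _P_CUTOFFS:
        if adj.p_confounder is None:
            raise MissingParameterError("adjusted fit lacks the confounder p-value")
        cutoff_used = _P_CUTOFFS[strategy]
        adjust = adj.p_confounder <= cutoff_used
    else:
        if strategy == "cie10":
            cutoff_used = 0.10
        else:
            if cutoff is None:
                raise MissingParameterError(f"strategy {strategy} requires a calibrated cutoff")
            cutoff_used = cutoff.delta_c
        if theta0 == 0:
            raise UndefinedCIEError("unadjusted effect is zero; CIE undefined")
        delta = delta_from_estimates(unadj, adj, binary_scale)
        adjust = delta >= cutoff_used

    return Decision(
        strategy=strategy, screened_out=False, adjust=bool(adjust),
        final_theta=thetaz if adjust else theta0,
        delta_observed=delta, cutoff_used=cutoff_used,
    )


def two_stage_identify(
    cohort: Cohort,
    strategy: str,
    alpha_screen: float = 0.05,
    cutoff: Optional[CutoffResult] = None,
    screen: bool = True,
    binary_scale: str = "rr",
) -> Decision:
    """Correlation screen, then the requested strategy on the surviving candidate.

    When the screen rejects the covariate the decision is ``screened_out``
    with the unadjusted effect as the final estimate; otherwise both models
    are fit and ``apply_strategy`` decides.
    """
    keep, r, p = screen_correlation(cohort.x_obs, cohort.z_obs, alpha_screen)
    if screen and not keep:
        unadj, _ = fit_cohort_models(cohort)
        return Decision(
            strategy=strategy, screened_out=True, adjust=False,
            final_theta=reporting_theta(unadj, binary_scale),
            screen_r=r, screen_p=p,
        )
    unadj, adj = fit_cohort_models(cohort)
    decision = apply_strategy(strategy, unadj, adj, cutoff, binary_scale)
    decision.screen_r = r
    decision.screen_p = p
    return decision
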