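"""Simulation-calibrated change-in-estimate (CIE) cutoffs.

Fixed CIE rules ("retain the covariate if the estimate moves by 10 %")
carry uncontrolled error rates once covariates are measured with error.
This module calibrates the cutoff delta_c by Monte Carlo:

* **type-I cutoff** — the distribution of Delta obtained when the outcome
  model is adjusted for an *independent* pseudo-confounder Z0 whose
  marginal matches the observed candidate; the (1-q) tail percentile (95th
  for a 5 % type-I error) is the cutoff above which an observed Delta is
  unlikely to be a finite-sample accident.
* **type-II cutoff** — the distribution of Delta under an *assumed true
  confounding structure* (regenerating complete cohorts, including the
  measurement-error layers, and adjusting for the mis-measured
  confounder); the s-th percentile (20th for 20 % type-II error) is the
  cutoff that would still flag the covariate in (1-s) of such studies.

Deltas are computed on the family's reporting scale (coefficient / risk
ratio / hazard ratio).  Replicates with an exactly-zero unadjusted effect
(undefined Delta) or non-converged fits are excluded and counted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .cohort_sim import (
    RandomSource,
    _as_generator,
    add_classical_error,
    draw_confounded_pair,
    generate_outcome,
)
from .config import CutoffSpec, DGPConfig
from .effect_models import (
    EffectEstimate,
    change_in_estimate,
    fit_exposure_model,
    odds_to_risk_ratio,
    reporting_theta,
)
from .exceptions import (
    CalibrationFailureError,
    DegenerateOutcomeError,
    InvalidParameterError,
    MissingParameterError,
    UndefinedCIEError,
)

#: quantile convention: linear interpolation between order statistics
#: (numpy's default, R's type 7), pinned for cross-run reproducibility.
QUANTILE_METHOD = "linear"


@dataclass
class DeltaSample:
    """A Monte Carlo sample of CIE values delta_k with exclusion metadata."""

    deltas: np.ndarray
    n_excluded: int = 0
    n_requested: int = 0

    def __len__(self) -> int:
        return len(self.deltas)

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.deltas, dtype=dtype)


@dataclass
class CutoffResult:
    """A calibrated CIE cutoff with its Monte Carlo uncertainty."""

    delta_c: float
    percentile_used: float
    replicates: int
    deltas_summary: dict = field(default_factory=dict)
    mc_se: float = 0.0
    n_excluded: int = 0
    error_type: str = "type1"
    level: float = 0.05

    def to_dict(self) -> dict:
        return {
            "delta_c": self.delta_c,
            "percentile_used": self.percentile_used,
            "replicates": self.replicates,
            "deltas_summary": self.deltas_summary,
            "mc_se": self.mc_se,
            "n_excluded": self.n_excluded,
            "error_type": self.error_type,
            "level": self.level,
        }


def delta_from_estimates(
    unadj: EffectEstimate, adj: EffectEstimate, binary_scale: str = "rr"
) -> float:
    """CIE between an unadjusted and an adjusted fit on the reporting scale.

    For the binary family on the risk-ratio scale both odds ratios are
    converted with one common baseline risk (the unadjusted model's), so
    the comparison reflects the exposure effect alone and not the
    intercept shift between the two models.
    """
    if unadj.family == "binary" and binary_scale == "rr":
        p0 = unadj.baseline_risk
        t0 = odds_to_risk_ratio(float(np.exp(unadj.beta_hat)), p0)
        tz = odds_to_risk_ratio(float(np.exp(adj.beta_hat)), p0)
        return change_in_estimate(t0, tz)
    return change_in_estimate(
        reporting_theta(unadj, binary_scale), reporting_theta(adj, binary_scale)
    )


def _simulate_cohort_arrays(config: DGPConfig, g: np.random.Generator):
    x, z = draw_confounded_pair(config.n, config.rho, g)
    x_obs = add_classical_error(x, config.err_var_x, g)
    z_obs = add_classical_error(z, config.err_var_z, g)
    outcome = generate_outcome(x, z, config, g)
    return x_obs, z_obs, outcome


def _collect_deltas(replicates, one_delta) -> DeltaSample:
    deltas = []
    excluded = 0
    for k in range(replicates):
        try:
            d = one_delta(k)
        except (UndefinedCIEError, DegenerateOutcomeError):
            excluded += 1
            continue
        if d is None or not np.isfinite(d):
            excluded += 1
            continue
        deltas.append(d)
    if not deltas:
        raise CalibrationFailureError("all calibration replicates were degenerate")
    if excluded > 0.01 * replicates:
        warnings.warn(
            f"{excluded}/{replicates} calibration replicates excluded "
            "(undefined CIE or non-converged fit)",
            stacklevel=3,
        )
    return DeltaSample(np.asarray(deltas), excluded, replicates)


def null_cie_distribution(
    spec: CutoffSpec,
    source,
    rng: RandomSource = None,
) -> DeltaSample:
    """Null CIE sample: adjust the exposure model for an independent Z0.

    ``source`` is a :class:`DGPConfig` in design mode — each replicate
    regenerates a complete cohort (observed exposure and outcome under the
    configured structure) and a fresh Z0 ~ N(0, 1 + sigma_z^2), the
    marginal of the error-contaminated confounder.  In data mode it is a
    cohort-like object with fixed (outcome, x_obs, z_obs); Z0 is a random
    permutation of the observed confounder column, which preserves its
    marginal exactly while destroying any association.
    """
    g = _as_generator(rng)

    if spec.mode == "design":
        if not isinstance(source, DGPConfig):
            raise InvalidParameterError("design mode requires a DGPConfig source")
        config = source
        sd_z0 = np.sqrt(1.0 + config.err_var_z)

        def one_delta(k):
            x_obs, _, outcome = _simulate_cohort_arrays(config, g)
            z0 = g.normal(0.0, sd_z0, config.n)
            unadj = fit_exposure_model(outcome, x_obs, None, config.outcome_family)
            adj = fit_exposure_model(outcome, x_obs, z0, config.outcome_family)
            if not (unadj.converged and adj.converged):
                return None
            return delta_from_estimates(unadj, adj)

    else:  # data mode: fixed observed study, permuted confounder column
        outcome = np.asarray(source.outcome, dtype=float)
        x_obs = np.asarray(source.x_obs, dtype=float)
        z_obs = np.asarray(source.z_obs, dtype=float)
        family = source.family
        unadj = fit_exposure_model(outcome, x_obs, None, family)

        def one_delta(k):
            z0 = g.permutation(z_obs)
            adj = fit_exposure_model(outcome, x_obs, z0, family)
            if not (unadj.converged and adj.converged):
                return None
            return delta_from_estimates(unadj, adj)

    return _collect_deltas(spec.replicates, one_delta)


def alt_cie_distribution(spec: CutoffSpec, rng: RandomSource = None) -> DeltaSample:
    """Alternative CIE sample under the assumed confounded structure.

    Each replicate regenerates a complete cohort from ``spec.alt_structure``
    (true correlated confounder, classical errors on exposure and
    confounder, outcome) and compares the fits with and without adjustment
    for the mis-measured confounder Z*.
    """
    if spec.alt_structure is None:
        raise MissingParameterError("alt_structure DGPConfig required for the type-II cutoff")
    config = spec.alt_structure
    g = _as_generator(rng)

    def one_delta(k):
        x_obs, z_obs, outcome = _simulate_cohort_arrays(config, g)
        unadj = fit_exposure_model(outcome, x_obs, None, config.outcome_family)
        adj = fit_exposure_model(outcome, x_obs, z_obs, config.outcome_family)
        if not (unadj.converged and adj.converged):
            return None
        return delta_from_estimates(unadj, adj)

    return _collect_deltas(spec.replicates, one_delta)


def _percentile_cutoff(
    deltas, percentile: float, n_boot: int = 200, rng: RandomSource = None
) -> tuple[float, float, dict]:
    sample = deltas.deltas if isinstance(deltas, DeltaSample) else np.asarray(deltas, dtype=float)
    if sample.size == 0:
        raise InvalidParameterError("empty delta sample")
    delta_c = float(np.percentile(sample, percentile, method=QUANTILE_METHOD))
    g = _as_generator(rng)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        boots[b] = np.percentile(
            g.choice(sample, size=sample.size, replace=True),
            percentile, method=QUANTILE_METHOD,
        )
    summary = {
        f"q{q:g}": float(np.percentile(sample, q, method=QUANTILE_METHOD))
        for q in (5, 20, 50, 80, 95)
    }
    return delta_c, float(boots.std(ddof=1)), summary


def type1_cutoff(deltas, level: float = 0.05, rng: RandomSource = None) -> CutoffResult:
    """Cutoff controlling type I error: the (1-level) quantile of null deltas."""
    if not 0 < level < 1:
        raise InvalidParameterError(f"level must be in (0,1), got {level}")
    percentile = 100.0 * (1.0 - level)
    delta_c, mc_se, summary = _percentile_cutoff(deltas, percentile, rng=rng)
    return CutoffResult(
        delta_c=delta_c, percentile_used=percentile,
        replicates=len(np.asarray(deltas)), deltas_summary=summary, mc_se=mc_se,
        n_excluded=getattr(deltas, "n_excluded", 0),
        error_type="type1", level=level,
    )


def type2_cutoff(deltas, level: float = 0.2, rng: RandomSource = None) -> CutoffResult:
    """Cutoff with type II error ``level``: the level-quantile of alternative deltas."""
    if not 0 < level < 1:
        raise InvalidParameterError(f"level must be in (0,1), got {level}")
    percentile = 100.0 * level
    delta_c, mc_se, summary = _percentile_cutoff(deltas, percentile, rng=rng)
    return CutoffResult(
        delta_c=delta_c, percentile_used=percentile,
        replicates=len(np.asarray(deltas)), deltas_summary=summary, mc_se=mc_se,
        n_excluded=getattr(deltas, "n_excluded", 0),
        error_type="type2", level=level,
    )


def calibrate_cutoff(
    dgp: DGPConfig,
    error_type: str = "type1",
    level: Optional[float] = None,
    replicates: int = 10_000,
    rng: RandomSource = None,
) -> CutoffResult:
    """One-call calibration of a simulated CIE cutoff for a planned study."""
    if level is None:
        level = 0.05 if error_type == "type1" else 0.2
    spec = CutoffSpec(
        error_type=error_type, level=level, replicates=replicates,
        mode="design", alt_structure=dgp if error_type == "type2" else None,
    )
    g = _as_generator(rng)
    if error_type == "type1":
        deltas = null_cie_distribution(spec, dgp, g)
        return type1_cutoff(deltas, level, rng=g)
    deltas = alt_cie_distribution(spec, g)
    return type2_cutoff(deltas, level, rng=g)
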