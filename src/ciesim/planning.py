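"""Study planning: how accurately must a confounder be measured?

The motivating design is the mercury-fish-depression triangle: latent
habitual fish intake F ~ N(0,1) raises blood mercury E (corr rho_FE) and
protects against depression D (latent corr rho_FD < 0), so an analysis of
E on D that can only adjust for a noisy fish measure W = F + eps,
eps ~ N(0, sigma^2), retains residual confounding that grows with the
noise-to-signal ratio sigma^2.

The emulator generates (E, D, F) by a liability-threshold model: D is a
latent Gaussian liability, correlated rho_FD with F (plus any direct
exposure effect), dichotomized at the quantile matching the target
prevalence.  For each sigma^2 in the planning grid, K replicate studies
are simulated and the logistic fit D ~ E + W records (i) whether the
exposure association is correctly null (p > 0.05) and (ii) the adjusted
risk ratio, yielding the planning table and the adjusted-effect
distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .cie_calibration import _collect_deltas, type1_cutoff
from .cohort_sim import RandomSource, _as_generator
from .config import PlanningConfig
from .effect_models import fit_exposure_model, reporting_theta
from .exceptions import InvalidStructureError


@dataclass
class PlanningRow:
    """Planning summary for one noise-to-signal level."""

    noise_to_signal: float
    prop_null: float
    mean_effect: float
    ci_low: float
    ci_high: float
    cie_cutoff: Optional[float] = None
    n_reps: int = 0

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "noise_to_signal", "prop_null", "mean_effect",
            "ci_low", "ci_high", "cie_cutoff", "n_reps",
        )}


def _structure_matrix(config: PlanningConfig) -> np.ndarray:
    """Correlation matrix of (F, E, latent liability) implied by the config."""
    r_fe, r_fd = config.rho_FE, config.rho_FD
    r_ed = r_fe * r_fd  # induced through F when the direct effect is zero
    m = np.array([[1.0, r_fe, r_fd], [r_fe, 1.0, r_ed], [r_fd, r_ed, 1.0]])
    return m


def emulate_study(
    config: PlanningConfig, rng: RandomSource = None
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw one study (E, D, F) from the liability-threshold structure."""
    if np.linalg.eigvalsh(_structure_matrix(config))[0] <= 0:
        raise InvalidStructureError("correlation structure is not positive definite")
    g = _as_generator(rng)
    n = config.n_study
    f = g.standard_normal(n)
    e = config.rho_FE * f + np.sqrt(1.0 - config.rho_FE**2) * g.standard_normal(n)
    liab = (
        config.rho_FD * f
        + np.sqrt(1.0 - config.rho_FD**2) * g.standard_normal(n)
        + config.direct_effect * e
    )
    # threshold at the quantile of the liability's own scale
    sd_liab = np.sqrt(
        1.0
        + config.direct_effect**2
        + 2.0 * config.direct_effect * config.rho_FE * config.rho_FD
    )
    thresh = stats.norm.ppf(1.0 - config.outcome_prevalence) * sd_liab
    d = (liab > thresh).astype(float)
    return e, d, f


def _one_adjusted_fit(config, sigma2, g):
    e, d, f = emulate_study(config, g)
    w = f + g.normal(0.0, np.sqrt(sigma2), config.n_study) if sigma2 > 0 else f
    return fit_exposure_model(d, e, w, "binary")


def unadjusted_effect(config: PlanningConfig, rng: RandomSource = None) -> float:
    """Risk ratio of D on E without any confounder adjustment (one study)."""
    e, d, _ = emulate_study(config, rng)
    est = fit_exposure_model(d, e, None, "binary")
    return reporting_theta(est, "rr")


def planning_cie_cutoff(
    config: PlanningConfig, sigma2: float, replicates: int,
    rng: RandomSource = None,
) -> float:
    """Simulated type-I CIE cutoff for the planning setting at one sigma^2.

    Each replicate draws a fresh study and an independent pseudo-confounder
    with W's marginal N(0, 1+sigma^2), and records the relative change of
    the exposure risk ratio upon adjustment.
    """
    g = _as_generator(rng)
    sd_z0 = np.sqrt(1.0 + sigma2)
    n = config.n_study

    def one_delta(k):
        e, d, _ = emulate_study(config, g)
        z0 = g.normal(0.0, sd_z0, n)
        unadj = fit_exposure_model(d, e, None, "binary")
        adj = fit_exposure_model(d, e, z0, "binary")
        if not (unadj.converged and adj.converged):
            return None
        t0 = reporting_theta(unadj, "rr")
        tz = reporting_theta(adj, "rr")
        if t0 == 0:
            return None
        return abs((t0 - tz) / t0)

    deltas = _collect_deltas(replicates, one_delta)
    return type1_cutoff(deltas, 0.05, rng=g).delta_c


def planning_grid(
    config: PlanningConfig,
    cutoff_reps: Optional[int] = None,
    rng: RandomSource = None,
) -> List[PlanningRow]:
    """Planning table over the configured noise-to-signal grid.

    For each sigma^2: K replicate studies, adjusted logistic fits
    D ~ E + W, the fraction with a null exposure association (p > 0.05),
    the mean adjusted risk ratio with its empirical 95 % interval, and the
    simulated type-I CIE cutoff for the setting.  ``cutoff_reps=0``
    disables the cutoff computation; None uses ``config.reps``.
    """
    g = _as_generator(rng if rng is not None else config.seed)
    rows: List[PlanningRow] = []
    for sigma2 in config.noise_grid:
        rrs = np.empty(config.reps)
        pnull = np.empty(config.reps, dtype=bool)
        if config.fixed_study:
            e, d, f = emulate_study(config, g)
        for k in range(config.reps):
            if config.fixed_study:
                w = f + g.normal(0.0, np.sqrt(sigma2), config.n_study) if sigma2 > 0 else f
                est = fit_exposure_model(d, e, w, "binary")
            else:
                est = _one_adjusted_fit(config, sigma2, g)
            rrs[k] = reporting_theta(est, "rr")
            pnull[k] = est.p_exposure > 0.05
        kreps = config.reps if cutoff_reps is None else cutoff_reps
        cutoff = planning_cie_cutoff(config, sigma2, kreps, g) if kreps else None
        rows.append(PlanningRow(
            noise_to_signal=float(sigma2),
            prop_null=float(pnull.mean()),
            mean_effect=float(rrs.mean()),
            ci_low=float(np.percentile(rrs, 2.5)),
            ci_high=float(np.percentile(rrs, 97.5)),
            cie_cutoff=cutoff,
            n_reps=config.reps,
        ))
    return rows


def adjusted_effect_distribution(
    config: PlanningConfig, sigma2: float, bins: int = 30,
    rng: RandomSource = None,
) -> dict:
    """Median, quartiles and histogram of the adjusted RR at one sigma^2."""
    g = _as_generator(rng if rng is not None else config.seed)
    rrs = np.empty(config.reps)
    for k in range(config.reps):
        est = _one_adjusted_fit(config, sigma2, g)
        rrs[k] = reporting_theta(est, "rr")
    counts, edges = np.histogram(rrs, bins=bins)
    return {
        "sigma2": float(sigma2),
        "median": float(np.median(rrs)),
        "q1": float(np.percentile(rrs, 25)),
        "q3": float(np.percentile(rrs, 75)),
        "hist_counts": counts.tolist(),
        "hist_edges": edges.tolist(),
        "values": rrs,
    }


def planning_table(rows: List[PlanningRow]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in rows])
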