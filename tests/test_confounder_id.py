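"""Screening pre-test and the five identification strategies."""

import numpy as np
import pytest
from scipy import stats

from ciesim import (
    DGPConfig,
    apply_strategy,
    generate_cohort,
    screen_correlation,
    two_stage_identify,
)
from ciesim.cie_calibration import CutoffResult
from ciesim.effect_models import EffectEstimate, fit_cohort_models, reporting_theta
from ciesim.exceptions import DegenerateInputError, MissingParameterError


def _estimate(family="continuous", adjusted=False, beta=0.1, theta=None,
              p_conf=None):
    return EffectEstimate(
        family=family, adjusted=adjusted, beta_hat=beta, se_beta=0.05,
        p_exposure=0.04, theta_hat=beta if theta is None else theta,
        p_confounder=p_conf, n=100,
    )


class TestScreen:
    def test_perfect_correlation_kept(self, rng):
        x = rng.standard_normal(50)
        keep, r, p = screen_correlation(x, x)
        assert keep and r == pytest.approx(1.0)

    def test_null_keep_rate_is_alpha(self, rng):
        """Independent normals: the screen keeps ~5 % of candidates."""
        keeps = sum(
            screen_correlation(rng.standard_normal(500), rng.standard_normal(500))[0]
            for _ in range(2000)
        )
        assert keeps / 2000 == pytest.approx(0.05, abs=0.01)

    def test_power_matches_fisher_z(self, rng):
        """True rho=0.3 with unit error variances attenuates to r=0.15;
        empirical keep rate tracks the Fisher-z power approximation."""
        n, reps, r_obs = 500, 2000, 0.15
        z = np.arctanh(r_obs) * np.sqrt(n - 3)
        crit = stats.norm.ppf(0.975)
        power = stats.norm.cdf(z - crit) + stats.norm.cdf(-z - crit)
        keeps = 0
        for _ in range(reps):
            x = rng.standard_normal(n)
            zc = 0.3 * x + np.sqrt(1 - 0.09) * rng.standard_normal(n)
            xs = x + rng.standard_normal(n)
            zs = zc + rng.standard_normal(n)
            keeps += screen_correlation(xs, zs)[0]
        assert keeps / reps == pytest.approx(power, abs=0.03)

    def test_strong_correlation_always_kept(self):
        cohort = generate_cohort(DGPConfig(n=2000, outcome_family="continuous",
                                           rho=0.9, seed=31))
        assert screen_correlation(cohort.x_obs, cohort.z_obs)[0]

    def test_zero_variance_rejected(self, fixtures):
        degenerate = fixtures["zero_variance_covariate"]
        with pytest.raises(DegenerateInputError):
            screen_correlation(degenerate.x_obs, degenerate.z_obs)


class TestApplyStrategy:
    def test_cie10_threshold(self):
        """Adjust exactly when Delta >= 0.10 (boundary inclusive)."""
        unadj = _estimate(theta=1.0)
        just_above = _estimate(adjusted=True, theta=0.8999, p_conf=0.5)
        just_below = _estimate(adjusted=True, theta=0.9001, p_conf=0.5)
        assert apply_strategy("cie10", unadj, just_above).adjust
        assert not apply_strategy("cie10", unadj, just_below).adjust
        # exact-boundary semantics: a Delta equal to the cutoff adjusts
        from ciesim import change_in_estimate
        from ciesim.cie_calibration import CutoffResult
        adj = _estimate(adjusted=True, theta=0.9, p_conf=0.5)
        cut = CutoffResult(delta_c=change_in_estimate(1.0, 0.9),
                           percentile_used=95, replicates=100)
        assert apply_strategy("cie_sim_type1", unadj, adj, cut).adjust

    def test_p_cutoffs_at_p_010(self):
        unadj = _estimate(theta=1.0)
        adj = _estimate(adjusted=True, theta=0.95, p_conf=0.10)
        assert not apply_strategy("p05", unadj, adj).adjust
        assert apply_strategy("p20", unadj, adj).adjust

    def test_simulated_cutoff_boundary_inclusive(self):
        unadj = _estimate(theta=1.0)
        adj = _estimate(adjusted=True, theta=0.998, p_conf=0.5)
        cut = CutoffResult(delta_c=0.002, percentile_used=95, replicates=100)
        d = apply_strategy("cie_sim_type1", unadj, adj, cut)
        assert d.adjust and d.cutoff_used == 0.002

    def test_missing_cutoff_raises(self):
        unadj = _estimate(theta=1.0)
        adj = _estimate(adjusted=True, theta=0.9, p_conf=0.5)
        with pytest.raises(MissingParameterError):
            apply_strategy("cie_sim_type1", unadj, adj, None)

    def test_final_theta_tracks_decision(self):
        unadj = _estimate(theta=1.0)
        adj = _estimate(adjusted=True, theta=0.7, p_conf=0.01)
        d_yes = apply_strategy("p05", unadj, adj)
        assert d_yes.final_theta == adj.theta_hat
        adj2 = _estimate(adjusted=True, theta=0.7, p_conf=0.9)
        d_no = apply_strategy("p05", unadj, adj2)
        assert d_no.final_theta == unadj.theta_hat

    def test_threshold_monotonicity(self):
        """Lowering delta_c never flips adjust=True back to False."""
        unadj = _estimate(theta=1.0)
        adj = _estimate(adjusted=True, theta=0.95, p_conf=0.5)
        cuts = [0.2, 0.08, 0.05, 0.01]
        decisions = [
            apply_strategy("cie_sim_type1", unadj, adj,
                           CutoffResult(delta_c=c, percentile_used=95, replicates=100)).adjust
            for c in cuts
        ]
        assert decisions == sorted(decisions)  # False..True monotone


class TestTwoStage:
    def test_screened_out_uses_unadjusted_estimate(self):
        """A candidate failing the screen yields the unadjusted fit, bit-for-bit."""
        cohort = generate_cohort(DGPConfig(n=300, outcome_family="continuous",
                                           rho=0.0, gamma=0.0, seed=17))
        d = two_stage_identify(cohort, "p05", alpha_screen=1e-6)
        assert d.screened_out and not d.adjust
        unadj, _ = fit_cohort_models(cohort)
        assert d.final_theta == reporting_theta(unadj)

    def test_screened_in_path_matches_apply_strategy(self):
        cohort = generate_cohort(DGPConfig(n=2000, outcome_family="continuous",
                                           rho=0.9, seed=23))
        d = two_stage_identify(cohort, "p20")
        assert not d.screened_out
        unadj, adj = fit_cohort_models(cohort)
        expected = apply_strategy("p20", unadj, adj)
        assert d.adjust == expected.adjust
        assert d.final_theta == expected.final_theta

    def test_independent_candidate_screened_in_near_alpha(self):
        """With rho=0 the two-stage entry rate stays near the screen alpha."""
        reps, kept = 400, 0
        for i in range(reps):
            cohort = generate_cohort(DGPConfig(n=2000, outcome_family="continuous",
                                               rho=0.0, seed=1000 + i))
            d = two_stage_identify(cohort, "p20")
            kept += not d.screened_out
        assert kept / reps <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / reps)
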