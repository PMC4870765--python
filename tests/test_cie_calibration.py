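"""Simulated CIE cutoffs: quantile rules, null/alternative distributions."""

import numpy as np
import pytest
from scipy import stats

from ciesim import (
    CutoffSpec,
    DGPConfig,
    alt_cie_distribution,
    null_cie_distribution,
    type1_cutoff,
    type2_cutoff,
)
from ciesim.cie_calibration import DeltaSample, _collect_deltas
from ciesim.exceptions import (
    CalibrationFailureError,
    InvalidParameterError,
    UndefinedCIEError,
)


def _lin_dgp(n, rho=0.5, sx2=1.0, sz2=1.0, **kw):
    return DGPConfig(n=n, outcome_family="continuous", rho=rho,
                     err_var_x=sx2, err_var_z=sz2, **kw)


class TestQuantileRules:
    def test_type1_on_known_grid(self):
        """0.01..1.00 grid, 5 % level: interpolated 95th percentile 0.9505."""
        deltas = np.arange(1, 101) / 100.0
        res = type1_cutoff(deltas, 0.05, rng=0)
        assert res.delta_c == pytest.approx(0.9505, abs=1e-12)
        assert res.percentile_used == 95.0

    def test_level_half_is_median(self):
        deltas = np.array([0.1, 0.2, 0.3, 0.7, 0.9])
        assert type1_cutoff(deltas, 0.5, rng=0).delta_c == pytest.approx(0.3)

    def test_degenerate_distribution(self):
        deltas = np.full(50, 0.042)
        assert type1_cutoff(deltas, 0.05, rng=0).delta_c == pytest.approx(0.042)
        assert type2_cutoff(deltas, 0.2, rng=0).delta_c == pytest.approx(0.042)

    def test_type2_on_known_grid(self):
        """1..100 grid at 20 % level: interpolated 20th percentile 20.8."""
        deltas = np.arange(1, 101, dtype=float)
        assert type2_cutoff(deltas, 0.2, rng=0).delta_c == pytest.approx(20.8)

    def test_type2_small_level_approaches_min(self):
        deltas = np.arange(1, 101, dtype=float)
        assert type2_cutoff(deltas, 0.001, rng=0).delta_c == pytest.approx(1.0, abs=0.2)

    def test_empty_and_bad_level_rejected(self):
        with pytest.raises(InvalidParameterError):
            type1_cutoff(np.array([]), 0.05)
        with pytest.raises(InvalidParameterError):
            type1_cutoff(np.array([0.1]), 1.5)

    def test_monotone_in_percentile(self):
        deltas = np.random.default_rng(0).exponential(size=500)
        cuts = [type1_cutoff(deltas, lv, rng=0).delta_c for lv in (0.2, 0.1, 0.05, 0.01)]
        assert np.all(np.diff(cuts) >= 0)

    def test_type2_self_consistency(self):
        """Applying the cutoff back flags >= (1-level) of the same sample."""
        deltas = np.random.default_rng(1).exponential(size=400)
        res = type2_cutoff(deltas, 0.2, rng=0)
        assert np.mean(deltas >= res.delta_c) >= 0.8 - 0.01


class TestNullDistribution:
    def test_nonnegative_and_shrinks_with_n(self):
        """Adjusting for an independent Z0 matters less in larger cohorts."""
        spec = CutoffSpec(error_type="type1", replicates=400)
        small = null_cie_distribution(spec, _lin_dgp(200), rng=2)
        large = null_cie_distribution(spec, _lin_dgp(5000), rng=2)
        assert np.all(small.deltas >= 0)
        assert np.median(large.deltas) < np.median(small.deltas)

    def test_reproducible_under_fixed_seed(self):
        spec = CutoffSpec(error_type="type1", replicates=150)
        a = null_cie_distribution(spec, _lin_dgp(300), rng=5)
        b = null_cie_distribution(spec, _lin_dgp(300), rng=5)
        assert np.array_equal(a.deltas, b.deltas)

    def test_data_mode_permutes_observed_confounder(self, fixtures):
        cohort = fixtures["continuous"]
        spec = CutoffSpec(error_type="type1", replicates=150, mode="data")
        sample = null_cie_distribution(spec, cohort, rng=3)
        assert len(sample) == 150
        assert np.all(sample.deltas >= 0)

    def test_design_mode_requires_dgp(self, fixtures):
        spec = CutoffSpec(error_type="type1", replicates=100, mode="design")
        with pytest.raises(InvalidParameterError):
            null_cie_distribution(spec, fixtures["continuous"], rng=0)


class TestAlternativeDistribution:
    def test_gamma_zero_rho_zero_degenerates_to_null(self):
        """With the covariate unrelated to exposure and outcome, the
        'alternative' structure is the null: same delta distribution (KS)."""
        dgp = _lin_dgp(400, rho=0.0, gamma=0.0)
        alt_spec = CutoffSpec(error_type="type2", replicates=500, alt_structure=dgp)
        null_spec = CutoffSpec(error_type="type1", replicates=500)
        alt = alt_cie_distribution(alt_spec, rng=7)
        null = null_cie_distribution(null_spec, dgp, rng=8)
        assert stats.ks_2samp(alt.deltas, null.deltas).pvalue > 0.01

    def test_alt_requires_structure(self):
        with pytest.raises(Exception):
            alt_cie_distribution(CutoffSpec(error_type="type2", replicates=100), rng=0)


class TestCalibrationClosure:
    def test_type1_closure(self):
        """Fresh null replicates exceed the calibrated cutoff ~5 % of the time."""
        dgp = _lin_dgp(300)
        spec = CutoffSpec(error_type="type1", replicates=1200)
        cut = type1_cutoff(null_cie_distribution(spec, dgp, rng=11), 0.05, rng=11)
        fresh = null_cie_distribution(CutoffSpec(error_type="type1", replicates=800),
                                      dgp, rng=12)
        flag_rate = np.mean(fresh.deltas >= cut.delta_c)
        se = np.sqrt(0.05 * 0.95 / 800)
        assert abs(flag_rate - 0.05) <= 3 * se + cut.mc_se

    def test_type2_closure(self):
        """Fresh alternative replicates fall below the cutoff ~20 % of the time."""
        dgp = _lin_dgp(300, rho=0.5)
        spec = CutoffSpec(error_type="type2", replicates=1200, alt_structure=dgp)
        cut = type2_cutoff(alt_cie_distribution(spec, rng=13), 0.2, rng=13)
        fresh = alt_cie_distribution(
            CutoffSpec(error_type="type2", replicates=800, alt_structure=dgp), rng=14)
        miss_rate = np.mean(fresh.deltas < cut.delta_c)
        se = np.sqrt(0.2 * 0.8 / 800)
        assert abs(miss_rate - 0.2) <= 3 * se + 0.02


class TestExclusionHandling:
    def test_undefined_replicates_counted_and_warned(self):
        calls = iter(range(200))

        def one_delta(k):
            if next(calls) % 10 == 0:
                raise UndefinedCIEError("zero unadjusted effect")
            return 0.5

        with pytest.warns(UserWarning, match="excluded"):
            sample = _collect_deltas(200, one_delta)
        assert sample.n_excluded == 20
        assert len(sample) == 180

    def test_all_degenerate_raises(self):
        def one_delta(k):
            raise UndefinedCIEError("always")

        with pytest.raises(CalibrationFailureError):
            _collect_deltas(100, one_delta)

    def test_delta_sample_is_arraylike(self):
        s = DeltaSample(np.array([0.1, 0.2]), 0, 2)
        assert np.asarray(s).sum() == pytest.approx(0.3)
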