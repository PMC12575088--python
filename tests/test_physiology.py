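"""Growth-rate fits, assay conversions, lag estimation, t-test."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from proteoalloc import physiology as phys
from proteoalloc.errors import (
    CalibrationError,
    DomainError,
    EstimationError,
    FitError,
)
from proteoalloc.physiology import GrowthCurve


def exp_curve(lam, od0=0.05, t_end=2.0, n=6):
    t = np.linspace(0.0, t_end, n)
    return GrowthCurve(times=t, od600=od0 * np.exp(lam * t))


class TestFitGrowthRate:
    def test_exact_on_noiseless_exponential(self):
        # doubling time 60 min -> lambda = ln2 per hour
        fit = phys.fit_growth_rate(exp_curve(0.693, t_end=math.log(0.5 / 0.05) / 0.693))
        assert fit.lam == pytest.approx(0.693, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.doubling_time * 60 == pytest.approx(60.0, rel=1e-3)

    def test_constant_od_has_zero_rate(self):
        curve = GrowthCurve(times=np.linspace(0, 2, 5), od600=np.full(5, 0.2))
        fit = phys.fit_growth_rate(curve)
        assert fit.lam == 0.0 and fit.r_squared == 1.0

    def test_too_few_points_in_window(self):
        curve = GrowthCurve(times=np.array([0.0, 1.0, 2.0]),
                            od600=np.array([0.9, 1.8, 3.6]))  # all above the window
        with pytest.raises(FitError):
            phys.fit_growth_rate(curve)

    def test_rescaling_od_preserves_rate(self):
        base = exp_curve(1.2, t_end=1.9)
        fit0 = phys.fit_growth_rate(base)
        # rescale but widen the window so the same points are used
        scaled = GrowthCurve(times=base.times, od600=base.od600 * 3.0)
        fit1 = phys.fit_growth_rate(scaled, od_window=(0.15, 1.5))
        assert fit1.lam == pytest.approx(fit0.lam, rel=1e-12)

    def test_only_window_points_are_fitted(self):
        # stationary points above OD 0.5 must not drag the slope down
        t = np.array([0.0, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0])
        od = np.minimum(0.05 * np.exp(1.0 * t), 0.6)
        fit = phys.fit_growth_rate(GrowthCurve(times=t, od600=od))
        assert fit.lam == pytest.approx(1.0, abs=1e-9)


class TestRnaAmount:
    def test_unit_readings_return_the_conversion_coefficient(self):
        assert phys.rna_amount(1.0, 1.0) == 31.0

    @pytest.mark.parametrize("od260, od600, expected",
                             [(0.0, 1.0, 0.0), (0.62, 2.0, 9.61)])
    def test_worked_examples(self, od260, od600, expected):
        assert phys.rna_amount(od260, od600) == pytest.approx(expected)

    def test_nonpositive_od600_rejected(self):
        with pytest.raises(DomainError):
            phys.rna_amount(1.0, 0.0)

    @given(st.floats(min_value=0.01, max_value=5.0), st.floats(min_value=1.1, max_value=10.0))
    def test_homogeneous_degree_one_in_od260(self, od260, k):
        assert phys.rna_amount(k * od260, 0.5) == pytest.approx(
            k * phys.rna_amount(od260, 0.5), rel=1e-12)


class TestProteinAmount:
    def test_linear_interpolation_between_standards(self):
        result = phys.protein_amount(0.15, [(1.0, 0.1), (2.0, 0.2)])
        assert result.conc == pytest.approx(1.5)
        assert not result.extrapolated

    def test_reading_at_a_standard_returns_its_concentration(self):
        result = phys.protein_amount(0.2, [(1.0, 0.1), (2.0, 0.2)])
        assert result.conc == pytest.approx(2.0)

    def test_extrapolation_is_flagged(self):
        result = phys.protein_amount(0.5, [(1.0, 0.1), (2.0, 0.2)])
        assert result.extrapolated

    def test_degenerate_standards_rejected(self):
        with pytest.raises(CalibrationError):
            phys.protein_amount(0.15, [(1.0, 0.1), (1.0, 0.2)])
        with pytest.raises(CalibrationError):
            phys.protein_amount(0.15, [(1.0, 0.1), (2.0, 0.1)])

    def test_noisy_standards_recover_known_line(self):
        rng = np.random.default_rng(4)
        a, b, truth = 0.11, 0.02, 1.3
        standards = [(c, a * c + b + 1e-3 * rng.standard_normal())
                     for c in (0.4, 0.8, 1.2, 1.6, 2.0)]
        result = phys.protein_amount(a * truth + b, standards)
        assert result.conc == pytest.approx(truth, abs=0.05)


class TestRatiosAndMiller:
    def test_rna_protein_ratio(self):
        assert phys.rna_protein_ratio(60.0, 200.0) == pytest.approx(0.30)
        assert phys.rna_protein_ratio(0.0, 200.0) == 0.0
        with pytest.raises(DomainError):
            phys.rna_protein_ratio(60.0, 0.0)

    def test_miller_units_worked_example(self):
        assert phys.miller_units(0.5, 10.0, 0.5, 0.4) == pytest.approx(250.0)

    def test_doubling_reaction_time_halves_units(self):
        u1 = phys.miller_units(0.5, 10.0, 0.5, 0.4)
        u2 = phys.miller_units(0.5, 20.0, 0.5, 0.4)
        assert u2 == pytest.approx(u1 / 2.0)

    @given(st.floats(min_value=0.01, max_value=2.0), st.floats(min_value=1.1, max_value=5.0))
    def test_miller_homogeneous_in_od420(self, od420, k):
        assert phys.miller_units(k * od420, 10.0, 0.5, 0.4) == pytest.approx(
            k * phys.miller_units(od420, 10.0, 0.5, 0.4), rel=1e-12)

    def test_miller_domain_errors(self):
        with pytest.raises(DomainError):
            phys.miller_units(0.5, 0.0, 0.5, 0.4)


class TestPromoterActivityRatio:
    def test_equal_activities_give_unity(self):
        result = phys.promoter_activity_ratio((120.0, 0.0), (120.0, 0.0))
        assert result.ratio == 1.0 and result.sd == 0.0

    def test_first_order_error_propagation(self):
        # relative variances add: sd = 3 * sqrt(0.1^2 + 0.1^2)
        result = phys.promoter_activity_ratio((300.0, 30.0), (100.0, 10.0))
        assert result.ratio == pytest.approx(3.0)
        assert result.sd == pytest.approx(3.0 * math.sqrt(0.02), rel=1e-9)

    def test_zero_wild_type_mean_rejected(self):
        with pytest.raises(DomainError):
            phys.promoter_activity_ratio((300.0, 30.0), (0.0, 1.0))


class TestLagEstimation:
    def test_pure_exponential_has_zero_lag(self):
        curve = GrowthCurve(times=np.linspace(0, 3, 12),
                            od600=0.1 * np.exp(0.9 * np.linspace(0, 3, 12)))
        est = phys.estimate_lag_time(curve)
        assert est.lag == pytest.approx(0.0, abs=1e-9)
        assert est.lambda_post == pytest.approx(0.9, abs=1e-12)

    def test_flat_then_exponential_recovers_the_flat_duration(self):
        lag, lam = 1.5, 0.9
        t = np.linspace(0, 4, 20)
        od = 0.1 * np.exp(lam * np.maximum(0.0, t - lag))
        est = phys.estimate_lag_time(GrowthCurve(times=t, od600=od))
        assert est.lag == pytest.approx(lag, abs=1e-9)

    def test_no_exponential_window_is_an_error(self):
        rng = np.random.default_rng(0)
        od = np.exp(rng.standard_normal(12))  # jagged noise, no steady window
        with pytest.raises(EstimationError):
            phys.estimate_lag_time(GrowthCurve(times=np.arange(12.0), od600=od))


class TestTwoSampleTest:
    def test_identical_groups(self):
        t, p = phys.two_sample_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_insufficient_n_rejected(self):
        with pytest.raises(DomainError):
            phys.two_sample_test([1.0], [1.0, 2.0])

    def test_clear_difference_is_significant(self):
        t, p = phys.two_sample_test([1.0, 1.1, 0.9, 1.05], [2.0, 2.1, 1.9, 2.05])
        assert p < 1e-4
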