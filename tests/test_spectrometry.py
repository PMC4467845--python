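import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from seadose import (
    EfficiencyCurve,
    EfficiencyPoint,
    GammaLine,
    PeakMeasurement,
    UncertaintyBudget,
    ValidationError,
    combine_lines,
    fit_efficiency,
    line_activity,
    minimum_detectable_activity,
    propagate_uncertainty,
)


def _curve_points(coeffs, energies):
    lne = np.log(energies)
    lneff = np.polynomial.polynomial.polyval(lne, coeffs)
    return [EfficiencyPoint(e, eff) for e, eff in zip(energies, np.exp(lneff))]


class TestEfficiencyFit:
    def test_exact_recovery_of_generating_polynomial(self):
        coeffs = (1.2, -0.9, -0.05)
        points = _curve_points(coeffs, [100, 300, 600, 1000, 1500])
        curve = fit_efficiency(points, order=2)
        assert curve.coefficients == pytest.approx(coeffs, abs=1e-9)
        assert curve.fit_residual < 1e-12

    def test_constant_fit(self):
        points = [EfficiencyPoint(e, 0.05) for e in (100, 500, 1000)]
        curve = fit_efficiency(points, order=0)
        assert curve.efficiency(700) == pytest.approx(0.05)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(7)
        energies = np.array([80, 150, 300, 600, 1000, 1600], dtype=float)
        true = (0.9, -0.7)
        lneff = np.polynomial.polynomial.polyval(np.log(energies), true)
        noisy = np.exp(lneff + rng.normal(0, 0.01, size=energies.size))
        points = [EfficiencyPoint(e, f) for e, f in zip(energies, noisy)]
        curve = fit_efficiency(points, order=2)
        # brute-force normal equations in ln-ln space
        X = np.vander(np.log(energies), 3, increasing=True)
        beta = np.linalg.solve(X.T @ X, X.T @ np.log(noisy))
        assert curve.coefficients == pytest.approx(tuple(beta), rel=1e-8)

    def test_too_few_points_rejected(self):
        points = [EfficiencyPoint(100, 0.05), EfficiencyPoint(500, 0.02)]
        with pytest.raises(ValidationError):
            fit_efficiency(points, order=2)

    def test_extrapolation_guard(self):
        points = [EfficiencyPoint(e, 0.05) for e in (200, 500, 1000)]
        curve = fit_efficiency(points, order=1)
        with pytest.raises(ValidationError):
            curve.efficiency(1500)
        assert curve.efficiency(1500, allow_extrapolation=True) > 0


LINE = GammaLine("Pb-214", "Ra-226", 351.9321, 0.356, primary=True)
FLAT_CURVE = EfficiencyCurve(coefficients=(math.log(0.05),), energy_range_kev=(50, 2000))


class TestLineActivity:
    def test_hand_evaluated_activity(self):
        peak = PeakMeasurement(LINE, 8640, 93, 0, 86400, 0.2)
        value, _ = line_activity(peak, FLAT_CURVE)
        # 8640 / (86400 * 0.05 * 0.356 * 0.2)
        assert value == pytest.approx(28.09, abs=0.005)

    def test_empty_peak_gives_zero(self):
        peak = PeakMeasurement(LINE, 0, 0, 100, 86400, 0.2)
        value, unc = line_activity(peak, FLAT_CURVE)
        assert value == 0.0 and unc == 0.0

    def test_inverse_linear_in_mass_and_linear_in_counts(self):
        a1, _ = line_activity(PeakMeasurement(LINE, 5000, 71, 0, 86400, 0.1), FLAT_CURVE)
        a2, _ = line_activity(PeakMeasurement(LINE, 5000, 71, 0, 86400, 0.2), FLAT_CURVE)
        a3, _ = line_activity(PeakMeasurement(LINE, 10000, 100, 0, 86400, 0.1), FLAT_CURVE)
        assert a1 == pytest.approx(2 * a2)
        assert a3 == pytest.approx(2 * a1)

    def test_branching_factor_enters_denominator(self):
        branched = GammaLine("Tl-208", "Th-232", 583.187, 0.85, True, 0.3594)
        plain = GammaLine("Tl-208", "Th-232", 583.187, 0.85, True, 1.0)
        pb = PeakMeasurement(branched, 1000, 32, 0, 86400, 0.2)
        pp = PeakMeasurement(plain, 1000, 32, 0, 86400, 0.2)
        vb, _ = line_activity(pb, FLAT_CURVE)
        vp, _ = line_activity(pp, FLAT_CURVE)
        assert vb == pytest.approx(vp / 0.3594)


class TestMDA:
    def test_zero_background_limit(self):
        mda = minimum_detectable_activity(0, 0.05, 1.0, 86400, 0.2)
        assert mda == pytest.approx(2.71 / 864, rel=1e-12)

    def test_hand_evaluated_currie_value(self):
        mda = minimum_detectable_activity(10000, 0.05, 1.0, 86400, 0.2)
        assert mda == pytest.approx((2.71 + 465.0) / 864, rel=1e-12)

    def test_nondecreasing_in_background(self):
        grid = [minimum_detectable_activity(b, 0.05, 0.5, 86400, 0.2) for b in range(0, 5000, 250)]
        assert all(b >= a for a, b in zip(grid, grid[1:]))

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValidationError):
            minimum_detectable_activity(100, 0.0, 0.5, 86400, 0.2)


class TestQuadrature:
    def test_published_budget_endpoints(self):
        # counting 10% + efficiency 4% + mass 1.5% + intensity 1% -> 10.9%
        assert propagate_uncertainty([0.10, 0.04, 0.015, 0.01]) == pytest.approx(0.109, abs=5e-4)
        # counting 0.5% with the same systematics -> 4.4%
        assert propagate_uncertainty([0.005, 0.04, 0.015, 0.01]) == pytest.approx(0.044, abs=5e-4)

    def test_identity_and_empty(self):
        assert propagate_uncertainty([0.073]) == pytest.approx(0.073)
        assert propagate_uncertainty([]) == 0.0

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(0, 0.5), min_size=1, max_size=6))
    def test_bounded_by_max_component_and_arithmetic_sum(self, comps):
        q = propagate_uncertainty(comps)
        assert q >= max(comps) - 1e-12
        assert q <= sum(comps) + 1e-12


class TestCombineLines:
    def test_single_line_identity(self):
        assert combine_lines([(7.79, 0.46)]) == pytest.approx((7.79, 0.46))

    def test_hand_evaluated_inverse_variance(self):
        value, unc = combine_lines([(10, 1), (12, 2)])
        assert value == pytest.approx(10.4)
        assert unc == pytest.approx(math.sqrt(1 / 1.25))

    def test_equal_values_any_weights(self):
        value, _ = combine_lines([(5.0, 0.3), (5.0, 1.7)])
        assert value == pytest.approx(5.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            combine_lines([])

    @settings(derandomize=True, max_examples=100)
    @given(
        st.lists(
            st.tuples(st.floats(0.1, 100), st.floats(0.01, 10)),
            min_size=1,
            max_size=5,
        )
    )
    def test_bounded_by_inputs_and_uncertainty_shrinks(self, lines):
        value, unc = combine_lines(lines)
        values = [v for v, _ in lines]
        sigmas = [s for _, s in lines]
        assert min(values) - 1e-9 <= value <= max(values) + 1e-9
        assert unc <= min(sigmas) + 1e-12

    def test_plain_mean_fallback(self):
        value, _ = combine_lines([(10, 0), (14, 0)], method="mean")
        assert value == pytest.approx(12.0)
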