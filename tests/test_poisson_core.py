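"""Poisson quantification: estimators, intervals and planning arithmetic."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ddmcn import (
    DropletCounts,
    estimate_lambda,
    expected_positives,
    gating_uncertainty,
    plan_reference_range,
    poisson_ci,
    quantify,
    ratio_estimate,
    to_concentration,
)
from ddmcn.errors import (
    EmptyWellError,
    InfeasibleShiftError,
    SaturatedWellError,
)


class TestEstimateLambda:
    @pytest.mark.parametrize(
        "n_neg, n_total, expected",
        [
            (16000, 16000, 0.0),
            (8000, 16000, math.log(2)),
            (1249, 16000, 2.550245491096340),  # -ln(1249/16000)
        ],
    )
    def test_closed_form(self, n_neg, n_total, expected):
        assert estimate_lambda(n_neg, n_total) == pytest.approx(expected, abs=1e-12)

    def test_saturated_well_raises(self):
        with pytest.raises(SaturatedWellError):
            estimate_lambda(0, 16000)

    def test_empty_well_raises(self):
        with pytest.raises(EmptyWellError):
            estimate_lambda(0, 0)

    @given(lam=st.floats(0.001, 6.0))
    @settings(max_examples=50, deadline=None)
    def test_inverts_poisson_negative_fraction(self, lam):
        """Round-free inversion: estimate(n*exp(-lam), n) returns lam."""
        n_total = 16000
        n_neg = n_total * math.exp(-lam)
        assert -math.log(n_neg / n_total) == pytest.approx(lam, rel=1e-12)


class TestPoissonCI:
    def test_interval_contains_point_estimate(self):
        lam = estimate_lambda(8000, 16000)
        lo, hi = poisson_ci(8000, 16000, 0.95)
        assert lo < lam < hi

    def test_all_negative_interval_starts_at_zero(self):
        lo, hi = poisson_ci(16000, 16000, 0.95)
        assert lo == 0.0
        assert hi > 0.0

    def test_width_shrinks_with_droplet_count(self):
        widths = []
        for n in (1000, 10000, 100000):
            lo, hi = poisson_ci(n // 2, n, 0.95)
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]

    def test_coverage_near_nominal(self, rng):
        """Nominal 95% interval covers true lambda ~95% of the time."""
        lam_true = 1.2
        n_total = 16000
        n_neg = rng.binomial(n_total, math.exp(-lam_true), size=2000)
        hits = 0
        for k in n_neg:
            lo, hi = poisson_ci(int(k), n_total, 0.95)
            hits += lo <= lam_true <= hi
        assert 0.93 <= hits / 2000 <= 0.97


class TestConcentration:
    @pytest.mark.parametrize(
        "lam, vd, expected",
        [
            (0.0, 0.85, 0.0),
            (2.5504, 0.85, 3000.4705882352941),
            (0.0017, 0.85, 2.0),
        ],
    )
    def test_unit_conversion(self, lam, vd, expected):
        assert to_concentration(lam, vd) == pytest.approx(expected, rel=1e-9)

    def test_rejects_nonpositive_volume(self):
        with pytest.raises(ValueError):
            to_concentration(1.0, 0.0)

    def test_quantify_scales_with_dilution(self):
        plain = quantify(8000, 16000)
        diluted = quantify(8000, 16000, dilution_factor=10.0)
        assert diluted.concentration == pytest.approx(10 * plain.concentration)
        assert diluted.ci_high == pytest.approx(10 * plain.ci_high)

    def test_quantify_saturated_is_censored_with_lower_bound(self):
        est = quantify(0, 16000)
        assert est.saturated
        assert math.isnan(est.concentration)
        assert est.ci_low > 0
        assert math.isinf(est.ci_high)


class TestExpectedPositives:
    def test_zero_concentration(self):
        assert expected_positives(0.0, 0.85, 16000) == 0.0

    def test_low_concentration_droplet_counts(self):
        # ~80 positive droplets at 6 copies/ul, ~27 at 2 copies/ul
        assert expected_positives(6.0, 0.85, 16000) == pytest.approx(81.39, abs=0.01)
        assert expected_positives(2.0, 0.85, 16000) == pytest.approx(27.18, abs=0.01)


class TestGatingUncertainty:
    def test_zero_discrepancy_is_exact(self):
        assert gating_uncertainty(3000, 0.85, 16000, 0) == 0.0

    def test_strictly_increasing_in_discrepancy(self):
        values = [gating_uncertainty(3000, 0.85, 16000, d) for d in (10, 50, 100, 200)]
        assert all(a < b for a, b in zip(values, values[1:]))

    def test_increases_with_concentration_above_inflection(self):
        low = gating_uncertainty(3000, 0.85, 16000, 100)
        high = gating_uncertainty(5000, 0.85, 16000, 100)
        assert high > low
        assert low == pytest.approx(0.031, abs=0.005)
        assert high == pytest.approx(0.111, abs=0.005)

    def test_infeasible_shift(self):
        # at 5000 copies/ul only ~228 negatives are expected
        with pytest.raises(InfeasibleShiftError):
            gating_uncertainty(5000, 0.85, 16000, 300)


class TestRatioEstimate:
    def test_identical_estimates_give_unity(self):
        a = quantify(4000, 16000, target="A")
        b = quantify(4000, 16000, target="B")
        r = ratio_estimate(a, b)
        assert r.ratio == pytest.approx(1.0)
        assert r.ci_low < 1.0 < r.ci_high

    def test_division(self):
        a = quantify(round(16000 * math.exp(-270 * 0.00085)), 16000, target="mt")
        b = quantify(round(16000 * math.exp(-2 * 0.00085)), 16000, target="ref")
        r = ratio_estimate(a, b)
        assert r.ratio == pytest.approx(135.0, rel=0.02)

    def test_saturated_denominator_rejected(self):
        a = quantify(4000, 16000)
        b = quantify(0, 16000)
        with pytest.raises(SaturatedWellError):
            ratio_estimate(a, b)

    def test_ci_coverage_on_simulated_duplex_counts(self, rng):
        """Delta-method ratio interval covers the true ratio at ~nominal rate."""
        lam_a, lam_b = 2.0, 0.05
        true_ratio = lam_a / lam_b
        n = 16000
        hits = 0
        trials = 1000
        for _ in range(trials):
            neg_a = int(rng.binomial(n, math.exp(-lam_a)))
            neg_b = int(rng.binomial(n, math.exp(-lam_b)))
            r = ratio_estimate(quantify(neg_a, n), quantify(neg_b, n))
            hits += r.ci_low <= true_ratio <= r.ci_high
        assert hits / trials >= 0.93


class TestPlanReferenceRange:
    def test_single_copy_reference_ceiling(self):
        lo, hi = plan_reference_range(3000, 1, 2, 3000.0)
        assert (lo, hi) == (0.0, 2.0)

    def test_three_copy_reference_ceiling(self):
        _, hi = plan_reference_range(3000, 3, 2, 3000.0)
        assert hi == 6.0

    def test_linearity_in_reference_copies(self):
        _, hi1 = plan_reference_range(1500, 1, 2, 3000.0)
        _, hi3 = plan_reference_range(1500, 3, 2, 3000.0)
        assert hi3 == pytest.approx(3 * hi1)

    def test_zero_mcn_rejected(self):
        with pytest.raises(ValueError):
            plan_reference_range(0.0)


class TestDropletCounts:
    def test_count_bookkeeping_enforced(self):
        with pytest.raises(ValueError):
            DropletCounts("w", 100, 50, {"posA": 40})  # 50 + 40 != 100

    def test_per_target_negatives_in_duplex(self):
        counts = DropletCounts(
            "w", 100, 40, {"posA": 30, "posB": 20, "double": 10}
        )
        # negative for A: fail + posB; negative for B: fail + posA
        assert counts.negatives_for_target("posA") == 60
        assert counts.negatives_for_target("posB") == 70
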