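"""Calibration-model fitting and duplex concentration selection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ddmcn import (
    CalibrationCurve,
    choose_duplex_concentrations,
    efficiency_from_k,
    fit_calibration,
    k_from_length,
    predict_intensity,
)
from ddmcn.errors import DesignInfeasibleError, FitError


class TestRateConstantModel:
    def test_printed_beta_actin_parameters(self):
        # 69-bp amplicon, detector constant 1235, efficiency 1.06
        assert k_from_length(69, 1235, 1.06) == pytest.approx(0.002778, abs=1e-6)

    def test_doubling_efficiency_quarters_k(self):
        assert k_from_length(100, 1235, 2.0) == pytest.approx(
            k_from_length(100, 1235, 1.0) / 4.0
        )

    def test_vanishing_length_limit(self):
        assert k_from_length(1e-9, 1235, 1.0) == pytest.approx(0.0, abs=1e-12)

    @given(
        length=st.floats(50, 250),
        a=st.floats(500, 5000),
        eff=st.floats(0.3, 1.5),
    )
    @settings(max_examples=50, deadline=None)
    def test_round_trip_with_efficiency(self, length, a, eff):
        k = k_from_length(length, a, eff)
        assert efficiency_from_k(k, length, a) == pytest.approx(eff, rel=1e-9)

    def test_unit_efficiency_identity(self):
        k = k_from_length(120, 1235, 1.0)
        assert efficiency_from_k(k, 120, 1235) == pytest.approx(1.0)


class TestPredictIntensity:
    def test_origin_and_plateau(self, ba_curve):
        assert predict_intensity(0.0, ba_curve) == 0.0
        assert predict_intensity(1e7, ba_curve) == pytest.approx(
            ba_curve.plateau, rel=1e-9
        )

    def test_beta_actin_at_100nM(self, ba_curve):
        assert predict_intensity(100.0, ba_curve) == pytest.approx(7277, abs=1.0)

    def test_monotone_in_concentration(self, ba_curve):
        concs = np.linspace(0, 400, 50)
        vals = [predict_intensity(c, ba_curve) for c in concs]
        assert all(a < b for a, b in zip(vals, vals[1:]))
        assert max(vals) < ba_curve.plateau


class TestFitCalibration:
    def test_noiseless_recovery(self, ba_curve):
        concs = [25, 50, 100, 200]
        points = [(c, predict_intensity(c, ba_curve)) for c in concs]
        fitted = fit_calibration(points, plateau=30000.0)
        assert fitted.k == pytest.approx(ba_curve.k, rel=1e-6)

    def test_free_plateau_noiseless_recovery(self, ba_curve):
        concs = [25, 50, 100, 200, 400, 800]
        points = [(c, predict_intensity(c, ba_curve)) for c in concs]
        fitted = fit_calibration(points, plateau=None)
        assert fitted.plateau == pytest.approx(30000.0, rel=1e-4)
        assert fitted.k == pytest.approx(ba_curve.k, rel=1e-4)

    def test_single_point_algebraic_solution(self, ba_curve):
        intensity = predict_intensity(100.0, ba_curve)
        fitted = fit_calibration([(100.0, intensity)], plateau=30000.0)
        assert fitted.k == pytest.approx(ba_curve.k, rel=1e-9)

    def test_noisy_four_point_design(self, ba_curve, rng):
        """2% intensity noise on the standard 4-concentration design: k within 5%."""
        concs = [25, 50, 100, 200]
        errors = []
        for _ in range(20):
            points = [
                (c, predict_intensity(c, ba_curve) * (1 + 0.02 * rng.standard_normal()))
                for c in concs
            ]
            fitted = fit_calibration(points, plateau=30000.0)
            errors.append(abs(fitted.k - ba_curve.k) / ba_curve.k)
        assert np.median(errors) < 0.05

    def test_insufficient_points_rejected(self):
        with pytest.raises(FitError):
            fit_calibration([(50, 5000), (100, 9000)], plateau=None)

    def test_all_zero_intensities_rejected(self):
        with pytest.raises(FitError):
            fit_calibration([(50, 0.0), (100, 0.0)], plateau=30000.0)

    def test_model_forms_superimpose(self, ba_curve):
        """Free-k fit and length/efficiency parameterisation coincide when
        efficiency is set from the fitted k."""
        points = [(c, predict_intensity(c, ba_curve)) for c in (25, 50, 100, 200)]
        fitted = fit_calibration(points, plateau=30000.0)
        eff = efficiency_from_k(fitted.k, 69, 1235)
        reparam = CalibrationCurve(plateau=30000.0, k=k_from_length(69, 1235, eff))
        for c in (10, 60, 150, 300):
            assert predict_intensity(c, reparam) == pytest.approx(
                predict_intensity(c, fitted), rel=1e-9
            )


class TestChooseDuplexConcentrations:
    def test_identical_curves_hit_required_gap_exactly(self, ba_curve):
        conc_a, conc_b = choose_duplex_concentrations(
            ba_curve, ba_curve, sd_a=1500.0, sd_b=1500.0, separation_multiple=2.0
        )
        gap = abs(
            predict_intensity(conc_a, ba_curve) - predict_intensity(conc_b, ba_curve)
        )
        assert gap == pytest.approx(6000.0, rel=1e-6)

    def test_grid_search_oracle_agreement(self, ba_curve):
        """Brute-force grid reproduces the selected pair's gap and feasibility."""
        sd = 1200.0
        conc_a, conc_b = choose_duplex_concentrations(
            ba_curve, ba_curve, sd, sd, separation_multiple=2.0
        )
        grid = np.arange(10.0, 501.0, 1.0)
        mu = 30000.0 * (1 - np.exp(-ba_curve.k * grid))
        gaps = np.abs(mu[:, None] - mu[None, :])
        feasible = gaps[gaps >= 2 * (sd + sd)]
        best_grid_gap = feasible.min()
        chosen_gap = abs(
            predict_intensity(conc_a, ba_curve) - predict_intensity(conc_b, ba_curve)
        )
        assert chosen_gap <= best_grid_gap + 1e-6

    def test_zero_multiple_allows_equal_concentrations(self, ba_curve):
        conc_a, conc_b = choose_duplex_concentrations(
            ba_curve, ba_curve, 1500.0, 1500.0, separation_multiple=0.0
        )
        assert conc_a == conc_b

    def test_infeasible_separation_raises(self, ba_curve):
        with pytest.raises(DesignInfeasibleError):
            choose_duplex_concentrations(
                ba_curve, ba_curve, 20000.0, 20000.0, separation_multiple=2.0
            )
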