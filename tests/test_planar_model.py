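"""Spiral fitting and the curvature-limit / ring geometry model."""

import math

import numpy as np
import pytest

from vippgeom.errors import InsufficientArcError, InvalidArgumentError, TraceError
from vippgeom.planar_model import (
    CurvatureModel,
    fit_spiral,
    min_planar_diameter,
    protofilament_count,
    requires_tilt,
    ring_geometry,
    ring_spacing_at_radius,
    simulate_spiral_trace,
    spacing_across_bend,
)


class TestFitSpiral:
    def test_exact_archimedean_recovery(self):
        trace = simulate_spiral_trace("archimedean", 10.0, 5.0, 80, 2.5)
        fit = fit_spiral(trace, "archimedean")
        assert fit.a == pytest.approx(10.0, abs=1e-7)
        assert fit.b == pytest.approx(5.0, abs=1e-8)
        assert fit.rms_residual_nm < 1e-9

    def test_exact_exponential_recovery(self):
        trace = simulate_spiral_trace("exponential", 8.0, 0.15, 80, 2.5)
        fit = fit_spiral(trace, "exponential")
        assert fit.a == pytest.approx(8.0, abs=1e-6)
        assert fit.b == pytest.approx(0.15, abs=1e-8)

    def test_center_recovered_with_offset(self):
        trace = simulate_spiral_trace("archimedean", 10.0, 5.0, 80, 2.0, center=(30.0, -12.0))
        fit = fit_spiral(trace, "archimedean")
        assert fit.center[0] == pytest.approx(30.0, abs=1e-6)
        assert fit.center[1] == pytest.approx(-12.0, abs=1e-6)

    def test_noisy_exponential_b_within_ten_percent(self):
        """b recovered within 10% RMSE at 0.5 nm noise over 100 draws."""
        errs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            trace = simulate_spiral_trace("exponential", 8.0, 0.15, 100, 2.5,
                                          noise_sd_nm=0.5, rng=rng)
            fit = fit_spiral(trace, "exponential")
            errs.append(fit.b / 0.15 - 1.0)
        errs = np.asarray(errs)
        assert abs(errs.mean()) < 0.02  # bias
        assert math.sqrt((errs**2).mean()) < 0.10  # RMSE

    def test_auto_model_selection(self):
        """AIC picks the generating form on >= 95% of 200 noisy traces."""
        rng = np.random.default_rng(42)
        correct = 0
        for i in range(200):
            if i % 2 == 0:
                model, a, b = "archimedean", rng.uniform(8, 12), rng.uniform(3, 6)
            else:
                model, a, b = "exponential", rng.uniform(7, 10), rng.uniform(0.12, 0.2)
            trace = simulate_spiral_trace(model, a, b, 100, 2.5, noise_sd_nm=0.5, rng=rng)
            if fit_spiral(trace, "auto").model == model:
                correct += 1
        assert correct >= 190

    def test_insufficient_arc(self):
        trace = simulate_spiral_trace("archimedean", 10.0, 5.0, 40, 1.0)
        with pytest.raises(InsufficientArcError):
            fit_spiral(trace)

    def test_non_monotone_trace(self):
        trace = simulate_spiral_trace("archimedean", 10.0, 5.0, 80, 2.5)
        scrambled = np.random.default_rng(0).permutation(trace)
        with pytest.raises((TraceError, InsufficientArcError)):
            fit_spiral(scrambled)

    def test_too_few_points(self):
        with pytest.raises(InvalidArgumentError):
            fit_spiral(np.zeros((5, 2)))


class TestCurvatureModel:
    def test_straight_filament_limit(self):
        s_in, s_out = spacing_across_bend(1e12)
        assert s_in == pytest.approx(54.0, abs=1e-6)
        assert s_out == pytest.approx(54.0, abs=1e-6)

    def test_stretch_bound_radius(self):
        # R solving s0 (R + w/2)/R = s_max
        _, s_out = spacing_across_bend(54.0 * 67.0 / 7.0)
        assert s_out == pytest.approx(61.0, abs=1e-9)

    def test_compression_bound_radius(self):
        s_in, _ = spacing_across_bend(54.0 * 67.0 / 13.0)
        assert s_in == pytest.approx(41.0, abs=1e-9)

    def test_self_overlap_rejected(self):
        with pytest.raises(InvalidArgumentError):
            spacing_across_bend(60.0)  # below half-width 67 Å

    def test_ordering_property(self):
        for R in (70.0, 150.0, 600.0, 5000.0):
            s_in, s_out = spacing_across_bend(R)
            assert s_in < 54.0 < s_out

    def test_min_planar_diameter_default(self):
        assert min_planar_diameter() == pytest.approx(103.37, abs=0.01)

    def test_min_planar_diameter_brute_force_agreement(self):
        """Closed form agrees with a scan of the spacing constraints to 0.1%."""
        model = CurvatureModel()
        radii = np.linspace(68.0, 2000.0, 400000)
        s_in = model.s0_A * (radii - model.width_A / 2) / radii
        s_out = model.s0_A * (radii + model.width_A / 2) / radii
        feasible = (s_in >= model.s_min_A) & (s_out <= model.s_max_A)
        brute = 2.0 * radii[feasible].min() / 10.0
        assert min_planar_diameter(model) == pytest.approx(brute, rel=1e-3)

    def test_zero_width_bends_freely(self):
        model = CurvatureModel(width_A=1e-9)
        assert min_planar_diameter(model) == pytest.approx(0.0, abs=1e-8)

    def test_symmetric_bounds_coincide(self):
        model = CurvatureModel(s0_A=54.0, s_min_A=47.0, s_max_A=61.0)
        half = model.width_A / 2.0
        assert 54.0 * half / 7.0 == pytest.approx(54.0 * half / 7.0)
        assert min_planar_diameter(model) == pytest.approx(2 * 54.0 * half / 7.0 / 10.0)

    def test_monotone_in_width(self):
        d = [min_planar_diameter(CurvatureModel(width_A=w)) for w in (60, 100, 134, 200)]
        assert d == sorted(d)

    def test_requires_tilt(self):
        assert requires_tilt(37.0) is True
        assert requires_tilt(200.0) is False
        assert requires_tilt(min_planar_diameter()) is False  # boundary feasible

    def test_sensitivity_to_bound_uncertainty(self):
        # the +/- 2 Å uncertainty on the ~41/~61 Å bounds moves the limit
        lo = min_planar_diameter(CurvatureModel(s_min_A=39.0, s_max_A=63.0))
        hi = min_planar_diameter(CurvatureModel(s_min_A=43.0, s_max_A=59.0))
        assert lo < min_planar_diameter() < hi
        assert requires_tilt(37.0, CurvatureModel(s_min_A=39.0, s_max_A=63.0))


class TestRings:
    def test_c17_ring(self):
        ring = ring_geometry(17, diameter_A=340.0)
        assert ring.subunit_arc_A == pytest.approx(62.8, abs=0.1)

    def test_c11_ring(self):
        assert ring_geometry(11, diameter_A=240.0).subunit_arc_A == pytest.approx(68.5, abs=0.1)

    def test_central_rung_spacing_in_measured_range(self):
        ring = ring_geometry(17, diameter_A=340.0)
        s = ring_spacing_at_radius(ring, 146.0)
        assert s == pytest.approx(54.0, abs=0.1)
        assert 53.0 <= s <= 59.0

    def test_round_trip_exact(self):
        ring = ring_geometry(14, diameter_A=300.0)
        back = ring_geometry(14, subunit_arc_A=ring.subunit_arc_A)
        assert back.diameter_A == pytest.approx(300.0, rel=1e-15)

    def test_argument_checks(self):
        with pytest.raises(InvalidArgumentError):
            ring_geometry(17)
        with pytest.raises(InvalidArgumentError):
            ring_geometry(17, diameter_A=300.0, subunit_arc_A=55.0)
        with pytest.raises(InvalidArgumentError):
            ring_geometry(2, diameter_A=300.0)


@pytest.mark.parametrize(
    "width, spacing, expected",
    [(122.0, 32.5, 4), (134.0, 32.5, 4), (65.0, 32.5, 2), (160.0, 32.5, 5), (10.0, 32.5, 1)],
)
def test_protofilament_count(width, spacing, expected):
    assert protofilament_count(width, spacing) == expected
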