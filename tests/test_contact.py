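"""Hertz sphere model, depth-segmented fits, bottom-effect correction."""
import numpy as np
import pytest

from fdmech import (DomainError, InsufficientDataError, bottom_effect_fit,
                    bottom_effect_force, hertz_force, hertz_slope_fit,
                    locate_contact_point, segmented_moduli, to_indentation)
from fdmech.model import IndentationCurve

from conftest import make_curve

R = 65.0


def hertz_indentation(e_kpa, deltas, nu=0.5, r=R):
    """Build an IndentationCurve directly from the closed-form sphere model."""
    f = (4.0 / 3.0) * (e_kpa * 1e-3) / (1 - nu ** 2) * np.sqrt(r) * deltas ** 1.5
    return IndentationCurve(contact_point=0.0, delta=deltas, force=f)


class TestHertzForce:
    def test_printed_parameters_evaluate_to_27pN(self):
        # independent arithmetic: (4/3)(5.3e-3/0.75) sqrt(65) 50^{3/2}
        expected = (4.0 / 3.0) * (5.3e-3 / 0.75) * 65.0 ** 0.5 * 50.0 ** 1.5
        got = hertz_force(5.3, R, 50.0, 0.5)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(26.9, abs=0.1)

    def test_zero_indentation_zero_force(self):
        assert hertz_force(5.3, R, 0.0) == 0.0

    def test_linear_in_modulus(self):
        assert hertz_force(10.6, R, 30.0) == pytest.approx(
            2 * hertz_force(5.3, R, 30.0), rel=1e-12)

    def test_negative_indentation_rejected(self):
        with pytest.raises(DomainError):
            hertz_force(5.3, R, -1.0)


class TestHertzSlopeFit:
    def test_noise_free_round_trip(self):
        deltas = np.linspace(0.5, 200.0, 300)
        curve = hertz_indentation(10.7, deltas)
        e, rms = hertz_slope_fit(curve, (0.0, 200.0), R)
        assert e == pytest.approx(10.7, rel=1e-3)
        assert rms < 1e-9

    def test_scale_equivariance(self):
        deltas = np.linspace(0.5, 150.0, 200)
        curve = hertz_indentation(8.0, deltas)
        scaled = IndentationCurve(0.0, curve.delta, 3.0 * curve.force)
        e1, _ = hertz_slope_fit(curve, (0.0, 150.0), R)
        e2, _ = hertz_slope_fit(scaled, (0.0, 150.0), R)
        assert e2 == pytest.approx(3.0 * e1, rel=1e-9)

    def test_monte_carlo_median_error_below_10pct(self):
        # sigma = 15 pN on the full-depth fit, 100 seeds
        deltas = np.linspace(0.5, 200.0, 280)
        clean = hertz_indentation(10.7, deltas)
        errs = []
        for s in range(100):
            rng = np.random.default_rng(s)
            noisy = IndentationCurve(0.0, deltas,
                                     clean.force + rng.normal(0, 15.0, deltas.size))
            e, _ = hertz_slope_fit(noisy, (0.0, 200.0), R)
            errs.append(abs(e - 10.7) / 10.7)
        assert np.median(errs) < 0.10

    def test_sparse_window_raises(self):
        curve = hertz_indentation(5.0, np.linspace(1, 200, 20))
        with pytest.raises(InsufficientDataError):
            hertz_slope_fit(curve, (0.0, 10.0), R)

    def test_nonpositive_slope_flags_failure(self):
        deltas = np.linspace(0.5, 100.0, 100)
        curve = IndentationCurve(0.0, deltas, -np.ones(100))
        e, _ = hertz_slope_fit(curve, (0.0, 100.0), R)
        assert e is None


class TestSegmentedModuli:
    def test_two_layer_noise_free_recovery(self):
        # forward-simulate the piecewise model, fit both windows within 5%
        curve = make_curve(e_pm=5.3, e_cortex=37.5, noise_sd=0.0)
        z0 = locate_contact_point(curve)
        ind = to_indentation(curve, z0, curve.acquisition.spring_constant)
        fit = segmented_moduli(ind, R)
        assert fit.e_pm == pytest.approx(5.3, rel=0.05)
        assert fit.e_cortex == pytest.approx(37.5, rel=0.05)

    def test_homogeneous_consistency(self):
        curve = make_curve(e_pm=12.0, e_cortex=12.0, noise_sd=0.0)
        z0 = locate_contact_point(curve)
        ind = to_indentation(curve, z0, curve.acquisition.spring_constant)
        fit = segmented_moduli(ind, R)
        assert fit.e_pm == pytest.approx(fit.e_cortex, rel=0.02)

    def test_shallow_curve_has_no_cortex_value(self):
        deltas = np.linspace(0.5, 40.0, 60)
        fit = segmented_moduli(hertz_indentation(5.0, deltas), R)
        assert fit.e_pm is not None
        assert fit.e_cortex is None


class TestBottomEffect:
    def test_thick_layer_limit_equals_hertz(self):
        # alpha -> 0: (16/9)E equals (4/3)E/(1 - 0.25) exactly
        f_be = bottom_effect_force(10.0, R, 50.0, layer_thickness=np.inf)
        f_h = hertz_force(10.0, R, 50.0, 0.5)
        assert f_be == pytest.approx(f_h, rel=1e-12)

    def test_printed_polynomial_factor(self):
        # independent Horner evaluation of the printed coefficients
        alpha = np.sqrt(R * 50.0) / 200.0
        expected = 1.0 + 0.884 * alpha + 0.781 * alpha ** 2 \
            + 0.386 * alpha ** 3 + 0.0048 * alpha ** 4
        ratio = bottom_effect_force(10.0, R, 50.0, 200.0) \
            / hertz_force(10.0, R, 50.0, 0.5)
        assert ratio == pytest.approx(expected, rel=1e-12)
        assert ratio == pytest.approx(1.324, abs=5e-4)

    def test_force_increases_as_layer_thins(self):
        forces = [bottom_effect_force(10.0, R, 50.0, h)
                  for h in (400.0, 200.0, 100.0, 50.0)]
        assert np.all(np.diff(forces) > 0)

    def test_fit_round_trip_machine_precision(self):
        deltas = np.linspace(0.5, 50.0, 120)
        f = bottom_effect_force(10.7, R, deltas, 50.0)
        curve = IndentationCurve(0.0, deltas, f)
        e, rms = bottom_effect_fit(curve, (0.0, 50.0), R, 50.0)
        assert e == pytest.approx(10.7, rel=1e-12)
        assert rms < 1e-9

    def test_plain_hertz_overestimates_on_thin_layer(self):
        deltas = np.linspace(0.5, 50.0, 120)
        f = bottom_effect_force(10.7, R, deltas, 50.0)
        curve = IndentationCurve(0.0, deltas, f)
        e_hertz, _ = hertz_slope_fit(curve, (0.0, 50.0), R)
        assert e_hertz > 10.7

    def test_zero_force_flags_failure(self):
        deltas = np.linspace(0.5, 50.0, 120)
        curve = IndentationCurve(0.0, deltas, np.zeros(120))
        e, _ = bottom_effect_fit(curve, (0.0, 50.0), R, 50.0)
        assert e is None

    def test_invalid_thickness_rejected(self):
        with pytest.raises(DomainError):
            bottom_effect_force(10.0, R, 50.0, 0.0)

    def test_deviation_at_tiny_alpha_is_analytic_remainder(self):
        # at alpha = 1e-6 the deviation from the half-space model is the
        # polynomial's own leading term, 0.884 alpha, to 1e-10
        alpha = 1e-6
        delta = 50.0
        h = np.sqrt(R * delta) / alpha
        rel = bottom_effect_force(5.0, R, delta, h) \
            / hertz_force(5.0, R, delta, 0.5) - 1.0
        remainder = 0.884 * alpha + 0.781 * alpha ** 2 \
            + 0.386 * alpha ** 3 + 0.0048 * alpha ** 4
        assert abs(rel - remainder) < 1e-10
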