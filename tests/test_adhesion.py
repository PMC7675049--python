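"""Rupture detection, WLC validation, specificity and strata."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fdmech import (AdhesionEvent, DomainError, WLCParams, classify_specific,
                    detect_ruptures, stratify_pixel, validate_wlc, wlc_force)
from fdmech.adhesion import wlc_extension_at_force
from fdmech.model import (STRATUM_CHOLESTEROL, STRATUM_INDETERMINATE,
                          STRATUM_NON_ADHESIVE)
from fdmech.pipeline import RunConfig, _iterated_contact
from fdmech.preprocess import NoiseEstimate
from fdmech.units import thermal_energy

from conftest import flat_noise_curve, make_curve


def processed(curve, cfg=None):
    cfg = cfg or RunConfig(mechanics=False)
    f_corr, noise, z0 = _iterated_contact(curve, cfg)
    return curve.with_retract_force(f_corr), noise, z0


class TestWLCModel:
    def test_zero_extension_zero_force(self):
        assert wlc_force(0.0, WLCParams(0.38, 30.0)) == 0.0

    def test_half_contour_closed_form(self):
        # F(Lc/2) = 1.25 kBT / Lp
        kbt = thermal_energy(310.0)
        params = WLCParams(0.38, 30.0, thermal_energy=kbt)
        assert wlc_force(15.0, params) == pytest.approx(1.25 * kbt / 0.38,
                                                        rel=1e-12)
        assert wlc_force(15.0, params) == pytest.approx(14.08, abs=0.02)

    def test_monotone_divergence_toward_contour_length(self):
        params = WLCParams(0.38, 30.0)
        x = np.linspace(0.0, 29.9, 200)
        f = wlc_force(x, params)
        assert (np.diff(f) > 0).all()
        assert f[-1] > 100 * f[100]

    def test_extension_beyond_contour_rejected(self):
        with pytest.raises(DomainError):
            wlc_force(30.0, WLCParams(0.38, 30.0))


class TestDetection:
    def test_single_injected_rupture_recovered(self):
        curve = make_curve(with_event=True, noise_sd=15.0, seed=5)
        f_rup, s_rup, _, _ = curve.scene.events[(0, 0)]
        corr, noise, z0 = processed(curve)
        cands = detect_ruptures(corr, noise, z0)
        near = [c for c in cands if abs(c.rupture_distance - s_rup) < 10.0]
        assert len(near) == 1
        assert near[0].rupture_force == pytest.approx(f_rup, abs=3 * 15.0)

    def test_flat_noise_rarely_fires(self):
        # >= 95% of 500 seeded flat curves yield zero candidates (3-sigma rule)
        fires = 0
        for s in range(500):
            curve = flat_noise_curve(sigma=15.0, seed=s)
            if detect_ruptures(curve, NoiseEstimate(15.0, 150), 220.0):
                fires += 1
        assert fires / 500 <= 0.05

    def test_candidates_ordered_by_distance(self):
        # two synthetic tether ruptures on one curve
        from fdmech.model import ForceCurve
        z = np.linspace(370.0, 0.0, 512)
        f = np.zeros(512)
        z0 = 220.0
        for target, depth in ((9.0, 120.0), (24.0, 150.0)):
            sep = z0 - z
            ramp = (sep > target - 6) & (sep <= target)
            f[ramp] -= depth * (sep[ramp] - (target - 6)) / 6.0
        curve = ForceCurve(z[::-1].copy(), f[::-1].copy(), z, f)
        cands = detect_ruptures(curve, NoiseEstimate(10.0, 150), z0)
        assert len(cands) == 2
        assert cands[0].rupture_distance < cands[1].rupture_distance

    def test_detection_sensitivity_and_fdr(self):
        # N(130, 35) pN tethers against 15 pN noise, 300 curves;
        # matches within 12 nm (3x the contact-point uncertainty)
        detected = n_cand = n_false = 0
        for s in range(300):
            curve = make_curve(with_event=True, noise_sd=15.0, seed=1000 + s)
            f_rup, s_rup, _, _ = curve.scene.events[(0, 0)]
            corr, noise, z0 = processed(curve)
            cands = detect_ruptures(corr, noise, z0)
            near = [c for c in cands if abs(c.rupture_distance - s_rup) < 12.0]
            detected += bool(near)
            n_cand += len(cands)
            n_false += len(cands) - len(near)
        assert detected / 300 >= 0.95
        assert n_false / max(n_cand, 1) <= 0.05


class TestValidateWLC:
    def test_round_trip_contour_length(self):
        recovered = []
        for s in range(30):
            curve = make_curve(with_event=True, noise_sd=15.0, seed=200 + s)
            f_rup, s_rup, lc, _ = curve.scene.events[(0, 0)]
            corr, noise, z0 = processed(curve)
            cands = detect_ruptures(corr, noise, z0)
            near = [c for c in cands if abs(c.rupture_distance - s_rup) < 10.0]
            if not near:
                continue
            wlc = validate_wlc(corr, near[0], noise, z0)
            if isinstance(wlc, WLCParams):
                recovered.append(abs(wlc.contour_length - lc) / lc)
        assert len(recovered) >= 20
        assert np.median(recovered) < 0.10

    @pytest.mark.parametrize("seed", range(8))
    def test_hookean_segment_rejected(self, seed):
        # a linear spring of equal depth (130 pN over 8 nm) is not WLC-like:
        # the RMS criterion rejects it whenever the shape misfit dominates
        # the noise floor (sigma = 5 pN here, so 2 sigma = 10 pN)
        from fdmech.model import ForceCurve
        rng = np.random.default_rng(seed)
        z = np.linspace(370.0, 0.0, 512)
        z0 = 220.0
        sep = np.clip(z0 - z, 0.0, None)
        f = np.where((sep > 0) & (sep <= 8.0), -130.0 / 8.0 * sep, 0.0)
        f = f + rng.normal(0, 5.0, 512)
        curve = ForceCurve(z[::-1].copy(), f[::-1].copy(), z, f)
        noise = NoiseEstimate(5.0, 150)
        cands = detect_ruptures(curve, noise, z0)
        assert cands, "spring detachment should register as a candidate"
        rejected = validate_wlc(curve, cands[0], noise, z0)
        assert not isinstance(rejected, WLCParams)

    def test_short_segment_rejected_with_reason(self):
        from fdmech.adhesion import RuptureCandidate
        curve = make_curve(with_event=True, noise_sd=15.0, seed=5)
        corr, noise, z0 = processed(curve)
        cand = RuptureCandidate(130.0, 2.0, index=300, start_index=298)
        # force the segment to be minuscule: rupture right at contact
        off = np.flatnonzero(corr.retract_z < z0)
        cand = RuptureCandidate(130.0, 2.0, index=int(off[0]) + 3,
                                start_index=int(off[0]))
        rej = validate_wlc(corr, cand, noise, z0)
        assert rej.reason == "too short"


class TestClassification:
    def test_printed_mean_event_is_specific(self):
        wlc = WLCParams(0.38, 30.0)
        ev = AdhesionEvent(141.0, 12.0, wlc=wlc)
        assert classify_specific(ev)

    def test_below_force_threshold_not_specific(self):
        ev = AdhesionEvent(60.0, 12.0, wlc=WLCParams(0.38, 30.0))
        assert not classify_specific(ev)

    def test_below_distance_threshold_not_specific(self):
        ev = AdhesionEvent(141.0, 3.0, wlc=WLCParams(0.38, 30.0))
        assert not classify_specific(ev)

    def test_missing_wlc_not_specific(self):
        assert not classify_specific(AdhesionEvent(141.0, 12.0, wlc=None))

    @settings(max_examples=60, deadline=None)
    @given(force=st.floats(0.0, 400.0), distance=st.floats(0.0, 60.0),
           df=st.floats(0.0, 100.0), dd=st.floats(0.0, 20.0))
    def test_monotone_in_force_and_distance(self, force, distance, df, dd):
        wlc = WLCParams(0.38, 30.0)
        base = classify_specific(AdhesionEvent(force, distance, wlc=wlc))
        raised = classify_specific(AdhesionEvent(force + df, distance + dd,
                                                 wlc=wlc))
        assert (not base) or raised


class TestStratification:
    def test_specific_129pN_event_is_cholesterol(self):
        ev = AdhesionEvent(129.0, 12.0, wlc=WLCParams(0.38, 30.0), specific=True)
        assert stratify_pixel([ev]) == STRATUM_CHOLESTEROL

    def test_no_candidates_is_non_adhesive(self):
        assert stratify_pixel([]) == STRATUM_NON_ADHESIVE

    def test_gap_force_is_indeterminate(self):
        ev = AdhesionEvent(60.0, 12.0, wlc=None, specific=False)
        assert stratify_pixel([ev]) == STRATUM_INDETERMINATE

    def test_small_forces_stay_non_adhesive(self):
        evs = [AdhesionEvent(20.0, 8.0, wlc=None, specific=False)]
        assert stratify_pixel(evs) == STRATUM_NON_ADHESIVE


def test_wlc_extension_inverse_consistency():
    params = WLCParams(0.38, 30.0)
    x = wlc_extension_at_force(130.0, params)
    assert wlc_force(x, params) == pytest.approx(130.0, rel=1e-3)
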