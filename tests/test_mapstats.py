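"""Map assembly, binding probability, domains, strata, derived ratios."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fdmech import (AdhesionEvent, DomainError, WLCParams, assemble_maps,
                    binding_probability, build_scene, domain_sizes,
                    fold_change, percent_change, simulate_map,
                    stratified_pm_elasticity)
from fdmech.model import (STRATUM_CHOLESTEROL, STRATUM_INDETERMINATE,
                          STRATUM_NON_ADHESIVE)


def empty_map(rows=5, cols=5, seed=0):
    scene = build_scene(rows, cols, coverage=0.0, seed=seed)
    return simulate_map(scene, seed=seed, n_samples=64)


def with_mask(fv, mask):
    fv.channels["height"] = np.zeros(fv.shape)
    fv.specific_mask = mask.astype(bool)
    return fv


class TestAssembly:
    def test_all_channels_share_grid(self):
        fv = empty_map(8, 8)
        results = {(r, c): {"height": 100.0, "e_pm": 5.0, "e_cortex": 20.0}
                   for r in range(8) for c in range(8)}
        fv = assemble_maps(fv, results)
        for name in ("height", "e_pm", "e_cortex", "adhesion_force"):
            assert fv.channels[name].shape == (8, 8)
        assert fv.specific_mask.shape == (8, 8)

    def test_no_contact_pixel_absent_everywhere(self):
        fv = empty_map(4, 4)
        results = {(r, c): {"height": 100.0, "e_pm": 5.0}
                   for r in range(4) for c in range(4) if (r, c) != (1, 2)}
        fv = assemble_maps(fv, results)
        assert np.isnan(fv.channels["height"][1, 2])
        assert np.isnan(fv.channels["e_pm"][1, 2])
        assert not fv.specific_mask[1, 2]

    def test_specific_pixels_match_events(self):
        fv = empty_map(4, 4)
        wlc = WLCParams(0.38, 30.0)
        ev = AdhesionEvent(120.0, 10.0, wlc=wlc, specific=True, row=2, col=3)
        results = {(2, 3): {"height": 100.0, "events": [ev],
                            "adhesion_force": 120.0}}
        fv = assemble_maps(fv, results)
        assert fv.specific_mask[2, 3]
        assert fv.specific_mask.sum() == 1
        assert len(fv.events) == 1


class TestBindingProbability:
    def test_basic_percentage(self):
        fv = empty_map(10, 10)
        mask = np.zeros((10, 10))
        mask.flat[:8] = 1
        fv = with_mask(fv, mask)
        assert binding_probability(fv) == pytest.approx(8.0)

    def test_empty_mask_is_zero(self):
        fv = with_mask(empty_map(), np.zeros((5, 5)))
        assert binding_probability(fv) == 0.0

    def test_no_analyzed_pixels_flagged(self):
        fv = with_mask(empty_map(), np.zeros((5, 5)))
        fv.channels["height"] = np.full((5, 5), np.nan)
        with pytest.raises(DomainError):
            binding_probability(fv)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2 ** 16 - 1))
    def test_equals_mask_mean_times_100(self, bits):
        mask = np.array([(bits >> i) & 1 for i in range(16)]).reshape(4, 4)
        fv = with_mask(empty_map(4, 4), mask)
        assert binding_probability(fv) == pytest.approx(100.0 * mask.mean())


class TestDomains:
    def test_connectivity_semantics(self):
        # two diagonal-touching blobs: one domain under 8, two under 4
        mask = np.zeros((5, 5))
        mask[0, 0] = mask[0, 1] = mask[1, 1] = 1          # 3 px
        mask[2, 2] = mask[2, 3] = mask[3, 2] = mask[3, 3] = 1  # 4 px
        fv = with_mask(empty_map(), mask)
        assert sorted(domain_sizes(fv, connectivity=8).sizes_px.tolist()) == [7]
        assert sorted(domain_sizes(fv, connectivity=4).sizes_px.tolist()) == [3, 4]

    def test_single_pixel_domain_area(self):
        mask = np.zeros((5, 5))
        mask[2, 2] = 1
        fv = with_mask(empty_map(), mask)
        ds = domain_sizes(fv)
        assert ds.sizes_px.tolist() == [1]
        assert ds.areas_nm2[0] == pytest.approx(100.0 * 100.0)

    def test_generator_blobs_recovered_exactly(self):
        from skimage import measure
        scene = build_scene(32, 32, coverage=0.2, seed=9)
        fv = with_mask(empty_map(4, 4), np.zeros((4, 4)))
        fv.specific_mask = scene.domain_mask
        fv.channels["height"] = np.zeros((32, 32))
        ds = domain_sizes(fv, connectivity=8)
        labels = measure.label(scene.domain_mask, connectivity=2)
        expected = sorted(np.bincount(labels.ravel())[1:].tolist(), reverse=True)
        assert ds.sizes_px.tolist() == expected

    def test_sizes_sum_to_specific_pixels(self):
        scene = build_scene(24, 24, coverage=0.3, seed=4)
        fv = with_mask(empty_map(4, 4), np.zeros((4, 4)))
        fv.specific_mask = scene.domain_mask
        fv.channels["height"] = np.zeros((24, 24))
        ds = domain_sizes(fv)
        assert ds.sizes_px.sum() == scene.domain_mask.sum()


class TestStratifiedElasticity:
    def make(self, strata, e_pm):
        fv = empty_map(*strata.shape)
        fv.channels["e_pm"] = e_pm
        fv.stratum = strata.astype(np.int8)
        return fv

    def test_groups_split_by_stratum(self):
        strata = np.full((4, 4), STRATUM_NON_ADHESIVE, dtype=int)
        strata[:2] = STRATUM_CHOLESTEROL
        e = np.where(strata == STRATUM_CHOLESTEROL, 13.1, 9.0).astype(float)
        groups = stratified_pm_elasticity(self.make(strata, e))
        assert np.allclose(groups["cholesterol"], 13.1)
        assert np.allclose(groups["non_adhesive"], 9.0)

    def test_indeterminate_excluded(self):
        strata = np.full((3, 3), STRATUM_INDETERMINATE, dtype=int)
        e = np.ones((3, 3))
        groups = stratified_pm_elasticity(self.make(strata, e))
        assert groups["cholesterol"].size == 0
        assert groups["non_adhesive"].size == 0

    def test_homogeneous_null_case(self):
        strata = np.zeros((4, 4), dtype=int)
        strata[::2] = STRATUM_CHOLESTEROL
        e = np.full((4, 4), 7.7)
        groups = stratified_pm_elasticity(self.make(strata, e))
        assert np.mean(groups["cholesterol"]) == pytest.approx(
            np.mean(groups["non_adhesive"]))


class TestDerivedRatios:
    def test_cortex_decrease_57pct(self):
        assert percent_change(37.5, 15.9) == pytest.approx(57.6, abs=0.05)

    def test_mbcd_pm_decrease_44pct(self):
        assert percent_change(6.1, 3.4) == pytest.approx(44.3, abs=0.05)

    def test_null_change(self):
        assert percent_change(8.8, 8.8) == 0.0

    def test_invalid_baseline_rejected(self):
        with pytest.raises(DomainError):
            percent_change(0.0, 1.0)

    def test_fold_changes_from_printed_moduli(self):
        assert fold_change(10.7, 5.3) == pytest.approx(2.02, abs=0.005)
        assert fold_change(10.7, 3.7) == pytest.approx(2.89, abs=0.005)
        assert fold_change(4.2, 4.2) == 1.0

    def test_zero_denominator_rejected(self):
        with pytest.raises(DomainError):
            fold_change(1.0, 0.0)
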