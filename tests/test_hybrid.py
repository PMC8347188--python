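"""Hybrid workflow: spine erasure, network-seeded lumen, thrombus cleanup."""

import numpy as np
import pytest

from vesselseg import expert_system as es
from vesselseg.hybrid import (HybridConfig, _fit_ellipse_mask, erase_spine,
                              postprocess_thrombus, segment_lumen_hybrid,
                              segment_thrombus_hybrid)
from vesselseg.imaging_io import BinaryMask3D
from vesselseg.metrics import evaluate
from vesselseg.phantom import PhantomSpec, ami_spec, generate_phantom


def _mask(arr, label="thrombus", spacing=(1.0, 1.0, 1.0)):
    return BinaryMask3D(np.asarray(arr, dtype=np.uint8), label, spacing)


class TestEraseSpine:
    def test_empty_mask_is_identity(self, clean_phantom):
        _, vol, _ = clean_phantom
        out = erase_spine(vol, _mask(np.zeros_like(vol.voxels), "spine", vol.spacing))
        np.testing.assert_array_equal(out.voxels, vol.voxels)

    def test_full_mask_zeroes_everything(self, clean_phantom):
        _, vol, _ = clean_phantom
        out = erase_spine(vol, _mask(np.ones_like(vol.voxels), "spine", vol.spacing))
        assert (out.voxels == 0).all()

    def test_changes_exactly_the_masked_voxels_to_zero(self, clean_phantom):
        _, vol, masks = clean_phantom
        out = erase_spine(vol, masks["spine"])
        changed = out.voxels != vol.voxels
        under = masks["spine"].voxels.astype(bool)
        # voxels already at 0 HU under the mask count as unchanged
        assert (out.voxels[under] == 0).all()
        assert changed.sum() == (vol.voxels[under] != 0).sum()
        assert not changed[~under].any()

    def test_grid_mismatch_raises(self, clean_phantom):
        _, vol, _ = clean_phantom
        with pytest.raises(ValueError, match="mismatch"):
            erase_spine(vol, _mask(np.zeros((2, 4, 4)), "spine"))


class TestPostprocessThrombus:
    @staticmethod
    def _lumen_slice(shape=(64, 64), center=(32, 32), r=8):
        rr, cc = np.mgrid[:shape[0], :shape[1]]
        return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= r * r

    def test_distant_component_removed_adjacent_kept(self):
        lum2d = self._lumen_slice()
        raw = np.zeros((1, 64, 64), dtype=np.uint8)
        # a ring segment hugging the lumen ...
        rr, cc = np.mgrid[:64, :64]
        d2 = (rr - 32) ** 2 + (cc - 32) ** 2
        raw[0] = ((d2 > 64) & (d2 <= 144) & (rr < 32)).astype(np.uint8)
        # ... and a compact blob 10+ voxels away
        raw[0, 54:58, 54:58] = 1
        lum = _mask(lum2d[None].astype(np.uint8), "lumen")
        out = postprocess_thrombus(_mask(raw), lum, HybridConfig(interpolation=False))
        assert not out.voxels[0, 54:58, 54:58].any()     # distant blob gone
        kept = ((d2 > 64) & (d2 <= 144) & (rr < 32))
        assert (out.voxels[0].astype(bool) == kept).all()  # adjacent kept intact

    def test_exact_crescent_is_fixed_point_of_smoothing(self):
        # ellipse-minus-lumen crescent: the eccentric-lumen cross-section
        rr, cc = np.mgrid[:64, :64]
        outer = (rr - 30) ** 2 / 400 + (cc - 32) ** 2 / 256 <= 1
        lum2d = (rr - 36) ** 2 + (cc - 32) ** 2 <= 81
        crescent = outer & ~lum2d
        lum = _mask(lum2d[None].astype(np.uint8), "lumen")
        out = postprocess_thrombus(_mask(crescent[None].astype(np.uint8)), lum,
                                   HybridConfig(interpolation=True))
        np.testing.assert_array_equal(out.voxels[0], crescent.astype(np.uint8))

    def test_salt_specks_cleaned_up(self, noise_free_phantom):
        _, vol, masks = noise_free_phantom
        z = int(np.argmax(masks["thrombus"].voxels.sum(axis=(1, 2))))
        truth = masks["thrombus"].voxels[z]
        lum = masks["lumen"].voxels[z]
        rng = np.random.default_rng(0)
        raw = truth.copy()
        # specks sprinkled around the aneurysm, none touching the lumen
        for _ in range(25):
            r, c = rng.integers(5, 123, 2)
            if lum[max(r - 2, 0):r + 3, max(c - 2, 0):c + 3].any():
                continue
            raw[r, c] = 1
        raw3 = raw[None]
        out = postprocess_thrombus(
            _mask(raw3), _mask(lum[None], "lumen"), HybridConfig())
        d_raw = evaluate(raw3, truth[None]).dice
        d_post = evaluate(out.voxels, truth[None]).dice
        assert d_post > d_raw

    def test_output_disjoint_from_lumen_and_bounded(self, noise_free_phantom):
        _, vol, masks = noise_free_phantom
        rng = np.random.default_rng(1)
        raw = (rng.random(vol.voxels.shape) < 0.01).astype(np.uint8)
        raw |= masks["thrombus"].voxels
        out = postprocess_thrombus(_mask(raw, spacing=vol.spacing),
                                   masks["lumen"], HybridConfig())
        assert not (out.voxels & masks["lumen"].voxels).any()

    def test_empty_raw_gives_empty_output(self, noise_free_phantom):
        _, vol, masks = noise_free_phantom
        out = postprocess_thrombus(_mask(np.zeros_like(vol.voxels), spacing=vol.spacing),
                                   masks["lumen"], HybridConfig())
        assert out.is_empty()


class TestEllipseFit:
    def test_rasterized_ellipses_recovered(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            a, b = rng.uniform(8, 18), rng.uniform(5, 12)
            th = rng.uniform(0, np.pi)
            rr, cc = np.mgrid[:80, :80]
            u = (rr - 40) * np.cos(th) + (cc - 40) * np.sin(th)
            v = -(rr - 40) * np.sin(th) + (cc - 40) * np.cos(th)
            ell = (u / a) ** 2 + (v / b) ** 2 <= 1
            fit = _fit_ellipse_mask(ell)
            inter = 2 * (fit & ell).sum() / (fit.sum() + ell.sum())
            assert inter >= 0.99


class TestHybridLumen:
    def test_requires_models(self, clean_phantom, expert_cfg):
        _, vol, _ = clean_phantom
        with pytest.raises(ValueError, match="model"):
            segment_lumen_hybrid(vol, HybridConfig(), expert_cfg)

    def test_clean_phantom_matches_expert(self, clean_phantom, expert_cfg,
                                          trained_models):
        """Good-contrast regime: hybrid and expert agree closely."""
        _, vol, masks = clean_phantom
        pre = es.preprocess(vol, expert_cfg)
        spine = es.segment_spine(pre, expert_cfg)
        d_expert = evaluate(es.segment_lumen(pre, spine, expert_cfg).mask,
                            masks["lumen"]).dice
        hcfg = HybridConfig(spine_model=trained_models["spine"],
                            lumen_model=trained_models["lumen"])
        res = segment_lumen_hybrid(vol, hcfg, expert_cfg)
        d_hybrid = evaluate(res.mask, masks["lumen"]).dice
        assert res.found and res.seed_source == "network"
        assert abs(d_hybrid - d_expert) < 0.05

    def test_network_seed_rescues_expert_failure(self, expert_cfg, trained_models):
        """Very low contrast: the brightness-window seed fails but the
        network still localizes the lumen (the failure mode the hybrid
        repairs)."""
        vol, masks = generate_phantom(ami_spec(seed=5, contrast_scale=0.3))
        pre = es.preprocess(vol, expert_cfg)
        spine = es.segment_spine(pre, expert_cfg)
        r_expert = es.segment_lumen(pre, spine, expert_cfg)
        hcfg = HybridConfig(spine_model=trained_models["spine"],
                            lumen_model=trained_models["lumen"])
        r_hybrid = segment_lumen_hybrid(vol, hcfg, expert_cfg)
        assert r_expert.status == "lumen-not-found" and r_expert.mask.is_empty()
        assert r_hybrid.found and not r_hybrid.mask.is_empty()
        assert evaluate(r_hybrid.mask, masks["lumen"]).dice > 0.8

    def test_reproducible_at_fixed_weights(self, clean_phantom, expert_cfg,
                                           trained_models):
        _, vol, _ = clean_phantom
        hcfg = HybridConfig(spine_model=trained_models["spine"],
                            lumen_model=trained_models["lumen"])
        r1 = segment_lumen_hybrid(vol, hcfg, expert_cfg)
        r2 = segment_lumen_hybrid(vol, hcfg, expert_cfg)
        np.testing.assert_array_equal(r1.mask.voxels, r2.mask.voxels)


class TestHybridThrombus:
    def test_missing_model_is_hard_error(self, clean_phantom):
        _, vol, masks = clean_phantom
        with pytest.raises(ValueError, match="model"):
            segment_thrombus_hybrid(vol, masks["lumen"], HybridConfig())

    def test_negative_control_false_positives_bounded(self, best_thrombus_model):
        """A healthy straight vessel (no aneurysm, no thrombus) must yield a
        (near-)empty prediction from a well-trained detector."""
        spec = PhantomSpec(seed=55, thrombus=False, bulge_amplitude_mm=0.0)
        vol, masks = generate_phantom(spec)
        hcfg = HybridConfig(thrombus_model=best_thrombus_model)
        out = segment_thrombus_hybrid(vol, masks["lumen"], hcfg)
        fp_per_slice = out.voxels.sum() / vol.n_slices
        lumen_area = masks["lumen"].voxels.sum() / vol.n_slices
        assert fp_per_slice <= 0.5 * lumen_area

    def test_covers_at_least_expert_slice_range(self, expert_cfg, trained_models,
                                                best_thrombus_model):
        """Axial coverage: the network generalizes across slices while the
        slice-propagated snake can truncate early."""
        vol, masks = generate_phantom(ami_spec(seed=42))
        res_e = es.segment_all(vol, expert_cfg)
        hcfg = HybridConfig(spine_model=trained_models["spine"],
                            lumen_model=trained_models["lumen"],
                            thrombus_model=best_thrombus_model)
        lum = res_e["lumen"] if not res_e["lumen"].is_empty() else masks["lumen"]
        out = segment_thrombus_hybrid(vol, lum, hcfg)

        def z_range(mask, min_area=10):
            areas = mask.voxels.sum(axis=(1, 2))
            zz = np.nonzero(areas >= min_area)[0]
            return (int(zz[0]), int(zz[-1])) if len(zz) else None

        r_hybrid = z_range(out)
        r_expert = z_range(res_e["thrombus"])
        truth_range = z_range(masks["thrombus"])
        assert r_hybrid is not None
        if r_expert is not None:
            covered_h = r_hybrid[1] - r_hybrid[0]
            covered_e = r_expert[1] - r_expert[0]
            assert covered_h >= 0.8 * covered_e
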