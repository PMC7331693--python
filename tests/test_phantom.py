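"""Phantom generator: determinism, geometry, mixture statistics, consistency."""

import numpy as np
import pytest
from scipy import ndimage

import xvlung as xv
from xvlung.core import BoundaryError, ConfigurationError, SizingError
from xvlung.expansion import jacobian_expansion


def small_cfg(**kw):
    kw.setdefault("grid_shape", (48, 48, 48))
    kw.setdefault("seed", 1)
    return xv.PhantomConfig(**kw)


class TestLungMask:
    def test_deterministic_under_seed(self):
        cfg = small_cfg(grid_shape=(96, 96, 96))
        m1 = xv.make_lung_mask(cfg)
        m2 = xv.make_lung_mask(cfg)
        assert np.array_equal(m1.data, m2.data)

    @pytest.mark.parametrize("seed", [0, 1, 7])
    def test_two_connected_components(self, seed):
        mask = xv.make_lung_mask(small_cfg(seed=seed))
        n = ndimage.label(mask.data)[1]
        assert n == 2
        assert mask.data.sum() > 0

    def test_grid_too_small(self):
        with pytest.raises(SizingError):
            xv.make_lung_mask(small_cfg(grid_shape=(8, 8, 8)))


class TestExpansionScene:
    def test_zero_variance_limit(self):
        cfg = small_cfg(sigma_main=0.0)
        mask = xv.make_lung_mask(cfg)
        emap, _ = xv.make_expansion_scene(cfg, mask)
        assert np.allclose(emap.in_mask_values(), cfg.mu_main)

    def test_mixture_mean_closed_form(self):
        cfg = small_cfg(
            grid_shape=(64, 64, 64),
            profile="clustered",
            mu_main=0.10,
            mu_low=0.05,
            weight_low=0.3,
        )
        mask = xv.make_lung_mask(cfg)
        emap, truth = xv.make_expansion_scene(cfg, mask)
        vals = emap.in_mask_values()
        assert vals.size >= 10_000
        w = truth.params["weight_low"]
        expect = w * 0.05 + (1 - w) * 0.10
        # sub-population means are re-centred exactly; the only slack is the
        # discreteness of the blob fraction
        assert abs(vals.mean() - expect) < 1e-9
        assert abs(expect - 0.085) < 0.002

    def test_clustered_requires_low_weight(self):
        with pytest.raises(ConfigurationError):
            small_cfg(profile="clustered", weight_low=0.0)

    def test_heart_blur_zeroes_exact_region(self):
        cfg = small_cfg(grid_shape=(64, 64, 64), heart_blur=0.10)
        mask = xv.make_lung_mask(cfg)
        emap, truth = xv.make_expansion_scene(cfg, mask)
        zero = np.isclose(emap.values, 0.0) & emap.mask
        assert np.array_equal(zero, truth.blur_region)
        frac = truth.blur_region.sum() / mask.data.sum()
        assert abs(frac - 0.10) < 0.01
        # lower-left locality: caudal z, left x
        cz, _, cx = ndimage.center_of_mass(truth.blur_region)
        assert cz > mask.data.shape[0] / 2
        assert cx < mask.data.shape[2] / 2

    def test_empty_mask_rejected(self):
        cfg = small_cfg()
        with pytest.raises(ConfigurationError):
            xv.make_expansion_scene(cfg, np.zeros((48, 48, 48), bool))


class TestBreathCurve:
    def test_peak_equals_tidal_fraction(self):
        curve = xv.make_breath_curve(small_cfg(tidal_fraction=0.12))
        assert curve.fractional_volume[curve.peak_phase] == pytest.approx(0.12)
        assert curve.fractional_volume[0] == 0.0

    def test_exponential_decay_closed_form(self):
        cfg = small_cfg(tidal_fraction=0.1, exp_rate=9.0)
        curve = xv.make_breath_curve(cfg)
        pk = curve.peak_phase
        dt = curve.times[pk + 2] - curve.times[pk]
        assert curve.fractional_volume[pk + 2] == pytest.approx(0.1 * np.exp(-9.0 * dt))

    def test_linear_decay_reaches_zero(self):
        curve = xv.make_breath_curve(small_cfg(exp_shape="linear", tidal_fraction=0.1))
        assert curve.fractional_volume[-1] == pytest.approx(0.0, abs=1e-12)

    def test_zero_tidal_flat(self):
        curve = xv.make_breath_curve(small_cfg(tidal_fraction=0.0))
        assert np.all(curve.fractional_volume == 0.0)

    def test_too_few_phases(self):
        with pytest.raises(ConfigurationError):
            small_cfg(n_phases=2)


class TestSpeckleSequence:
    def test_zero_expansion_scene_static(self):
        cfg = small_cfg(tidal_fraction=0.0, n_phases=5)
        mask = xv.make_lung_mask(cfg)
        _, truth = xv.make_expansion_scene(cfg, mask)
        curve = xv.make_breath_curve(cfg)
        vols, _ = xv.make_speckle_sequence(truth, curve, cfg)
        for v in vols[1:]:
            assert np.array_equal(v.data, vols[0].data)

    def test_deterministic_under_seed(self):
        cfg = small_cfg(n_phases=4, seed=5)
        out1 = xv.simulate_animal(cfg, with_images=True)
        out2 = xv.simulate_animal(cfg, with_images=True)
        for a, b in zip(out1["volumes"], out2["volumes"]):
            assert np.array_equal(a.data, b.data)

    def test_truth_series_integrates_to_peak_map(self):
        """Summing the true per-frame fields over inspiration must reproduce
        the stored expansion map (fine grid, well within 2% RMS)."""
        cfg = small_cfg(grid_shape=(64, 64, 64), n_phases=8)
        out = xv.simulate_animal(cfg, with_images=True)
        truth = out["truth"]
        pk = out["curve"].peak_phase
        total = sum(truth.frame_displacement(p) for p in range(pk))
        assert np.allclose(total, truth.peak_displacement, atol=1e-6)
        det = jacobian_expansion(truth.peak_displacement.astype(float), 1.0)
        m = truth.lung_mask
        rms = np.sqrt(((det[m] - truth.expansion_map[m]) ** 2).mean())
        assert rms < 0.02 * abs(truth.expansion_map[m].mean())

    def test_xv_sampled_consistency(self):
        """At XV resolution (stride 4) the sampled truth fields still carry
        the scene expansion within 2% RMS of the mean level."""
        cfg = small_cfg(grid_shape=(64, 64, 64), smooth_vox=12.0, n_phases=8)
        out = xv.simulate_animal(cfg, with_images=True)
        truth = out["truth"]
        fields = xv.ground_truth_fields(truth, 8, 0.5)
        xvm = xv.xv_mask(truth.lung_mask, 8, 0.5)
        pk = out["curve"].peak_phase
        emap = xv.fractional_expansion(fields, xvm, peak_phase=pk)
        from conftest import window_mean_truth

        gt, cov = window_mean_truth(truth, 8, 4)
        sel = emap.effective_mask & (cov > 0.999)
        rms = np.sqrt(((emap.values[sel] - gt[sel]) ** 2).mean())
        assert rms < 0.02 * abs(gt[sel].mean())

    def test_phase_count_mismatch(self):
        cfg = small_cfg(n_phases=5)
        mask = xv.make_lung_mask(cfg)
        _, truth = xv.make_expansion_scene(cfg, mask)
        other = xv.make_breath_curve(small_cfg(n_phases=7))
        with pytest.raises(ConfigurationError):
            xv.make_speckle_sequence(truth, other, cfg)


class TestBonePhantom:
    def test_symmetric_projection_at_zero(self):
        vol = xv.make_bone_phantom(0.0, seed=2)
        proj = vol.data.max(axis=0)
        mirrored = proj[:, ::-1]
        r = np.corrcoef(proj.ravel(), mirrored.ravel())[0, 1]
        assert r > 0.95

    def test_rotation_reduces_midline_symmetry(self):
        p0 = xv.make_bone_phantom(0.0, seed=2).data.max(axis=0)
        p17 = xv.make_bone_phantom(17.0, seed=2).data.max(axis=0)

        def mirror_r(p):
            return np.corrcoef(p.ravel(), p[:, ::-1].ravel())[0, 1]

        assert mirror_r(p17) < mirror_r(p0)

    def test_deterministic(self):
        a = xv.make_bone_phantom(12.0, seed=4)
        b = xv.make_bone_phantom(12.0, seed=4)
        assert np.array_equal(a.data, b.data)
        assert a.meta["true_angle"] == 12.0

    def test_angle_bounds(self):
        with pytest.raises(ConfigurationError):
            xv.make_bone_phantom(95.0, seed=0)
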