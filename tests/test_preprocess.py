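"""Orientation, segmentation, lung volume and heart-blur QC."""

import numpy as np
import pytest
from scipy import ndimage

import xvlung as xv
from xvlung.core import SegmentationError, ShapeError, XVError
from xvlung.preprocess import detect_heart_blur, lung_volume, segment_lungs


class TestSymmetryAxis:
    def test_unrotated_phantom_recovers_zero(self):
        r = xv.find_symmetry_axis(xv.make_bone_phantom(0.0, seed=2))
        assert abs(r.angle) <= 0.5
        assert r.reliable
        assert r.spine_end == "bottom"

    @pytest.mark.parametrize("angle", [17.0, -33.5])
    def test_rotated_phantom_recovered_within_one_degree(self, angle):
        r = xv.find_symmetry_axis(xv.make_bone_phantom(angle, seed=2))
        assert abs(r.angle + angle) <= 1.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_structureless_input_flagged_unreliable(self, seed):
        noise = xv.VoxelGrid3D(np.random.default_rng(seed).uniform(size=(16, 80, 80)))
        r = xv.find_symmetry_axis(noise)
        assert not r.reliable

    def test_constant_volume_rejected(self):
        with pytest.raises(SegmentationError):
            xv.find_symmetry_axis(xv.VoxelGrid3D(np.zeros((8, 32, 32))))


class TestOrientAndCrop:
    def test_already_correct_volume_kept(self):
        vol = xv.make_bone_phantom(0.0, seed=2)
        r = xv.find_symmetry_axis(vol)
        out = xv.orient_and_crop(vol, r)
        (z0, z1), (y0, y1), (x0, x1) = out.meta["crop"]
        assert np.allclose(out.data, vol.data[z0:z1, y0:y1, x0:x1])

    def test_spine_lands_in_bottom_third(self):
        vol = xv.make_bone_phantom(17.0, seed=2)
        out = xv.orient_and_crop(vol, xv.find_symmetry_axis(vol))
        proj = out.data.max(axis=0)
        bones = proj >= np.quantile(proj, 0.97)
        labels, n = ndimage.label(bones)
        sizes = ndimage.sum_labels(bones, labels, np.arange(1, n + 1))
        cy = ndimage.center_of_mass(labels == (int(np.argmax(sizes)) + 1))[0]
        assert cy > 2 * proj.shape[0] / 3

    def test_flipped_sample_rotated_to_spine_bottom(self):
        vol = xv.make_bone_phantom(0.0, seed=3)
        flipped = xv.VoxelGrid3D(vol.data[:, ::-1, :], vol.voxel_size)
        r = xv.find_symmetry_axis(flipped)
        assert r.spine_end == "top"
        out = xv.orient_and_crop(flipped, r)
        assert xv.find_symmetry_axis(out).spine_end == "bottom"

    def test_idempotent(self):
        vol = xv.make_bone_phantom(17.0, seed=2)
        out = xv.orient_and_crop(vol, xv.find_symmetry_axis(vol))
        second = xv.find_symmetry_axis(out)
        assert abs(second.angle) <= 0.5


class TestSegmentLungs:
    def test_noise_free_dice(self):
        cfg = xv.PhantomConfig(grid_shape=(96, 96, 96), profile="healthy", seed=7, n_phases=3)
        res = xv.simulate_animal(cfg, with_images=True)
        seg = segment_lungs(res["volumes"][0])
        truth = res["truth"].lung_mask
        dice = 2 * (seg.data & truth).sum() / (seg.data.sum() + truth.sum())
        assert dice >= 0.95
        assert seg.meta["n_components"] == 2

    def test_noisy_dice_degrades_gracefully(self):
        cfg = xv.PhantomConfig(
            grid_shape=(96, 96, 96), profile="healthy", seed=8, n_phases=3, noise_std=0.05
        )
        res = xv.simulate_animal(cfg, with_images=True)
        seg = segment_lungs(res["volumes"][0])
        truth = res["truth"].lung_mask
        dice = 2 * (seg.data & truth).sum() / (seg.data.sum() + truth.sum())
        assert dice >= 0.85

    def test_constant_volume_fails(self):
        with pytest.raises(SegmentationError):
            segment_lungs(xv.VoxelGrid3D(np.full((32, 32, 32), 0.5)))

    def test_deterministic(self):
        cfg = xv.PhantomConfig(grid_shape=(48, 48, 48), seed=4, n_phases=3)
        res = xv.simulate_animal(cfg, with_images=True)
        a = segment_lungs(res["volumes"][0])
        b = segment_lungs(res["volumes"][0])
        assert np.array_equal(a.data, b.data)


class TestLungVolume:
    def test_arithmetic(self):
        mask = np.zeros((20, 20, 20), bool)
        mask.ravel()[:1000] = True
        assert lung_volume(mask, voxel_size=0.1) == pytest.approx(1.0)

    def test_scaling_law(self):
        mask = np.ones((10, 10, 10), bool)
        assert lung_volume(mask, 0.2) == pytest.approx(8 * lung_volume(mask, 0.1))

    def test_phantom_bookkeeping(self):
        cfg = xv.PhantomConfig(grid_shape=(48, 48, 48), seed=1)
        mask = xv.make_lung_mask(cfg)
        assert lung_volume(mask) == pytest.approx(mask.data.sum() * cfg.voxel_size**3)

    def test_empty_mask(self):
        with pytest.raises(XVError):
            lung_volume(np.zeros((4, 4, 4), bool), 1.0)


class TestHeartBlur:
    def block_field(self, shape=(12, 12, 12), base=1.0):
        vec = np.full(shape + (3,), base / np.sqrt(3))
        return vec

    def test_no_near_zero_vectors(self):
        mask = np.ones((12, 12, 12), bool)
        qc = detect_heart_blur(self.block_field(), mask)
        assert not qc.heart_blur_flag
        assert qc.zero_fraction == 0.0

    def test_all_zero_field(self):
        mask = np.ones((12, 12, 12), bool)
        qc = detect_heart_blur(np.zeros((12, 12, 12, 3)), mask)
        assert qc.heart_blur_flag
        assert qc.zero_fraction == 1.0

    def test_injected_blob_detected_with_centroid(self):
        mask = np.ones((12, 12, 12), bool)
        vec = self.block_field()
        blob = np.zeros((12, 12, 12), bool)
        blob[8:12, 4:8, 0:4] = True  # ~3.7% ... enlarge to 10%
        blob[7:12, 3:8, 0:5] = True
        vec[blob] = 0.0
        qc = detect_heart_blur(vec, mask, blob_threshold=0.05)
        assert qc.heart_blur_flag
        cz, cy, cx = qc.centroid
        assert blob[int(round(cz)), int(round(cy)), int(round(cx))]

    def test_monotone_in_blob_size(self):
        mask = np.ones((12, 12, 12), bool)
        prev = -1.0
        for k in (2, 4, 6, 8):
            vec = self.block_field()
            vec[:k, :k, :k] = 0.0
            qc = detect_heart_blur(vec, mask)
            assert qc.zero_fraction >= prev
            prev = qc.zero_fraction

    def test_empty_mask_rejected(self):
        with pytest.raises(XVError):
            detect_heart_blur(self.block_field(), np.zeros((12, 12, 12), bool))

    def test_misaligned_mask(self):
        with pytest.raises(ShapeError):
            detect_heart_blur(self.block_field(), np.ones((6, 6, 6), bool))

    def test_phantom_blur_region_found(self, healthy_truth_64):
        """A phantom with a contiguous 10% zero-displacement region is
        flagged at the 5% threshold with the centroid inside the region."""
        from xvlung.pipeline import _attach_truth_fields

        cfg = xv.PhantomConfig(grid_shape=(64, 64, 64), profile="healthy", heart_blur=0.10, seed=11)
        res = xv.simulate_animal(cfg)
        _, truth = _attach_truth_fields(res["truth"], res["curve"], cfg)
        fields = xv.ground_truth_fields(truth, 8, 0.5)
        xvm = xv.xv_mask(truth.lung_mask, 8, 0.5)
        pk = res["curve"].peak_phase
        qc = detect_heart_blur(xv.accumulate_fields(fields, pk), xvm, blob_threshold=0.05)
        assert qc.heart_blur_flag
        # centroid (XV grid) maps into the injected fine-grid region
        stride, origin = fields[0].grid_stride, fields[0].grid_origin[0]
        fine = tuple(int(round(origin + stride * c)) for c in qc.centroid)
        grown = ndimage.binary_dilation(truth.blur_region, iterations=stride)
        assert grown[fine]

        # the same animal without blur is never flagged
        no_blur = healthy_truth_64
        fields0 = xv.ground_truth_fields(no_blur["truth"], 8, 0.5)
        qc0 = detect_heart_blur(
            xv.accumulate_fields(fields0, no_blur["curve"].peak_phase),
            xv.xv_mask(no_blur["truth"].lung_mask, 8, 0.5),
        )
        assert not qc0.heart_blur_flag
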