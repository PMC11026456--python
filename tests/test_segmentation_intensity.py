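"""Segmentation, cytoplasm masks, intensity quantification."""

import numpy as np
import pytest

from mechanophen.core import ImageStack, LabelMask, RasterImage
from mechanophen.segmentation_intensity import (
    SegmentationParams,
    border_labels,
    cytoplasm_mask,
    estimate_background,
    mean_intensity,
    plane_intensity_profile,
    segment_objects,
    yap_ratio,
)
from mechanophen.synthetic_data import ObjectSpec, gen_cell_scene


def scene_image(spec, channel, **kw):
    scene, truth = gen_cell_scene(spec, **kw)
    return RasterImage(scene.channel(channel), scene.pixel_size), truth


class TestSegmentObjects:
    def test_blank_image_empty_mask_warns(self):
        img = RasterImage(np.full((64, 64), 5.0), 1.0)
        with pytest.warns(UserWarning, match="blank"):
            mask = segment_objects(img)
        assert mask.ids.size == 0

    def test_single_disk_count_and_area(self):
        spec = [ObjectSpec(center=(30.0, 30.0), semi_axes=(12.0, 12.0), intensity={"c": 100.0})]
        img, truth = scene_image(spec, "c", shape=(120, 120), pixel_size=0.5, noise_sd=10.0, seed=0)
        mask = segment_objects(img)
        assert mask.ids.size == 1
        assert mask.area_um2(1) == pytest.approx(truth.masks["cell"].area_um2(1), rel=0.02)

    def test_two_disks_two_labels(self):
        spec = [
            ObjectSpec(center=(15.0, 15.0), semi_axes=(6.0, 6.0), intensity={"c": 80.0}),
            ObjectSpec(center=(45.0, 45.0), semi_axes=(8.0, 8.0), intensity={"c": 80.0}),
        ]
        img, _ = scene_image(spec, "c", shape=(120, 120), pixel_size=0.5, noise_sd=8.0, seed=1)
        mask = segment_objects(img)
        assert mask.ids.size == 2

    def test_adaptive_threshold(self):
        spec = [ObjectSpec(center=(20.0, 20.0), semi_axes=(8.0, 8.0), intensity={"c": 60.0})]
        img, _ = scene_image(spec, "c", shape=(80, 80), pixel_size=0.5, noise_sd=5.0, seed=2)
        mask = segment_objects(img, SegmentationParams(adaptive_block=51, adaptive_offset=10.0))
        assert mask.ids.size == 1

    def test_border_flag(self):
        spec = [ObjectSpec(center=(2.0, 20.0), semi_axes=(6.0, 6.0), intensity={"c": 90.0})]
        img, _ = scene_image(spec, "c", shape=(80, 80), pixel_size=0.5, seed=3)
        mask = segment_objects(img)
        assert border_labels(mask) == {1}

    def test_min_area_filter(self):
        data = np.zeros((64, 64))
        data[10:12, 10:12] = 100.0  # 4 px = 4 um^2 at ps 1.0 < 20 um^2 default
        mask = segment_objects(RasterImage(data, 1.0))
        assert mask.ids.size == 0


class TestCytoplasmMask:
    def make_masks(self):
        cell = np.zeros((40, 40), dtype=np.int32)
        cell[5:35, 5:35] = 1
        nuc = np.zeros((40, 40), dtype=np.int32)
        nuc[15:25, 15:25] = 1
        return LabelMask(cell, 1.0), LabelMask(nuc, 1.0)

    def test_area_difference(self):
        cell, nuc = self.make_masks()
        cyto = cytoplasm_mask(cell, nuc)
        assert cyto.area_um2(1) == cell.area_um2(1) - nuc.area_um2(1)

    def test_empty_nucleus(self):
        cell, _ = self.make_masks()
        empty = LabelMask(np.zeros((40, 40), dtype=np.int32), 1.0)
        cyto = cytoplasm_mask(cell, empty)
        assert np.array_equal(cyto.labels, cell.labels)

    def test_nucleus_covers_cell_flagged(self):
        cell, _ = self.make_masks()
        with pytest.warns(UserWarning, match="empty cytoplasm"):
            cyto = cytoplasm_mask(cell, cell)
        assert cyto.ids.size == 0

    def test_shape_mismatch(self):
        cell, _ = self.make_masks()
        other = LabelMask(np.zeros((10, 10), dtype=np.int32), 1.0)
        with pytest.raises(ValueError):
            cytoplasm_mask(cell, other)


class TestMeanIntensity:
    def test_uniform_scalar_background(self):
        img = RasterImage(np.full((32, 32), 50.0), 1.0)
        labels = np.zeros((32, 32), dtype=np.int32)
        labels[8:24, 8:24] = 1
        res = mean_intensity(img, LabelMask(labels, 1.0), background=10.0)
        assert res[0].background_subtracted_mean == pytest.approx(40.0)

    def test_recovers_generator_truth(self):
        spec = [ObjectSpec(center=(25.0, 25.0), semi_axes=(10.0, 10.0), intensity={"td": 70.0})]
        scene, truth = gen_cell_scene(spec, shape=(100, 100), pixel_size=0.5,
                                      background=12.0, noise_sd=4.0, seed=5)
        img = RasterImage(scene.channel("td"), 0.5)
        res = mean_intensity(img, truth.masks["cell"], background="auto")
        # noise sd 4 over ~1250 px -> sem ~0.11; allow 5 sigma plus bg estimate error
        assert res[0].background_subtracted_mean == pytest.approx(70.0, abs=1.0)

    def test_negative_clamped(self):
        img = RasterImage(np.full((16, 16), 5.0), 1.0)
        labels = np.ones((16, 16), dtype=np.int32)
        with pytest.warns(UserWarning, match="clamping"):
            res = mean_intensity(img, LabelMask(labels, 1.0), background=10.0)
        assert res[0].background_subtracted_mean == 0.0
        assert res[0].clamped

    def test_missing_label(self):
        img = RasterImage(np.zeros((16, 16)) + 1.0, 1.0)
        labels = np.ones((16, 16), dtype=np.int32)
        with pytest.raises(ValueError):
            mean_intensity(img, LabelMask(labels, 1.0), background=0.0, labels=[2])


class TestYapRatio:
    def masks(self):
        nuc = np.zeros((40, 40), dtype=np.int32)
        nuc[15:25, 15:25] = 1
        cyto = np.zeros((40, 40), dtype=np.int32)
        cyto[5:35, 5:35] = 1
        cyto[15:25, 15:25] = 0
        return LabelMask(nuc, 1.0), LabelMask(cyto, 1.0)

    def test_uniform_image_ratio_one(self):
        nuc, cyto = self.masks()
        img = RasterImage(np.full((40, 40), 33.0), 1.0)
        assert yap_ratio(img, nuc, cyto)[1] == pytest.approx(1.0)

    def test_noiseless_two_to_one(self):
        spec = [
            ObjectSpec(center=(10.0, 10.0), semi_axes=(8.0, 8.0), intensity={"yap": 40.0},
                       nucleus_fraction=0.5, nucleus_intensity={"yap": 80.0})
        ]
        scene, truth = gen_cell_scene(spec, shape=(40, 40), pixel_size=0.5, background=0.0)
        img = RasterImage(scene.channel("yap"), 0.5)
        cyto = cytoplasm_mask(truth.masks["cell"], truth.masks["nucleus"])
        assert yap_ratio(img, truth.masks["nucleus"], cyto)[1] == pytest.approx(2.0)

    def test_scale_invariance(self):
        nuc, cyto = self.masks()
        rng = np.random.default_rng(0)
        data = rng.uniform(10, 50, (40, 40))
        r1 = yap_ratio(RasterImage(data, 1.0), nuc, cyto)[1]
        r2 = yap_ratio(RasterImage(7.3 * data, 1.0), nuc, cyto)[1]
        assert r2 == pytest.approx(r1, rel=1e-12)

    def test_zero_cytoplasm_missing(self):
        nuc, cyto = self.masks()
        img = RasterImage(np.zeros((40, 40)), 1.0)
        img.data[nuc.labels == 1] = 5.0
        with pytest.warns(UserWarning, match="zero cytoplasmic"):
            ratios = yap_ratio(img, nuc, cyto)
        assert ratios[1] is None


class TestPlaneProfile:
    def make_stack(self, values, z_step=5.0):
        data = np.stack([np.full((20, 20), v) for v in values])
        return ImageStack(data, pixel_size=1.0, z_step=z_step)

    def full_mask(self):
        return LabelMask(np.ones((20, 20), dtype=np.int32), 1.0)

    def test_four_plane_mean(self):
        stack = self.make_stack([10.0, 20.0, 30.0, 40.0])
        val = plane_intensity_profile(stack, self.full_mask(), [0.0, 5.0, 10.0, 15.0])
        assert val == pytest.approx(25.0)

    def test_single_plane_matches_mean_intensity(self):
        stack = self.make_stack([10.0, 20.0, 30.0])
        val = plane_intensity_profile(stack, self.full_mask(), [5.0])
        assert val == pytest.approx(20.0)

    def test_half_mask_same_for_uniform(self):
        stack = self.make_stack([10.0, 20.0, 30.0])
        half = np.zeros((20, 20), dtype=np.int32)
        half[:, :10] = 1
        a = plane_intensity_profile(stack, LabelMask(half, 1.0), [0.0, 5.0])
        b = plane_intensity_profile(stack, self.full_mask(), [0.0, 5.0])
        assert a == pytest.approx(b)

    def test_offset_out_of_range(self):
        stack = self.make_stack([1.0, 2.0])
        with pytest.raises(ValueError):
            plane_intensity_profile(stack, self.full_mask(), [100.0])


class TestBackground:
    def test_median_of_complement(self):
        data = np.full((50, 50), 20.0)
        labels = np.zeros((50, 50), dtype=np.int32)
        labels[10:20, 10:20] = 1
        data[labels == 1] = 200.0
        img = RasterImage(data, 1.0)
        assert estimate_background(img, LabelMask(labels, 1.0)) == 20.0
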