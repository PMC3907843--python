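"""Classification stages: supervised, two-class, filaments, gating, counting."""

import numpy as np
import pytest

from stromspat import (
    CalibratedImage,
    DegenerateInputError,
    ParameterError,
    build_scene,
    classify_supervised,
    classify_twoclass,
    colocalize,
    microsphere_spec,
    render_scene,
    segment_and_count,
    subtract_filaments,
    type1_spec,
)
from stromspat.pipeline import canonical_training, classify_mat_image
from stromspat.scenes import NoiseModel, _disk_pixels
from stromspat.window import Window

from conftest import manual_scene


def image_from(channels, px=0.2):
    return CalibratedImage(channels=channels, pixel_size_um=px)


class TestSupervised:
    def test_pure_blob_assigned_to_trained_class(self):
        probe = np.zeros((32, 32))
        probe[10:15, 10:15] = 100.0
        img = image_from({"probe": probe, "counterstain": probe.copy(),
                          "reflectance": np.zeros((32, 32))})
        masks = classify_supervised(img, canonical_training(background=0.0))
        assert masks["srm"][10:15, 10:15].all()
        assert masks["srm"].sum() == 25

    def test_pixel_equal_to_background_sample_is_background(self):
        flat = np.full((8, 8), 10.0)
        img = image_from({"probe": flat, "counterstain": flat.copy(),
                          "reflectance": flat.copy()})
        masks = classify_supervised(img, canonical_training(background=10.0))
        assert masks["background"].all()

    def test_missing_background_class_rejected(self):
        img = image_from({"probe": np.ones((4, 4))})
        with pytest.raises(ParameterError):
            classify_supervised(img, {"srm": np.array([[1.0]])})

    def test_invariant_to_uniform_intensity_scaling(self):
        rng = np.random.default_rng(5)
        chans = {k: rng.uniform(0, 100, (24, 24)) for k in
                 ("probe", "counterstain", "reflectance")}
        train = canonical_training(background=10.0)
        a = classify_supervised(image_from(chans), train)
        scaled = image_from({k: 3.7 * v for k, v in chans.items()})
        train_scaled = {k: 3.7 * v for k, v in train.items()}
        b = classify_supervised(scaled, train_scaled)
        assert all(np.array_equal(a[k], b[k]) for k in a)

    def test_noiseless_render_reproduces_truth_masks(self):
        spec = type1_spec(seed=8, noise=NoiseModel.noiseless())
        scene = build_scene(spec)
        image = render_scene(scene)
        masks = classify_mat_image(image, training=canonical_training(background=0.0))
        assert np.array_equal(masks.srm, scene.masks["srm"])
        truth_stain = (scene.masks["other_bacteria"] | scene.masks["filaments"]) \
            & ~scene.masks["srm"]
        assert np.array_equal(masks.other_bacteria | masks.filaments, truth_stain)
        # cells planted on top of precipitates win the pixel (both signals
        # fluoresce there); away from cells the mineral mask is exact
        truth_mineral = scene.masks["precipitates"] | scene.masks["ooids"]
        truth_cells = (scene.masks["srm"] | scene.masks["other_bacteria"]
                       | scene.masks["filaments"])
        mismatch = masks.precipitates ^ truth_mineral
        assert not (mismatch & ~truth_cells).any()

    def test_noisy_render_pixel_accuracy_at_least_95_percent(self):
        scene = build_scene(type1_spec(seed=9))  # default SNR 10
        image = render_scene(scene)
        masks = classify_mat_image(image)
        truth = np.zeros(image.shape, dtype=int)
        truth[scene.masks["precipitates"] | scene.masks["ooids"]] = 3
        truth[scene.masks["other_bacteria"] | scene.masks["filaments"]] = 2
        truth[scene.masks["srm"]] = 1
        pred = np.zeros(image.shape, dtype=int)
        pred[masks.precipitates] = 3
        pred[masks.other_bacteria | masks.filaments] = 2
        pred[masks.srm] = 1
        assert np.mean(pred == truth) >= 0.95


class TestTwoClass:
    def test_bimodal_channel_splits_between_modes(self):
        rng = np.random.default_rng(1)
        labels = rng.uniform(size=(64, 64)) < 0.3
        chan = np.where(labels, 200.0, 30.0) + rng.normal(0, 5, (64, 64))
        fg = classify_twoclass(chan)
        assert np.array_equal(fg, labels)

    def test_misclassification_near_bayes_rate_for_gaussian_mixture(self):
        """2-means on N(30,15)/N(200,15) mixture: error within 2 points of Bayes."""
        rng = np.random.default_rng(2)
        labels = rng.uniform(size=(128, 128)) < 0.5
        chan = np.where(labels, rng.normal(200, 15, labels.shape),
                        rng.normal(30, 15, labels.shape))
        chan = np.clip(chan, 0, None)
        fg = classify_twoclass(chan)
        # Bayes threshold (equal variances, equal priors) at 115: error ~ 0
        assert np.mean(fg != labels) <= 0.02

    def test_constant_channel_rejected(self):
        with pytest.raises(DegenerateInputError):
            classify_twoclass(np.full((16, 16), 7.0))


class TestFilaments:
    PX = 0.2

    def test_straight_line_is_filament_blobs_are_residual(self):
        mask = np.zeros((256, 256), dtype=bool)
        mask[125:127, 3:253] = True  # 50-um-long, 2-px-wide line
        w = Window(51.2, 51.2, self.PX)
        for x, y in [(10.0, 10.0), (40.0, 40.0)]:
            rr, cc = _disk_pixels(x, y, 0.5, w)
            mask[rr, cc] = True
        fil, res = subtract_filaments(mask, self.PX)
        assert fil[125:127, 3:253].all()
        assert not res[125:127, 3:253].any()
        assert res[np.ix_([49, 50], [49, 50])].any()  # blob near (10, 10)

    def test_dashed_line_closed_into_single_filament(self):
        """Dashes with 2-um gaps under max_gap 3 um act as one linear feature."""
        mask = np.zeros((128, 256), dtype=bool)
        x = 5
        while x < 230:
            mask[60:62, x : x + 25] = True  # 5-um dash
            x += 35  # 2-um gap
        fil, res = subtract_filaments(mask, self.PX, max_gap_um=3.0)
        assert np.array_equal(fil, mask)
        assert not res.any()

    def test_filament_and_residual_partition_input(self):
        rng = np.random.default_rng(7)
        mask = rng.uniform(size=(96, 96)) < 0.05
        mask[40:42, 5:90] = True
        fil, res = subtract_filaments(mask, self.PX)
        assert np.array_equal(fil | res, mask)
        assert not (fil & res).any()


class TestColocalize:
    def test_identical_masks_pass_through(self):
        rng = np.random.default_rng(3)
        mask = rng.uniform(size=(32, 32)) < 0.2
        assert np.array_equal(colocalize(mask, mask, 0.5), mask)

    def test_disjoint_masks_give_empty_output(self):
        probe = np.zeros((16, 16), dtype=bool)
        counter = np.zeros((16, 16), dtype=bool)
        probe[2:5, 2:5] = True
        counter[10:13, 10:13] = True
        assert not colocalize(probe, counter, 0.5).any()

    def test_overlap_fraction_threshold_is_exact(self):
        probe = np.zeros((8, 16), dtype=bool)
        probe[3, 2:12] = True  # one 10-px object
        counter = np.zeros_like(probe)
        counter[3, 2:8] = True  # 60% overlap
        assert np.array_equal(colocalize(probe, counter, 0.5), probe)
        counter[:] = False
        counter[3, 2:6] = True  # 40% overlap
        assert not colocalize(probe, counter, 0.5).any()


class TestCounting:
    def test_seven_disjoint_disks_count_seven(self, fine_window):
        scene = manual_scene(
            fine_window,
            [("srm", 6.0 + 6.5 * k, 25.0, 1.5) for k in range(7)],
        )
        typical = np.pi * 1.5**2
        _, count = segment_and_count(scene.masks["srm"], typical,
                                     fine_window.pixel_size_um)
        assert count == 7

    def test_border_half_disks_sum_to_one(self, fine_window):
        scene = manual_scene(
            fine_window,
            [("srm", 0.0, 25.0, 2.0), ("srm", fine_window.width_um, 25.0, 2.0)],
        )
        typical = np.pi * 2.0**2
        _, count = segment_and_count(scene.masks["srm"], typical,
                                     fine_window.pixel_size_um)
        assert count == 1

    def test_microsphere_field_count_within_5_percent(self):
        scene = build_scene(microsphere_spec(200, seed=12))
        image = render_scene(scene)
        mask = classify_twoclass(image.channels["probe"])
        _, count = segment_and_count(mask, np.pi * 0.25, image.pixel_size_um)
        assert abs(count - 200) <= 10

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_counting_rule_bounds(self, seed):
        """Never exceeds the naive component count; never drops full objects."""
        from scipy import ndimage

        rng = np.random.default_rng(seed)
        mask = rng.uniform(size=(64, 64)) < 0.08
        px = 0.5
        typical = 4 * px**2  # four pixels
        objects, count = segment_and_count(mask, typical, px)
        naive = ndimage.label(mask, structure=np.ones((3, 3)))[1]
        full = ((objects.table["area_um2"] >= 0.5 * typical)
                & ~objects.table["border"]).sum()
        assert full <= count <= naive
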