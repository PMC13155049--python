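"""Synthetic generator: determinism, planted-mask contrast, patient-wise
splitting, augmentation semantics and standardization."""

import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from cramnet import synth


class TestGenerateImage:
    def test_benign_has_empty_mask(self):
        im = synth.generate_image(synth.BENIGN, seed=1)
        assert im.gt_mask.sum() == 0
        assert im.label == synth.BENIGN

    def test_seeded_determinism_bit_identical(self):
        a = synth.generate_image(synth.MALIGNANT, seed=1)
        b = synth.generate_image(synth.MALIGNANT, seed=1)
        assert np.array_equal(a.pixels, b.pixels)
        assert np.array_equal(a.gt_mask, b.gt_mask)

    def test_different_seeds_differ(self):
        a = synth.generate_image(synth.MALIGNANT, seed=1)
        b = synth.generate_image(synth.MALIGNANT, seed=2)
        assert not np.array_equal(a.pixels, b.pixels)

    @pytest.mark.parametrize("seed", [7, 0, 5, 23])
    def test_mask_region_exceeds_stated_contrast(self, seed):
        """Mean intensity inside the planted region sits more than the
        generator's contrast parameter below the outside mean."""
        params = synth.GeneratorParams()
        im = synth.generate_image(synth.MALIGNANT, params, seed=seed)
        gray = im.pixels.mean(axis=2)
        inside = gray[im.gt_mask].mean()
        outside = gray[~im.gt_mask].mean()
        assert outside - inside > params.contrast

    def test_pixels_in_unit_interval(self):
        for seed in range(5):
            im = synth.generate_image(synth.MALIGNANT, seed=seed)
            assert im.pixels.min() >= 0.0 and im.pixels.max() <= 1.0

    def test_invalid_size_rejected(self):
        with pytest.raises(ValueError, match="32"):
            synth.generate_image(synth.BENIGN, synth.GeneratorParams(height=16), seed=0)

    def test_empty_range_rejected(self):
        bad = synth.GeneratorParams(cluster_count=(3, 1))
        with pytest.raises(ValueError, match="cluster_count"):
            synth.generate_image(synth.MALIGNANT, bad, seed=0)


class TestGenerateDataset:
    def test_exact_fractions_with_unit_groups(self):
        ds = synth.generate_dataset(10, (0.8, 0.1, 0.1), 1, seed=4)
        assert (len(ds.train), len(ds.val), len(ds.test)) == (16, 2, 2)

    def test_patient_disjoint_with_grouped_images(self):
        ds = synth.generate_dataset(10, (0.8, 0.1, 0.1), 5, seed=4)
        seen = {}
        for part, images in ds.partitions().items():
            for im in images:
                assert seen.setdefault(im.patient_id, part) == part, (
                    f"patient {im.patient_id} appears in {seen[im.patient_id]} and {part}")

    def test_class_balance_per_partition(self):
        ds = synth.generate_dataset(20, (0.8, 0.1, 0.1), 1, seed=0)
        for part, images in ds.partitions().items():
            labels = synth.labels_of(images)
            assert (labels == 0).sum() == (labels == 1).sum()

    def test_determinism(self):
        a = synth.generate_dataset(6, (0.5, 0.25, 0.25), 1, seed=9)
        b = synth.generate_dataset(6, (0.5, 0.25, 0.25), 1, seed=9)
        for pa, pb in zip(a.partitions().values(), b.partitions().values()):
            assert [im.patient_id for im in pa] == [im.patient_id for im in pb]
            assert all(np.array_equal(x.pixels, y.pixels) for x, y in zip(pa, pb))

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError, match="fractions"):
            synth.generate_dataset(10, (0.8, 0.1, 0.2), 1, seed=0)

    def test_separability_of_default_conditions(self):
        """A scaled 2-feature logistic fit (mean intensity, dark fraction)
        separates the classes essentially perfectly — downstream training
        tests are well-posed."""
        X, y = [], []
        for s in range(100):
            for lab in (synth.BENIGN, synth.MALIGNANT):
                im = synth.generate_image(lab, seed=40_000 + 2 * s + lab)
                X.append(synth.intensity_features(im))
                y.append(lab)
        clf = make_pipeline(StandardScaler(), LogisticRegression())
        clf.fit(X, y)
        assert clf.score(X, y) > 0.95


class TestAugment:
    def test_identity_config_returns_input(self):
        im = synth.generate_image(synth.MALIGNANT, seed=2)
        out = synth.augment(im, seed=5, config=synth.AugmentConfig.identity())
        assert np.array_equal(out.pixels, im.pixels)
        assert np.array_equal(out.gt_mask, im.gt_mask)

    def test_horizontal_flip_is_involution(self):
        """Applying the same flip-only augmentation twice restores the image."""
        im = synth.generate_image(synth.MALIGNANT, seed=2)
        cfg = synth.AugmentConfig(rotate=False, hflip=True, vflip=False,
                                  brightness_jitter=0, contrast_jitter=0, color_jitter=0)
        seed = next(s for s in range(20)
                    if not np.array_equal(synth.augment(im, s, cfg).pixels, im.pixels))
        once = synth.augment(im, seed, cfg)
        twice = synth.augment(once, seed, cfg)
        assert np.array_equal(twice.pixels, im.pixels)
        assert np.array_equal(twice.gt_mask, im.gt_mask)

    def test_mask_area_preserved_under_geometric_transforms(self):
        im = synth.generate_image(synth.MALIGNANT, seed=2)
        cfg = synth.AugmentConfig(rotate=True, hflip=True, vflip=True,
                                  brightness_jitter=0, contrast_jitter=0, color_jitter=0)
        for seed in range(10):
            out = synth.augment(im, seed=seed, config=cfg)
            assert out.gt_mask.sum() == im.gt_mask.sum()
            assert out.label == im.label

    def test_jitter_keeps_unit_interval_and_determinism(self):
        im = synth.generate_image(synth.BENIGN, seed=3)
        a = synth.augment(im, seed=7)
        b = synth.augment(im, seed=7)
        assert np.array_equal(a.pixels, b.pixels)
        assert a.pixels.min() >= 0.0 and a.pixels.max() <= 1.0


class TestNormalize:
    def test_self_derived_stats_give_zero_mean_unit_variance(self):
        rng = np.random.default_rng(0)
        stack = rng.uniform(0.2, 0.9, size=(8, 16, 16, 3))
        out, stats = synth.normalize(stack)
        assert np.all(np.abs(out.mean(axis=(0, 1, 2))) < 1e-6)
        assert np.all(np.abs(out.std(axis=(0, 1, 2)) - 1) < 1e-6)

    def test_zero_variance_channel_named_in_error(self):
        stack = np.full((4, 8, 8, 3), 0.5)
        stack[..., 0] = np.random.default_rng(0).uniform(size=(4, 8, 8))
        with pytest.raises(ValueError, match="channel 1"):
            synth.normalize(stack)

    def test_two_image_toy_set_hand_computed(self):
        """Two constant images at 0.2 and 0.6: mean 0.4, std 0.2, so the
        standardized values are exactly -1 and +1."""
        stack = np.stack([np.full((4, 4, 3), 0.2), np.full((4, 4, 3), 0.6)])
        out, stats = synth.normalize(stack)
        np.testing.assert_allclose(stats.mean, 0.4)
        np.testing.assert_allclose(stats.std, 0.2)
        np.testing.assert_allclose(out[0], -1.0)
        np.testing.assert_allclose(out[1], 1.0)

    def test_external_stats_are_applied_not_recomputed(self):
        stats = synth.ChannelStats(mean=np.array([0.5] * 3), std=np.array([0.25] * 3))
        stack = np.full((2, 4, 4, 3), 0.75)
        out, _ = synth.normalize(stack, stats)
        np.testing.assert_allclose(out, 1.0)


def test_roundtrip_disk_layout(tmp_path):
    ds = synth.generate_dataset(4, (0.5, 0.25, 0.25), 1, seed=2)
    manifest = synth.save_dataset(ds, str(tmp_path / "data"))
    loaded = synth.load_dataset(str(tmp_path / "data"))
    for part in ("train", "val", "test"):
        orig, back = ds.partitions()[part], loaded.partitions()[part]
        assert len(orig) == len(back)
        assert sorted(im.label for im in orig) == sorted(im.label for im in back)
    # masks survive the round trip for malignant images
    mal = [im for im in loaded.train if im.label == synth.MALIGNANT]
    assert all(im.gt_mask.any() for im in mal)
    # 8-bit quantization error only
    for lo, lb in zip(sorted(ds.train, key=lambda i: i.patient_id),
                      sorted(loaded.train, key=lambda i: i.patient_id)):
        assert np.abs(lo.pixels - lb.pixels).max() < 1 / 255 + 1e-9
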