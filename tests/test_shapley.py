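"""Superpixel Shapley attribution: segmentation contract, masking operator,
the exact-enumeration oracle and its axioms, Kernel SHAP equivalence, and
the diverging overlay rendering."""

import numpy as np
import pytest

from cramnet import shapley, synth


@pytest.fixture(scope="module")
def image():
    return synth.generate_image(synth.MALIGNANT, seed=3).pixels


@pytest.fixture(scope="module")
def seg8(image):
    seg = shapley.segment_superpixels(image, 8, seed=0)
    assert 4 <= seg.max() + 1 <= 12  # exact enumeration stays feasible
    return seg


class TestSegmentation:
    def test_labels_partition_every_pixel(self, image):
        seg = shapley.segment_superpixels(image, 50, seed=0)
        k = seg.max() + 1
        assert seg.min() == 0
        assert np.array_equal(np.unique(seg), np.arange(k))

    def test_achieved_count_within_band(self, image):
        for k_target in (10, 50):
            seg = shapley.segment_superpixels(image, k_target, seed=0)
            k = seg.max() + 1
            assert 0.5 * k_target <= k <= 2 * k_target

    def test_uniform_image_gives_near_equal_tiles(self):
        seg = shapley.segment_superpixels(np.full((64, 64, 3), 0.5), 4, seed=0)
        sizes = np.bincount(seg.ravel())
        assert len(sizes) == 4
        assert sizes.min() > 0.8 * sizes.mean()

    def test_deterministic(self, image):
        a = shapley.segment_superpixels(image, 30, seed=0)
        b = shapley.segment_superpixels(image, 30, seed=0)
        assert np.array_equal(a, b)

    def test_too_many_regions_rejected(self):
        tiny = np.full((4, 4, 3), 0.5)
        with pytest.raises(ValueError, match="fewer pixels"):
            shapley.segment_superpixels(tiny, 100)


class TestMasking:
    def test_full_coalition_leaves_image_unchanged(self, image, seg8):
        k = seg8.max() + 1
        out = shapley.mask_superpixels(image, seg8, range(k))
        np.testing.assert_array_equal(out, image)

    def test_empty_coalition_gives_mean_color(self, image, seg8):
        out = shapley.mask_superpixels(image, seg8, [])
        np.testing.assert_allclose(
            out, np.broadcast_to(image.mean(axis=(0, 1)), out.shape))

    def test_single_absent_region_changes_exactly_that_region(self, image, seg8):
        k = seg8.max() + 1
        out = shapley.mask_superpixels(image, seg8, [r for r in range(k) if r != 2])
        changed = np.any(out != image, axis=-1)
        region = seg8 == 2
        # every changed pixel is in region 2 (pixels equal to the mean color stay equal)
        assert np.all(changed <= region)
        assert changed.sum() > 0.9 * region.sum()

    def test_out_of_range_indices_rejected(self, image, seg8):
        with pytest.raises(ValueError, match="coalition"):
            shapley.mask_superpixels(image, seg8, [999])


class TestExactShapley:
    def test_constant_model_gives_zero_attributions(self, image, seg8):
        sv = shapley.exact_shapley(lambda b: np.full(len(b), 2.5), image, seg8)
        np.testing.assert_allclose(sv.phi, 0.0, atol=1e-12)
        assert sv.efficiency_residual == pytest.approx(0.0, abs=1e-10)

    def test_additive_value_function_recovers_own_terms(self, image, seg8):
        """v additive over present-region red-channel sums -> phi_i is
        exactly region i's own term relative to the masked baseline."""
        k = seg8.max() + 1
        baseline = image.mean(axis=(0, 1))

        def fn(batch):
            return batch[..., 0].sum(axis=(1, 2))

        sv = shapley.exact_shapley(fn, image, seg8)
        expected = np.array([
            image[seg8 == i, 0].sum() - baseline[0] * (seg8 == i).sum()
            for i in range(k)])
        np.testing.assert_allclose(sv.phi, expected, atol=1e-8)

    def test_symmetry_axiom_on_constructed_game(self, image, seg8):
        """Two regions entering v only through an interchangeable indicator
        get equal attributions."""
        def fn(batch):
            # value depends on regions 0 and 1 only via how many are present
            baseline = image.mean(axis=(0, 1))
            present0 = np.abs(batch[:, seg8 == 0] - baseline).sum(axis=(1, 2)) > 1e-9
            present1 = np.abs(batch[:, seg8 == 1] - baseline).sum(axis=(1, 2)) > 1e-9
            return present0.astype(float) + present1.astype(float)

        sv = shapley.exact_shapley(fn, image, seg8)
        assert sv.phi[0] == pytest.approx(sv.phi[1], abs=1e-10)

    def test_large_k_refused_with_guidance(self, image):
        seg = shapley.segment_superpixels(image, 40, seed=0)
        if seg.max() + 1 > shapley.EXACT_K_LIMIT:
            with pytest.raises(ValueError, match="kernel_shap"):
                shapley.exact_shapley(lambda b: np.zeros(len(b)), image, seg)


class TestKernelShap:
    def test_full_enumeration_matches_exact_oracle(self, image, seg8, rng):
        """A nonlinear value function, K<=16 regions: enumerated Kernel SHAP
        equals the exact oracle to 1e-6."""
        w = rng.normal(size=3)

        def fn(batch):
            s = np.tensordot(batch, w, axes=([-1], [0])).mean(axis=(1, 2))
            return np.tanh(3 * s) + 0.5 * s ** 2

        ex = shapley.exact_shapley(fn, image, seg8)
        ks = shapley.kernel_shap(fn, image, seg8, n_samples=1 << 16, seed=0)
        np.testing.assert_allclose(ks.phi, ex.phi, atol=1e-6)

    def test_sampled_estimate_approaches_exact(self, image, seg8, rng):
        w = rng.normal(size=3)

        def fn(batch):
            return np.tanh(np.tensordot(batch, w, axes=([-1], [0])).mean(axis=(1, 2)) * 5)

        ex = shapley.exact_shapley(fn, image, seg8)
        ks = shapley.kernel_shap(fn, image, seg8, n_samples=120, seed=1)
        assert ks.efficiency_residual == pytest.approx(0.0, abs=1e-8)
        assert np.abs(ks.phi - ex.phi).max() < 0.1 * max(1.0, np.abs(ex.phi).max())

    def test_constant_model_gives_zero(self, image, seg8):
        ks = shapley.kernel_shap(lambda b: np.ones(len(b)), image, seg8, n_samples=64, seed=0)
        np.testing.assert_allclose(ks.phi, 0.0, atol=1e-10)

    def test_efficiency_enforced_exactly(self, image, seg8, rng):
        def fn(batch):
            return batch.std(axis=(1, 2, 3))

        ks = shapley.kernel_shap(fn, image, seg8, n_samples=100, seed=2)
        assert ks.efficiency_residual == pytest.approx(0.0, abs=1e-8)

    def test_too_few_samples_rejected(self, image, seg8):
        with pytest.raises(ValueError, match="n_samples"):
            shapley.kernel_shap(lambda b: np.zeros(len(b)), image, seg8, n_samples=3)


class TestOverlay:
    def test_zero_attributions_render_white(self, image, seg8):
        phi = np.zeros(seg8.max() + 1)
        out = shapley.shap_overlay(image, seg8, phi)
        np.testing.assert_allclose(out, 1.0)

    def test_sign_flip_swaps_red_and_blue_exactly(self, image, seg8, rng):
        phi = rng.normal(size=seg8.max() + 1)
        a = shapley.shap_overlay(image, seg8, phi)
        b = shapley.shap_overlay(image, seg8, -phi)
        np.testing.assert_allclose(a[..., 0], b[..., 2], atol=1e-12)
        np.testing.assert_allclose(a[..., 1], b[..., 1], atol=1e-12)

    def test_most_positive_region_is_reddest(self, image, seg8, rng):
        phi = rng.normal(size=seg8.max() + 1)
        out = shapley.shap_overlay(image, seg8, phi)
        redness = np.array([
            (out[seg8 == i, 0] - out[seg8 == i, 2]).mean()
            for i in range(seg8.max() + 1)])
        assert redness.argmax() == phi.argmax()

    def test_mismatched_phi_length_rejected(self, image, seg8):
        with pytest.raises(ValueError, match="phi"):
            shapley.shap_overlay(image, seg8, np.zeros(seg8.max() + 5))


def test_trained_model_attributes_planted_regions_positively(trained_model, desk_dataset,
                                                             malignant_eval_images):
    """Desk-scale agreement: over correctly classified malignant images, the
    summed SHAP of superpixels intersecting the planted mask is positive for
    >=90%."""
    from cramnet import model as M
    from cramnet import pipeline
    m, _ = trained_model
    scores = M.evaluate_scores(m, malignant_eval_images)
    correct = [im for im, s in zip(malignant_eval_images, scores) if s >= 0.5]
    assert len(correct) >= 45  # the trained model classifies nearly all correctly
    frame = pipeline.shap_mask_alignment(m, correct, k_target=50, n_samples=512, seed=0)
    assert np.abs(frame.efficiency_residual).max() < 1e-8
    assert (frame.mask_phi_sum > 0).mean() >= 0.9
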