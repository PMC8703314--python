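import numpy as np
import pytest
from matplotlib import colormaps

from flairseg import (
    ConfigurationError,
    DegenerateInputError,
    NoTumorDetected,
    PooledWeights,
    SaliencyMap,
    ValidationError,
    apply_colormap,
    gradient_magnitude,
    gradient_stack,
    mean_saliency,
    normalize_to_grayscale,
    pool_gradient_weights,
    segment_slice,
    spatial_gradient,
    superimpose,
    threshold_mask,
    threshold_sweep,
    upsample_saliency,
    weight_feature_maps,
)
from flairseg.cnn import FeatureStack
from flairseg.saliency import DEFAULT_TAUS, compute_saliency


class TestSpatialGradient:
    def test_constant_map_has_zero_gradients(self):
        H, V = spatial_gradient(np.full((5, 5), 3.0))
        assert not H.any() and not V.any()

    def test_horizontal_ramp(self):
        X = np.tile(np.arange(6.0), (4, 1))  # X[i, j] = j
        H, V = spatial_gradient(X)
        np.testing.assert_array_equal(H[:, :-1], 1.0)
        np.testing.assert_array_equal(H[:, -1], 0.0)  # undefined edge -> 0
        assert not V.any()

    def test_hand_evaluated_3x3(self):
        X = np.array([[0.0, 1, 3], [0, 2, 4], [1, 1, 1]])
        H, V = spatial_gradient(X)
        np.testing.assert_array_equal(H, [[1, 2, 0], [2, 2, 0], [0, 0, 0]])
        np.testing.assert_array_equal(V, [[0, 1, 1], [1, -1, -3], [0, 0, 0]])

    def test_degenerate_row_vector_rejected(self):
        with pytest.raises(DegenerateInputError):
            spatial_gradient(np.ones((1, 8)))


class TestGradientMagnitude:
    def test_pythagorean_pixel(self):
        H = np.array([[3.0]])
        V = np.array([[4.0]])
        assert gradient_magnitude(H, V)[0, 0] == 5.0

    def test_matches_per_pixel_loop(self, rng):
        H = rng.normal(size=(8, 8))
        V = rng.normal(size=(8, 8))
        M = gradient_magnitude(H, V)
        for i in range(8):
            for j in range(8):
                assert M[i, j] == pytest.approx(
                    np.sqrt(H[i, j] ** 2 + V[i, j] ** 2), abs=1e-12
                )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            gradient_magnitude(np.zeros((3, 3)), np.zeros((4, 4)))


class TestPooledWeights:
    def test_constant_stack_pools_to_zero(self):
        f = FeatureStack(maps=np.ones((4, 6, 6)))
        w = pool_gradient_weights(gradient_stack(f))
        assert not w.mean_vec.any() and not w.max_vec.any()

    def test_step_edge_max_equals_height(self):
        h = 2.5
        m = np.zeros((8, 8))
        m[:, 4:] = h  # vertical step edge of height h
        f = FeatureStack(maps=m[None])
        w = pool_gradient_weights(gradient_stack(f))
        assert w.max_vec[0] == pytest.approx(h)

    def test_max_dominates_mean_on_random_stacks(self, rng):
        f = FeatureStack(maps=rng.uniform(0, 5, (6, 10, 10)))
        w = pool_gradient_weights(gradient_stack(f))
        assert (w.max_vec >= w.mean_vec).all()
        assert (w.mean_vec >= 0).all()


class TestWeightFeatureMaps:
    def test_unit_weights_are_identity(self, rng):
        f = FeatureStack(maps=rng.uniform(0, 1, (4, 5, 5)))
        w = PooledWeights(mean_vec=np.ones(4), max_vec=np.ones(4))
        np.testing.assert_array_equal(weight_feature_maps(f, w).maps, f.maps)

    def test_zero_weight_silences_its_map(self, rng):
        f = FeatureStack(maps=rng.uniform(0, 1, (3, 4, 4)))
        w = PooledWeights(mean_vec=np.array([1.0, 0.0, 1.0]),
                          max_vec=np.ones(3))
        out = weight_feature_maps(f, w)
        assert not out.maps[1].any()
        assert out.maps[0].any()

    def test_length_mismatch_rejected(self, rng):
        f = FeatureStack(maps=rng.uniform(0, 1, (3, 4, 4)))
        w = PooledWeights(mean_vec=np.ones(2), max_vec=np.ones(2))
        with pytest.raises(ValidationError):
            weight_feature_maps(f, w)

    def test_unknown_combine_rule_rejected(self, rng):
        f = FeatureStack(maps=rng.uniform(0, 1, (2, 4, 4)))
        w = PooledWeights(mean_vec=np.ones(2), max_vec=np.ones(2))
        with pytest.raises(ConfigurationError):
            weight_feature_maps(f, w, combine="median")


class TestMeanSaliency:
    def test_identical_maps_average_to_themselves(self, rng):
        m = rng.uniform(0, 1, (6, 6))
        f = FeatureStack(maps=np.stack([m, m, m]))
        np.testing.assert_allclose(mean_saliency(f), m)

    def test_two_constant_maps(self):
        f = FeatureStack(maps=np.stack([np.zeros((4, 4)), np.full((4, 4), 2.0)]))
        np.testing.assert_array_equal(mean_saliency(f), np.ones((4, 4)))


def test_weighted_mean_pipeline_matches_triple_loop_oracle(rng):
    """The vectorized gradient->pool->weight->mean chain must agree with a
    naive per-element loop to 1e-12 on random 4-map 8x8 stacks."""
    for _ in range(5):
        maps = rng.uniform(0, 3, (4, 8, 8))
        f = FeatureStack(maps=maps)
        got = mean_saliency(
            weight_feature_maps(f, pool_gradient_weights(gradient_stack(f)))
        )

        # independent brute-force computation
        n, s, _ = maps.shape
        expected = np.zeros((s, s))
        for k in range(n):
            H = np.zeros((s, s))
            V = np.zeros((s, s))
            for i in range(s):
                for j in range(s):
                    if j + 1 < s:
                        H[i, j] = maps[k, i, j + 1] - maps[k, i, j]
                    if i + 1 < s:
                        V[i, j] = maps[k, i + 1, j] - maps[k, i, j]
            mag = np.sqrt(H**2 + V**2)
            wk = mag.mean() * mag.max()
            expected += maps[k] * wk
        expected /= n
        np.testing.assert_allclose(got, expected, atol=1e-12)


class TestNormalizeToGrayscale:
    def test_all_zero_maps_to_all_zero(self):
        out = normalize_to_grayscale(np.zeros((5, 5)))
        assert not out.gray.any()

    def test_peak_becomes_one(self, rng):
        out = normalize_to_grayscale(rng.uniform(0, 10, (6, 6)))
        assert out.gray.max() == pytest.approx(1.0)

    def test_clamp_then_scale_hand_example(self):
        out = normalize_to_grayscale(np.array([[-5.0, 0.0], [5.0, 10.0]]))
        np.testing.assert_allclose(out.gray, [[0.0, 0.0], [0.5, 1.0]])

    def test_non_finite_rejected(self):
        with pytest.raises(ValidationError):
            normalize_to_grayscale(np.array([[np.nan, 1.0]]))


class TestUpsample:
    def test_identity_when_target_is_source_shape(self, rng):
        m = SaliencyMap(gray=rng.uniform(0, 1, (8, 8)))
        np.testing.assert_array_equal(upsample_saliency(m, (8, 8)).gray, m.gray)

    def test_constant_stays_constant(self):
        m = SaliencyMap(gray=np.full((8, 8), 0.3))
        np.testing.assert_allclose(upsample_saliency(m, (32, 32)).gray, 0.3)

    def test_hot_pixel_argmax_lands_in_matching_block(self):
        g = np.zeros((32, 32))
        g[10, 20] = 1.0
        up = upsample_saliency(SaliencyMap(gray=g), (128, 128)).gray
        r, c = np.unravel_index(up.argmax(), up.shape)
        assert 10 * 4 <= r < 11 * 4 + 4
        assert 20 * 4 <= c < 21 * 4 + 4

    def test_range_preserved(self, rng):
        m = SaliencyMap(gray=rng.uniform(0, 1, (16, 16)))
        up = upsample_saliency(m, (64, 64))
        assert up.gray.min() >= 0.0 and up.gray.max() <= 1.0


class TestColormapOverlay:
    def test_colormap_shape_and_determinism(self, rng):
        m = SaliencyMap(gray=rng.uniform(0, 1, (16, 16)))
        rgb = apply_colormap(m)
        assert rgb.shape == (16, 16, 3)
        np.testing.assert_array_equal(rgb, apply_colormap(m))

    def test_equal_gray_maps_to_equal_rgb(self):
        m = SaliencyMap(gray=np.array([[0.4, 0.4], [0.1, 0.4]]))
        rgb = apply_colormap(m)
        np.testing.assert_array_equal(rgb[0, 0], rgb[0, 1])
        np.testing.assert_array_equal(rgb[0, 0], rgb[1, 1])

    def test_endpoints_are_jet_endpoints(self):
        m = SaliencyMap(gray=np.array([[0.0, 1.0]]))
        rgb = apply_colormap(m)
        jet = colormaps["jet"]
        np.testing.assert_allclose(rgb[0, 0], jet(0.0)[:3])
        np.testing.assert_allclose(rgb[0, 1], jet(1.0)[:3])

    def test_zero_alpha_returns_original(self, rng):
        img = rng.uniform(0, 1, (8, 8, 3))
        cm = rng.uniform(0, 1, (8, 8, 3))
        np.testing.assert_array_equal(superimpose(img, cm, 0.0), img)

    def test_zero_saliency_layer_changes_nothing(self, rng):
        img = rng.uniform(0, 1, (8, 8, 3))
        np.testing.assert_array_equal(
            superimpose(img, np.zeros((8, 8, 3)), 0.7), img
        )

    def test_output_clipped_to_display_range(self):
        img = np.full((4, 4, 3), 0.9)
        cm = np.full((4, 4, 3), 1.0)
        out = superimpose(img, cm, 1.0)
        assert out.max() <= 1.0


class TestThresholding:
    def test_tau_zero_covers_everything(self, rng):
        m = SaliencyMap(gray=rng.uniform(0, 1, (8, 8)))
        assert threshold_mask(m, 0.0).mask.all()

    def test_tau_one_keeps_only_saturated_pixels(self):
        m = SaliencyMap(gray=np.array([[0.2, 1.0], [0.99, 0.5]]))
        np.testing.assert_array_equal(
            threshold_mask(m, 1.0).mask, [[0, 1], [0, 0]]
        )

    def test_hand_example(self):
        m = SaliencyMap(gray=np.array([[0.2, 0.5, 0.9]]))
        np.testing.assert_array_equal(
            threshold_mask(m, 0.5).mask, [[0, 1, 1]]
        )

    def test_coverage_monotone_in_tau(self, rng):
        for _ in range(20):
            m = SaliencyMap(gray=rng.uniform(0, 1, (16, 16)))
            t1, t2 = sorted(rng.uniform(0, 1, 2))
            m1 = threshold_mask(m, t1).mask.astype(bool)
            m2 = threshold_mask(m, t2).mask.astype(bool)
            assert not (m2 & ~m1).any()  # mask(t2) subset of mask(t1)


class TestThresholdSweep:
    def test_default_grid_is_the_published_sequence(self):
        assert DEFAULT_TAUS[0] == 0.33
        assert DEFAULT_TAUS[-1] == 0.85
        assert len(DEFAULT_TAUS) == 27
        steps = np.diff(DEFAULT_TAUS)
        np.testing.assert_allclose(steps, 0.02, atol=1e-9)

    def test_saliency_equal_to_reference_ties_to_smallest_tau(self):
        ref = np.zeros((40, 40), dtype=np.uint8)
        ref[15:25, 15:25] = 1
        m = SaliencyMap(gray=ref.astype(float))
        best_tau, mask, table = threshold_sweep(m, ref)
        assert best_tau == DEFAULT_TAUS[0]
        assert table["dsc_post"].max() == 1.0
        np.testing.assert_array_equal(mask.mask, ref)

    def test_empty_reference_flags_empty_overlap(self):
        gray = np.zeros((40, 40))
        gray[10:20, 10:20] = 1.0  # saliency positive, reference empty
        best_tau, mask, table = threshold_sweep(
            SaliencyMap(gray=gray), np.zeros((40, 40), dtype=np.uint8)
        )
        assert best_tau == DEFAULT_TAUS[0]
        assert (table["dsc_post"] == 0.0).all()
        assert table["empty_overlap"].all()

    def test_two_plateau_saliency_selects_separating_tau(self):
        gray = np.zeros((60, 60))
        gray[10:50, 10:50] = 0.4     # broad low plateau
        gray[20:40, 20:40] = 0.8     # compact high plateau = the lesion
        ref = (gray == 0.8).astype(np.uint8)
        best_tau, _, _ = threshold_sweep(SaliencyMap(gray=gray), ref)
        assert 0.4 < best_tau <= 0.8


class TestSegmentSlice:
    def test_gate_raises_on_not_tumor(self, trained_small_net, small_phantoms):
        data = small_phantoms
        # pick a slice the classifier actually calls not-tumor
        from flairseg import classify

        for i in range(len(data["normed"])):
            label, _, _ = classify(trained_small_net, data["normed"][i])
            if label == "not tumor":
                with pytest.raises(NoTumorDetected):
                    segment_slice(trained_small_net, data["normed"][i])
                return
        pytest.skip("classifier called every phantom tumor")

    def test_sweep_without_reference_is_config_error(
        self, trained_small_net, small_phantoms
    ):
        with pytest.raises(ConfigurationError):
            segment_slice(trained_small_net, small_phantoms["normed"][0],
                          mode="sweep")

    def _first_true_positive(self, net, data):
        from flairseg import classify

        for i in range(len(data["normed"])):
            if data["labels"][i] == 1:
                label, _, _ = classify(net, data["normed"][i])
                if label == "tumor":
                    return i
        pytest.skip("no held tumor phantom classified as tumor")

    def test_sweep_mask_dominates_every_other_tau(
        self, trained_small_net, small_phantoms
    ):
        i = self._first_true_positive(trained_small_net, small_phantoms)
        res = segment_slice(
            trained_small_net, small_phantoms["normed"][i], mode="sweep",
            ref=small_phantoms["masks"][i],
        )
        chosen = res.sweep_table.loc[
            res.sweep_table["tau"] == res.mask.threshold_used, "dsc_post"
        ].iloc[0]
        assert chosen == res.sweep_table["dsc_post"].max()

    def test_end_to_end_bit_reproducible(self, trained_small_net, small_phantoms):
        i = self._first_true_positive(trained_small_net, small_phantoms)
        s = small_phantoms["normed"][i]
        a = segment_slice(trained_small_net, s, mode="fixed", tau_fixed=0.5)
        b = segment_slice(trained_small_net, s, mode="fixed", tau_fixed=0.5)
        np.testing.assert_array_equal(a.mask.mask, b.mask.mask)
        np.testing.assert_array_equal(a.saliency.gray, b.saliency.gray)
        np.testing.assert_array_equal(a.overlay, b.overlay)

    def test_saliency_localizes_isolated_blob_feature(self):
        """A stack where one map holds a sharp blob and the rest are flat
        must put the saliency argmax inside the blob's bounding box."""
        maps = np.ones((4, 32, 32)) * 0.5
        maps[2, 10:16, 18:24] = 4.0
        sal = compute_saliency(FeatureStack(maps=maps), (128, 128))
        r, c = np.unravel_index(sal.gray.argmax(), sal.gray.shape)
        assert 10 * 4 <= r < 16 * 4
        assert 18 * 4 <= c < 24 * 4
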