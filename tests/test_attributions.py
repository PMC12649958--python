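"""Attribution-method tests: closed forms, axioms, determinism, CAM sanity."""

import numpy as np
import pytest

from fundus_xai import (
    AttributionConfig,
    CapabilityError,
    ConfigurationError,
    aggregate_channels,
    compute_saliency,
    deeplift_rescale,
    gradcam_pp,
    integrated_gradients,
    scorecam,
    shap_attribution,
    smoothgrad,
    vanilla_gradient,
)
from fundus_xai.attributions import _upsample
from fundus_xai.models import Conv2d, GlobalAvgPool, Linear, NetworkClassifier, ReLU


def cosine(a, b):
    a, b = np.ravel(a), np.ravel(b)
    return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))


@pytest.fixture(scope="module")
def one_map_net(small_spec):
    """Score for class 1 = global mean of a single everywhere-positive map."""
    rng = np.random.default_rng(7)
    conv = Conv2d(3, 1, ksize=3, stride=2, pad=1, rng=rng, name="conv1")
    conv.weight = np.abs(conv.weight) + 0.05
    fc = Linear(1, small_spec.num_classes, name="fc")
    fc.weight[0, 1] = 1.0
    return NetworkClassifier(
        [conv, ReLU(name="relu1"), GlobalAvgPool(name="gap"), fc],
        spec=small_spec, identity="one_map", feature_layer="relu1")


class TestAggregateChannels:
    def test_sums_absolute_values_per_pixel(self):
        raw = np.zeros((2, 2, 3))
        raw[0, 0] = (+1.0, -1.0, 0.0)
        out = aggregate_channels(raw)
        assert out[0, 0] == 2.0 and out[1, 1] == 0.0

    def test_channel_permutation_invariant(self):
        raw = np.random.default_rng(0).normal(size=(4, 4, 3))
        out = aggregate_channels(raw)
        assert np.allclose(out, aggregate_channels(raw[..., ::-1]), rtol=1e-14)

    def test_all_zero_raw_gives_zero_map(self):
        assert not aggregate_channels(np.zeros((3, 3, 3))).any()


class TestVanillaGradient:
    def test_linear_model_map_is_channel_summed_weights(self, linear_model, small_spec,
                                                        small_image):
        sal = vanilla_gradient(linear_model, small_image, 2)
        w = linear_model.layers[-1].weight[:, 2].reshape(small_spec.shape)
        assert np.allclose(sal.map2d, np.abs(w).sum(axis=-1))

    def test_composition_is_bit_identical_to_input_gradient(self, tiny_cnn,
                                                            small_image):
        sal = vanilla_gradient(tiny_cnn, small_image, 1)
        assert np.array_equal(sal.raw, tiny_cnn.input_gradient(small_image, 1))
        assert np.array_equal(sal.map2d, aggregate_channels(sal.raw))

    def test_non_differentiable_handle_raises(self, tiny_cnn, small_image):
        with pytest.raises(CapabilityError):
            vanilla_gradient(tiny_cnn.without_gradients(), small_image, 1)


class TestSmoothGrad:
    def test_zero_sigma_is_bit_identical_to_vanilla_gradient(self, tiny_cnn,
                                                             small_image):
        sal = smoothgrad(tiny_cnn, small_image, 1, AttributionConfig(sg_sigma=0.0))
        assert np.array_equal(sal.raw, vanilla_gradient(tiny_cnn, small_image, 1).raw)

    def test_linear_model_mean_gradient_recovers_weights(self, linear_model,
                                                         small_spec, small_image):
        # E[grad] = w for a linear score, any noise level; Monte-Carlo oracle
        cfg = AttributionConfig(sg_samples=1000, sg_sigma=0.2, rng_seed=4)
        sal = smoothgrad(linear_model, small_image, 0, cfg)
        w = linear_model.layers[-1].weight[:, 0].reshape(small_spec.shape)
        # gradients are exactly w at every sample point, so the mean is exact
        assert np.allclose(sal.raw, w, atol=1e-12)

    def test_same_seed_reproduces_map(self, tiny_cnn, small_image):
        cfg = AttributionConfig(sg_samples=8, rng_seed=21)
        a = smoothgrad(tiny_cnn, small_image, 2, cfg)
        b = smoothgrad(tiny_cnn, small_image, 2, cfg)
        assert np.array_equal(a.raw, b.raw)

    def test_invalid_sample_count_rejected(self):
        with pytest.raises(ConfigurationError):
            AttributionConfig(sg_samples=0)


class TestIntegratedGradients:
    def test_linear_model_closed_form_any_step_count(self, linear_model, small_spec,
                                                     small_image):
        w = linear_model.layers[-1].weight[:, 3].reshape(small_spec.shape)
        for steps in (1, 7, 32):
            sal = integrated_gradients(linear_model, small_image, 3,
                                       AttributionConfig(ig_steps=steps))
            assert np.allclose(sal.raw, w * small_image, atol=1e-12)

    def test_zero_at_baseline(self, tiny_cnn, small_spec):
        black = np.zeros(small_spec.shape)
        sal = integrated_gradients(tiny_cnn, black, 1)
        assert not sal.raw.any()

    def test_completeness_on_tiny_cnn(self, tiny_cnn, small_spec, small_image):
        sal = integrated_gradients(tiny_cnn, small_image, 1,
                                   AttributionConfig(ig_steps=256))
        delta = tiny_cnn.score(small_image, 1) - tiny_cnn.score(
            np.zeros(small_spec.shape), 1)
        assert abs(sal.raw.sum() - delta) < 1e-2 * abs(delta) + 1e-4

    def test_baseline_shape_mismatch_is_config_error(self, tiny_cnn, small_image):
        with pytest.raises(ConfigurationError):
            integrated_gradients(tiny_cnn, small_image, 0,
                                 AttributionConfig(baseline=np.zeros((2, 2, 3))))


class TestShapExpectedGradients:
    def test_linear_model_monte_carlo_recovers_ig(self, linear_model, small_spec,
                                                  small_image):
        # for a linear score the estimator is exact per sample: (x-0) * w
        cfg = AttributionConfig(shap_samples=2000, rng_seed=17)
        sal = shap_attribution(linear_model, small_image, 0, cfg)
        w = linear_model.layers[-1].weight[:, 0].reshape(small_spec.shape)
        assert np.allclose(sal.raw, w * small_image, atol=1e-12)

    def test_zero_when_image_equals_sole_baseline(self, tiny_cnn, small_spec):
        black = np.zeros(small_spec.shape)
        assert not shap_attribution(tiny_cnn, black, 2).raw.any()

    def test_same_seed_twice_is_identical(self, tiny_cnn, small_image):
        cfg = AttributionConfig(shap_samples=16, rng_seed=9)
        a = shap_attribution(tiny_cnn, small_image, 1, cfg)
        b = shap_attribution(tiny_cnn, small_image, 1, cfg)
        assert np.array_equal(a.raw, b.raw)

    def test_empty_baseline_set_is_config_error(self, tiny_cnn, small_image):
        with pytest.raises(ConfigurationError):
            shap_attribution(tiny_cnn, small_image, 0,
                             AttributionConfig(baseline=[]))


class TestDeepLiftRescale:
    def test_linear_model_exact_closed_form(self, linear_model, small_spec,
                                            small_image):
        sal = deeplift_rescale(linear_model, small_image, 2)
        w = linear_model.layers[-1].weight[:, 2].reshape(small_spec.shape)
        assert np.allclose(sal.raw, w * small_image, atol=1e-12)

    def test_zero_at_baseline(self, tiny_cnn, small_spec):
        black = np.zeros(small_spec.shape)
        assert not deeplift_rescale(tiny_cnn, black, 0).raw.any()

    def test_summation_to_delta_on_relu_net(self, tiny_cnn, small_spec, small_image):
        sal = deeplift_rescale(tiny_cnn, small_image, 1)
        delta = tiny_cnn.score(small_image, 1) - tiny_cnn.score(
            np.zeros(small_spec.shape), 1)
        assert abs(sal.raw.sum() - delta) < 1e-5

    def test_unstructured_handle_raises_capability_error(self, region_10x10):
        model, _, spec = region_10x10
        with pytest.raises(CapabilityError):
            deeplift_rescale(model, np.ones(spec.shape), 1)


class TestGradCamPP:
    def test_single_positive_map_recovers_activation(self, one_map_net, small_image):
        sal = gradcam_pp(one_map_net, small_image, 1)
        A = one_map_net.feature_maps(small_image)[0]
        assert cosine(sal.map2d, _upsample(A, sal.map2d.shape)) > 0.999

    def test_map_is_nonnegative(self, tiny_cnn, small_image):
        assert np.all(gradcam_pp(tiny_cnn, small_image, 0).map2d >= 0)

    def test_constant_output_model_gives_zero_map(self, small_spec, small_image):
        conv = Conv2d(3, 2, rng=np.random.default_rng(0), name="conv1")
        fc = Linear(2, small_spec.num_classes, name="fc")  # zero weights
        net = NetworkClassifier(
            [conv, ReLU(name="relu1"), GlobalAvgPool(name="gap"), fc],
            spec=small_spec, identity="const", feature_layer="relu1")
        assert not gradcam_pp(net, small_image, 1).map2d.any()

    def test_handle_without_feature_maps_raises(self, region_10x10):
        model, _, spec = region_10x10
        with pytest.raises(CapabilityError):
            gradcam_pp(model, np.ones(spec.shape), 1)


class TestScoreCam:
    def test_runs_with_gradient_tracking_disabled(self, one_map_net, small_image):
        sal = scorecam(one_map_net.without_gradients(), small_image, 1)
        assert np.all(sal.map2d >= 0)

    def test_single_map_degenerate_softmax(self, one_map_net, small_image):
        sal = scorecam(one_map_net, small_image, 1)
        A = one_map_net.feature_maps(small_image)[0]
        norm = (A - A.min()) / (A.max() - A.min())
        assert cosine(sal.map2d, _upsample(norm, sal.map2d.shape)) > 0.999

    def test_all_zero_feature_stack_gives_zero_map(self, small_spec, small_image):
        conv = Conv2d(3, 2, name="conv1")  # zero weights -> zero maps
        fc = Linear(2, small_spec.num_classes, name="fc")
        net = NetworkClassifier(
            [conv, ReLU(name="relu1"), GlobalAvgPool(name="gap"), fc],
            spec=small_spec, identity="zero_maps", feature_layer="relu1")
        assert not scorecam(net, small_image, 1).map2d.any()


class TestInvariants:
    def test_every_method_zero_on_constant_output_model(self, small_spec, small_image):
        conv = Conv2d(3, 2, rng=np.random.default_rng(1), name="conv1")
        fc = Linear(2, small_spec.num_classes, name="fc")  # zero head
        net = NetworkClassifier(
            [conv, ReLU(name="relu1"), GlobalAvgPool(name="gap"), fc],
            spec=small_spec, identity="const", feature_layer="relu1")
        cfg = AttributionConfig(sg_samples=4, shap_samples=4, ig_steps=4, rng_seed=0)
        for method in ("gradient", "smoothgrad", "integrated_gradients", "shap",
                       "deeplift", "gradcam++", "scorecam"):
            sal = compute_saliency(net, small_image, 1, method, config=cfg)
            assert not sal.map2d.any(), method

    def test_cam_maps_align_with_input_grid(self, tiny_cnn, small_spec, small_image):
        for method in ("gradcam++", "scorecam"):
            sal = compute_saliency(tiny_cnn, small_image, 0, method)
            assert sal.map2d.shape == (small_spec.height, small_spec.width)
            assert np.all(sal.map2d >= 0)

    def test_unknown_method_name_rejected(self, tiny_cnn, small_image):
        with pytest.raises(ConfigurationError):
            compute_saliency(tiny_cnn, small_image, 0, "lime")
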