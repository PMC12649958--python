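"""Saliency-metric tests: normalization, entropy, curves, AOPC, overlap."""

import math

import numpy as np
import pytest

from fundus_xai import (
    AttributionConfig,
    ConfigurationError,
    InputContractError,
    InputSpec,
    UndefinedMetricError,
    aopc,
    binarize_top_percentile,
    dice,
    entropy,
    evaluate_batch,
    make_region_fraction_model,
    make_tiny_cnn,
    normalize_minmax,
    perturbation_curve,
    recall,
    summarize_records,
    to_distribution,
)
from fundus_xai.metrics import PerturbationCurve


class TestNormalizeMinmax:
    def test_affine_identity_on_known_values(self):
        m = np.array([[0.0, 127.5], [255.0, 0.0]])
        out = normalize_minmax(m)
        assert out[0, 0] == 0.0 and out[0, 1] == 0.5 and out[1, 0] == 1.0

    def test_idempotent(self):
        m = np.random.default_rng(0).uniform(3, 9, (6, 6))
        once = normalize_minmax(m)
        assert np.allclose(normalize_minmax(once), once)

    def test_constant_map_degenerates_to_uniform_with_warning(self):
        with pytest.warns(UserWarning):
            out = normalize_minmax(np.full((4, 4), 2.5))
        assert np.ptp(out) == 0.0


class TestToDistribution:
    def test_two_equal_pixels_split_mass(self):
        m = np.zeros((3, 3))
        m[0, 0] = m[2, 2] = 1.0
        d = to_distribution(m)
        assert d.p[0] == 0.5 and d.p[-1] == 0.5

    def test_delta_map_concentrates_all_mass(self):
        m = np.zeros((4, 4))
        m[1, 2] = 7.0
        d = to_distribution(m)
        assert d.p[1 * 4 + 2] == 1.0

    def test_random_maps_always_sum_to_one(self):
        gen = np.random.default_rng(3)
        for _ in range(100):
            d = to_distribution(gen.uniform(0, 1, (5, 5)))
            assert d.p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_negative_values_rejected(self):
        with pytest.raises(InputContractError):
            to_distribution(np.array([[-1.0, 1.0]]))


class TestEntropy:
    def test_delta_distribution_is_zero_bits(self):
        m = np.zeros((4, 4))
        m[0, 0] = 1.0
        assert entropy(to_distribution(m)) == 0.0

    def test_uniform_224_map_attains_log2_n(self):
        h = entropy(to_distribution(np.ones((224, 224))))
        assert h == pytest.approx(math.log2(224 * 224), abs=1e-9)

    def test_two_equal_atoms_give_one_bit(self):
        m = np.zeros((2, 2))
        m[0, 0] = m[1, 1] = 3.0
        assert entropy(to_distribution(m)) == pytest.approx(1.0)

    def test_bounds_hold_for_random_maps(self):
        gen = np.random.default_rng(11)
        for _ in range(50):
            m = gen.uniform(0, 1, (12, 12))
            h = entropy(to_distribution(normalize_minmax(m)))
            assert 0.0 <= h <= math.log2(144) + 1e-12


class TestPerturbationCurve:
    def test_planted_region_model_decays_linearly_then_flat(self, region_10x10):
        model, region, spec = region_10x10
        img = np.ones(spec.shape)
        curve = perturbation_curve(model, img, region.astype(float), 1)
        n, r = 100, int(region.sum())
        expected = [1.0] + [max(0.0, 1.0 - math.ceil(k * n / 50) / r)
                            for k in range(1, 51)]
        assert np.max(np.abs(curve.confidences - expected)) <= 1e-6

    def test_default_step_gives_51_points_starting_at_zero(self, region_10x10):
        model, region, spec = region_10x10
        curve = perturbation_curve(model, np.ones(spec.shape),
                                   region.astype(float), 1)
        assert curve.K == 50 and len(curve.ratios) == 51
        assert curve.ratios[0] == 0.0 and curve.ratios[-1] == pytest.approx(1.0)

    def test_constant_model_yields_flat_curve(self, small_spec, small_image):
        net = make_tiny_cnn(small_spec, seed=0)
        net.layers[-1].weight[...] = 0.0  # constant scores
        sal = np.random.default_rng(0).uniform(0, 1, (8, 8))
        curve = perturbation_curve(net, small_image, sal, 2)
        assert np.ptp(curve.confidences) == 0.0

    def test_monotone_decay_under_correct_saliency(self, region_10x10):
        # confidence is non-decreasing in unmasked region content, so the
        # curve under the indicator saliency is non-increasing
        model, region, spec = region_10x10
        curve = perturbation_curve(model, np.ones(spec.shape),
                                   region.astype(float), 1)
        assert np.all(np.diff(curve.confidences) <= 1e-12)

    def test_bad_step_is_config_error(self, region_10x10):
        model, region, spec = region_10x10
        with pytest.raises(ConfigurationError):
            perturbation_curve(model, np.ones(spec.shape),
                               region.astype(float), 1, step=0.03)

    def test_misaligned_map_rejected(self, region_10x10):
        model, _, spec = region_10x10
        with pytest.raises(InputContractError):
            perturbation_curve(model, np.ones(spec.shape), np.ones((4, 4)), 1)


class TestAopc:
    def test_flat_curve_scores_zero(self):
        c = PerturbationCurve(np.linspace(0, 1, 51), np.full(51, 0.3), 50)
        assert aopc(c) == 0.0

    def test_maximal_drop_scores_one(self):
        conf = np.zeros(51)
        conf[0] = 1.0
        assert aopc(PerturbationCurve(np.linspace(0, 1, 51), conf, 50)) == 1.0

    def test_matches_hand_summed_drops_on_planted_model(self, region_10x10):
        model, region, spec = region_10x10
        curve = perturbation_curve(model, np.ones(spec.shape),
                                   region.astype(float), 1)
        by_hand = sum(curve.confidences[0] - c for c in curve.confidences[1:]) / 50
        assert aopc(curve) == pytest.approx(by_hand, abs=1e-12)

    def test_indicator_saliency_beats_random_saliency(self, region_10x10):
        model, region, spec = region_10x10
        img = np.ones(spec.shape)
        indicator = aopc(perturbation_curve(model, img, region.astype(float), 1))
        gen = np.random.default_rng(42)
        random_scores = [
            aopc(perturbation_curve(model, img, gen.uniform(0, 1, (10, 10)), 1))
            for _ in range(20)
        ]
        assert indicator > np.mean(random_scores)


class TestBinarizeTopPercentile:
    def test_distinct_values_1_to_100_retain_exactly_ten(self):
        m = np.arange(1.0, 101.0).reshape(10, 10)
        b = binarize_top_percentile(m, 0.9)
        assert int(b.highlight.sum()) == 10
        assert set(m[b.highlight]) == set(range(91, 101))

    def test_constant_map_retains_nothing(self):
        with pytest.warns(UserWarning):
            b = binarize_top_percentile(np.full((5, 5), 0.7))
        assert not b.highlight.any()

    def test_retention_bounded_by_decile_plus_ties(self):
        gen = np.random.default_rng(5)
        for _ in range(20):
            m = gen.integers(0, 5, (10, 10)).astype(float)
            b = binarize_top_percentile(m)
            ties = int((m == b.threshold_value).sum())
            assert int(b.highlight.sum()) <= 10 + ties


class TestRecallDice:
    def test_recall_three_of_four(self):
        A = np.zeros((4, 4), bool)
        B = np.zeros((4, 4), bool)
        A[0, :3] = True
        B[0, :3] = True
        B[1, 0] = True
        assert recall(A, B) == 0.75

    def test_recall_is_one_when_highlight_covers_truth(self):
        A = np.ones((3, 3), bool)
        B = np.zeros((3, 3), bool)
        B[1, 1] = True
        assert recall(A, B) == 1.0

    def test_dice_identical_sets(self):
        A = np.zeros((3, 3), bool)
        A[0] = True
        assert dice(A, A.copy()) == 1.0

    def test_dice_disjoint_sets(self):
        A = np.zeros((3, 3), bool)
        B = np.zeros((3, 3), bool)
        A[0] = True
        B[2] = True
        assert dice(A, B) == 0.0

    def test_dice_half_overlap(self):
        A = np.zeros((5, 5), bool)
        B = np.zeros((5, 5), bool)
        A.ravel()[:10] = True
        B.ravel()[5:15] = True
        assert dice(A, B) == 0.5

    def test_empty_truth_is_undefined_metric(self):
        A = np.ones((3, 3), bool)
        with pytest.raises(UndefinedMetricError):
            recall(A, np.zeros((3, 3), bool))
        with pytest.raises(UndefinedMetricError):
            dice(np.zeros((3, 3), bool), np.zeros((3, 3), bool))

    def test_invariant_under_joint_spatial_permutation(self):
        gen = np.random.default_rng(8)
        A = gen.uniform(size=(6, 6)) > 0.6
        B = gen.uniform(size=(6, 6)) > 0.5
        perm = gen.permutation(36)
        Ap = A.ravel()[perm].reshape(6, 6)
        Bp = B.ravel()[perm].reshape(6, 6)
        assert recall(A, B) == recall(Ap, Bp)
        assert dice(A, B) == dice(Ap, Bp)


class TestEvaluateBatch:
    @pytest.fixture()
    def batch_model(self, small_spec):
        return make_tiny_cnn(small_spec, seed=3)

    def test_one_image_one_method_gives_one_record(self, batch_model, small_image):
        recs = evaluate_batch(batch_model, [(small_image, 1, None)], ["gradient"])
        assert len(recs) == 1
        assert recs[0].entropy is not None and recs[0].aopc is not None

    def test_empty_mask_skips_overlap_metrics(self, batch_model, small_image):
        mask = np.zeros((8, 8), bool)
        recs = evaluate_batch(batch_model, [(small_image, 0, mask)], ["gradient"])
        assert recs[0].recall is None and recs[0].dice is None

    def test_nonempty_mask_fills_overlap_metrics(self, batch_model, small_image):
        mask = np.zeros((8, 8), bool)
        mask[2:5, 2:5] = True
        recs = evaluate_batch(batch_model, [(small_image, 2, mask)], ["gradient"])
        assert 0.0 <= recs[0].recall <= 1.0
        assert 0.0 <= recs[0].dice <= 1.0

    def test_per_label_mean_matches_hand_computation(self, batch_model, small_spec):
        gen = np.random.default_rng(1)
        items = [(gen.uniform(0, 1, small_spec.shape), 1, None) for _ in range(3)]
        recs = evaluate_batch(batch_model, items, ["gradient"])
        table = summarize_records(recs, exclude_methods=())
        assert table.loc[0, "Entropy"] == pytest.approx(
            np.mean([r.entropy for r in recs]))
        assert table.loc[0, "AOPC_Score"] == pytest.approx(
            np.mean([r.aopc for r in recs]))

    def test_failures_are_recorded_not_raised(self, small_image):
        spec = InputSpec(height=8, width=8)
        region = np.zeros((8, 8), bool)
        region[0, 0] = True
        model = make_region_fraction_model(region, spec)  # no feature maps
        recs = evaluate_batch(model, [(small_image, 1, None)],
                              ["gradient", "scorecam"])
        by_method = {r.method: r for r in recs}
        assert by_method["gradient"].error is None
        assert "Capability" in by_method["scorecam"].error

    def test_cam_methods_excluded_from_quality_summary_by_default(
            self, batch_model, small_image):
        recs = evaluate_batch(batch_model, [(small_image, 1, None)],
                              ["gradient", "gradcam++", "scorecam"])
        table = summarize_records(recs)
        only_grad = [r for r in recs if r.method == "gradient"]
        assert table.loc[0, "Entropy"] == pytest.approx(only_grad[0].entropy)
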