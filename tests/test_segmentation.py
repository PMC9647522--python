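"""Filter bank, pixel classifier, binarization and the threshold fallback."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage as ndi

from mitoholo import simkit
from mitoholo.segmentation import (
    binarize,
    compute_features,
    dice_coefficient,
    load_classifier,
    predict_probability,
    save_classifier,
    threshold_segment,
    train_pixel_classifier,
)

from _oracles import flood_fill_filter


def _two_blob_frame(rng, shape=(48, 48), level=100.0):
    """Linearly separable synthetic frame: two bright blobs on flat background."""
    frame = np.full(shape, 20.0) + rng.normal(0, 0.5, shape)
    frame[8:16, 8:20] += level
    frame[30:40, 28:40] += level
    scrib = np.zeros(shape, np.uint8)
    scrib[9:15, 9:19] = 1
    scrib[31:39, 29:39] = 1
    scrib[0:6, :] = 2
    scrib[:, 44:] = 2
    return frame, scrib


class TestFeatures:
    def test_constant_image_has_zero_gradient(self):
        feats = compute_features(np.full((16, 16), 7.0), [("gradient_magnitude", 1.5)])
        assert np.allclose(feats, 0.0)

    def test_gaussian_preserves_mean(self, rng):
        frame = rng.random((32, 32)) * 50
        feats = compute_features(frame, [("gaussian", 2.0)])
        assert feats[0].mean() == pytest.approx(frame.mean(), rel=1e-3)

    def test_laplacian_of_impulse_matches_derivative_convolution(self):
        frame = np.zeros((21, 21))
        frame[10, 10] = 1.0
        feats = compute_features(frame, [("laplacian", 1.5)])
        # independent route: sum of the two second-derivative-of-Gaussian responses
        oracle = ndi.gaussian_filter(frame, 1.5, order=(2, 0)) + ndi.gaussian_filter(
            frame, 1.5, order=(0, 2)
        )
        assert np.allclose(feats[0], oracle, atol=1e-10)

    def test_unknown_filter_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown filter kind"):
            compute_features(np.zeros((8, 8)), [("sobel", 1.0)])

    def test_one_plane_per_feature(self, rng):
        frame = rng.random((16, 16))
        spec = [("gaussian", 1.0), ("dog", 1.0), ("hessian_eigen", 1.5)]
        assert compute_features(frame, spec).shape == (3, 16, 16)


class TestClassifier:
    def test_separable_blobs_reach_perfect_holdout_accuracy(self, rng):
        frame, scrib = _two_blob_frame(rng)
        clf = train_pixel_classifier(frame, scrib, seed=0)
        assert clf.train_summary["holdout_accuracy"] == 1.0

    def test_same_seed_gives_identical_predictions(self, rng):
        frame, scrib = _two_blob_frame(rng)
        p1 = predict_probability(train_pixel_classifier(frame, scrib, seed=3), frame)
        p2 = predict_probability(train_pixel_classifier(frame, scrib, seed=3), frame)
        assert np.array_equal(p1, p2)

    def test_single_class_scribbles_rejected(self, rng):
        frame, scrib = _two_blob_frame(rng)
        scrib[scrib == 2] = 0
        with pytest.raises(ValueError, match="each class"):
            train_pixel_classifier(frame, scrib)

    def test_probabilities_bounded_and_ordered_on_training_pixels(self, rng):
        frame, scrib = _two_blob_frame(rng)
        clf = train_pixel_classifier(frame, scrib, seed=0)
        prob = predict_probability(clf, frame)
        assert prob.min() >= 0.0 and prob.max() <= 1.0
        assert prob[scrib == 1].mean() > prob[scrib == 2].mean()

    def test_constant_frame_gives_constant_map(self, rng):
        frame, scrib = _two_blob_frame(rng)
        clf = train_pixel_classifier(frame, scrib, seed=0)
        prob = predict_probability(clf, np.full((16, 16), 20.0))
        assert np.ptp(prob) == 0.0

    def test_all_background_frame_scores_below_half(self, rng):
        frame, scrib = _two_blob_frame(rng)
        clf = train_pixel_classifier(frame, scrib, seed=0)
        bg = np.full((32, 32), 20.0) + rng.normal(0, 0.5, (32, 32))
        assert predict_probability(clf, bg).max() < 0.5

    def test_simulated_frame_with_ground_truth_labels(self, noisefree_wt):
        scenario, ri, _, gt = noisefree_wt
        frame = ri.pixels[0].astype(float)
        gtm = simkit.ground_truth_mask(scenario, gt, 0)
        scrib = np.where(gtm, 1, 2).astype(np.uint8)
        clf = train_pixel_classifier(frame, scrib, seed=0)
        assert clf.train_summary["holdout_accuracy"] > 0.9

    def test_save_load_round_trip(self, tmp_path, rng):
        frame, scrib = _two_blob_frame(rng)
        clf = train_pixel_classifier(frame, scrib, seed=0)
        save_classifier(clf, tmp_path / "clf.pkl")
        back = load_classifier(tmp_path / "clf.pkl")
        assert np.array_equal(predict_probability(back, frame), predict_probability(clf, frame))

    def test_feature_mismatch_rejected(self, rng):
        frame, scrib = _two_blob_frame(rng)
        clf = train_pixel_classifier(frame, scrib, seed=0)
        clf.feature_spec = (("gaussian", 1.0),)
        with pytest.raises(ValueError, match="feature_spec mismatch"):
            predict_probability(clf, frame)


class TestBinarize:
    def test_zero_map_gives_empty_mask(self):
        assert not binarize(np.zeros((10, 10)), 0.5, 5).any()

    def test_blob_below_size_filter_removed(self):
        m = np.zeros((10, 10))
        m[4, 4:7] = 1.0  # 3-pixel blob
        assert not binarize(m, 0.5, min_object_px=5).any()
        assert binarize(m, 0.5, min_object_px=3).sum() == 3

    def test_probability_threshold_domain_enforced(self):
        with pytest.raises(ValueError):
            binarize(np.zeros((4, 4)), threshold=1.5)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_matches_flood_fill_oracle(self, seed):
        r = np.random.default_rng(seed)
        values = ndi.gaussian_filter(r.random((24, 24)), 1.2)
        thr = float(np.quantile(values, 0.7))
        min_px = int(r.integers(2, 9))
        ours = binarize(values, thr, min_px, is_probability=False)
        assert np.array_equal(ours, flood_fill_filter(values, thr, min_px))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), t_lo=st.floats(0.1, 0.5), dt=st.floats(0.01, 0.4))
    def test_raising_threshold_never_grows_the_mask(self, seed, t_lo, dt):
        values = np.random.default_rng(seed).random((20, 20))
        lo = binarize(values, t_lo, 4)
        hi = binarize(values, min(t_lo + dt, 0.99), 4)
        assert hi.sum() <= lo.sum()
        assert np.all(lo | ~hi)  # hi is a subset of lo


class TestThresholdSegment:
    def test_bimodal_image_split_between_modes(self):
        frame = np.full((40, 40), 10.0)
        frame[10:20, 10:25] = 90.0
        mask = threshold_segment(frame, bg_sigma=50.0, min_object_px=5)
        assert np.array_equal(mask, frame > 50.0)

    def test_polarity_flag_recovers_dark_objects(self):
        frame = np.full((40, 40), 90.0)
        frame[10:20, 10:25] = 10.0
        mask = threshold_segment(frame, bg_sigma=50.0, min_object_px=5, polarity="dark")
        assert np.array_equal(mask, frame < 50.0)

    def test_constant_frame_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="constant frame"):
            mask = threshold_segment(np.full((16, 16), 3.0))
        assert not mask.any()

    def test_noise_only_frame_yields_empty_mask(self, rng):
        frame = 100.0 + rng.normal(0, 4.0, (64, 64))
        assert not threshold_segment(frame).any()

    def test_dice_on_simulated_frame_at_default_noise(self, wt_movie):
        scenario, _, gt = wt_movie
        ri, _, _ = simkit.simulate_experiment(scenario)
        mask = threshold_segment(ri.pixels[0].astype(float))
        gtm = simkit.ground_truth_mask(scenario, gt, 0)
        assert dice_coefficient(mask, gtm) >= 0.8


def test_dice_coefficient_definition():
    a = np.zeros((4, 4), bool)
    b = np.zeros((4, 4), bool)
    assert dice_coefficient(a, b) == 1.0
    a[0, 0] = True
    assert dice_coefficient(a, b) == 0.0
    b[0, 0] = True
    assert dice_coefficient(a, b) == 1.0
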