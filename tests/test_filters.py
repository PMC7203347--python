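import numpy as np
import pytest

from spikewta import (
    ConvFilter,
    FilterBank,
    NonSeparableError,
    compute_feature_map,
    convolve_valid,
    pool_and_binarize,
    train_class_filter,
    train_feature_filters,
    train_filter_bank,
)
from spikewta.filters import _quantize


def naive_convolve(image, weights):
    """Independent quadruple-loop oracle for the valid cross-correlation."""
    out = np.zeros((9, 9), dtype=np.int64)
    for r in range(9):
        for c in range(9):
            acc = 0
            for i in range(20):
                for j in range(20):
                    acc += int(image[r + i][c + j]) * int(weights[i][j])
            out[r, c] = acc
    return out


class TestConvolveValid:
    def test_zero_image_gives_zero_response(self):
        f = ConvFilter(np.ones((20, 20)), "feature", 0)
        assert np.all(convolve_valid(np.zeros((28, 28), dtype=int), f) == 0)

    def test_saturated_image_all_ones_filter_closed_form(self):
        img = np.full((28, 28), 255)
        resp = convolve_valid(img, np.ones((20, 20), dtype=int))
        assert resp.shape == (9, 9)
        assert np.all(resp == 20 * 20 * 255)  # 102000, needs wide accumulators

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 256, size=(28, 28))
        w = rng.integers(-128, 128, size=(20, 20))
        assert np.array_equal(convolve_valid(img, w), naive_convolve(img, w))

    def test_shape_errors(self):
        with pytest.raises(ValueError):
            convolve_valid(np.zeros((27, 28)), np.zeros((20, 20)))
        with pytest.raises(ValueError):
            convolve_valid(np.zeros((28, 28)), np.zeros((19, 20)))
        with pytest.raises(ValueError):
            convolve_valid(np.full((28, 28), 256), np.zeros((20, 20)))


class TestPoolAndBinarize:
    def test_response_equal_to_threshold_does_not_fire(self):
        resp = np.zeros((9, 9), dtype=int)
        resp[4, 4] = 1000
        assert pool_and_binarize(resp, 1000) == 0
        assert pool_and_binarize(resp, 999) == 1

    def test_threshold_below_minimum_always_fires(self):
        resp = np.full((9, 9), -50)
        assert pool_and_binarize(resp, -51) == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_bruteforce_max_scan(self, seed):
        rng = np.random.default_rng(100 + seed)
        resp = rng.integers(-10**6, 10**6, size=(9, 9))
        t = int(rng.integers(-10**6, 10**6))
        best = max(int(v) for row in resp for v in row)
        assert pool_and_binarize(resp, t) == int(best > t)


def _toy_bank():
    rng = np.random.default_rng(0)
    cfs = [
        ConvFilter(rng.integers(-128, 128, (20, 20)), "class", 10**6, target_class=c)
        for c in range(2)
    ]
    ffs = [
        ConvFilter(rng.integers(-128, 128, (20, 20)), "feature", 10**6)
        for _ in range(14)
    ]
    return FilterBank(cfs + ffs)


class TestFeatureMap:
    def test_length_16_and_deterministic(self):
        bank = _toy_bank()
        rng = np.random.default_rng(1)
        img = rng.integers(0, 256, (28, 28))
        fm1 = compute_feature_map(img, bank)
        fm2 = bank.compute_feature_map(img)
        assert fm1.shape == (16,)
        assert np.array_equal(fm1, fm2)
        assert set(np.unique(fm1)) <= {0, 1}

    def test_zero_image_positive_thresholds_all_zero_map(self):
        assert np.all(compute_feature_map(np.zeros((28, 28), int), _toy_bank()) == 0)

    def test_batch_maps_match_single_image_path(self):
        bank = _toy_bank()
        rng = np.random.default_rng(2)
        imgs = rng.integers(0, 256, (5, 28, 28))
        batch = bank.compute_feature_maps(imgs)
        singles = np.stack([bank.compute_feature_map(im) for im in imgs])
        assert np.array_equal(batch, singles)

    def test_self_match_embedding_fires_at_calibrated_threshold(self):
        rng = np.random.default_rng(3)
        w = rng.integers(-128, 128, (20, 20))
        img = np.zeros((28, 28), dtype=int)
        img[4:24, 4:24] = np.clip(w, 0, 127) * 2  # rescaled, clipped template
        resp = convolve_valid(img, w)
        theta = int(resp[4, 4]) - 1
        f = ConvFilter(w, "feature", theta)
        assert pool_and_binarize(resp, f.threshold) == 1

    def test_class_filters_must_precede_feature_filters(self):
        rng = np.random.default_rng(4)
        ff = ConvFilter(rng.integers(-128, 128, (20, 20)), "feature", 0)
        cf = ConvFilter(rng.integers(-128, 128, (20, 20)), "class", 0, target_class=1)
        with pytest.raises(ValueError):
            FilterBank([ff, cf])


class TestConvFilterValidation:
    def test_weight_range_and_shape(self):
        with pytest.raises(ValueError):
            ConvFilter(np.full((20, 20), 200), "feature", 0)
        with pytest.raises(ValueError):
            ConvFilter(np.zeros((10, 10)), "feature", 0)

    def test_kind_target_consistency(self):
        with pytest.raises(ValueError):
            ConvFilter(np.zeros((20, 20)), "class", 0)  # missing target
        with pytest.raises(ValueError):
            ConvFilter(np.zeros((20, 20)), "feature", 0, target_class=3)


class TestClassFilterTraining:
    def test_separates_two_stroke_classes_on_held_out_split(self, stroke_images):
        images, labels = stroke_images
        train, test = slice(0, 110), slice(110, None)
        f = train_class_filter(images[train], labels[train], 0, seed=0)
        bits = [
            pool_and_binarize(convolve_valid(im, f), f.threshold)
            for im in images[test]
        ]
        truth = (labels[test] == 0).astype(int)
        acc = float(np.mean(np.array(bits) == truth))
        assert acc >= 0.95

    def test_single_target_image_limit_correlates_with_best_crop(self, stroke_images):
        images, labels = stroke_images
        target = images[labels == 0][:1]
        negatives = images[labels == 1][:12]
        X = np.concatenate([target, negatives])
        y = np.array([0] + [1] * len(negatives))
        f = train_class_filter(X, y, 0, seed=0)
        # best-matching 20x20 crop of the single target image
        resp = convolve_valid(target[0], f)
        r, c = np.unravel_index(np.argmax(resp), (9, 9))
        crop = target[0][r : r + 20, c : c + 20].astype(float).ravel()
        w = f.weights.astype(float).ravel()
        cosine = float(w @ crop / (np.linalg.norm(w) * np.linalg.norm(crop)))
        assert cosine > 0

    def test_training_needs_both_classes(self, stroke_images):
        images, labels = stroke_images
        only = images[labels == 0]
        with pytest.raises(ValueError):
            train_class_filter(only, np.zeros(len(only)), 0)

    def test_identical_images_across_classes_not_separable(self):
        img = np.full((28, 28), 50)
        X = np.stack([img] * 20)
        y = np.array([0] * 10 + [1] * 10)
        with pytest.raises(NonSeparableError):
            train_class_filter(X, y, 0, seed=0)

    def test_quantization_changes_few_held_out_decisions(self, stroke_images):
        images, labels = stroke_images
        train, test = slice(0, 110), slice(110, None)
        f, diag = train_class_filter(
            images[train], labels[train], 0, seed=0, with_diagnostics=True
        )
        n_diff = 0
        for im in images[test]:
            q_bit = pool_and_binarize(convolve_valid(im, f), f.threshold)
            # float-path decision: pre-quantization kernel + logistic midpoint
            s = (
                np.einsum(
                    "rcij,ij->rc",
                    np.lib.stride_tricks.sliding_window_view(
                        im.astype(float) / 255.0, (20, 20)
                    ),
                    diag["float_weights"],
                ).max()
                + diag["float_bias"]
            )
            n_diff += int(q_bit != int(s > 0))
        assert n_diff / (len(images) - 110) <= 0.05


class TestFeatureFilterTraining:
    def test_each_filter_fires_on_a_nontrivial_fraction(self, stroke_images):
        images, labels = stroke_images
        ffs = train_feature_filters(images, labels, 4, seed=1)
        assert len(ffs) == 4
        sigs = []
        for ff in ffs:
            bits = np.array([
                pool_and_binarize(convolve_valid(im, ff), ff.threshold)
                for im in images
            ])
            assert 0.0 < bits.mean() < 1.0
            sigs.append(bits)
        # pairwise non-identical kernels
        keys = {f.weights.tobytes() for f in ffs}
        assert len(keys) == 4
        # at least two classes receive distinct FF response vectors
        sigs = np.stack(sigs, axis=1)
        mean0 = sigs[labels == 0].mean(axis=0)
        mean1 = sigs[labels == 1].mean(axis=0)
        assert not np.allclose(mean0, mean1)

    def test_blank_training_set_rejected(self):
        X = np.zeros((10, 28, 28), dtype=int)
        with pytest.raises(NonSeparableError):
            train_feature_filters(X, np.zeros(10), 2)

    def test_capacity_overflow_rejected(self):
        X = np.zeros((4, 28, 28), dtype=int)
        with pytest.raises(ValueError):
            train_feature_filters(X, np.zeros(4), 10, max_filters=9)


def test_bank_training_respects_cf_ff_split(stroke_images):
    images, labels = stroke_images
    bank = train_filter_bank(images, labels, (0, 1), n_total=5, seed=0)
    assert bank.n_total == 5
    assert bank.n_class_filters == 2
    assert bank.trained_classes == [0, 1]
    kinds = [f.kind for f in bank.filters]
    assert kinds == ["class", "class", "feature", "feature", "feature"]


def test_quantize_maps_peak_to_127():
    w = np.array([[0.5, -1.0], [0.25, 0.0]])
    q = _quantize(np.pad(w, ((0, 18), (0, 18))))
    assert q.min() == -127 and q.max() == 64
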