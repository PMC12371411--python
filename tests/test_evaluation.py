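"""Metrics vs brute force, pentagon score closed forms, permutation test,
connected-component binarization vs a flood-fill oracle."""

import numpy as np
import pytest

from flairwm import (binarize_segmentation, compute_metrics, mlcps_percent,
                     permutation_test)


def brute_force_metrics(y_true, y_pred):
    tp = sum(1 for t, p in zip(y_true, y_pred) if t == 1 and p == 1)
    fp = sum(1 for t, p in zip(y_true, y_pred) if t == 0 and p == 1)
    tn = sum(1 for t, p in zip(y_true, y_pred) if t == 0 and p == 0)
    fn = sum(1 for t, p in zip(y_true, y_pred) if t == 1 and p == 0)
    out = {"accuracy": 100 * (tp + tn) / len(y_true)}
    out["sensitivity"] = 100 * tp / (tp + fn) if tp + fn else np.nan
    out["specificity"] = 100 * tn / (tn + fp) if tn + fp else np.nan
    out["precision"] = 100 * tp / (tp + fp) if tp + fp else np.nan
    p, r = out["precision"], out["sensitivity"]
    out["f1"] = 2 * p * r / (p + r) if np.isfinite(p) and np.isfinite(r) and p + r else np.nan
    return out, (tp, fp, tn, fn)


def pairwise_auroc(y_true, scores):
    """Exhaustive pairwise-comparison AUROC with half-credit for ties."""
    pos = [s for t, s in zip(y_true, scores) if t == 1]
    neg = [s for t, s in zip(y_true, scores) if t == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestComputeMetrics:
    def test_holdout_confusion_reproduces_published_row(self):
        """TP=9, FN=1, TN=5, FP=5 on 20 scans: 70% accuracy, 90% sensitivity,
        50% specificity."""
        y_true = [1] * 10 + [0] * 10
        y_pred = [1] * 9 + [0] + [1] * 5 + [0] * 5
        r = compute_metrics(y_true, y_pred)
        assert r.confusion == (9, 5, 5, 1)
        assert r.accuracy == pytest.approx(70.0)
        assert r.sensitivity == pytest.approx(90.0)
        assert r.specificity == pytest.approx(50.0)

    def test_perfect_predictions(self):
        y = [1, 0, 1, 0, 1]
        r = compute_metrics(y, y, y_score=[0.9, 0.1, 0.8, 0.2, 0.7])
        for v in (r.accuracy, r.sensitivity, r.specificity, r.precision,
                  r.f1, r.auroc, r.mlcps_percent):
            assert v == pytest.approx(100.0)

    def test_matches_brute_force_on_random_cases(self, rng):
        import warnings as _warnings
        for _ in range(1000):
            n = int(rng.integers(4, 30))
            y_true = rng.integers(0, 2, n)
            y_pred = rng.integers(0, 2, n)
            expected, conf = brute_force_metrics(y_true, y_pred)
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore", UserWarning)
                r = compute_metrics(y_true, y_pred)
            assert r.confusion == conf
            for key, val in expected.items():
                got = getattr(r, key)
                if np.isnan(val):
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(val)

    def test_auroc_matches_pairwise_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 50))
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            scores = rng.integers(0, 5, n).astype(float)  # forces ties
            r = compute_metrics(y, y, y_score=scores)
            assert r.auroc == pytest.approx(100 * pairwise_auroc(y, scores))

    def test_random_scores_auroc_near_half(self, rng):
        n = 10_000
        y = rng.integers(0, 2, n)
        r = compute_metrics(y, y, y_score=rng.random(n))
        assert r.auroc == pytest.approx(50.0, abs=2.0)

    def test_single_class_truth_flagged(self):
        with pytest.warns(UserWarning, match="single-class"):
            r = compute_metrics([1, 1, 1], [1, 0, 1])
        assert np.isnan(r.specificity)

    def test_string_labels_accepted(self):
        r = compute_metrics(["positive", "negative"], ["positive", "negative"])
        assert r.accuracy == 100.0


class TestMLcps:
    def test_all_hundred_is_hundred(self):
        assert mlcps_percent([100] * 5) == pytest.approx(100.0)

    @pytest.mark.parametrize("m", [0, 25, 50, 80, 100])
    def test_all_equal_closed_form(self, m):
        # equal radii m: pentagon area scales as m^2
        assert mlcps_percent([m] * 5) == pytest.approx(m * m / 100)

    def test_single_zero_axis(self):
        # two adjacent cross terms vanish: 3/5 of the maximum remains
        assert mlcps_percent([100, 100, 0, 100, 100]) == pytest.approx(60.0)

    def test_monotone_in_each_argument(self, rng):
        for _ in range(50):
            base = rng.uniform(0, 100, 5)
            i = int(rng.integers(5))
            bumped = base.copy()
            bumped[i] = min(bumped[i] + rng.uniform(0, 100 - bumped[i]), 100)
            assert mlcps_percent(bumped) >= mlcps_percent(base) - 1e-12

    def test_cyclic_and_reversal_invariance(self, rng):
        v = rng.uniform(0, 100, 5)
        base = mlcps_percent(v)
        for shift in range(1, 5):
            assert mlcps_percent(np.roll(v, shift)) == pytest.approx(base)
        assert mlcps_percent(v[::-1]) == pytest.approx(base)

    def test_not_invariant_under_arbitrary_permutation(self):
        v = [100, 80, 0, 50, 10]
        swapped = [100, 0, 80, 50, 10]   # non-cyclic, non-reversal
        assert mlcps_percent(v) != pytest.approx(mlcps_percent(swapped))

    def test_wrong_arity_rejected(self):
        with pytest.raises(ValueError):
            mlcps_percent([100, 100, 100])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            mlcps_percent([100, 100, 100, 100, 101])


class _ConstantClassifier:
    """Always predicts the positive class."""

    def __init__(self, seed=0):
        pass

    def fit(self, x, y, xv, yv):
        return self

    def score_accuracy(self, x, y):
        return float(np.mean(np.asarray(y) == 1))


class TestPermutationTest:
    def test_constant_classifier_null_is_half(self):
        x = np.zeros((8, 1))
        y = np.tile([1, 0], 4)
        res = permutation_test(lambda seed: _ConstantClassifier(), (x, y),
                               (x, y), (x, y), n_permutations=20, seed=1)
        np.testing.assert_allclose(res.null_accuracies, 0.5)
        assert res.observed_accuracy == 0.5
        assert res.p_value == 1.0

    def test_add_one_p_value(self):
        x = np.zeros((8, 1))
        y = np.tile([1, 0], 4)
        res = permutation_test(lambda seed: _ConstantClassifier(), (x, y),
                               (x, y), (x, y), n_permutations=19, seed=1,
                               observed_accuracy=0.9)
        assert res.p_value == pytest.approx(1 / 20)


def flood_fill_label(mask):
    """Brute-force 6-connected component labeling by BFS."""
    mask = np.asarray(mask, bool)
    seen = np.zeros_like(mask)
    sizes = []
    offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    for start in np.argwhere(mask):
        start = tuple(start)
        if seen[start]:
            continue
        queue = [start]
        seen[start] = True
        size = 0
        while queue:
            cur = queue.pop()
            size += 1
            for off in offsets:
                nb = tuple(np.add(cur, off))
                if all(0 <= nb[i] < mask.shape[i] for i in range(3)) \
                        and mask[nb] and not seen[nb]:
                    seen[nb] = True
                    queue.append(nb)
        sizes.append(size)
    return sizes


class TestBinarizeSegmentation:
    def test_straight_run_of_five_positive(self):
        m = np.zeros((8, 8, 8), bool)
        m[2, 3, 1:6] = True
        assert binarize_segmentation(m) == "positive"

    def test_two_small_components_not_merged(self):
        m = np.zeros((8, 8, 8), bool)
        m[0, 0, 0:4] = True
        m[5, 5, 0:4] = True
        assert binarize_segmentation(m) == "negative"

    def test_diagonal_touch_not_connected_under_face_connectivity(self):
        m = np.zeros((4, 4, 4), bool)
        m[1, 1, 1] = True
        m[2, 2, 1] = True
        assert binarize_segmentation(m, min_voxels=2) == "negative"
        assert binarize_segmentation(m, min_voxels=2, connectivity=26) == "positive"

    def test_empty_negative(self):
        assert binarize_segmentation(np.zeros((4, 4, 4), bool)) == "negative"

    def test_matches_flood_fill_oracle(self, rng):
        for _ in range(200):
            m = rng.random((12, 12, 12)) < rng.uniform(0.02, 0.3)
            sizes = flood_fill_label(m)
            expected = "positive" if sizes and max(sizes) >= 5 else "negative"
            assert binarize_segmentation(m) == expected
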