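import numpy as np
import pytest

from cnvsift import trees
from cnvsift.trees import (
    DecisionTree,
    build_tree,
    entropy,
    information_gain,
    predict_batch,
    predict_tree,
)


class TestEntropy:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ((10, 0), 0.0),
            ((5, 5), 1.0),
            ((3, 1), 0.811278),  # -0.75 log2 0.75 - 0.25 log2 0.25
            ((2, 2, 2, 2), 2.0),
        ],
    )
    def test_values(self, counts, expected):
        assert entropy(counts) == pytest.approx(expected, abs=1e-6)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            entropy((0, 0))


class TestInformationGain:
    def test_perfect_split_of_uniform_parent(self):
        parent = np.array([0] * 5 + [1] * 5)
        assert information_gain(parent, [parent[:5], parent[5:]]) == pytest.approx(1.0)

    def test_proportional_split_gains_nothing(self):
        parent = np.array([0, 0, 1, 1, 0, 0, 1, 1])
        assert information_gain(
            parent, [parent[:4], parent[4:]]
        ) == pytest.approx(0.0)

    def test_hand_computed_partial_split(self):
        # parent (4,4) -> children (3,1)/(1,3): 1 - 0.811278
        parent = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        kids = [np.array([0, 0, 0, 1]), np.array([0, 1, 1, 1])]
        assert information_gain(parent, kids) == pytest.approx(0.188722, abs=1e-6)

    def test_partition_must_cover_parent(self):
        with pytest.raises(ValueError):
            information_gain(np.array([0, 1, 1]), [np.array([0, 1])])


class TestBuildTree:
    def test_perfect_single_feature_gives_depth_one(self):
        X = np.array([[0.1], [0.2], [0.8], [0.9]])
        y = np.array([0, 0, 1, 1])
        t = build_tree(X, y, min_leaf=1)
        assert t.n_nodes == 3  # root + 2 leaves
        pred, _ = predict_batch(t, X)
        np.testing.assert_array_equal(pred, y)
        # threshold at the midpoint of the adjacent distinct values
        assert t.threshold[0] == pytest.approx(0.5)

    def test_constant_features_single_majority_leaf(self):
        X = np.ones((6, 3))
        y = np.array([0, 0, 0, 0, 1, 1])
        t = build_tree(X, y, min_leaf=1)
        assert t.n_nodes == 1
        cls, prob = predict_tree(t, X[0])
        assert cls == 0
        assert prob[0] == pytest.approx(4 / 6)

    def test_xor_needs_depth_two(self):
        # jittered XOR: exact XOR has zero gain for every single split, so
        # the zero-best-IG stopping rule would (correctly) refuse to split
        rng = np.random.default_rng(0)
        X = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]] * 3)
        X = X + rng.normal(0, 0.01, X.shape)
        y = np.array([0, 1, 1, 0] * 3)
        t = build_tree(X, y, min_leaf=1)
        pred, _ = predict_batch(t, X)
        np.testing.assert_array_equal(pred, y)
        # root and at least one child split -> > 1 internal node
        assert (t.feature >= 0).sum() >= 2

    def test_empty_candidate_set_rejected(self):
        with pytest.raises(ValueError):
            build_tree(np.zeros((4, 2)), np.array([0, 0, 1, 1]), candidate_features=[])

    def test_consistent_data_fit_perfectly(self):
        """Unrestricted trees reach training accuracy 1 on consistent data."""
        rng = np.random.default_rng(0)
        for _ in range(5):
            X = rng.standard_normal((60, 4))
            y = (rng.random(60) < 0.5).astype(int)
            t = build_tree(X, y, min_leaf=1)
            pred, _ = predict_batch(t, X)
            assert (pred == y).all()

    def test_split_gain_matches_entropy_difference(self):
        """Recorded IG at every internal node equals the entropy identity."""
        rng = np.random.default_rng(3)
        X = rng.standard_normal((80, 5))
        y = (rng.random(80) < 0.4).astype(int)
        t = build_tree(X, y, min_leaf=2)

        def walk(node, idx):
            if t.feature[node] < 0:
                return
            f, thr = t.feature[node], t.threshold[node]
            lmask = X[idx, f] <= thr
            ig = information_gain(y[idx], [y[idx[lmask]], y[idx[~lmask]]])
            assert ig == pytest.approx(t.gain[node], abs=1e-12)
            walk(t.left[node], idx[lmask])
            walk(t.right[node], idx[~lmask])

        walk(0, np.arange(80))

    def test_min_leaf_respected(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((50, 3))
        y = (rng.random(50) < 0.5).astype(int)
        t = build_tree(X, y, min_leaf=5)
        leaf_sizes = t.counts[t.feature < 0].sum(axis=1)
        assert leaf_sizes.min() >= 5


class TestPredict:
    def test_single_leaf_always_majority(self):
        t = build_tree(np.ones((4, 1)), np.array([1, 1, 1, 0]), min_leaf=1)
        assert predict_tree(t, [123.0])[0] == 1

    def test_value_at_threshold_routes_left(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = np.array([0, 0, 1, 1])
        t = build_tree(X, y, min_leaf=1)
        thr = t.threshold[0]
        cls, _ = predict_tree(t, [thr])
        left_cls = int(np.argmax(t.counts[t.left[0]]))
        assert cls == left_cls

    def test_batch_matches_recursive_oracle(self):
        """Vectorized routing equals an independent recursive walk."""
        rng = np.random.default_rng(9)
        X = rng.standard_normal((100, 6))
        y = (rng.random(100) < 0.5).astype(int)
        t = build_tree(X, y, min_leaf=2)
        Xnew = rng.standard_normal((100, 6))

        def oracle(node, x):
            if t.feature[node] < 0:
                return int(np.argmax(t.counts[node]))
            child = (
                t.left[node]
                if x[t.feature[node]] <= t.threshold[node]
                else t.right[node]
            )
            return oracle(child, x)

        batch, _ = predict_batch(t, Xnew)
        expected = [oracle(0, x) for x in Xnew]
        np.testing.assert_array_equal(batch, expected)

    def test_json_round_trip(self):
        t = build_tree(
            np.array([[0.0], [1.0], [2.0], [3.0]]), np.array([0, 0, 1, 1]), min_leaf=1
        )
        back = DecisionTree.from_json(t.to_json())
        np.testing.assert_array_equal(back.feature, t.feature)
        np.testing.assert_array_equal(back.threshold, t.threshold)


class TestSplitSearchImplementations:
    def test_numpy_and_compiled_agree(self):
        """Reference numpy scan and the compiled scan pick identical splits."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = int(rng.integers(5, 60))
            m = int(rng.integers(1, 8))
            X = np.round(rng.standard_normal((n, m)), 2)  # force ties
            y = (rng.random(n) < 0.5).astype(int)
            if len(np.unique(y)) < 2:
                continue
            a = trees._best_split_numpy(X, y, 2, 2)
            b = trees.best_split(X, y, 2, 2)
            assert a[0] == b[0]
            assert a[2] == pytest.approx(b[2], abs=1e-9)
            if a[0] >= 0:
                assert a[1] == pytest.approx(b[1], abs=1e-12)
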