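"""Information-gain decision trees.

These binary trees are the working parts of both the Monte Carlo feature
selection scoring (which needs per-node information gain, split feature and
node size) and the random forest classifier (which grows them on bootstrap
resamples with per-node random feature subsets).

Conventions, fixed for determinism:

* numeric splits are placed at midpoints between adjacent sorted distinct
  values;
* a sample with ``value <= threshold`` is routed to the left child;
* ties in best information gain are broken by lowest feature index, then
  lowest threshold;
* entropy is Shannon entropy in bits (log base 2).

The split search has two interchangeable implementations: a vectorized
numpy reference and a numba-compiled loop used when numba is importable.
Both return bit-identical results (this is asserted in the test suite).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "DecisionTree",
    "entropy",
    "information_gain",
    "build_tree",
    "predict_tree",
    "predict_batch",
]

_TIE_TOL = 1e-12


def entropy(class_counts) -> float:
    """Shannon entropy (bits) of a frequency table of class counts."""
    counts = np.asarray(class_counts, dtype=np.float64)
    if counts.size == 0 or (counts < 0).any():
        raise ValueError("class counts must be non-negative")
    total = counts.sum()
    if total <= 0:
        raise ValueError("at least one class count must be positive")
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def information_gain(parent_labels, partition: Sequence) -> float:
    """Information gain of splitting *parent_labels* into *partition*.

    *partition* is a sequence of child label arrays that must jointly
    contain exactly the parent's labels (empty cells are ignored). The
    result is parent entropy minus the child-size-weighted mean child
    entropy, which is always >= 0.
    """
    parent = np.asarray(parent_labels)
    children = [np.asarray(c) for c in partition if len(c) > 0]
    n = parent.size
    if sum(c.size for c in children) != n:
        raise ValueError("partition does not cover the parent exactly")
    classes = np.unique(parent)
    parent_counts = np.array([(parent == k).sum() for k in classes])
    child_counts = [np.array([(c == k).sum() for k in classes]) for c in children]
    if any(cc.sum() != c.size for cc, c in zip(child_counts, children)):
        raise ValueError("partition contains labels absent from the parent")
    if sum(int(cc.sum()) for cc in child_counts) != n:
        raise ValueError("partition does not cover the parent exactly")
    h_children = sum(c.size / n * entropy(cc) for cc, c in zip(child_counts, children))
    return float(entropy(parent_counts) - h_children)


# ---------------------------------------------------------------------------
# best-split search
# ---------------------------------------------------------------------------

def _best_split_numpy(X, y, n_classes: int, min_leaf: int):
    """Best (feature column, threshold, gain) by exhaustive midpoint scan.

    Returns ``(-1, nan, 0.0)`` when no valid split exists. Columns are
    scanned in order, so ties resolve to the lowest column index and, within
    a column, the lowest threshold.
    """
    n, m = X.shape
    order = np.argsort(X, axis=0, kind="stable")
    xs = np.take_along_axis(X, order, axis=0)
    ys = y[order]  # (n, m)

    left = np.empty((n - 1, m, n_classes))
    for k in range(n_classes):
        left[:, :, k] = np.cumsum(ys == k, axis=0)[:-1]
    total = np.bincount(y, minlength=n_classes).astype(np.float64)
    right = total[None, None, :] - left

    n_left = np.arange(1, n, dtype=np.float64)[:, None]
    n_right = n - n_left
    with np.errstate(divide="ignore", invalid="ignore"):
        pl = left / n_left[:, :, None]
        pr = right / n_right[:, :, None]
        h_left = -np.where(pl > 0, pl * np.log2(pl), 0.0).sum(axis=2)
        h_right = -np.where(pr > 0, pr * np.log2(pr), 0.0).sum(axis=2)
    h_parent = entropy(total)
    ig = h_parent - (n_left * h_left + n_right * h_right) / n

    valid = xs[:-1] < xs[1:]
    if min_leaf > 1:
        pos = np.arange(1, n)[:, None]
        valid &= (pos >= min_leaf) & (n - pos >= min_leaf)
    ig = np.where(valid, ig, -1.0)

    col_best = ig.max(axis=0)
    gmax = col_best.max()
    if gmax <= 0.0:
        return -1, float("nan"), 0.0
    j = int(np.argmax(col_best >= gmax - _TIE_TOL))
    i = int(np.argmax(ig[:, j] >= col_best[j] - _TIE_TOL))
    thr = 0.5 * (xs[i, j] + xs[i + 1, j])
    return j, float(thr), float(max(ig[i, j], 0.0))


def _best_split_loops(X, y, n_classes, min_leaf):  # pragma: no cover - numba path
    n, m = X.shape
    total = np.zeros(n_classes)
    for i in range(n):
        total[y[i]] += 1.0
    h_parent = 0.0
    for k in range(n_classes):
        if total[k] > 0:
            p = total[k] / n
            h_parent -= p * np.log2(p)
    best_gain = 0.0
    best_j = -1
    best_thr = np.nan
    left = np.zeros(n_classes)
    for j in range(m):
        order = np.argsort(X[:, j], kind="mergesort")
        for k in range(n_classes):
            left[k] = 0.0
        col_best = -1.0
        col_thr = np.nan
        for i in range(n - 1):
            left[y[order[i]]] += 1.0
            nl = i + 1.0
            nr = n - nl
            if X[order[i], j] >= X[order[i + 1], j]:
                continue
            if nl < min_leaf or nr < min_leaf:
                continue
            hl = 0.0
            hr = 0.0
            for k in range(n_classes):
                if left[k] > 0:
                    p = left[k] / nl
                    hl -= p * np.log2(p)
                r = total[k] - left[k]
                if r > 0:
                    p = r / nr
                    hr -= p * np.log2(p)
            gain = h_parent - (nl * hl + nr * hr) / n
            if gain > col_best + _TIE_TOL:
                col_best = gain
                col_thr = 0.5 * (X[order[i], j] + X[order[i + 1], j])
        if col_best > best_gain + _TIE_TOL and col_best > 0.0:
            best_gain = col_best
            best_j = j
            best_thr = col_thr
    if best_j < 0:
        return -1, np.nan, 0.0
    return best_j, best_thr, best_gain


try:  # optional acceleration; the numpy path is the reference
    import numba as _numba

    _best_split_fast = _numba.njit(cache=False)(_best_split_loops)
except Exception:  # pragma: no cover
    _best_split_fast = None


def best_split(X, y, n_classes: int, min_leaf: int = 1, *, use_fast: bool = True):
    """Dispatch to the compiled split search when available."""
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.int64)
    if use_fast and _best_split_fast is not None:
        j, thr, gain = _best_split_fast(X, y, n_classes, min_leaf)
        return int(j), float(thr), float(gain)
    return _best_split_numpy(X, y, n_classes, min_leaf)


# ---------------------------------------------------------------------------
# tree container and induction
# ---------------------------------------------------------------------------

@dataclass
class DecisionTree:
    """Flat-array binary decision tree.

    ``feature[i] == -1`` marks a leaf. ``counts[i]`` is the class frequency
    table of training samples reaching node ``i``; ``gain[i]`` the
    information gain (bits) of the split at internal node ``i``.
    """

    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    counts: np.ndarray
    gain: np.ndarray
    n_classes: int = 2

    @property
    def n_nodes(self) -> int:
        return len(self.feature)

    @property
    def n_samples(self) -> int:
        return int(self.counts[0].sum())

    def internal_nodes(self):
        """Yield (feature, gain, node sample count) over internal nodes."""
        for i in range(self.n_nodes):
            if self.feature[i] >= 0:
                yield int(self.feature[i]), float(self.gain[i]), int(self.counts[i].sum())

    def to_json(self) -> str:
        return json.dumps(
            {
                "feature": self.feature.tolist(),
                "threshold": self.threshold.tolist(),
                "left": self.left.tolist(),
                "right": self.right.tolist(),
                "counts": self.counts.tolist(),
                "gain": self.gain.tolist(),
                "n_classes": self.n_classes,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "DecisionTree":
        d = json.loads(text)
        return cls(
            feature=np.array(d["feature"], dtype=np.int64),
            threshold=np.array(d["threshold"], dtype=np.float64),
            left=np.array(d["left"], dtype=np.int64),
            right=np.array(d["right"], dtype=np.int64),
            counts=np.array(d["counts"], dtype=np.float64),
            gain=np.array(d["gain"], dtype=np.float64),
            n_classes=int(d["n_classes"]),
        )


def build_tree(
    X,
    y,
    candidate_features=None,
    *,
    min_leaf: int = 2,
    max_depth: int | None = None,
    features_per_split: int | None = None,
    rng: np.random.Generator | None = None,
    n_classes: int | None = None,
) -> DecisionTree:
    """Grow a tree by greedy top-down information-gain maximization.

    Parameters
    ----------
    X, y
        Sample-by-feature matrix and integer class labels.
    candidate_features
        Column indices the tree may split on (default: all). Feature indices
        stored in the tree are **global** column indices of ``X``.
    min_leaf
        Minimum samples in each child of a split.
    max_depth
        Optional depth cap (root has depth 0).
    features_per_split
        If given, at every node a fresh random subset of this many candidate
        features is drawn (random-forest style); requires *rng*.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X and y disagree on sample count")
    if len(y) < 2:
        raise ValueError("need at least 2 samples")
    if candidate_features is None:
        candidate_features = np.arange(X.shape[1])
    cand = np.sort(np.asarray(candidate_features, dtype=np.int64))
    if cand.size == 0:
        raise ValueError("candidate feature set is empty")
    if features_per_split is not None and rng is None:
        raise ValueError("features_per_split requires an rng")
    if n_classes is None:
        n_classes = int(y.max()) + 1 if y.size else 2
    n_classes = max(n_classes, 2)

    feature, threshold, left, right, counts, gain = [], [], [], [], [], []

    def new_node(idx):
        i = len(feature)
        feature.append(-1)
        threshold.append(np.nan)
        left.append(-1)
        right.append(-1)
        counts.append(np.bincount(y[idx], minlength=n_classes).astype(np.float64))
        gain.append(0.0)
        return i

    stack = [(new_node(np.arange(len(y))), np.arange(len(y)), 0)]
    while stack:
        node, idx, depth = stack.pop()
        c = counts[node]
        if (
            len(idx) < 2 * min_leaf
            or (c > 0).sum() < 2
            or (max_depth is not None and depth >= max_depth)
        ):
            continue
        if features_per_split is not None and features_per_split < cand.size:
            feats = np.sort(rng.choice(cand, size=features_per_split, replace=False))
        else:
            feats = cand
        j, thr, g = best_split(X[np.ix_(idx, feats)], y[idx], n_classes, min_leaf)
        if j < 0 or g <= 0.0:
            continue
        fglob = int(feats[j])
        feature[node] = fglob
        threshold[node] = thr
        gain[node] = g
        mask = X[idx, fglob] <= thr
        li = new_node(idx[mask])
        ri = new_node(idx[~mask])
        left[node], right[node] = li, ri
        stack.append((ri, idx[~mask], depth + 1))
        stack.append((li, idx[mask], depth + 1))

    return DecisionTree(
        feature=np.array(feature, dtype=np.int64),
        threshold=np.array(threshold, dtype=np.float64),
        left=np.array(left, dtype=np.int64),
        right=np.array(right, dtype=np.int64),
        counts=np.array(counts, dtype=np.float64),
        gain=np.array(gain, dtype=np.float64),
        n_classes=n_classes,
    )


def predict_tree(tree: DecisionTree, vector) -> tuple[int, np.ndarray]:
    """Route one vector to a leaf; return (majority class, class probabilities).

    A value exactly equal to the threshold goes left (the ``<=`` child).
    Probability ties resolve to the lower class index.
    """
    x = np.asarray(vector, dtype=np.float64)
    node = 0
    while tree.feature[node] >= 0:
        f = tree.feature[node]
        if f >= x.size:
            raise ValueError(f"input vector lacks split feature {f}")
        node = tree.left[node] if x[f] <= tree.threshold[node] else tree.right[node]
    c = tree.counts[node]
    prob = c / c.sum()
    return int(np.argmax(prob)), prob


def predict_batch(tree: DecisionTree, X) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized prediction: (majority classes, positive-class probability)."""
    X = np.asarray(X, dtype=np.float64)
    n = len(X)
    node = np.zeros(n, dtype=np.int64)
    active = tree.feature[node] >= 0
    while active.any():
        idx = np.nonzero(active)[0]
        nd = node[idx]
        f = tree.feature[nd]
        goes_left = X[idx, f] <= tree.threshold[nd]
        node[idx] = np.where(goes_left, tree.left[nd], tree.right[nd])
        active = tree.feature[node] >= 0
    c = tree.counts[node]
    prob = c / c.sum(axis=1, keepdims=True)
    return np.argmax(prob, axis=1), prob[:, 1] if tree.n_classes >= 2 else prob[:, 0]
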