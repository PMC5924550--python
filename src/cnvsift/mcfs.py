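"""Monte Carlo feature selection: relative-importance ranking.

The procedure draws ``s`` random feature subsets of size ``m`` (out of
``M`` features); for each subset it grows ``t`` information-gain decision
trees, each on a fresh stratified train/test split of the samples, and
scores the tree by its weighted accuracy (mean per-class recall) on the
held-out split. Every feature then accumulates relative importance

    RI_f = sum over all s*t trees of
           wAcc^u * sum over nodes splitting on f of
                    IG(node) * (node samples / tree samples)^v

so a feature gains weight when it splits often, with high information
gain, near the top of accurate trees. Features never chosen keep RI = 0.
The output is a totally ordered ranked feature list (ties broken by
feature index) that downstream incremental feature selection consumes.

Defaults (the original method's authors only require ``s`` and ``t``
"sufficiently large"): ``m = max(ceil(0.05 M), 10)``, ``t = 5`` and ``s``
chosen so each feature is expected in 15 subsets (``s m / M = 15``),
train fraction 0.66.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import trees
from .dataset import CopyNumberDataset

__all__ = [
    "MCFSParams",
    "RankedFeatureList",
    "TreeRecord",
    "weighted_accuracy",
    "relative_importance",
    "run_mcfs",
]


@dataclass(frozen=True)
class MCFSParams:
    """Protocol parameters; ``m``/``s`` of ``None`` resolve from M."""

    m: int | None = None
    s: int | None = None
    t: int = 5
    u: float = 1.0
    v: float = 1.0
    train_fraction: float = 0.66
    min_leaf: int = 2
    max_depth: int | None = None
    expected_coverage: float = 15.0  # target s*m/M when s is auto
    seed: int = 0

    def __post_init__(self) -> None:
        if self.t < 1:
            raise ValueError("t must be >= 1")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")

    def resolve(self, n_features: int) -> tuple[int, int]:
        """Concrete (m, s) for a dataset with *n_features* features."""
        m = self.m if self.m is not None else max(math.ceil(0.05 * n_features), 10)
        m = min(m, n_features)
        if m < 1:
            raise ValueError("m must be >= 1")
        if self.m is not None and self.m > n_features:
            raise ValueError(f"m={self.m} exceeds the number of features {n_features}")
        s = (
            self.s
            if self.s is not None
            else max(1, math.ceil(self.expected_coverage * n_features / m))
        )
        if s < 1:
            raise ValueError("s must be >= 1")
        return m, s


@dataclass
class RankedFeatureList:
    """Features in descending relative importance; ties by feature index."""

    feature_ids: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if len(self.feature_ids) != len(self.scores):
            raise ValueError("ids/scores length mismatch")
        if (self.scores < 0).any():
            raise ValueError("relative importance must be non-negative")
        if np.any(np.diff(self.scores) > 1e-12):
            raise ValueError("scores must be in descending order")

    def __len__(self) -> int:
        return len(self.feature_ids)

    def top(self, n: int) -> list[str]:
        return self.feature_ids[:n]

    def rank_of(self, feature_id: str) -> int:
        """0-based rank of a feature."""
        return self.feature_ids.index(feature_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self) + 1),
                "feature": self.feature_ids,
                "ri": self.scores,
            }
        )

    @classmethod
    def from_scores(
        cls, feature_ids: Sequence[str], ri: np.ndarray
    ) -> "RankedFeatureList":
        ri = np.asarray(ri, dtype=np.float64)
        order = np.lexsort((np.arange(len(ri)), -ri))
        return cls([feature_ids[i] for i in order], ri[order])


@dataclass
class TreeRecord:
    """What Eq.-style RI accumulation needs from one fitted tree."""

    w_acc: float
    nodes: list[tuple[int, float, int]]  # (feature, IG, node sample count)
    tree_size: int  # samples the tree was grown on


def weighted_accuracy(confusion: np.ndarray) -> float:
    """Mean per-class recall of a c x c confusion count matrix."""
    cm = np.asarray(confusion, dtype=np.float64)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    row_sums = cm.sum(axis=1)
    if (row_sums == 0).any():
        missing = int(np.nonzero(row_sums == 0)[0][0])
        raise ValueError(f"class {missing} is absent from the evaluation set")
    return float(np.mean(np.diag(cm) / row_sums))


def relative_importance(
    tree_records: Iterable[TreeRecord],
    n_features: int,
    u: float = 1.0,
    v: float = 1.0,
) -> np.ndarray:
    """Accumulate per-feature RI over tree records."""
    ri = np.zeros(n_features, dtype=np.float64)
    count = 0
    for rec in tree_records:
        count += 1
        w = rec.w_acc**u
        for feature, ig, node_n in rec.nodes:
            if node_n > rec.tree_size:
                raise ValueError(
                    f"node with {node_n} samples exceeds tree size {rec.tree_size}"
                )
            ri[feature] += w * ig * (node_n / rec.tree_size) ** v
    if count == 0:
        raise ValueError("at least one tree record is required")
    return ri


def _stratified_split(y: np.ndarray, frac: float, rng: np.random.Generator):
    train = np.zeros(len(y), dtype=bool)
    for cls in np.unique(y):
        idx = rng.permutation(np.nonzero(y == cls)[0])
        k = min(max(1, int(round(frac * len(idx)))), len(idx) - 1)
        train[idx[:k]] = True
    return np.nonzero(train)[0], np.nonzero(~train)[0]


def run_mcfs(
    dataset: CopyNumberDataset, params: MCFSParams = MCFSParams()
) -> RankedFeatureList:
    """Rank every probe by relative importance. Deterministic given seed."""
    X, y = dataset.X, dataset.y
    M = dataset.n_probes
    n_classes = int(y.max()) + 1
    m, s = params.resolve(M)
    if s * params.t < 1:
        raise ValueError("s*t must be >= 1")
    rng = np.random.default_rng(params.seed)
    ri = np.zeros(M, dtype=np.float64)
    for _ in range(s):
        feats = np.sort(rng.choice(M, size=m, replace=False))
        for _ in range(params.t):
            train, test = _stratified_split(y, params.train_fraction, rng)
            tree = trees.build_tree(
                X[np.ix_(train, feats)],
                y[train],
                min_leaf=params.min_leaf,
                max_depth=params.max_depth,
                n_classes=n_classes,
            )
            pred, _ = trees.predict_batch(tree, X[np.ix_(test, feats)])
            cm = np.zeros((n_classes, n_classes))
            np.add.at(cm, (y[test], pred), 1)
            rec = TreeRecord(
                w_acc=weighted_accuracy(cm),
                nodes=[(int(feats[f]), g, n) for f, g, n in tree.internal_nodes()],
                tree_size=len(train),
            )
            ri += relative_importance([rec], M, params.u, params.v)
    return RankedFeatureList.from_scores(dataset.probe_ids, ri)
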