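"""Two-stage incremental feature selection over a ranked feature list.

Stage 1 scans prefixes of the ranking at a coarse step (``k`` = 10 by
default) up to ``n_max``, cross-validating a classifier on each prefix and
recording MCC/AUC — the IFS curve. An interval of prefix sizes is then
selected around the best-performing region, and stage 2 rescans it at step
1; the prefix maximizing MCC (ties toward fewer features) is the optimal
feature subset.

The same cross-validation seed is reused at every prefix size so that
neighboring curve points differ only by the features used, not by fold
assignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classifiers import make_estimator
from .dataset import CopyNumberDataset
from .evaluation import cross_validate
from .mcfs import RankedFeatureList

__all__ = [
    "IFSCurve",
    "IFSResult",
    "stage1_scan",
    "select_interval",
    "stage2_scan",
    "optimal_subset",
    "run_ifs",
]


@dataclass
class IFSCurve:
    """Ordered (n_features, mcc, auc) points with strictly increasing n."""

    n_features: np.ndarray
    mcc: np.ndarray
    auc: np.ndarray

    def __post_init__(self) -> None:
        self.n_features = np.asarray(self.n_features, dtype=np.int64)
        self.mcc = np.asarray(self.mcc, dtype=np.float64)
        self.auc = np.asarray(self.auc, dtype=np.float64)
        if not (len(self.n_features) == len(self.mcc) == len(self.auc)):
            raise ValueError("curve arrays disagree in length")
        if len(self.n_features) and (np.diff(self.n_features) <= 0).any():
            raise ValueError("n_features must be strictly increasing")

    def __len__(self) -> int:
        return len(self.n_features)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"n_features": self.n_features, "mcc": self.mcc, "auc": self.auc}
        )


@dataclass
class IFSResult:
    stage1: IFSCurve
    interval: tuple[int, int]
    stage2: IFSCurve
    optimal_n: int
    optimal_features: list[str]
    optimal_mcc: float
    optimal_auc: float

    def to_dict(self) -> dict:
        return {
            "interval": list(self.interval),
            "optimal_n": self.optimal_n,
            "optimal_mcc": self.optimal_mcc,
            "optimal_auc": self.optimal_auc,
            "optimal_features": self.optimal_features,
            "stage1": self.stage1.to_frame().to_dict(orient="list"),
            "stage2": self.stage2.to_frame().to_dict(orient="list"),
        }


def _scan(
    dataset: CopyNumberDataset,
    ranking: RankedFeatureList,
    sizes,
    classifier: str,
    config,
    cv_k: int,
    cv_seed: int,
) -> IFSCurve:
    order = [dataset.probe_index(f) for f in ranking.feature_ids]
    X_ranked = dataset.X[:, order]
    y = dataset.y
    mccs, aucs = [], []
    for n in sizes:
        res = cross_validate(
            X_ranked[:, :n],
            y,
            lambda seed: make_estimator(classifier, config, seed),
            k=cv_k,
            seed=cv_seed,
        )
        mccs.append(res.mcc)
        aucs.append(res.auc)
    return IFSCurve(np.asarray(list(sizes)), np.asarray(mccs), np.asarray(aucs))


def stage1_scan(
    dataset: CopyNumberDataset,
    ranking: RankedFeatureList,
    classifier: str = "rf",
    config=None,
    k: int = 10,
    n_max: int = 5000,
    cv_k: int = 10,
    cv_seed: int = 0,
) -> IFSCurve:
    """Coarse scan at prefix sizes k, 2k, ..., n_max."""
    if k < 1:
        raise ValueError("step k must be >= 1")
    if n_max > len(ranking):
        raise ValueError(
            f"n_max={n_max} exceeds ranking length {len(ranking)}"
        )
    sizes = range(k, n_max + 1, k)
    return _scan(dataset, ranking, sizes, classifier, config, cv_k, cv_seed)


def select_interval(
    curve: IFSCurve, delta: float = 0.05, n_max: int | None = None
) -> tuple[int, int]:
    """Interval of prefix sizes worth a fine rescan.

    Takes the widest contiguous run of stage-1 points whose MCC is within
    *delta* of the maximum, expands it by one (exclusive) step on each
    side, and clips to ``[1, n_max]``.
    """
    if len(curve) == 0:
        raise ValueError("curve is empty")
    if n_max is None:
        n_max = int(curve.n_features[-1])
    good = curve.mcc >= curve.mcc.max() - delta
    best_len, best_run = 0, (0, 0)
    i = 0
    while i < len(good):
        if good[i]:
            j = i
            while j + 1 < len(good) and good[j + 1]:
                j += 1
            if j - i + 1 > best_len:
                best_len, best_run = j - i + 1, (i, j)
            i = j + 1
        else:
            i += 1
    lo_idx, hi_idx = best_run
    ns = curve.n_features
    step = int(ns[1] - ns[0]) if len(ns) > 1 else int(ns[0])
    lo = int(ns[lo_idx]) - step + 1
    hi = int(ns[hi_idx]) + step - 1
    return max(1, lo), min(n_max, hi)


def stage2_scan(
    dataset: CopyNumberDataset,
    ranking: RankedFeatureList,
    interval: tuple[int, int],
    classifier: str = "rf",
    config=None,
    cv_k: int = 10,
    cv_seed: int = 0,
    budget: int = 3000,
) -> IFSCurve:
    """Fine scan of every prefix size in ``[min, max]`` (step 1)."""
    lo, hi = int(interval[0]), int(interval[1])
    if not 1 <= lo <= hi <= len(ranking):
        raise ValueError(f"invalid interval {interval}")
    if hi - lo + 1 > budget:
        raise ValueError(
            f"interval {interval} spans {hi - lo + 1} sizes, over the budget "
            f"of {budget}; raise `budget` to run it anyway"
        )
    sizes = range(lo, hi + 1)
    return _scan(dataset, ranking, sizes, classifier, config, cv_k, cv_seed)


def optimal_subset(
    stage1: IFSCurve,
    stage2: IFSCurve,
    ranking: RankedFeatureList,
    interval: tuple[int, int],
) -> IFSResult:
    """Pick the stage-2 argmax MCC (ties toward fewer features)."""
    if len(stage2) == 0:
        raise ValueError("stage-2 curve is empty")
    best = int(np.argmax(stage2.mcc))  # argmax returns the first (smallest n) max
    n_opt = int(stage2.n_features[best])
    return IFSResult(
        stage1=stage1,
        interval=(int(interval[0]), int(interval[1])),
        stage2=stage2,
        optimal_n=n_opt,
        optimal_features=ranking.top(n_opt),
        optimal_mcc=float(stage2.mcc[best]),
        optimal_auc=float(stage2.auc[best]),
    )


def run_ifs(
    dataset: CopyNumberDataset,
    ranking: RankedFeatureList,
    classifier: str = "rf",
    config=None,
    k: int = 10,
    n_max: int = 5000,
    delta: float = 0.05,
    cv_k: int = 10,
    cv_seed: int = 0,
    budget: int = 3000,
) -> IFSResult:
    """Full two-stage IFS: coarse scan, interval, fine scan, optimum."""
    stage1 = stage1_scan(
        dataset, ranking, classifier, config, k=k, n_max=n_max, cv_k=cv_k, cv_seed=cv_seed
    )
    interval = select_interval(stage1, delta=delta, n_max=n_max)
    stage2 = stage2_scan(
        dataset, ranking, interval, classifier, config,
        cv_k=cv_k, cv_seed=cv_seed, budget=budget,
    )
    return optimal_subset(stage1, stage2, ranking, interval)
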