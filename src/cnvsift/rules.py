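"""Human-readable IF-THEN threshold rules from ranked copy-number features.

Two classical components cooperate here:

* the **Johnson reducer** — a greedy rough-set heuristic that picks a small
  feature subset (a reduct) covering the discernibility structure of the
  data: repeatedly take the feature that discerns the most not-yet-discerned
  case/control sample pairs;
* a **RIPPER-style rule learner** (IREP with MDL stopping and optimization
  passes) that produces an ordered list of threshold rules for the target
  class, with a default class for "other conditions".

Rules operate on raw continuous log2 ratios (conditions are ``<=`` / ``>=``
threshold tests); discretization is only used internally by the reducer.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import gammaln
from scipy.stats import norm

from .dataset import CopyNumberDataset
from . import trees
from .evaluation import ConfusionCounts, mcc as _mcc

__all__ = [
    "Condition",
    "Rule",
    "RuleSet",
    "RipperParams",
    "RuleEvaluation",
    "select_informative",
    "johnson_reduce",
    "ripper",
    "evaluate_rules",
    "odds_ratio_ci",
]

_LN2 = math.log(2.0)


@dataclass(frozen=True)
class Condition:
    """A single threshold test ``feature <op> cut`` with op in {<=, >=}."""

    feature: str
    op: str
    cut: float

    def __post_init__(self) -> None:
        if self.op not in ("<=", ">="):
            raise ValueError(f"operator must be '<=' or '>=', got {self.op!r}")

    def holds(self, x: np.ndarray) -> np.ndarray:
        return x <= self.cut if self.op == "<=" else x >= self.cut

    def __str__(self) -> str:
        return f"{self.feature} {self.op} {self.cut:.6g}"


@dataclass
class Rule:
    """Ordered conjunction of conditions with a predicted class.

    Per feature a rule keeps at most one ``<=`` and one ``>=`` condition
    (an interval); this is enforced at construction by tightening.
    """

    conditions: list[Condition]
    predicted: int

    def __post_init__(self) -> None:
        merged: dict[tuple[str, str], Condition] = {}
        for c in self.conditions:
            key = (c.feature, c.op)
            if key in merged:
                old = merged[key]
                cut = min(old.cut, c.cut) if c.op == "<=" else max(old.cut, c.cut)
                merged[key] = Condition(c.feature, c.op, cut)
            else:
                merged[key] = c
        self.conditions = list(merged.values())

    def covers(self, X: np.ndarray, feature_index: dict[str, int]) -> np.ndarray:
        mask = np.ones(len(X), dtype=bool)
        for c in self.conditions:
            mask &= c.holds(X[:, feature_index[c.feature]])
        return mask

    def __str__(self) -> str:
        body = " AND ".join(str(c) for c in self.conditions) or "TRUE"
        return f"IF {body} THEN class={self.predicted}"


@dataclass
class RuleSet:
    """Ordered decision list: first matching rule wins, else the default."""

    rules: list[Rule]
    default: int

    def apply(self, X: np.ndarray, feature_ids: Sequence[str]) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        index = {f: i for i, f in enumerate(feature_ids)}
        out = np.full(len(X), -1, dtype=np.int64)
        for rule in self.rules:
            mask = rule.covers(X, index) & (out < 0)
            out[mask] = rule.predicted
        out[out < 0] = self.default
        return out

    def apply_dataset(self, dataset: CopyNumberDataset) -> np.ndarray:
        return self.apply(dataset.X, dataset.probe_ids)

    def to_json(self) -> str:
        return json.dumps(
            {
                "rules": [
                    {
                        "conditions": [
                            {"feature": c.feature, "op": c.op, "cut": c.cut}
                            for c in r.conditions
                        ],
                        "predicted": r.predicted,
                    }
                    for r in self.rules
                ],
                "default": self.default,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "RuleSet":
        d = json.loads(text)
        return cls(
            rules=[
                Rule(
                    [Condition(c["feature"], c["op"], c["cut"]) for c in r["conditions"]],
                    r["predicted"],
                )
                for r in d["rules"]
            ],
            default=int(d["default"]),
        )

    def to_text(self) -> str:
        lines = []
        for i, r in enumerate(self.rules, 1):
            cls_name = "case" if r.predicted == 1 else "control"
            for j, c in enumerate(r.conditions):
                head = f"Rule {i} ({cls_name})" if j == 0 else " " * (len(f"Rule {i} ({cls_name})"))
                lines.append(f"{head}\t{c.feature}\t{c.op} {c.cut:.6g}")
        default_name = "case" if self.default == 1 else "control"
        lines.append(f"Default ({default_name})\tOther conditions\t")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# feature selection helpers
# ---------------------------------------------------------------------------

def select_informative(ranking, p: float) -> list[str]:
    """Top ``ceil(p/100 * M)`` features from a ranked feature list."""
    if not 0 < p <= 100:
        raise ValueError("p must lie in (0, 100]")
    ids = list(getattr(ranking, "feature_ids", ranking))
    k = math.ceil(p / 100.0 * len(ids))
    return ids[:k]


def _discretize_binary(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Entropy-best binary cut of one feature; constant features -> one bin."""
    j, thr, gain = trees.best_split(x[:, None], y, int(y.max()) + 1, min_leaf=1)
    if j < 0:
        return np.zeros(len(x), dtype=np.int8)
    return (x > thr).astype(np.int8)


def johnson_reduce(dataset: CopyNumberDataset) -> list[str]:
    """Greedy discernibility set cover over entropy-discretized features.

    Repeatedly picks the feature discerning the most not-yet-discerned
    case/control pairs (ties: lowest feature index) until every discernible
    pair is covered. The result is a single reduct, not guaranteed minimal.
    """
    X, y = dataset.X, dataset.y
    pos = np.nonzero(y == 1)[0]
    neg = np.nonzero(y == 0)[0]
    n_feat = dataset.n_probes
    bins = np.stack(
        [_discretize_binary(X[:, f], y) for f in range(n_feat)], axis=1
    )  # (n_samples, n_feat)
    # discern[f] flattened over case x control pairs
    discern = np.empty((n_feat, len(pos) * len(neg)), dtype=bool)
    for f in range(n_feat):
        discern[f] = (bins[pos, f][:, None] != bins[neg, f][None, :]).ravel()
    discernible = discern.any(axis=0)
    if not discernible.any():
        raise ValueError("no feature discerns any case/control pair")
    uncovered = discernible.copy()
    reduct: list[str] = []
    chosen = np.zeros(n_feat, dtype=bool)
    while uncovered.any():
        counts = discern[:, uncovered].sum(axis=1)
        counts[chosen] = -1
        f = int(np.argmax(counts))
        if counts[f] <= 0:
            break
        chosen[f] = True
        reduct.append(dataset.probe_ids[f])
        uncovered &= ~discern[f]
    return reduct


# ---------------------------------------------------------------------------
# RIPPER
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RipperParams:
    optimization_passes: int = 2
    min_coverage: int = 1
    dl_allowance: float = 64.0
    grow_fraction: float = 2.0 / 3.0
    target_class: int | None = None  # default: minority class (ties -> case)
    seed: int = 0


def _log2_choose(n: int, k: int) -> float:
    if k < 0 or k > n:
        return 0.0
    return (gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)) / _LN2


def _exception_bits(cov: int, fp: int, uncov: int, fn: int) -> float:
    return (
        math.log2(cov + 1)
        + _log2_choose(cov, fp)
        + math.log2(uncov + 1)
        + _log2_choose(uncov, fn)
    )


def _ruleset_dl(
    rules: list[dict], X, y, target: int, feature_index, n_possible: float
) -> float:
    """Total description length (bits): theory + exceptions on (X, y)."""
    theory = 0.0
    covered = np.zeros(len(X), dtype=bool)
    for r in rules:
        k = len(r)
        theory += 0.5 * k * (math.log2(max(n_possible, 2.0)) + 1.0)
        covered |= _covers(r, X, feature_index)
    cov = int(covered.sum())
    uncov = len(X) - cov
    fp = int((y[covered] != target).sum())
    fn = int((y[~covered] == target).sum())
    return theory + _exception_bits(cov, fp, uncov, fn)


def _covers(rule: dict, X, feature_index) -> np.ndarray:
    mask = np.ones(len(X), dtype=bool)
    for (f, op), cut in rule.items():
        col = X[:, feature_index[f]]
        mask &= col <= cut if op == "<=" else col >= cut
    return mask


def _foil_grow(
    X, y, target: int, feature_ids, feature_index, min_coverage: int
) -> dict:
    """Greedily grow one rule maximizing FOIL information gain."""
    rule: dict[tuple[str, str], float] = {}
    mask = np.ones(len(X), dtype=bool)
    while True:
        p0 = int((y[mask] == target).sum())
        n0 = int((y[mask] != target).sum())
        if p0 == 0 or n0 == 0:
            break
        base = math.log2(p0 / (p0 + n0))
        best_gain = 0.0
        best = None
        for f in feature_ids:
            col = X[:, feature_index[f]]
            vals = np.unique(col[mask])
            if len(vals) < 2:
                continue
            cuts = 0.5 * (vals[:-1] + vals[1:])
            for op in ("<=", ">="):
                for cut in cuts:
                    sel = mask & (col <= cut if op == "<=" else col >= cut)
                    p1 = int((y[sel] == target).sum())
                    if p1 == 0 or p1 + (sel.sum() - p1) < min_coverage:
                        continue
                    n1 = int(sel.sum()) - p1
                    gain = p1 * (math.log2(p1 / (p1 + n1)) - base)
                    if gain > best_gain + 1e-12:
                        best_gain = gain
                        best = (f, op, float(cut))
        if best is None:
            break
        f, op, cut = best
        key = (f, op)
        if key in rule:
            rule[key] = min(rule[key], cut) if op == "<=" else max(rule[key], cut)
        else:
            rule[key] = cut
        col = X[:, feature_index[f]]
        mask &= col <= rule[key] if op == "<=" else col >= rule[key]
    return rule


def _prune_rule(rule: dict, X, y, target: int, feature_index) -> dict:
    """Drop trailing conditions to maximize (p - n) / (p + n) on prune data."""
    if not rule:
        return rule
    items = list(rule.items())

    def value(upto: int) -> float:
        sub = dict(items[:upto])
        mask = _covers(sub, X, feature_index)
        tot = int(mask.sum())
        if tot == 0:
            return -1.0
        p = int((y[mask] == target).sum())
        return (2.0 * p - tot) / tot

    best_k = len(items)
    best_v = value(best_k)
    for k in range(len(items) - 1, 0, -1):
        v = value(k)
        if v > best_v + 1e-12:
            best_v = v
            best_k = k
    return dict(items[:best_k])


def _simplify_by_dl(
    rules: list[dict], X, y, target, feature_index, n_possible
) -> list[dict]:
    """Delete rules (last to first) whose removal reduces the total DL.

    This is the standard final MDL simplification; it is what discards
    rules that only fit sampling noise.
    """
    rules = list(rules)
    changed = True
    while changed:
        changed = False
        for i in range(len(rules) - 1, -1, -1):
            with_rule = _ruleset_dl(rules, X, y, target, feature_index, n_possible)
            without = _ruleset_dl(
                rules[:i] + rules[i + 1 :], X, y, target, feature_index, n_possible
            )
            if without <= with_rule:
                del rules[i]
                changed = True
    return rules


def _grow_prune_split(y, target, grow_fraction, rng):
    """Stratified grow/prune split indices."""
    n = len(y)
    grow = np.zeros(n, dtype=bool)
    for cls in np.unique(y):
        idx = np.nonzero(y == cls)[0]
        idx = rng.permutation(idx)
        k = max(1, int(round(grow_fraction * len(idx))))
        grow[idx[:k]] = True
    return grow


def ripper(
    dataset: CopyNumberDataset, params: RipperParams = RipperParams()
) -> RuleSet:
    """Learn an ordered threshold-rule list for the target class.

    IREP loop: split the remaining data 2:1 into grow/prune sets, grow a
    rule by FOIL gain, prune it by (p-n)/(p+n), and stop adding rules when
    the pruned rule's precision on the prune set drops to 1/2 or the total
    description length exceeds the best seen by ``dl_allowance`` bits.
    The configured optimization passes then revisit each rule with
    replacement and revision candidates, keeping the variant with the
    smallest description length. Uncovered samples get the default class.
    """
    X, y = dataset.X, dataset.y
    feature_ids = list(dataset.probe_ids)
    feature_index = {f: i for i, f in enumerate(feature_ids)}
    rng = np.random.default_rng(params.seed)

    counts = np.bincount(y, minlength=2)
    if params.target_class is not None:
        target = int(params.target_class)
    else:
        target = 1 if counts[1] <= counts[0] else 0
    default = 1 - target
    n_possible = 2.0 * sum(
        max(len(np.unique(X[:, feature_index[f]])) - 1, 1) for f in feature_ids
    )

    rules: list[dict] = []
    remaining = np.ones(len(y), dtype=bool)
    best_dl = _ruleset_dl([], X, y, target, feature_index, n_possible)

    while (y[remaining] == target).any():
        idx = np.nonzero(remaining)[0]
        ysub = y[idx]
        if len(np.unique(ysub)) < 2:
            break
        grow_mask = _grow_prune_split(ysub, target, params.grow_fraction, rng)
        Xg, yg = X[idx[grow_mask]], ysub[grow_mask]
        Xp, yp = X[idx[~grow_mask]], ysub[~grow_mask]
        if (yg == target).sum() == 0:
            break
        rule = _foil_grow(Xg, yg, target, feature_ids, feature_index, params.min_coverage)
        if not rule:
            break
        if len(yp):
            rule = _prune_rule(rule, Xp, yp, target, feature_index)
        # precision check on the prune set
        if len(yp):
            mask_p = _covers(rule, Xp, feature_index)
            if mask_p.any():
                p = int((yp[mask_p] == target).sum())
                if 2 * p <= int(mask_p.sum()):
                    break
            else:
                break
        dl = _ruleset_dl(rules + [rule], X, y, target, feature_index, n_possible)
        if dl > best_dl + params.dl_allowance:
            break
        rules.append(rule)
        best_dl = min(best_dl, dl)
        remaining &= ~_covers(rule, X, feature_index)

    # optimization passes: replacement / revision per rule, judged by DL
    for _ in range(params.optimization_passes):
        for i in range(len(rules)):
            others = rules[:i] + rules[i + 1 :]
            covered_by_others = np.zeros(len(y), dtype=bool)
            for r in others:
                covered_by_others |= _covers(r, X, feature_index)
            free = ~covered_by_others
            idx = np.nonzero(free)[0]
            candidates = [rules[i]]
            if len(idx) >= 2 and len(np.unique(y[idx])) == 2:
                ysub = y[idx]
                grow_mask = _grow_prune_split(ysub, target, params.grow_fraction, rng)
                Xg, yg = X[idx[grow_mask]], ysub[grow_mask]
                Xp, yp = X[idx[~grow_mask]], ysub[~grow_mask]
                if (yg == target).any() and (yg != target).any():
                    repl = _foil_grow(
                        Xg, yg, target, feature_ids, feature_index, params.min_coverage
                    )
                    if repl and len(yp):
                        repl = _prune_rule(repl, Xp, yp, target, feature_index)
                    if repl:
                        candidates.append(repl)
            best_rule = min(
                candidates,
                key=lambda r: _ruleset_dl(
                    rules[:i] + [r] + rules[i + 1 :],
                    X, y, target, feature_index, n_possible,
                ),
            )
            rules[i] = best_rule

    rules = _simplify_by_dl(rules, X, y, target, feature_index, n_possible)

    out_rules = [
        Rule([Condition(f, op, cut) for (f, op), cut in r.items()], predicted=target)
        for r in rules
    ]
    return RuleSet(rules=out_rules, default=default)


# ---------------------------------------------------------------------------
# rule evaluation
# ---------------------------------------------------------------------------

@dataclass
class RuleEvaluation:
    counts: ConfusionCounts
    mcc: float
    odds_ratio: float
    ci95: tuple[float, float]
    p_value: float
    continuity_corrected: bool

    def to_json(self) -> str:
        return json.dumps(
            {
                "TP": self.counts.tp,
                "TN": self.counts.tn,
                "FP": self.counts.fp,
                "FN": self.counts.fn,
                "mcc": self.mcc,
                "odds_ratio": self.odds_ratio,
                "ci95": list(self.ci95),
                "p_value": self.p_value,
                "continuity_corrected": self.continuity_corrected,
            }
        )


def odds_ratio_ci(
    tp: int, fp: int, fn: int, tn: int
) -> tuple[float, tuple[float, float], float, bool]:
    """Odds ratio with 95% CI (log-OR normal approximation) and z-test p.

    Any zero cell triggers the Haldane-Anscombe 0.5 continuity correction
    (applied to all four cells), reported via the returned flag.
    """
    cells = [tp, fp, fn, tn]
    corrected = any(c == 0 for c in cells)
    a, b, c, d = ((x + 0.5) for x in cells) if corrected else cells
    or_ = (a * d) / (b * c)
    se = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    lo = math.exp(math.log(or_) - 1.96 * se)
    hi = math.exp(math.log(or_) + 1.96 * se)
    z = math.log(or_) / se
    p = 2.0 * float(norm.sf(abs(z)))
    return or_, (lo, hi), p, corrected


def evaluate_rules(ruleset: RuleSet, dataset: CopyNumberDataset) -> RuleEvaluation:
    """Apply the rule list and report MCC plus the 2x2 odds-ratio statistics."""
    pred = ruleset.apply_dataset(dataset)
    y = dataset.y
    counts = ConfusionCounts(
        tp=int(((pred == 1) & (y == 1)).sum()),
        tn=int(((pred == 0) & (y == 0)).sum()),
        fp=int(((pred == 1) & (y == 0)).sum()),
        fn=int(((pred == 0) & (y == 1)).sum()),
    )
    or_, ci, p, corrected = odds_ratio_ci(counts.tp, counts.fp, counts.fn, counts.tn)
    return RuleEvaluation(
        counts=counts,
        mcc=_mcc(counts),
        odds_ratio=or_,
        ci95=ci,
        p_value=p,
        continuity_corrected=corrected,
    )
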