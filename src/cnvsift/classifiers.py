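"""Self-normalizing feed-forward network and random forest classifiers.

The self-normalizing network (SNN) relies on three ingredients:

* the **SELU** activation ``selu(x) = lambda * (x if x > 0 else
  alpha*(exp(x) - 1))`` with the scale/saturation pair (lambda, alpha)
  chosen so that for standard-normal pre-activations the activations have
  mean 0 and variance 1 — :func:`solve_selu_fixed_point` recovers that pair
  (lambda = 1.0507, alpha = 1.6733) from the two moment equations;
* LeCun-style weight initialization, Gaussian with mean 0 and variance
  ``1/fan_in``, biases 0, so unit-variance inputs yield approximately
  standard-normal pre-activations;
* **alpha dropout**, which replaces dropped units by the most negative
  SELU value ``-lambda*alpha`` and applies an affine correction restoring
  the first two moments in expectation.

The network here is a plain numpy implementation (three SELU hidden
layers of 200 units by default, logistic output head, cross-entropy loss,
SGD with momentum, optional early stopping on a stratified validation
split). Inputs are standardized per feature with training-set statistics
inside ``fit`` — the self-normalizing fixed point assumes unit-variance
inputs.

The random forest grows information-gain trees (:mod:`cnvsift.trees`) on
bootstrap resamples with a fresh random feature subset at every node and
predicts by majority vote; the score is the fraction of trees voting
positive, with ties broken toward the negative class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.stats import norm

from . import trees

__all__ = [
    "SeluParams",
    "SELU_LAMBDA",
    "SELU_ALPHA",
    "selu",
    "selu_moments",
    "solve_selu_fixed_point",
    "init_weights",
    "alpha_dropout",
    "SNNConfig",
    "SNNClassifier",
    "RFConfig",
    "RandomForestClassifier",
    "make_estimator",
]


@dataclass(frozen=True)
class SeluParams:
    """SELU scale (lambda) and negative-branch saturation (alpha)."""

    lam: float
    alpha: float

    def __post_init__(self) -> None:
        if self.lam <= 1.0 or self.alpha <= 0.0:
            raise ValueError("self-normalizing regime needs lambda > 1, alpha > 0")


#: Fixed-point constants for zero-mean / unit-variance activations.
SELU_LAMBDA = 1.0507009873554805
SELU_ALPHA = 1.6732632423543772

_DEFAULT_PARAMS = SeluParams(SELU_LAMBDA, SELU_ALPHA)


def selu(x, params: SeluParams = _DEFAULT_PARAMS):
    """Scaled exponential linear unit, continuous at 0."""
    x = np.asarray(x, dtype=np.float64)
    # expm1 only on the non-positive branch to avoid overflow warnings
    out = params.lam * np.where(x > 0, x, params.alpha * np.expm1(np.minimum(x, 0.0)))
    return out if out.ndim else float(out)


def selu_moments(lam: float, alpha: float) -> tuple[float, float]:
    """(E[selu(Z)], E[selu(Z)^2]) for Z ~ N(0,1), in closed form.

    Uses E[Z 1{Z>0}] = 1/sqrt(2 pi), E[Z^2 1{Z>0}] = 1/2,
    E[e^Z 1{Z<=0}] = sqrt(e) Phi(-1) and E[e^{2Z} 1{Z<=0}] = e^2 Phi(-2).
    """
    phi_m1 = float(norm.cdf(-1.0))
    phi_m2 = float(norm.cdf(-2.0))
    m1 = lam * (
        1.0 / math.sqrt(2.0 * math.pi)
        + alpha * (math.sqrt(math.e) * phi_m1 - 0.5)
    )
    m2 = lam**2 * (
        0.5
        + alpha**2
        * (math.e**2 * phi_m2 - 2.0 * math.sqrt(math.e) * phi_m1 + 0.5)
    )
    return m1, m2


def solve_selu_fixed_point(
    target_mean: float = 0.0, target_variance: float = 1.0
) -> SeluParams:
    """Solve E[selu(Z)] = 0, E[selu(Z)^2] = 1 for (lambda, alpha).

    Two-dimensional root finding on the closed-form moment equations;
    residuals are checked to be below 1e-9. Only the (0, 1) fixed point is
    supported — it is the self-normalizing regime.
    """
    if (target_mean, target_variance) != (0.0, 1.0):
        raise ValueError("only the (mean=0, variance=1) fixed point is supported")

    def residuals(v):
        m1, m2 = selu_moments(v[0], v[1])
        return [m1 - target_mean, m2 - target_variance]

    sol = optimize.root(residuals, x0=[1.0, 2.0], tol=1e-13)
    res = residuals(sol.x)
    if not sol.success or max(abs(r) for r in res) > 1e-9:
        raise RuntimeError(f"fixed-point solve did not converge: residuals {res}")
    return SeluParams(float(sol.x[0]), float(sol.x[1]))


def init_weights(
    n_inputs: int, n_outputs: int, rng: np.random.Generator
) -> np.ndarray:
    """LeCun Gaussian initialization: mean 0, variance 1/n_inputs."""
    if n_inputs < 1:
        raise ValueError("n_inputs must be >= 1")
    return rng.normal(0.0, math.sqrt(1.0 / n_inputs), size=(n_inputs, n_outputs))


def alpha_dropout(
    activations,
    rate: float,
    params: SeluParams = _DEFAULT_PARAMS,
    rng: np.random.Generator | None = None,
    training: bool = True,
):
    """Alpha dropout preserving the (0, 1) activation moments.

    In training mode each unit is set to ``-alpha*lambda`` with probability
    *rate*, then the affine map ``a*x + b`` with

        a = (q + ap^2 * p * q)^(-1/2),   b = -a * p * ap,   ap = -alpha*lambda

    (q = 1 - rate) restores mean 0 / variance 1 in expectation. In
    inference mode the transform is the identity.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("dropout rate must lie in [0, 1)")
    x = np.asarray(activations, dtype=np.float64)
    if not training or rate == 0.0:
        return x
    if rng is None:
        raise ValueError("training-mode alpha dropout requires an rng")
    out, _ = _alpha_dropout_with_mask(x, rate, params, rng)
    return out


def _alpha_dropout_coeffs(rate: float, params: SeluParams) -> tuple[float, float, float]:
    ap = -params.alpha * params.lam
    q = 1.0 - rate
    a = 1.0 / math.sqrt(q + ap**2 * rate * q)
    b = -a * rate * ap
    return ap, a, b


def _alpha_dropout_with_mask(x, rate, params, rng):
    ap, a, b = _alpha_dropout_coeffs(rate, params)
    keep = rng.random(x.shape) >= rate
    dropped = np.where(keep, x, ap)
    # d(out)/d(x) = a * keep
    return a * dropped + b, a * keep


# ---------------------------------------------------------------------------
# SNN
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SNNConfig:
    hidden_layers: int = 3
    hidden_width: int = 200
    dropout_rate: float = 0.05
    epochs: int = 200
    batch_size: int = 32
    learning_rate: float = 0.01
    momentum: float = 0.9
    early_stopping: bool = True
    validation_fraction: float = 0.1
    patience: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.hidden_layers < 1 or self.hidden_width < 1:
            raise ValueError("need at least one hidden unit")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class SNNClassifier:
    """Self-normalizing feed-forward binary classifier (pure numpy)."""

    def __init__(self, config: SNNConfig = SNNConfig()):
        self.config = config
        self.params = _DEFAULT_PARAMS
        self._W: list[np.ndarray] | None = None
        self._b: list[np.ndarray] | None = None
        self._mu: np.ndarray | None = None
        self._sd: np.ndarray | None = None

    # forward helpers ---------------------------------------------------
    def _forward(self, X, rng=None, training=False):
        cfg = self.config
        acts = [X]
        pre = []
        drop_grads = []
        h = X
        for layer in range(cfg.hidden_layers):
            z = h @ self._W[layer] + self._b[layer]
            pre.append(z)
            h = selu(z, self.params)
            if training and cfg.dropout_rate > 0:
                h, dgrad = _alpha_dropout_with_mask(
                    h, cfg.dropout_rate, self.params, rng
                )
            else:
                dgrad = None
            drop_grads.append(dgrad)
            acts.append(h)
        logits = (h @ self._W[-1] + self._b[-1]).ravel()
        return logits, acts, pre, drop_grads

    def fit(self, X, y):
        cfg = self.config
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.int64)
        if len(np.unique(y)) < 2:
            raise ValueError("training set must contain both classes")
        rng = np.random.default_rng(cfg.seed)

        self._mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        self._sd = sd
        Xs = (X - self._mu) / self._sd

        # stratified validation split for early stopping
        if cfg.early_stopping and cfg.validation_fraction > 0:
            val = np.zeros(len(y), dtype=bool)
            for cls in (0, 1):
                idx = rng.permutation(np.nonzero(y == cls)[0])
                k = max(1, int(round(cfg.validation_fraction * len(idx))))
                if len(idx) - k >= 1:
                    val[idx[:k]] = True
            if val.all() or (~val).sum() < 2 or len(np.unique(y[~val])) < 2:
                val[:] = False
        else:
            val = np.zeros(len(y), dtype=bool)
        Xtr, ytr = Xs[~val], y[~val]
        Xval, yval = Xs[val], y[val]

        dims = [X.shape[1]] + [cfg.hidden_width] * cfg.hidden_layers + [1]
        self._W = [init_weights(dims[i], dims[i + 1], rng) for i in range(len(dims) - 1)]
        self._b = [np.zeros(dims[i + 1]) for i in range(len(dims) - 1)]
        vW = [np.zeros_like(w) for w in self._W]
        vb = [np.zeros_like(b) for b in self._b]

        best_loss = np.inf
        best_state = None
        since_best = 0
        n = len(ytr)
        for epoch in range(cfg.epochs):
            order = rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                batch = order[start : start + cfg.batch_size]
                xb, yb = Xtr[batch], ytr[batch]
                logits, acts, pre, dgrads = self._forward(
                    xb, rng=rng, training=True
                )
                prob = _sigmoid(logits)
                delta = (prob - yb)[:, None] / len(yb)
                grads_W = [None] * len(self._W)
                grads_b = [None] * len(self._b)
                grads_W[-1] = acts[-1].T @ delta
                grads_b[-1] = delta.sum(axis=0)
                back = delta @ self._W[-1].T
                for layer in range(cfg.hidden_layers - 1, -1, -1):
                    if dgrads[layer] is not None:
                        back = back * dgrads[layer]
                    z = pre[layer]
                    dselu = np.where(
                        z > 0,
                        self.params.lam,
                        self.params.lam * self.params.alpha * np.exp(np.minimum(z, 0.0)),
                    )
                    back = back * dselu
                    grads_W[layer] = acts[layer].T @ back
                    grads_b[layer] = back.sum(axis=0)
                    if layer > 0:
                        back = back @ self._W[layer].T
                for i in range(len(self._W)):
                    vW[i] = cfg.momentum * vW[i] - cfg.learning_rate * grads_W[i]
                    vb[i] = cfg.momentum * vb[i] - cfg.learning_rate * grads_b[i]
                    self._W[i] += vW[i]
                    self._b[i] += vb[i]
            if len(yval):
                logits, *_ = self._forward(Xval)
                # numerically stable BCE-with-logits
                loss = float(
                    np.mean(np.maximum(logits, 0) - logits * yval + np.log1p(np.exp(-np.abs(logits))))
                )
                if loss < best_loss - 1e-6:
                    best_loss = loss
                    best_state = (
                        [w.copy() for w in self._W],
                        [b.copy() for b in self._b],
                    )
                    since_best = 0
                else:
                    since_best += 1
                    if since_best >= cfg.patience:
                        break
        if best_state is not None:
            self._W, self._b = best_state
        return self

    def predict_scores(self, X) -> np.ndarray:
        if self._W is None:
            raise RuntimeError("classifier is not fitted")
        Xs = (np.asarray(X, dtype=np.float64) - self._mu) / self._sd
        logits, *_ = self._forward(Xs)
        return _sigmoid(logits)

    def predict(self, X) -> np.ndarray:
        return (self.predict_scores(X) > 0.5).astype(np.int64)


# ---------------------------------------------------------------------------
# random forest
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RFConfig:
    n_trees: int = 100
    features_per_split: int | None = None  # default floor(log2(M) + 1)
    sample_size: int | None = None  # default: training-set size
    min_leaf: int = 1
    max_depth: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


class RandomForestClassifier:
    """Bagged information-gain trees with per-node random feature subsets."""

    def __init__(self, config: RFConfig = RFConfig()):
        self.config = config
        self.trees_: list[trees.DecisionTree] = []

    def fit(self, X, y):
        cfg = self.config
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.int64)
        if len(np.unique(y)) < 2:
            raise ValueError("training set must contain both classes")
        rng = np.random.default_rng(cfg.seed)
        n, m = X.shape
        k = cfg.features_per_split or max(1, int(math.floor(math.log2(m) + 1)))
        k = min(k, m)
        size = cfg.sample_size or n
        self.trees_ = []
        for _ in range(cfg.n_trees):
            idx = rng.integers(0, n, size=size)
            if len(np.unique(y[idx])) < 2:  # degenerate bootstrap; redraw once
                idx = rng.integers(0, n, size=size)
                if len(np.unique(y[idx])) < 2:
                    continue
            tree = trees.build_tree(
                X[idx],
                y[idx],
                min_leaf=cfg.min_leaf,
                max_depth=cfg.max_depth,
                features_per_split=k if k < m else None,
                rng=rng,
                n_classes=2,
            )
            self.trees_.append(tree)
        if not self.trees_:
            raise RuntimeError("no valid bootstrap resample contained both classes")
        return self

    def predict_scores(self, X) -> np.ndarray:
        """Fraction of trees voting for the positive class."""
        if not self.trees_:
            raise RuntimeError("classifier is not fitted")
        X = np.asarray(X, dtype=np.float64)
        votes = np.zeros(len(X))
        for tree in self.trees_:
            labels, _ = trees.predict_batch(tree, X)
            votes += labels == 1
        return votes / len(self.trees_)

    def predict(self, X) -> np.ndarray:
        # strict majority; a tied vote goes to the negative class
        return (self.predict_scores(X) > 0.5).astype(np.int64)


def make_estimator(kind: str, config=None, seed: int | None = None):
    """Factory for the two IFS classifiers; *seed* overrides the config's."""
    from dataclasses import replace

    if kind == "snn":
        cfg = config or SNNConfig()
        if seed is not None:
            cfg = replace(cfg, seed=seed)
        return SNNClassifier(cfg)
    if kind == "rf":
        cfg = config or RFConfig()
        if seed is not None:
            cfg = replace(cfg, seed=seed)
        return RandomForestClassifier(cfg)
    raise ValueError(f"unknown classifier kind {kind!r}")
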