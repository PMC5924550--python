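"""Synthetic labeled copy-number datasets with known ground truth.

The generator emulates the structure of an aCGH case/control study on a
single chromosome: log2-ratio probe values centered near 0 with small
magnitudes, mild along-chromosome (AR(1)) correlation mimicking segmental
CNVs, and a small planted set of discriminative probes whose case-class
mean is shifted. Defaults follow the study design this package targets:
236 case and 290 control samples.

Everything is driven by a single :class:`numpy.random.Generator` seeded
from the spec, so identical spec + seed gives a bitwise-identical dataset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import lfilter

from .dataset import CopyNumberDataset
from .rules import Condition, Rule, RuleSet

__all__ = [
    "SyntheticSpec",
    "generate_dataset",
    "generate_rule_dataset",
    "generate_xor_dataset",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Study-design parameters for a synthetic copy-number cohort.

    Defaults: 236 cases / 290 controls (the cohort sizes this pipeline is
    designed around); per-probe noise sd 0.05 and effect sizes on the order
    of a few hundredths, matching the magnitude of log2-ratio thresholds
    that show up in copy-number decision rules; AR(1) correlation 0.3
    between neighboring probes.
    """

    n_case: int = 236
    n_control: int = 290
    n_probes: int = 500
    n_informative: int = 10
    effect_size: float = 0.1
    noise_sd: float = 0.05
    block_rho: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_case < 1 or self.n_control < 1:
            raise ValueError("both classes need at least one sample")
        if self.n_probes < 1:
            raise ValueError("n_probes must be positive")
        if not 0 <= self.n_informative <= self.n_probes:
            raise ValueError("n_informative must lie in [0, n_probes]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not 0 <= self.block_rho < 1:
            raise ValueError("block_rho must lie in [0, 1)")

    @property
    def n_samples(self) -> int:
        return self.n_case + self.n_control


def _probe_ids(n: int) -> list[str]:
    width = max(6, len(str(n)))
    return [f"P{i:0{width}d}" for i in range(n)]


def _sample_ids(spec: SyntheticSpec) -> tuple[list[str], np.ndarray]:
    ids = [f"CASE{i:04d}" for i in range(spec.n_case)]
    ids += [f"CTRL{i:04d}" for i in range(spec.n_control)]
    labels = np.concatenate(
        [np.ones(spec.n_case, dtype=np.int64), np.zeros(spec.n_control, dtype=np.int64)]
    )
    return ids, labels


def _baseline_noise(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Mean-0 Gaussian noise with AR(1) correlation along probe order.

    The recurrence e[p] = rho*e[p-1] + sqrt(1-rho^2)*z[p] keeps the marginal
    sd equal to noise_sd at every probe.
    """
    z = rng.standard_normal((spec.n_probes, spec.n_samples))
    rho = spec.block_rho
    if rho == 0:
        return spec.noise_sd * z
    x = z * np.sqrt(1.0 - rho**2)
    x[0] = z[0]
    e = lfilter([1.0], [1.0, -rho], x, axis=0)
    return spec.noise_sd * e


def generate_dataset(
    spec: SyntheticSpec,
) -> tuple[CopyNumberDataset, set[str]]:
    """Generate a labeled cohort plus the set of planted informative probes.

    Each informative probe's case-class mean is shifted by +-effect_size
    (the sign per probe fixed by the seed); all other probes are pure noise.
    """
    rng = np.random.default_rng(spec.seed)
    values = _baseline_noise(spec, rng)
    probe_ids = _probe_ids(spec.n_probes)
    sample_ids, labels = _sample_ids(spec)

    informative = np.sort(
        rng.choice(spec.n_probes, size=spec.n_informative, replace=False)
    )
    signs = rng.choice([-1.0, 1.0], size=spec.n_informative)
    case_cols = labels == 1
    for k, p in enumerate(informative):
        values[p, case_cols] += signs[k] * spec.effect_size

    ds = CopyNumberDataset(probe_ids, sample_ids, values, labels)
    return ds, {probe_ids[p] for p in informative}


def generate_rule_dataset(
    spec: SyntheticSpec,
    rule_thresholds: Sequence[tuple[str, float, str]],
    label_noise: float = 0.0,
) -> tuple[CopyNumberDataset, RuleSet]:
    """Generate a dataset whose labels are planted by a threshold rule.

    *rule_thresholds* is a conjunction of ``(probe_id, cutpoint, direction)``
    conditions with direction ``"<="`` or ``">="``; samples satisfying all
    conditions are cases, the rest controls, with an optional label-flip
    noise rate. Returns the dataset and the planted rule as ground truth.

    Note the class sizes of *spec* only set the total sample count here;
    the labels come from the rule.
    """
    if not 0 <= label_noise < 1:
        raise ValueError("label_noise must lie in [0, 1)")
    if not rule_thresholds:
        raise ValueError("at least one rule condition is required")
    rng = np.random.default_rng(spec.seed)
    values = _baseline_noise(spec, rng)
    probe_ids = _probe_ids(spec.n_probes)
    known = set(probe_ids)

    lo: dict[str, float] = {}
    hi: dict[str, float] = {}
    conditions = []
    for probe, cut, direction in rule_thresholds:
        if probe not in known:
            raise ValueError(f"unknown probe in rule: {probe!r}")
        if direction not in ("<=", ">="):
            raise ValueError(f"direction must be '<=' or '>=', got {direction!r}")
        if direction == "<=":
            hi[probe] = min(hi.get(probe, np.inf), cut)
        else:
            lo[probe] = max(lo.get(probe, -np.inf), cut)
        if probe in lo and probe in hi and lo[probe] > hi[probe]:
            raise ValueError(f"contradictory thresholds on probe {probe!r}")
        conditions.append(Condition(probe, direction, float(cut)))
    planted = RuleSet(rules=[Rule(conditions, predicted=1)], default=0)

    labels = planted.apply(values.T, probe_ids)
    if label_noise > 0:
        flip = rng.random(len(labels)) < label_noise
        labels = np.where(flip, 1 - labels, labels)
    if labels.min() == labels.max():
        raise ValueError(
            "planted rule left one class empty; adjust cutpoints or noise"
        )

    n = spec.n_samples
    sample_ids = [f"S{i:04d}" for i in range(n)]
    ds = CopyNumberDataset(probe_ids, sample_ids, values, labels)
    return ds, planted


def generate_xor_dataset(
    n_samples: int = 400,
    n_probes: int = 20,
    effect_size: float = 0.3,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[CopyNumberDataset, set[str]]:
    """Two informative probes with an XOR-like interaction plus nuisance.

    The first two probes take values near +-effect_size; the label is 1
    when their signs agree and 0 otherwise, so neither probe carries any
    marginal signal. The remaining probes are nuisance noise. This is the
    nonlinear fixture used to compare classifiers that can represent
    feature interactions against those that rely on axis-aligned marginal
    splits.
    """
    if n_probes < 2:
        raise ValueError("need at least the two interacting probes")
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_samples, 2))
    labels = (signs[:, 0] == signs[:, 1]).astype(np.int64)
    values = noise_sd * rng.standard_normal((n_probes, n_samples))
    values[0] += effect_size * signs[:, 0]
    values[1] += effect_size * signs[:, 1]
    probe_ids = _probe_ids(n_probes)
    sample_ids = [f"S{i:04d}" for i in range(n_samples)]
    ds = CopyNumberDataset(probe_ids, sample_ids, values, labels)
    return ds, {probe_ids[0], probe_ids[1]}
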