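"""Labeled probe-by-sample copy-number matrices.

The central container is :class:`CopyNumberDataset`: a matrix of log2-ratio
copy-number values with probes as rows and samples as columns, plus an
optional binary label per sample (positive = case, negative = control).
Matrices and label tables are plain delimited text; the delimiter is always
explicit (no sniffing), floats are serialized with 9 significant digits so a
write/read round trip is lossless at that precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CopyNumberDataset",
    "read_matrix",
    "write_matrix",
    "read_label_table",
    "write_label_table",
    "attach_labels",
    "POSITIVE_TOKENS",
    "NEGATIVE_TOKENS",
]

#: Class tokens accepted in label tables (matched case-insensitively).
POSITIVE_TOKENS = frozenset({"1", "case", "avsd", "positive"})
NEGATIVE_TOKENS = frozenset({"0", "control", "negative"})


class DatasetError(ValueError):
    """Raised when a matrix or label table violates a dataset invariant."""


@dataclass
class CopyNumberDataset:
    """Probe x sample log2-ratio matrix with optional binary sample labels.

    Parameters
    ----------
    probe_ids
        Unique probe identifiers, one per matrix row.
    sample_ids
        Unique sample identifiers, one per matrix column.
    values
        Array of shape ``(n_probes, n_samples)``; all entries finite.
    labels
        Optional array of shape ``(n_samples,)`` with entries in {0, 1};
        1 marks a case (positive) sample.
    """

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    labels: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.probe_ids = [str(p) for p in self.probe_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        for name, ids in (("probe", self.probe_ids), ("sample", self.sample_ids)):
            seen: set[str] = set()
            for i in ids:
                if i in seen:
                    raise DatasetError(f"duplicate {name} ID {i!r}")
                seen.add(i)
        if self.values.ndim != 2 or self.values.shape != (
            len(self.probe_ids),
            len(self.sample_ids),
        ):
            raise DatasetError(
                f"matrix shape {self.values.shape} does not match "
                f"({len(self.probe_ids)} probes, {len(self.sample_ids)} samples)"
            )
        if not np.all(np.isfinite(self.values)):
            r, c = np.argwhere(~np.isfinite(self.values))[0]
            raise DatasetError(
                f"non-finite value at probe {self.probe_ids[r]!r}, "
                f"sample {self.sample_ids[c]!r}"
            )
        if self.labels is not None:
            if self.labels.shape != (len(self.sample_ids),):
                raise DatasetError("labels must cover every sample exactly once")
            if not np.isin(self.labels, (0, 1)).all():
                raise DatasetError("labels must be binary (0=control, 1=case)")
            if self.labels.min() == self.labels.max():
                raise DatasetError("both classes must be non-empty")

    # -- convenience ----------------------------------------------------
    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def X(self) -> np.ndarray:
        """Sample-by-probe feature matrix (transposed view for learners)."""
        return self.values.T

    @property
    def y(self) -> np.ndarray:
        if self.labels is None:
            raise DatasetError("dataset has no labels attached")
        return self.labels

    @property
    def n_case(self) -> int:
        return int(self.y.sum())

    @property
    def n_control(self) -> int:
        return int(len(self.y) - self.y.sum())

    def probe_index(self, probe_id: str) -> int:
        try:
            return self.probe_ids.index(probe_id)
        except ValueError:
            raise DatasetError(f"unknown probe ID {probe_id!r}") from None

    def subset(self, probe_ids: Sequence[str]) -> "CopyNumberDataset":
        """Restrict to the given probes, preserving their given order."""
        idx = [self.probe_index(p) for p in probe_ids]
        return CopyNumberDataset(
            probe_ids=[self.probe_ids[i] for i in idx],
            sample_ids=list(self.sample_ids),
            values=self.values[idx, :].copy(),
            labels=None if self.labels is None else self.labels.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.sample_ids)


def read_matrix(path: str | Path, delimiter: str = "\t") -> CopyNumberDataset:
    """Read a probes-by-samples matrix from delimited text (labels unset).

    The first row is the sample header, the first column holds probe IDs.
    Duplicate IDs and non-numeric or non-finite cells raise
    :class:`DatasetError` naming the offending coordinate.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, sep=delimiter, index_col=0, header=0, dtype=str)
    probe_ids = [str(p) for p in frame.index]
    sample_ids = [str(s) for s in frame.columns]
    values = np.empty(frame.shape, dtype=np.float64)
    raw = frame.to_numpy()
    for r in range(frame.shape[0]):
        for c in range(frame.shape[1]):
            try:
                values[r, c] = float(raw[r, c])
            except (TypeError, ValueError):
                raise DatasetError(
                    f"non-numeric cell {raw[r, c]!r} at probe {probe_ids[r]!r} "
                    f"(row {r + 2}), sample {sample_ids[c]!r} (column {c + 2})"
                ) from None
    return CopyNumberDataset(probe_ids, sample_ids, values)


def write_matrix(
    dataset: CopyNumberDataset, path: str | Path, delimiter: str = "\t"
) -> Path:
    """Write the matrix so that :func:`read_matrix` recovers it exactly.

    Floats are serialized with 9 significant digits. Refuses to write a
    degenerate (zero-probe or zero-sample) matrix.
    """
    if dataset.n_probes == 0 or dataset.n_samples == 0:
        raise DatasetError("refusing to write a degenerate (empty) matrix")
    path = Path(path)
    dataset.to_frame().to_csv(path, sep=delimiter, float_format="%.9g")
    return path


def read_label_table(path: str | Path, delimiter: str = "\t") -> dict[str, str]:
    """Read a two-column (sample ID, class token) table without header."""
    frame = pd.read_csv(path, sep=delimiter, header=None, dtype=str)
    if frame.shape[1] != 2:
        raise DatasetError(
            f"label table must have exactly 2 columns, found {frame.shape[1]}"
        )
    return dict(zip(frame.iloc[:, 0].astype(str), frame.iloc[:, 1].astype(str)))


def write_label_table(
    dataset: CopyNumberDataset, path: str | Path, delimiter: str = "\t"
) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for sid, lab in zip(dataset.sample_ids, dataset.y):
            fh.write(f"{sid}{delimiter}{'case' if lab else 'control'}\n")
    return path


def _parse_class_token(token: str) -> int:
    low = str(token).strip().lower()
    if low in POSITIVE_TOKENS:
        return 1
    if low in NEGATIVE_TOKENS:
        return 0
    raise DatasetError(
        f"unknown class token {token!r}; accepted (case-insensitive): "
        f"positive={sorted(POSITIVE_TOKENS)}, negative={sorted(NEGATIVE_TOKENS)}"
    )


def attach_labels(
    dataset: CopyNumberDataset, label_table: Mapping[str, str]
) -> CopyNumberDataset:
    """Return a copy of *dataset* with labels resolved from *label_table*.

    Every sample must appear in the table; extra table entries are ignored.
    """
    missing = [s for s in dataset.sample_ids if s not in label_table]
    if missing:
        raise DatasetError(f"label table is missing samples: {missing}")
    labels = np.array(
        [_parse_class_token(label_table[s]) for s in dataset.sample_ids],
        dtype=np.int64,
    )
    out = replace(dataset, labels=labels)
    return out
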