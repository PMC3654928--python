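"""Expression dataset container and delimited-text I/O.

The in-memory model is an M-samples x N-features real matrix with unique
sample and feature identifiers and one subclass label per sample.  Subclass
indices are assigned lexicographically over the distinct labels at
construction time so that downstream tie-breaking is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["ExpressionDataset", "load_dataset", "save_dataset", "subset_features"]


@dataclass(frozen=True)
class ExpressionDataset:
    """An M x N expression matrix with per-sample subclass labels.

    Parameters
    ----------
    values
        Real matrix of shape (M, N); samples in rows, features in columns.
    sample_ids
        M unique sample identifiers.
    feature_ids
        N unique feature identifiers.
    labels
        M subclass labels (strings) over K >= 2 distinct values.

    The derived attribute ``class_index`` maps each distinct label to its
    subclass index ``k`` in ``0..K-1``, ordered lexicographically.
    """

    values: np.ndarray
    sample_ids: tuple[str, ...]
    feature_ids: tuple[str, ...]
    labels: tuple[str, ...]
    class_index: dict[str, int] = field(init=False, compare=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "feature_ids", tuple(str(f) for f in self.feature_ids))
        object.__setattr__(self, "labels", tuple(str(l) for l in self.labels))

        if values.ndim != 2:
            raise ValueError(f"values must be 2-D, got shape {values.shape}")
        m, n = values.shape
        if m < 2:
            raise ValueError(f"need at least 2 samples, got {m}")
        if n < 1:
            raise ValueError("need at least 1 feature")
        if len(self.sample_ids) != m:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {m} rows")
        if len(self.feature_ids) != n:
            raise ValueError(f"{len(self.feature_ids)} feature ids for {n} columns")
        if len(self.labels) != m:
            raise ValueError(f"{len(self.labels)} labels for {m} samples")
        if any(s == "" for s in self.sample_ids):
            raise ValueError("empty-string sample id")
        if any(f == "" for f in self.feature_ids):
            raise ValueError("empty-string feature id")
        dup = _duplicates(self.sample_ids)
        if dup:
            raise ValueError(f"duplicate sample ids: {sorted(dup)}")
        dup = _duplicates(self.feature_ids)
        if dup:
            raise ValueError(f"duplicate feature ids: {sorted(dup)}")
        if not np.isfinite(values).all():
            bad = int(np.count_nonzero(~np.isfinite(values)))
            raise ValueError(f"values contain {bad} missing/non-finite entries")
        classes = sorted(set(self.labels))
        if len(classes) < 2:
            raise ValueError("need at least 2 distinct subclass labels")
        object.__setattr__(self, "class_index", {c: k for k, c in enumerate(classes)})

    # -- convenience views -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def n_classes(self) -> int:
        return len(self.class_index)

    @property
    def classes(self) -> tuple[str, ...]:
        """Distinct labels in subclass-index (lexicographic) order."""
        return tuple(self.class_index)

    def label_codes(self) -> np.ndarray:
        """Integer subclass index per sample, shape (M,)."""
        return np.array([self.class_index[l] for l in self.labels], dtype=int)

    def class_members(self, label: str) -> np.ndarray:
        """Row indices of the samples carrying ``label``."""
        return np.flatnonzero(np.array([l == label for l in self.labels]))

    def take_samples(self, rows: Sequence[int]) -> "ExpressionDataset":
        """Dataset restricted to the given sample rows (order preserved)."""
        rows = np.asarray(rows, dtype=int)
        return ExpressionDataset(
            values=self.values[rows],
            sample_ids=tuple(self.sample_ids[i] for i in rows),
            feature_ids=self.feature_ids,
            labels=tuple(self.labels[i] for i in rows),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionDataset):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.feature_ids == other.feature_ids
            and self.labels == other.labels
            and self.values.shape == other.values.shape
            and bool(np.array_equal(self.values, other.values))
        )


def _duplicates(items: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for x in items:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def load_dataset(
    matrix_path: str | Path,
    labels_path: str | Path,
    orientation: str = "samples_in_rows",
) -> ExpressionDataset:
    """Read a delimited expression matrix plus a two-column label file.

    The matrix file has a header row of feature identifiers and a first
    column of sample identifiers (roles swap under
    ``orientation="features_in_rows"``).  The label file has two columns,
    ``sample_id<sep>label``, no header.  Delimiter is chosen by extension:
    comma for ``.csv``, tab otherwise.

    Missing values are a hard error — there is no imputation mechanism in
    the correlation pipeline downstream.
    """
    matrix_path, labels_path = Path(matrix_path), Path(labels_path)
    if orientation not in ("samples_in_rows", "features_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    frame = pd.read_csv(
        matrix_path, sep=_sep_for(matrix_path), index_col=0,
        float_precision="round_trip",
    )
    if orientation == "features_in_rows":
        frame = frame.T
    if frame.isna().to_numpy().any():
        n_bad = int(frame.isna().to_numpy().sum())
        raise ValueError(
            f"{matrix_path}: {n_bad} missing values; missing data are not supported"
        )

    lab = pd.read_csv(
        labels_path, sep=_sep_for(labels_path), header=None,
        names=["sample_id", "label"], dtype=str,
    )
    label_map = dict(zip(lab["sample_id"], lab["label"]))
    if len(label_map) != len(lab):
        raise ValueError(f"{labels_path}: duplicate sample ids in label file")

    matrix_ids = [str(s) for s in frame.index]
    missing = [s for s in matrix_ids if s not in label_map]
    if missing:
        raise ValueError(f"samples without labels: {missing}")
    extra = sorted(set(label_map) - set(matrix_ids))
    if extra:
        raise ValueError(f"labels for unknown samples: {extra}")

    return ExpressionDataset(
        values=frame.to_numpy(dtype=float),
        sample_ids=tuple(matrix_ids),
        feature_ids=tuple(str(f) for f in frame.columns),
        labels=tuple(label_map[s] for s in matrix_ids),
    )


def save_dataset(
    ds: ExpressionDataset, matrix_path: str | Path, labels_path: str | Path
) -> None:
    """Write ``ds`` so that :func:`load_dataset` reproduces it bitwise.

    Values are formatted with ``repr``-level (17 significant digit)
    precision, which round-trips IEEE doubles exactly.
    """
    matrix_path, labels_path = Path(matrix_path), Path(labels_path)
    frame = pd.DataFrame(
        ds.values, index=list(ds.sample_ids), columns=list(ds.feature_ids)
    )
    frame.to_csv(matrix_path, sep=_sep_for(matrix_path), float_format="%.17g")
    sep = _sep_for(labels_path)
    with open(labels_path, "w") as fh:
        for sid, lab in zip(ds.sample_ids, ds.labels):
            fh.write(f"{sid}{sep}{lab}\n")


def subset_features(
    ds: ExpressionDataset, feature_indices: Sequence[int]
) -> ExpressionDataset:
    """Restrict and reorder columns to ``feature_indices``; labels unchanged."""
    idx = np.asarray(feature_indices, dtype=int)
    if idx.ndim != 1 or idx.size < 1:
        raise ValueError("feature_indices must be a non-empty 1-D index list")
    if idx.min() < 0 or idx.max() >= ds.n_features:
        raise IndexError(
            f"feature index out of range [0, {ds.n_features}): "
            f"{idx[(idx < 0) | (idx >= ds.n_features)].tolist()}"
        )
    if len(np.unique(idx)) != len(idx):
        raise ValueError("feature_indices contains duplicates")
    return ExpressionDataset(
        values=ds.values[:, idx],
        sample_ids=ds.sample_ids,
        feature_ids=tuple(ds.feature_ids[i] for i in idx),
        labels=ds.labels,
    )
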