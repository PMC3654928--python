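"""Template-based POC classification and the KNN variants.

The classifier builds one "virtual sample template" per subclass — the
per-feature mean of the subclass's training samples, i.e. its centroid —
and assigns a test profile to the subclass whose template gives the highest
POC correlation peak.  It is a nearest-centroid rule with POC-peak
similarity, and inherits POC's amplitude invariance: rescaling a test
sample by any positive factor leaves the prediction unchanged.

Two k-nearest-neighbour variants are also provided: one ranking neighbours
by POC peak (the template-free counterpart) and one by correlation distance
(1 minus the Pearson correlation), the standard baseline metric.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import Counter
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset
from .poc import poc_1d, poc_2d, reshape_to_square

__all__ = [
    "ClassTemplate",
    "PeakScores",
    "build_templates",
    "classify_poc",
    "classify_dataset",
    "classify_poc_knn",
    "correlation_distance",
    "classify_corr_knn",
    "peak_table",
]

#: Peaks equal within this tolerance are ties; resolved to the lowest
#: subclass index for determinism.
PEAK_TIE_TOL = 1e-12


@dataclass(frozen=True)
class ClassTemplate:
    """Per-subclass centroid: the mean training profile of one subclass."""

    label: str
    mu: np.ndarray
    n_members: int


@dataclass(frozen=True)
class PeakScores:
    """POC peaks of one test sample against every subclass template."""

    labels: tuple[str, ...]
    peaks: np.ndarray
    predicted_label: str
    #: Top peak minus runner-up peak; 0.0 when K == 1 would be degenerate,
    #: but K >= 2 always holds here.
    margin: float


def build_templates(train: ExpressionDataset) -> list[ClassTemplate]:
    """One template per subclass, ordered by subclass index.

    Each template's ``mu[j]`` is the arithmetic mean over the subclass's
    training samples of feature ``j``.
    """
    templates = []
    for label in train.classes:
        rows = train.class_members(label)
        if rows.size == 0:
            raise ValueError(f"subclass {label!r} has no training samples")
        mu = train.values[rows].mean(axis=0)
        templates.append(ClassTemplate(label=label, mu=mu, n_members=int(rows.size)))
    return templates


def _peak(test: np.ndarray, template: np.ndarray, mode: str) -> float:
    if mode == "one_d":
        return poc_1d(test, template).peak_value
    if mode == "two_d":
        return poc_2d(reshape_to_square(test), reshape_to_square(template)).peak_value
    raise ValueError(f"unknown mode {mode!r}; expected 'one_d' or 'two_d'")


def classify_poc(
    test_sample: np.ndarray,
    templates: Sequence[ClassTemplate],
    mode: str = "one_d",
) -> PeakScores:
    """Score one test profile against every template; label = argmax peak.

    In ``two_d`` mode the profile and templates are reshaped row-major to
    p x p matrices (the length must be a perfect square) and 2-D POC is
    used; peak values from the two modes are generally close but not equal.
    Ties within ``PEAK_TIE_TOL`` go to the lowest subclass index.
    """
    test_sample = np.asarray(test_sample, dtype=float)
    if not templates:
        raise ValueError("no templates given")
    n = templates[0].mu.size
    if test_sample.ndim != 1 or test_sample.size != n:
        raise ValueError(
            f"test sample length {test_sample.size} != template length {n}"
        )
    peaks = np.array([_peak(test_sample, t.mu, mode) for t in templates])
    best = peaks.max()
    winner = int(np.flatnonzero(peaks >= best - PEAK_TIE_TOL)[0])
    order = np.sort(peaks)[::-1]
    margin = float(order[0] - order[1]) if peaks.size > 1 else 0.0
    return PeakScores(
        labels=tuple(t.label for t in templates),
        peaks=peaks,
        predicted_label=templates[winner].label,
        margin=margin,
    )


def classify_dataset(
    test: ExpressionDataset,
    templates: Sequence[ClassTemplate],
    mode: str = "one_d",
) -> tuple[list[PeakScores], float]:
    """Classify every sample of ``test``; return scores and the accuracy."""
    scores = [classify_poc(row, templates, mode=mode) for row in test.values]
    correct = sum(
        s.predicted_label == truth for s, truth in zip(scores, test.labels)
    )
    return scores, correct / test.n_samples


def _majority_vote(neighbor_labels: Sequence[str]) -> str:
    """Majority label; a tie falls back to the single nearest neighbour."""
    counts = Counter(neighbor_labels)
    top = counts.most_common()
    if len(top) > 1 and top[0][1] == top[1][1]:
        return neighbor_labels[0]
    return top[0][0]


def classify_poc_knn(
    test_sample: np.ndarray, train: ExpressionDataset, k: int = 5
) -> str:
    """k-NN with POC peak value as the similarity between samples.

    The k training samples with the highest peak against the test profile
    vote by majority; the default k = 5 follows common practice for
    expression KNN baselines.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > train.n_samples:
        raise ValueError(f"k={k} exceeds {train.n_samples} training samples")
    test_sample = np.asarray(test_sample, dtype=float)
    peaks = np.array(
        [poc_1d(test_sample, row).peak_value for row in train.values]
    )
    # stable sort on (-peak, index): deterministic neighbour order under ties
    order = np.argsort(-peaks, kind="stable")[:k]
    return _majority_vote([train.labels[i] for i in order])


def correlation_distance(xs: np.ndarray, yt: np.ndarray) -> float:
    """One minus the sample (Pearson) correlation between two vectors.

    Ranges over [0, 2]: 0 for perfectly correlated, 2 for exactly
    anti-correlated vectors.  Constant vectors have zero centered norm and
    are rejected.
    """
    xs = np.asarray(xs, dtype=float)
    yt = np.asarray(yt, dtype=float)
    if xs.shape != yt.shape or xs.ndim != 1:
        raise ValueError("inputs must be 1-D vectors of equal length")
    if xs.size < 2:
        raise ValueError("need length >= 2")
    xc = xs - xs.mean()
    yc = yt - yt.mean()
    nx = np.sqrt(xc @ xc)
    ny = np.sqrt(yc @ yc)
    if nx == 0.0 or ny == 0.0:
        raise ValueError("correlation distance undefined for constant vectors")
    return float(1.0 - (xc @ yc) / (nx * ny))


def classify_corr_knn(
    test_sample: np.ndarray, train: ExpressionDataset, k: int = 5
) -> str:
    """k-NN under correlation distance with majority vote."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > train.n_samples:
        raise ValueError(f"k={k} exceeds {train.n_samples} training samples")
    test_sample = np.asarray(test_sample, dtype=float)
    d = np.array(
        [correlation_distance(test_sample, row) for row in train.values]
    )
    order = np.argsort(d, kind="stable")[:k]
    return _majority_vote([train.labels[i] for i in order])


def peak_table(
    scores: Sequence[PeakScores], sample_ids: Sequence[str]
) -> pd.DataFrame:
    """Per-sample peak values against every template, as a tidy table.

    This is the data behind per-subclass separability plots: one row per
    test sample, one column per subclass peak, plus the predicted label and
    the margin between the top two peaks.
    """
    if len(scores) != len(sample_ids):
        raise ValueError("one sample id per PeakScores required")
    labels = scores[0].labels if scores else ()
    rows = []
    for sid, s in zip(sample_ids, scores):
        if s.labels != labels:
            raise ValueError("inconsistent template label sets across scores")
        row = {"sample_id": sid}
        row.update({f"peak_{lab}": p for lab, p in zip(s.labels, s.peaks)})
        row["predicted_label"] = s.predicted_label
        row["margin"] = s.margin
        rows.append(row)
    return pd.DataFrame(rows)
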