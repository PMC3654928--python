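"""Balanced splitting, repeated-randomization accuracy, and permutation tests.

The Balance Division Method (BDM) draws exactly Q samples per subclass into
the training set (without replacement) and leaves everything else as test,
so training class sizes are uniform regardless of how imbalanced the
dataset is.  Accuracy is estimated as the mean over many random BDM splits,
each running the full pipeline: rank features on the training split, keep
the top m, build subclass templates, classify the held-out samples.

The label-permutation assessment measures whether that accuracy could arise
by chance: for each of r randomized splits the trained model's predictions
are scored against l random permutations of the test labels (training
labels stay intact), giving an r x l matrix of null accuracies.  The
p-value is the +1-smoothed fraction of null accuracies at or above the
observed mean accuracy:

    p = (#{Acc_ij >= a_mean} + 1) / (r*l + 1)

so p is bounded below by 1/(r*l + 1) and above by 1.  On balanced data the
grand null mean b_mean sits near 1/K; a b_mean far from 1/K flags a biased
evaluation.

All randomness derives from a single master seed through
`numpy.random.SeedSequence(master_seed, spawn_key=(stream, repeat))`, so any
individual repeat is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classify import build_templates, classify_dataset
from .dataset import ExpressionDataset, subset_features
from .features import kruskal_wallis_rank, select_top

__all__ = [
    "SplitSpec",
    "PermutationResult",
    "bdm_split",
    "repeated_accuracy",
    "permutation_test",
    "permutation_p_value",
]

# spawn-key stream tags, so the three seed consumers never collide
_STREAM_REPEATS = 0
_STREAM_PERM_SPLITS = 1
_STREAM_PERM_LABELS = 2
_STREAM_AMEAN = 3


@dataclass(frozen=True)
class SplitSpec:
    """BDM parameters: Q training samples per subclass, plus the draw seed."""

    q_per_class: int
    seed: int


@dataclass(frozen=True)
class PermutationResult:
    """Output of the label-permutation reliability assessment."""

    #: r x l matrix of accuracies on label-permuted test sets.
    acc_matrix: np.ndarray
    #: Mean over the l permutations, per randomization (length r).
    mean_acc_per_randomization: np.ndarray
    #: Observed mean accuracy over the unpermuted randomizations.
    a_mean: float
    #: Grand mean of acc_matrix; near 1/K for an unbiased balanced setup.
    b_mean: float
    #: +1-smoothed permutation p-value.
    p_value: float


def _rng(master_seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=key))


def bdm_split(
    ds: ExpressionDataset, spec: SplitSpec
) -> tuple[ExpressionDataset, ExpressionDataset]:
    """Split ``ds`` into a Q-per-subclass training set and the rest as test.

    Train and test partition the dataset exactly.  A Q that exhausts every
    subclass would leave an empty test set and is rejected.
    """
    q = spec.q_per_class
    if q < 1:
        raise ValueError("q_per_class must be >= 1")
    rng = np.random.default_rng(spec.seed)
    train_rows: list[np.ndarray] = []
    for label in ds.classes:
        members = ds.class_members(label)
        if members.size < q:
            raise ValueError(
                f"q_per_class={q} exceeds subclass {label!r} size {members.size}"
            )
        train_rows.append(rng.choice(members, size=q, replace=False))
    train_idx = np.sort(np.concatenate(train_rows))
    mask = np.zeros(ds.n_samples, dtype=bool)
    mask[train_idx] = True
    test_idx = np.flatnonzero(~mask)
    if test_idx.size == 0:
        raise ValueError(
            "q_per_class equals every subclass size: the test set would be empty"
        )
    return ds.take_samples(train_idx), ds.take_samples(test_idx)


def _single_run(
    ds: ExpressionDataset,
    q_per_class: int,
    n_features: int,
    mode: str,
    selection_scope: str,
    split_seed: int,
    full_selection: np.ndarray | None,
) -> tuple[float, list[str], ExpressionDataset]:
    """One split -> select -> template -> classify pass.

    Returns (accuracy, predicted labels, test split on selected features).
    """
    train, test = bdm_split(ds, SplitSpec(q_per_class=q_per_class, seed=split_seed))
    if selection_scope == "train_only":
        keep = select_top(kruskal_wallis_rank(train), n_features)
    elif selection_scope == "full":
        keep = full_selection
        if keep is None:
            keep = select_top(kruskal_wallis_rank(ds), n_features)
    else:
        raise ValueError(f"unknown selection_scope {selection_scope!r}")
    train_sel = subset_features(train, keep)
    test_sel = subset_features(test, keep)
    templates = build_templates(train_sel)
    scores, acc = classify_dataset(test_sel, templates, mode=mode)
    return acc, [s.predicted_label for s in scores], test_sel


def repeated_accuracy(
    ds: ExpressionDataset,
    q_per_class: int,
    n_features: int,
    n_repeats: int = 200,
    mode: str = "one_d",
    selection_scope: str = "train_only",
    master_seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Mean held-out accuracy over ``n_repeats`` random BDM splits.

    Each repeat draws a fresh split, ranks features (on the training split
    by default; ``selection_scope="full"`` ranks once on the whole dataset
    for reproduction of pipelines that select before splitting), keeps the
    top ``n_features``, builds templates and classifies the test split.

    Returns ``(mean_accuracy, per_repeat_accuracies)``; the per-repeat
    vector is bitwise reproducible from ``master_seed``.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if not 1 <= n_features <= ds.n_features:
        raise ValueError(f"n_features must be in [1, {ds.n_features}]")
    full_sel = (
        select_top(kruskal_wallis_rank(ds), n_features)
        if selection_scope == "full"
        else None
    )
    accs = np.empty(n_repeats)
    for i in range(n_repeats):
        seed = int(_rng(master_seed, _STREAM_REPEATS, i).integers(2**31))
        accs[i], _, _ = _single_run(
            ds, q_per_class, n_features, mode, selection_scope, seed, full_sel
        )
    return float(accs.mean()), accs


def permutation_p_value(acc_matrix: np.ndarray, a_mean: float) -> float:
    """+1-smoothed p-value: fraction of null accuracies >= the observed mean."""
    acc_matrix = np.asarray(acc_matrix, dtype=float)
    n_null = acc_matrix.size
    if n_null == 0:
        raise ValueError("empty accuracy matrix")
    return (int(np.count_nonzero(acc_matrix >= a_mean)) + 1) / (n_null + 1)


def permutation_test(
    ds: ExpressionDataset,
    q_per_class: int = 8,
    n_features: int = 182,
    r: int = 1000,
    l: int = 50,
    mode: str = "one_d",
    selection_scope: str = "train_only",
    master_seed: int = 0,
    n_unpermuted: int = 200,
) -> PermutationResult:
    """Label-permutation reliability assessment.

    For each of ``r`` randomized splits the model is trained once and its
    fixed predictions are scored against ``l`` uniform random permutations
    of the test-label multiset (class counts preserved; training labels are
    never permuted).  The observed reference ``a_mean`` is computed from
    ``n_unpermuted`` separate unpermuted randomizations.  Defaults
    ``q_per_class=8, n_features=182, r=1000, l=50`` are the full-scale
    assessment; r=100, l=10 is a desk-scale reduction with the same
    structure.
    """
    if r < 1 or l < 1:
        raise ValueError("r and l must be >= 1")
    a_mean, _ = repeated_accuracy(
        ds,
        q_per_class,
        n_features,
        n_repeats=n_unpermuted,
        mode=mode,
        selection_scope=selection_scope,
        master_seed=int(_rng(master_seed, _STREAM_AMEAN).integers(2**31)),
    )
    full_sel = (
        select_top(kruskal_wallis_rank(ds), n_features)
        if selection_scope == "full"
        else None
    )
    acc = np.empty((r, l))
    for i in range(r):
        seed = int(_rng(master_seed, _STREAM_PERM_SPLITS, i).integers(2**31))
        _, preds, test_sel = _single_run(
            ds, q_per_class, n_features, mode, selection_scope, seed, full_sel
        )
        preds_arr = np.array(preds)
        labels_arr = np.array(test_sel.labels)
        perm_rng = _rng(master_seed, _STREAM_PERM_LABELS, i)
        for j in range(l):
            permuted = perm_rng.permutation(labels_arr)
            acc[i, j] = float(np.mean(preds_arr == permuted))
    mean_per_rand = acc.mean(axis=1)
    b_mean = float(acc.mean())
    return PermutationResult(
        acc_matrix=acc,
        mean_acc_per_randomization=mean_per_rand,
        a_mean=a_mean,
        b_mean=b_mean,
        p_value=permutation_p_value(acc, a_mean),
    )
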