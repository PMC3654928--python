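"""Kruskal-Wallis feature ranking and top-m selection.

Features are ranked by the Kruskal-Wallis rank sum statistic H across the K
subclasses — a nonparametric K-group location test, so the ranking is
invariant under any strictly monotone transform of a feature's values.
Selection is by rank (take the m most significant), not by a significance
threshold, so no multiple-testing correction applies.

The statistic is computed vectorized over all features at once: per-feature
mid-ranks via `scipy.stats.rankdata`, the usual H with tie correction, and
a chi-squared p-value with K-1 degrees of freedom.  A feature constant
across all samples carries no information; it gets H = 0, p = 1 and ranks
last.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import ExpressionDataset
from .poc import nearest_squares

__all__ = ["FeatureRanking", "kruskal_wallis_rank", "select_top", "ranking_table"]


@dataclass(frozen=True)
class FeatureRanking:
    """Per-feature H statistic, p-value and rank (1 = most significant)."""

    feature_ids: tuple[str, ...]
    statistic: np.ndarray
    p_value: np.ndarray
    rank: np.ndarray
    #: Feature indices sorted best-first (rank order); ``rank[order[0]] == 1``.
    order: np.ndarray


def kruskal_wallis_rank(ds: ExpressionDataset) -> FeatureRanking:
    """Rank every feature by the tie-corrected Kruskal-Wallis H statistic.

    p-values come from the chi-squared approximation with K-1 degrees of
    freedom regardless of group sizes (no exact small-sample enumeration).
    Rank ties (equal p) are broken by descending H, then ascending feature
    index, so the ordering is deterministic.
    """
    x = ds.values  # (M, N)
    m, n = x.shape
    codes = ds.label_codes()
    k = ds.n_classes

    ranks = stats.rankdata(x, axis=0)  # mid-ranks per feature column
    group_counts = np.bincount(codes, minlength=k).astype(float)  # all >= 1
    # per-class rank sums, shape (K, N)
    rank_sums = np.zeros((k, n))
    np.add.at(rank_sums, codes, ranks)
    mean_ranks = rank_sums / group_counts[:, None]
    grand_mean = (m + 1) / 2.0
    h = (12.0 / (m * (m + 1.0))) * (
        group_counts[:, None] * (mean_ranks - grand_mean) ** 2
    ).sum(axis=0)

    # tie correction: 1 - sum(t^3 - t) / (M^3 - M) per feature, vectorized
    # over columns: runs of equal sorted ranks never cross column boundaries
    # because every column starts a new run.
    sorted_ranks = np.sort(ranks, axis=0)
    new_run = np.ones_like(sorted_ranks, dtype=bool)
    new_run[1:] = sorted_ranks[1:] != sorted_ranks[:-1]
    flat_starts = new_run.ravel(order="F")
    run_id = np.cumsum(flat_starts) - 1
    run_len = np.bincount(run_id).astype(float)
    run_col = np.flatnonzero(flat_starts) // m
    tie_term = np.bincount(run_col, weights=run_len**3 - run_len, minlength=n)
    correction = 1.0 - tie_term / (m**3 - m)

    constant = correction <= 0.0  # all samples tied -> no information
    h = np.where(constant, 0.0, h / np.where(constant, 1.0, correction))
    p = np.where(constant, 1.0, stats.chi2.sf(h, df=k - 1))

    order = np.lexsort((np.arange(n), -h, p))
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(1, n + 1)
    return FeatureRanking(
        feature_ids=ds.feature_ids,
        statistic=h,
        p_value=p,
        rank=rank,
        order=order,
    )


def select_top(
    ranking: FeatureRanking, m: int, require_square: bool = False
) -> np.ndarray:
    """Indices of the m best-ranked features, in rank order.

    With ``require_square`` (needed before 2-D POC, which reshapes the
    profile to a p x p matrix) a non-square m is rejected and the nearest
    perfect squares are suggested.
    """
    n = len(ranking.feature_ids)
    if not 1 <= m <= n:
        raise ValueError(f"m must be in [1, {n}], got {m}")
    if require_square:
        p = int(np.sqrt(m))
        if p * p != m:
            lo, hi = nearest_squares(m)
            raise ValueError(
                f"m={m} is not a perfect square (required for 2-D POC); "
                f"nearest squares are {lo} and {hi}"
            )
    return ranking.order[:m].copy()


def ranking_table(ranking: FeatureRanking) -> pd.DataFrame:
    """Ranking as a tidy table (feature_id, H, p, rank), best-first."""
    frame = pd.DataFrame(
        {
            "feature_id": ranking.feature_ids,
            "H": ranking.statistic,
            "p": ranking.p_value,
            "rank": ranking.rank,
        }
    )
    return frame.sort_values("rank", kind="stable").reset_index(drop=True)
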