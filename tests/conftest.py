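"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid numpy's FFT and vectorized shortcuts: direct
O(T^2) DFT summation, explicit rank assignment, direct-summation means and
correlations.  They exist so the fast implementation paths are checked
against arithmetic that shares no code with them.
"""

from __future__ import annotations

import numpy as np
import pytest

from pocclass import ExpressionDataset


# ---------------------------------------------------------------------------
# brute-force DFT / POC oracles

def dft_direct(f: np.ndarray) -> np.ndarray:
    """O(T^2) direct-summation DFT."""
    f = np.asarray(f, dtype=complex)
    t = f.size
    n = np.arange(t)
    w = np.exp(-2j * np.pi * np.outer(n, n) / t)
    return w @ f


def idft_direct(F: np.ndarray) -> np.ndarray:
    """Direct inverse DFT with the 1/T factor on the inverse transform."""
    F = np.asarray(F, dtype=complex)
    t = F.size
    n = np.arange(t)
    w = np.exp(2j * np.pi * np.outer(n, n) / t)
    return (w @ F) / t


def poc_1d_direct(fa: np.ndarray, fb: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    """Brute-force 1-D phase-only correlation function."""
    cross = dft_direct(fa) * np.conj(dft_direct(fb))
    mag = np.abs(cross)
    floor = eps * mag.max() if mag.max() > 0 else 0.0
    r = np.zeros_like(cross)
    keep = mag > floor
    r[keep] = cross[keep] / mag[keep]
    return idft_direct(r).real


def dft2_direct(f: np.ndarray) -> np.ndarray:
    """O((pq)^2) direct-summation 2-D DFT."""
    f = np.asarray(f, dtype=complex)
    p, q = f.shape
    out = np.zeros((p, q), dtype=complex)
    for u in range(p):
        for v in range(q):
            acc = 0.0 + 0.0j
            for a in range(p):
                for b in range(q):
                    acc += f[a, b] * np.exp(-2j * np.pi * (u * a / p + v * b / q))
            out[u, v] = acc
    return out


def poc_2d_direct(fa: np.ndarray, fb: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    """Brute-force 2-D phase-only correlation function."""
    cross = dft2_direct(fa) * np.conj(dft2_direct(fb))
    mag = np.abs(cross)
    floor = eps * mag.max() if mag.max() > 0 else 0.0
    r = np.zeros_like(cross)
    keep = mag > floor
    r[keep] = cross[keep] / mag[keep]
    p, q = r.shape
    out = np.zeros((p, q), dtype=complex)
    for a in range(p):
        for b in range(q):
            acc = 0.0 + 0.0j
            for u in range(p):
                for v in range(q):
                    acc += r[u, v] * np.exp(2j * np.pi * (u * a / p + v * b / q))
            out[a, b] = acc / (p * q)
    return out.real


# ---------------------------------------------------------------------------
# rank / statistics oracles

def hand_ranks(values) -> list[float]:
    """Mid-ranks assigned by explicit sorting, no library calls."""
    values = list(values)
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        mid = (i + j) / 2.0 + 1.0
        for t in range(i, j + 1):
            ranks[order[t]] = mid
        i = j + 1
    return ranks


def kruskal_h_direct(groups: list[list[float]]) -> float:
    """Tie-corrected Kruskal-Wallis H by explicit rank arithmetic."""
    pooled = [v for g in groups for v in g]
    m = len(pooled)
    ranks = hand_ranks(pooled)
    grand = (m + 1) / 2.0
    h = 0.0
    pos = 0
    for g in groups:
        rs = ranks[pos: pos + len(g)]
        pos += len(g)
        mean_rank = sum(rs) / len(rs)
        h += len(g) * (mean_rank - grand) ** 2
    h *= 12.0 / (m * (m + 1.0))
    # tie correction
    tie = 0.0
    for v in set(pooled):
        t = pooled.count(v)
        tie += t**3 - t
    denom = 1.0 - tie / (m**3 - m)
    if denom <= 0:
        return 0.0
    return h / denom


def pearson_direct(x, y) -> float:
    """Sample correlation by direct summation."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    dx = sum((a - mx) ** 2 for a in x) ** 0.5
    dy = sum((b - my) ** 2 for b in y) ** 0.5
    return num / (dx * dy)


# ---------------------------------------------------------------------------
# fixtures

@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20130509)


@pytest.fixture
def small_dataset() -> ExpressionDataset:
    """6 samples x 5 features, 3 subclasses, fixed values."""
    vals = np.arange(30, dtype=float).reshape(6, 5)
    vals[3:, :] += 0.5  # avoid pure ties everywhere
    return ExpressionDataset(
        values=vals,
        sample_ids=tuple(f"s{i}" for i in range(6)),
        feature_ids=tuple(f"g{j}" for j in range(5)),
        labels=("x", "x", "y", "y", "z", "z"),
    )


def random_dataset(
    rng: np.random.Generator,
    m_per_class: tuple[int, ...] = (4, 5),
    n_features: int = 7,
) -> ExpressionDataset:
    """Unstructured random dataset for property tests."""
    m = sum(m_per_class)
    labels = []
    for k, c in enumerate(m_per_class):
        labels += [f"k{k}"] * c
    return ExpressionDataset(
        values=rng.normal(size=(m, n_features)),
        sample_ids=tuple(f"s{i}" for i in range(m)),
        feature_ids=tuple(f"g{j}" for j in range(n_features)),
        labels=tuple(labels),
    )
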