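"""Phase-only correlation (POC) in one and two dimensions.

POC measures the similarity of two real signals by discarding the amplitude
of their cross-power spectrum and keeping only the phase.  For signals
``fa``, ``fb`` of common length ``T`` with DFTs ``Fa``, ``Fb``, the
cross-phase spectrum is

    R(n) = Fa(n) * conj(Fb(n)) / |Fa(n) * conj(Fb(n))|

and the POC function is the inverse DFT of R (with the 1/T factor on the
inverse transform), which is real for real inputs.  Its maximum — the
correlation peak — equals 1 exactly when ``fb`` is a circular shift of
``fa`` (up to a positive amplitude factor) and decays toward 0 as the two
signals decorrelate.  The peak *value* is what the classifier uses; the
peak *location* encodes the circular shift and is reported but unused for
labels.

Indexing is the standard 0..T-1 DFT convention.  A symmetric -Q..Q
convention would relabel the correlation entries (a circular shift of the
output) without changing the set of values, hence the peak value is
identical under either convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PhaseSpectrum",
    "POCResult",
    "cross_phase_spectrum",
    "poc_1d",
    "poc_2d",
    "reshape_to_square",
]

#: Relative spectral-magnitude floor below which a frequency bin is treated
#: as having no phase information (contributes 0 to R instead of 0/0).
DEFAULT_EPS = 1e-12

#: Imaginary residue beyond this (relative) magnitude indicates the inputs
#: were not real / conjugate symmetry was violated.
_IMAG_TOL = 1e-9


@dataclass(frozen=True)
class PhaseSpectrum:
    """Unit-modulus cross-phase spectrum; zero where amplitude vanished."""

    phase_factors: np.ndarray
    #: True when every spectral bin was below the floor (all-zero input).
    degenerate: bool = False


@dataclass(frozen=True)
class POCResult:
    """POC function with its peak value and location.

    ``correlation`` has the shape of the inputs; entries lie approximately
    in [-1, 1].  ``peak_value`` is the signed maximum (POC values can be
    negative in exact arithmetic even though well-matched signals peak near
    +1), ``peak_location`` its flat index (1-D) or index pair (2-D).
    """

    correlation: np.ndarray
    peak_value: float
    peak_location: int | tuple[int, int]


def _normalize_cross_spectrum(cross: np.ndarray, eps: float) -> tuple[np.ndarray, bool]:
    mag = np.abs(cross)
    scale = mag.max()
    if scale == 0.0:
        return np.zeros_like(cross), True
    floor = eps * scale
    out = np.zeros_like(cross)
    keep = mag > floor
    out[keep] = cross[keep] / mag[keep]
    return out, False


def cross_phase_spectrum(
    fa: np.ndarray, fb: np.ndarray, eps: float = DEFAULT_EPS
) -> PhaseSpectrum:
    """Cross-phase spectrum R(n) of two equal-length real vectors.

    Bins whose cross-spectral magnitude is at most ``eps`` times the maximum
    magnitude are set to 0 (no reliable phase); an all-zero input yields an
    all-zero spectrum flagged ``degenerate`` rather than an error.
    """
    fa = np.asarray(fa, dtype=float)
    fb = np.asarray(fb, dtype=float)
    if fa.ndim != 1 or fb.ndim != 1:
        raise ValueError("inputs must be 1-D vectors")
    if fa.shape != fb.shape:
        raise ValueError(f"length mismatch: {fa.shape[0]} vs {fb.shape[0]}")
    if fa.size < 1:
        raise ValueError("inputs must have length >= 1")
    cross = np.fft.fft(fa) * np.conj(np.fft.fft(fb))
    factors, degenerate = _normalize_cross_spectrum(cross, eps)
    return PhaseSpectrum(phase_factors=factors, degenerate=degenerate)


def _real_inverse(spectrum: np.ndarray, inverse) -> np.ndarray:
    r = inverse(spectrum)
    scale = max(np.abs(r).max(), 1.0)
    resid = np.abs(r.imag).max()
    if resid > _IMAG_TOL * scale:
        raise ValueError(f"non-negligible imaginary residue {resid:.3g}")
    return np.ascontiguousarray(r.real)


def poc_1d(fa: np.ndarray, fb: np.ndarray, eps: float = DEFAULT_EPS) -> POCResult:
    """1-D POC function between two equal-length real vectors.

    ``correlation = Re IDFT[R]`` with the 1/T factor on the inverse
    transform, so the self-correlation peak is exactly 1.
    """
    spec = cross_phase_spectrum(fa, fb, eps=eps)
    r = _real_inverse(spec.phase_factors, np.fft.ifft)
    loc = int(np.argmax(r))
    return POCResult(correlation=r, peak_value=float(r[loc]), peak_location=loc)


def reshape_to_square(f: np.ndarray) -> np.ndarray:
    """Reshape a square-number-length vector to a p x p matrix, row-major.

    ``reshape_to_square`` then ``ravel`` is the identity.  Non-square
    lengths are rejected with the nearest admissible lengths named.
    """
    f = np.asarray(f, dtype=float)
    if f.ndim != 1:
        raise ValueError("input must be a 1-D vector")
    t = f.size
    p = int(np.sqrt(t))
    if p * p != t:
        lo, hi = nearest_squares(t)
        raise ValueError(
            f"length {t} is not a perfect square; nearest admissible lengths "
            f"are {lo} ({int(np.sqrt(lo))}^2) and {hi} ({int(np.sqrt(hi))}^2)"
        )
    return f.reshape(p, p)


def nearest_squares(t: int) -> tuple[int, int]:
    """Perfect squares bracketing ``t`` (largest <= t where possible, next above)."""
    p = int(np.sqrt(t))
    lo = max(p, 1) ** 2
    hi = (p + 1) ** 2
    if lo > t:
        lo = max(p - 1, 1) ** 2
    return lo, hi


def poc_2d(Fa: np.ndarray, Fb: np.ndarray, eps: float = DEFAULT_EPS) -> POCResult:
    """2-D POC between two equal-shape real matrices (2-D DFT / IDFT)."""
    Fa = np.asarray(Fa, dtype=float)
    Fb = np.asarray(Fb, dtype=float)
    if Fa.ndim != 2 or Fb.ndim != 2:
        raise ValueError("inputs must be 2-D matrices")
    if Fa.shape != Fb.shape:
        raise ValueError(f"shape mismatch: {Fa.shape} vs {Fb.shape}")
    cross = np.fft.fft2(Fa) * np.conj(np.fft.fft2(Fb))
    factors, _ = _normalize_cross_spectrum(cross, eps)
    r = _real_inverse(factors, np.fft.ifft2)
    flat = int(np.argmax(r))
    loc = np.unravel_index(flat, r.shape)
    return POCResult(
        correlation=r,
        peak_value=float(r[loc]),
        peak_location=(int(loc[0]), int(loc[1])),
    )
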