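"""Derivative dynamic time warping (DDTW) with a Sakoe-Chiba band.

Plain DTW on pulse amplitudes tends to align points of similar *height*
rather than similar *shape*; substituting each series with a local slope
estimate before warping (derivative DTW) aligns morphological events —
peaks, notches, shoulders — instead.  Pulses are z-normalized before
differentiation, so the measure ignores affine amplitude changes.

The dynamic program uses the classical three-move recurrence with cell cost
|s_i - t_j| and returns the raw cumulative cost (no step weights, no path
normalization).  The Sakoe-Chiba band restricts alignment to |i - j| <= w;
the default half-width is 20 samples on the 100-sample pulse grid.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .preprocess import znormalize_pulse

__all__ = [
    "derivative_series",
    "dtw_distance",
    "ddtw_distance",
    "pairwise_ddtw",
    "DEFAULT_BAND",
]

DEFAULT_BAND = 20


def derivative_series(x: np.ndarray) -> np.ndarray:
    """Local slope estimate: d[i] = ((x[i]-x[i-1]) + (x[i+1]-x[i-1])/2) / 2.

    The estimate averages the left one-step slope with the centered
    two-step slope, which damps single-sample noise; endpoints copy their
    nearest interior value.  Output has the same length as the input.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("need a 1-D series of length >= 3")
    d = np.empty_like(x)
    d[1:-1] = ((x[1:-1] - x[:-2]) + (x[2:] - x[:-2]) / 2.0) / 2.0
    d[0] = d[1]
    d[-1] = d[-2]
    return d


@njit(cache=True)
def _dtw_kernel(s: np.ndarray, t: np.ndarray, w: int) -> float:
    n, m = s.shape[0], t.shape[0]
    big = np.inf
    D = np.full((n + 1, m + 1), big)
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        if w >= 0:
            jlo = max(1, i - w)
            jhi = min(m, i + w)
        else:
            jlo, jhi = 1, m
        for j in range(jlo, jhi + 1):
            cost = abs(s[i - 1] - t[j - 1])
            best = D[i - 1, j - 1]
            if D[i - 1, j] < best:
                best = D[i - 1, j]
            if D[i, j - 1] < best:
                best = D[i, j - 1]
            D[i, j] = cost + best
    return D[n, m]


def dtw_distance(s: np.ndarray, t: np.ndarray, w: int | None = None) -> float:
    """Exact DTW alignment cost between two series, optionally banded.

    ``w`` is the Sakoe-Chiba half-width in samples (``None`` = unbanded).
    The band must be feasible: ``w >= |len(s) - len(t)|``.
    """
    s = np.asarray(s, dtype=float)
    t = np.asarray(t, dtype=float)
    if s.size == 0 or t.size == 0:
        raise ValueError("series must be nonempty")
    if w is not None:
        w = int(w)
        if w < 0:
            raise ValueError("band half-width must be >= 0")
        if w < abs(s.size - t.size):
            raise ValueError(
                f"band w={w} infeasible for lengths {s.size}, {t.size}"
            )
    return float(_dtw_kernel(s, t, -1 if w is None else w))


def _ddtw_transform(pulse: np.ndarray) -> np.ndarray:
    return derivative_series(znormalize_pulse(pulse))


def ddtw_distance(p: np.ndarray, q: np.ndarray, w: int | None = DEFAULT_BAND) -> float:
    """DDTW cost between two pulses: z-normalize, differentiate, banded DTW."""
    return dtw_distance(_ddtw_transform(p), _ddtw_transform(q), w)


@njit(cache=True)
def _pairwise_kernel(X: np.ndarray, w: int) -> np.ndarray:
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = _dtw_kernel(X[i], X[j], w)
            D[i, j] = d
            D[j, i] = d
    return D


def pairwise_ddtw(pulses: np.ndarray, w: int | None = DEFAULT_BAND) -> np.ndarray:
    """Symmetric zero-diagonal matrix of DDTW costs over all pulse pairs.

    ``pulses`` is an (n, L) array of normalized pulses (equal lengths).
    Pairs are computed once each in row-major upper-triangle order.
    """
    P = np.asarray(pulses, dtype=float)
    if P.ndim != 2 or P.shape[0] < 2:
        raise ValueError("need a 2-D array with at least 2 pulses")
    T = np.empty_like(P)
    for i in range(P.shape[0]):
        try:
            T[i] = _ddtw_transform(P[i])
        except ValueError as exc:
            raise ValueError(f"pulse {i}: {exc}") from exc
    return _pairwise_kernel(T, -1 if w is None else int(w))


def cross_ddtw(
    pulses: np.ndarray, references: np.ndarray, w: int | None = DEFAULT_BAND
) -> np.ndarray:
    """(n, m) matrix of DDTW costs from each pulse to each reference pulse."""
    P = np.asarray(pulses, dtype=float)
    R = np.asarray(references, dtype=float)
    TP = np.vstack([_ddtw_transform(p) for p in P])
    TR = np.vstack([_ddtw_transform(r) for r in R])
    wband = -1 if w is None else int(w)
    out = np.empty((TP.shape[0], TR.shape[0]))
    for i in range(TP.shape[0]):
        for j in range(TR.shape[0]):
            out[i, j] = _dtw_kernel(TP[i], TR[j], wband)
    return out
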