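"""Choosing the number of clusters: silhouette, inertia, prediction strength.

The scan runs K-medoids for every k on a grid (default 1..15) and records
three curves:

* silhouette — mean over samples of (b - a) / max(a, b), where a is the
  mean distance to the own cluster (excluding self) and b the mean distance
  to the nearest foreign cluster; singleton clusters score 0 by convention;
* inertia — mean squared distance to the own medoid (an elbow indicates a
  parsimonious k);
* prediction strength — cluster the data twice on disjoint halves, assign
  the test half to the train medoids, and take the minimum over test
  clusters of the fraction of ordered sample pairs that stay co-assigned;
  stable clusterings score near 1.

The joint selection rule keeps the k whose prediction strength clears a
threshold (default 0.7; ignored where the curve was not computed) and among
those picks the silhouette maximum, breaking ties toward the inertia-curve
elbow.  The returned k is a recommendation: the curves themselves are the
primary output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .clustering import cluster_inertia, kmedoids_fit, pairwise_euclidean

__all__ = [
    "SelectionCurves",
    "silhouette_samples_precomputed",
    "silhouette_score_precomputed",
    "prediction_strength",
    "prediction_strength_precomputed",
    "scan_k",
    "choose_k",
]


def silhouette_samples_precomputed(
    labels: np.ndarray, dissimilarity: np.ndarray
) -> np.ndarray:
    """Per-sample silhouette values from a precomputed dissimilarity matrix.

    ``a`` excludes the sample itself; members of singleton clusters score 0.
    Requires at least two non-empty clusters.
    """
    labels = np.asarray(labels)
    D = np.asarray(dissimilarity, dtype=float)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("silhouette undefined for a single cluster")
    n = len(labels)
    sizes = {c: int(np.sum(labels == c)) for c in uniq}
    s = np.zeros(n)
    for i in range(n):
        c = labels[i]
        if sizes[c] == 1:
            continue
        own = labels == c
        a = D[i, own].sum() / (sizes[c] - 1)
        b = min(D[i, labels == o].mean() for o in uniq if o != c)
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return s


def silhouette_score_precomputed(labels: np.ndarray, dissimilarity: np.ndarray) -> float:
    """Mean silhouette over all samples."""
    return float(silhouette_samples_precomputed(labels, dissimilarity).mean())


def _ps_from_parts(
    labels_te: np.ndarray, train_assign: np.ndarray, k: int
) -> float:
    """Minimum over test clusters of the co-assignment fraction of ordered pairs."""
    ps = 1.0
    for j in range(k):
        members = np.flatnonzero(labels_te == j)
        nj = members.size
        if nj <= 1:
            continue  # singleton/empty test clusters contribute 1
        counts = np.bincount(train_assign[members])
        co = float(np.sum(counts * (counts - 1)))
        ps = min(ps, co / (nj * (nj - 1)))
    return ps


def prediction_strength(
    X_tr: np.ndarray, X_te: np.ndarray, k: int, seed: int = 0
) -> float:
    """Prediction strength of K-medoids with Euclidean distances on features."""
    X_tr = np.asarray(X_tr, dtype=float)
    X_te = np.asarray(X_te, dtype=float)
    if k > min(len(X_tr), len(X_te)):
        raise ValueError("k exceeds a partition size")
    if k == 1:
        return 1.0
    fit_tr = kmedoids_fit(X_tr, k, seed=seed)
    fit_te = kmedoids_fit(X_te, k, seed=seed)
    train_assign = np.argmin(cdist(X_te, X_tr[fit_tr.medoid_indices]), axis=1)
    return _ps_from_parts(fit_te.labels, train_assign, k)


def prediction_strength_precomputed(
    D: np.ndarray, tr_idx: np.ndarray, te_idx: np.ndarray, k: int, seed: int = 0
) -> float:
    """Prediction strength from a full precomputed dissimilarity matrix."""
    D = np.asarray(D, dtype=float)
    tr_idx = np.asarray(tr_idx)
    te_idx = np.asarray(te_idx)
    if k > min(len(tr_idx), len(te_idx)):
        raise ValueError("k exceeds a partition size")
    if k == 1:
        return 1.0
    fit_tr = kmedoids_fit(D[np.ix_(tr_idx, tr_idx)], k, seed=seed, metric="precomputed")
    fit_te = kmedoids_fit(D[np.ix_(te_idx, te_idx)], k, seed=seed, metric="precomputed")
    cross = D[np.ix_(te_idx, tr_idx[fit_tr.medoid_indices])]
    train_assign = np.argmin(cross, axis=1)
    return _ps_from_parts(fit_te.labels, train_assign, k)


@dataclass
class SelectionCurves:
    """Model-selection curves over a k grid for one representation."""

    ks: np.ndarray
    silhouette: np.ndarray
    inertia: np.ndarray
    ps: np.ndarray | None = None
    method: str = ""
    chosen_k: int | None = None
    results: dict = field(default_factory=dict, repr=False)

    def to_dataframe(self) -> pd.DataFrame:
        data = {"k": self.ks, "silhouette": self.silhouette, "inertia": self.inertia}
        if self.ps is not None:
            data["ps"] = self.ps
        return pd.DataFrame(data)


def scan_k(
    data: np.ndarray,
    k_range=range(1, 16),
    metric: str = "euclidean",
    method: str = "",
    seed: int = 0,
    compute_ps: bool = False,
    ps_split: float = 0.5,
) -> SelectionCurves:
    """Fit K-medoids across a k grid and record the three selection curves.

    Silhouette is NaN at k=1 and k=n (undefined / degenerate).  Prediction
    strength (optional; it requires 2 extra fits per k on half-size data)
    uses a seeded half/half split of the input.
    """
    if metric == "precomputed":
        D = np.asarray(data, dtype=float)
    else:
        D = pairwise_euclidean(data)
    n = D.shape[0]
    ks = np.array([k for k in k_range if 1 <= k <= n], dtype=int)
    sil = np.full(len(ks), np.nan)
    inertia = np.empty(len(ks))
    ps = np.full(len(ks), np.nan) if compute_ps else None
    results: dict[int, object] = {}

    if compute_ps:
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        n_tr = int(round(ps_split * n))
        tr_idx, te_idx = perm[:n_tr], perm[n_tr:]

    for pos, k in enumerate(ks):
        res = kmedoids_fit(D, int(k), seed=seed, metric="precomputed")
        results[int(k)] = res
        inertia[pos] = cluster_inertia(res, D, kind="mean")
        if 1 < k < n:
            sil[pos] = silhouette_score_precomputed(res.labels, D)
        if compute_ps and k <= min(len(tr_idx), len(te_idx)):
            ps[pos] = prediction_strength_precomputed(D, tr_idx, te_idx, int(k), seed=seed)

    curves = SelectionCurves(
        ks=ks, silhouette=sil, inertia=inertia, ps=ps, method=method, results=results
    )
    curves.chosen_k = choose_k(curves)
    return curves


def _elbow_k(ks: np.ndarray, inertia: np.ndarray) -> int:
    """k with maximum perpendicular distance to the chord joining the curve ends."""
    x = (ks - ks[0]) / max(ks[-1] - ks[0], 1)
    rng_y = inertia.max() - inertia.min()
    y = (inertia - inertia.min()) / (rng_y if rng_y > 0 else 1.0)
    # distance from (x, y) to the line through (x0, y0) and (x1, y1)
    dx, dy = x[-1] - x[0], y[-1] - y[0]
    norm = np.hypot(dx, dy)
    dist = np.abs(dy * (x - x[0]) - dx * (y - y[0])) / (norm if norm > 0 else 1.0)
    return int(ks[np.argmax(dist)])


def choose_k(curves: SelectionCurves, ps_threshold: float = 0.7) -> int:
    """Joint selection: silhouette argmax among prediction-strength-feasible k.

    Ties (silhouette within 1e-12) are broken toward the inertia elbow.
    If no k clears the threshold, falls back to the unrestricted silhouette
    argmax with a warning.
    """
    valid = np.isfinite(curves.silhouette)
    if not valid.any():
        raise ValueError("no k with a defined silhouette score")
    feasible = valid.copy()
    if curves.ps is not None:
        with np.errstate(invalid="ignore"):
            feasible &= ~(curves.ps < ps_threshold)
        if not feasible.any():
            warnings.warn(
                "prediction strength below threshold everywhere; "
                "falling back to silhouette argmax",
                stacklevel=2,
            )
            feasible = valid
    best = np.nanmax(np.where(feasible, curves.silhouette, -np.inf))
    tied = feasible & (curves.silhouette >= best - 1e-12)
    if tied.sum() > 1:
        elbow = _elbow_k(curves.ks, curves.inertia)
        if elbow in curves.ks[tied]:
            return elbow
    return int(curves.ks[np.argmax(np.where(tied, curves.silhouette, -np.inf))])
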