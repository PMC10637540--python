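"""K-medoids (PAM) clustering over feature matrices or precomputed dissimilarities.

Three usage modes mirror the experimental design of the pipeline:

* ``baseline`` — free PAM with k fixed (typically 4),
* ``template`` — cluster centers held fixed at externally supplied
  reference pulses (e.g., the four canonical notch-class templates) and
  every pulse assigned to its nearest template,
* ``optimal`` — free PAM at a k chosen by model selection.

PAM is the classical BUILD + SWAP formulation: greedy initialization that
successively adds the medoid with the largest cost reduction, then
first-improvement-free full SWAP scans until no single medoid/non-medoid
exchange lowers the total dissimilarity.  Deterministic given the input
order; the objective is non-increasing across swaps by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "ClusterResult",
    "pairwise_euclidean",
    "kmedoids_fit",
    "assign_fixed_medoids",
    "cluster_inertia",
]


@dataclass
class ClusterResult:
    """Labels, medoids and objective of one clustering run.

    ``medoid_indices[j]`` is the dataset index of the center of cluster j
    (for template mode: the index into the supplied template set).
    ``objective`` is the sum over samples of the dissimilarity to the own
    medoid.
    """

    labels: np.ndarray
    medoid_indices: np.ndarray
    k: int
    mode: str
    objective: float
    meta: dict = field(default_factory=dict)


def pairwise_euclidean(X: np.ndarray) -> np.ndarray:
    """Symmetric Euclidean distance matrix of a feature matrix."""
    X = np.asarray(X, dtype=float)
    D = cdist(X, X)
    np.fill_diagonal(D, 0.0)
    return D


def _validate_square(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("dissimilarity matrix must be symmetric")
    if (D < -1e-12).any():
        raise ValueError("dissimilarities must be nonnegative")
    return D


def _build(D: np.ndarray, k: int) -> list[int]:
    n = D.shape[0]
    medoids = [int(np.argmin(D.sum(axis=0)))]
    nearest = D[:, medoids[0]].copy()
    while len(medoids) < k:
        # gain of adding candidate c: sum_j max(0, nearest_j - D[j, c])
        gains = np.maximum(nearest[:, None] - D, 0.0).sum(axis=0)
        gains[medoids] = -np.inf
        c = int(np.argmax(gains))
        medoids.append(c)
        nearest = np.minimum(nearest, D[:, c])
    return medoids


def _nearest_two(D: np.ndarray, medoids: np.ndarray):
    sub = D[:, medoids]
    order = np.argsort(sub, axis=1, kind="stable")
    nearest_m = order[:, 0]
    nearest_d = sub[np.arange(len(sub)), nearest_m]
    if len(medoids) > 1:
        second_d = sub[np.arange(len(sub)), order[:, 1]]
    else:
        second_d = np.full(len(sub), np.inf)
    return nearest_m, nearest_d, second_d


def kmedoids_fit(
    data: np.ndarray,
    k: int,
    seed: int = 0,
    metric: str = "euclidean",
    max_iter: int = 300,
    mode: str = "baseline",
) -> ClusterResult:
    """PAM K-medoids on a feature matrix or a precomputed dissimilarity matrix.

    Parameters
    ----------
    data : feature matrix (``metric='euclidean'``) or square symmetric
        dissimilarity matrix with zero diagonal (``metric='precomputed'``).
    k : number of clusters, ``1 <= k <= n``.
    seed : accepted for interface stability; BUILD+SWAP with deterministic
        lowest-index tie-breaks does not consume randomness.
    """
    if metric == "precomputed":
        D = _validate_square(data)
    elif metric == "euclidean":
        D = pairwise_euclidean(data)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    n = D.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} must be in 1..{n}")

    medoids = np.array(_build(D, k), dtype=int)
    nearest_m, nearest_d, second_d = _nearest_two(D, medoids)
    objective = float(nearest_d.sum())

    for _ in range(max_iter):
        best_delta, best_swap = -1e-12, None
        is_medoid = np.zeros(n, dtype=bool)
        is_medoid[medoids] = True
        for h in np.flatnonzero(~is_medoid):
            dh = D[:, h]
            common = np.minimum(dh - nearest_d, 0.0)
            total_common = common.sum()
            for mi in range(k):
                in_m = nearest_m == mi
                delta = (
                    total_common
                    - common[in_m].sum()
                    + (np.minimum(dh[in_m], second_d[in_m]) - nearest_d[in_m]).sum()
                )
                if delta < best_delta:
                    best_delta, best_swap = delta, (mi, h)
        if best_swap is None:
            break
        mi, h = best_swap
        medoids[mi] = h
        nearest_m, nearest_d, second_d = _nearest_two(D, medoids)
        new_objective = float(nearest_d.sum())
        assert new_objective <= objective + 1e-9, "PAM objective increased"
        objective = new_objective

    # canonical ordering: medoids ascending by dataset index
    order = np.argsort(medoids)
    medoids = medoids[order]
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    labels = remap[nearest_m]
    return ClusterResult(
        labels=labels,
        medoid_indices=medoids,
        k=k,
        mode=mode,
        objective=objective,
        meta={"seed": seed, "metric": metric},
    )


def assign_fixed_medoids(
    dissimilarity_to_templates: np.ndarray,
    refine: bool = False,
    pairwise: np.ndarray | None = None,
    max_iter: int = 50,
) -> ClusterResult:
    """Template-mode clustering: centers fixed at external reference pulses.

    ``dissimilarity_to_templates`` is the (n_pulses, m_templates) distance
    matrix; each pulse is assigned to its nearest template, ties broken
    toward the lowest template index.  With ``refine=True`` (requires the
    full ``pairwise`` pulse dissimilarity matrix) the template-seeded
    partition is instead iteratively re-medoided within the dataset.
    """
    C = np.asarray(dissimilarity_to_templates, dtype=float)
    if C.ndim != 2 or C.shape[1] < 1:
        raise ValueError("need an (n_pulses, n_templates) matrix")
    m = C.shape[1]
    labels = np.argmin(C, axis=1)
    objective = float(C[np.arange(C.shape[0]), labels].sum())

    if not refine:
        return ClusterResult(
            labels=labels,
            medoid_indices=np.arange(m),
            k=m,
            mode="template",
            objective=objective,
            meta={"refined": False},
        )

    if pairwise is None:
        raise ValueError("refine=True requires the full pairwise matrix")
    D = _validate_square(pairwise)
    medoids = np.array(
        [int(np.argmin(np.where(labels == j, C[:, j], np.inf))) for j in range(m)]
    )
    for _ in range(max_iter):
        labels_new = np.argmin(D[:, medoids], axis=1)
        medoids_new = medoids.copy()
        for j in range(m):
            members = np.flatnonzero(labels_new == j)
            if members.size:
                medoids_new[j] = members[np.argmin(D[np.ix_(members, members)].sum(axis=1))]
        if np.array_equal(medoids_new, medoids) and np.array_equal(labels_new, labels):
            break
        medoids, labels = medoids_new, labels_new
    objective = float(D[np.arange(D.shape[0]), medoids[labels]].sum())
    return ClusterResult(
        labels=labels,
        medoid_indices=medoids,
        k=m,
        mode="template",
        objective=objective,
        meta={"refined": True},
    )


def cluster_inertia(
    result: ClusterResult,
    dissimilarity: np.ndarray,
    kind: str = "mean",
) -> float:
    """Squared distance of each sample to its cluster center, aggregated.

    ``kind='mean'`` (default) averages over samples, which keeps the value
    comparable across representations with different distance scales;
    ``kind='sum'`` returns the raw sum.  ``dissimilarity`` is either the
    square pulse matrix (free modes) or the pulses-to-templates matrix
    (template mode without refinement).
    """
    D = np.asarray(dissimilarity, dtype=float)
    n = len(result.labels)
    if result.mode == "template" and not result.meta.get("refined", False):
        d_own = D[np.arange(n), result.labels]
    else:
        d_own = D[np.arange(n), result.medoid_indices[result.labels]]
    sq = float(np.sum(d_own**2))
    if kind == "sum":
        return sq
    if kind == "mean":
        return sq / n
    raise ValueError(f"unknown kind {kind!r}")
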