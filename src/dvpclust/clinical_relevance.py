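"""Do the pulse-shape clusters separate clinical covariates?

Three complementary views:

* per-cluster normalized means (the values behind a radar plot),
* hypothesis tests — Kruskal-Wallis across clusters per variable, followed
  (only where significant) by pairwise Welch t-tests with Holm adjustment,
* a weighted quantile-distance statistic d: for each pair of clusters the
  distance between the empirical quantile functions of the covariate is
  computed on a fixed probability grid, deliberately *keeping* location
  shifts (a cluster of uniformly older subjects should count as different);
  pairs are averaged with cluster-size weights w_n = N_n / N, penalising
  tiny clusters:

      d = 1/(k(k-1)) * sum_i w_i * sum_{j != i} w_j * dist(i, j).

  Larger d = the clustering separates that covariate's distribution better.
  The default pair distance is the mean absolute quantile gap (the
  1-Wasserstein distance between the empirical distributions); a
  root-mean-square variant is available.  Covariates are min-max normalized
  over the full dataset by default so that d is comparable across variables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CLINICAL_VARIABLES",
    "CSMReport",
    "TestReport",
    "cluster_means_normalized",
    "kruskal_then_welch",
    "quantile_distance",
    "csm_weighted_distance",
    "csm_table",
]

CLINICAL_VARIABLES = ["age", "weight", "height", "PWV", "PAS", "PAD", "BMI", "BPM", "TT"]


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = np.min(x), np.max(x)
    if hi == lo:
        return np.zeros_like(x, dtype=float)
    return (x - lo) / (hi - lo)


def cluster_means_normalized(
    labels: np.ndarray,
    clinical: pd.DataFrame,
    variables: list[str] | None = None,
) -> pd.DataFrame:
    """Per-cluster means of min-max-normalized covariates (radar-plot values).

    Normalization is over the full dataset, so all entries lie in [0, 1].
    Clusters absent from ``labels`` simply do not appear as rows.
    """
    variables = variables or [v for v in CLINICAL_VARIABLES if v in clinical.columns]
    labels = np.asarray(labels)
    if len(labels) != len(clinical):
        raise ValueError("labels and clinical table must align row-for-row")
    norm = pd.DataFrame(
        {v: _minmax(clinical[v].to_numpy(dtype=float)) for v in variables}
    )
    norm["cluster"] = labels
    return norm.groupby("cluster").mean()


@dataclass
class TestReport:
    """Kruskal-Wallis screen plus Welch post-hoc pairs (Holm-adjusted)."""

    kruskal: pd.DataFrame
    welch: pd.DataFrame
    alpha: float


def kruskal_then_welch(
    labels: np.ndarray,
    clinical: pd.DataFrame,
    alpha: float = 0.05,
    variables: list[str] | None = None,
) -> TestReport:
    """Screen each covariate with Kruskal-Wallis; follow up significant ones.

    Post-hoc: all pairwise Welch (unequal-variance) t-tests with Holm
    adjustment, run only for variables whose Kruskal-Wallis null (equal
    mean ranks) is rejected at ``alpha``.  Variables with fewer than two
    usable clusters (size >= 2) are skipped with a warning.
    """
    variables = variables or [v for v in CLINICAL_VARIABLES if v in clinical.columns]
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    kw_rows, welch_rows = [], []
    for v in variables:
        x = clinical[v].to_numpy(dtype=float)
        groups = {c: x[labels == c] for c in uniq}
        usable = {c: g for c, g in groups.items() if g.size >= 2}
        if len(usable) < 2:
            warnings.warn(f"variable {v!r}: fewer than 2 clusters of size >= 2; skipped")
            continue
        try:
            stat, p = stats.kruskal(*usable.values())
        except ValueError as exc:  # all values identical
            warnings.warn(f"variable {v!r}: Kruskal-Wallis undefined ({exc}); skipped")
            continue
        significant = bool(p < alpha)
        kw_rows.append((v, float(stat), float(p), significant))
        if not significant:
            continue
        pairs, praw = [], []
        cs = sorted(usable)
        for a_i in range(len(cs)):
            for b_i in range(a_i + 1, len(cs)):
                ca, cb = cs[a_i], cs[b_i]
                t, pw = stats.ttest_ind(usable[ca], usable[cb], equal_var=False)
                pairs.append((ca, cb, float(t)))
                praw.append(float(pw))
        reject, padj, _, _ = multipletests(praw, alpha=alpha, method="holm")
        for (ca, cb, t), pr, pa, rj in zip(pairs, praw, padj, reject):
            welch_rows.append((v, ca, cb, t, pr, float(pa), bool(rj)))

    kruskal = pd.DataFrame(
        kw_rows, columns=["variable", "statistic", "p", "significant"]
    )
    welch = pd.DataFrame(
        welch_rows,
        columns=["variable", "cluster_i", "cluster_j", "statistic", "p_raw", "p_adj", "significant"],
    )
    return TestReport(kruskal=kruskal, welch=welch, alpha=alpha)


def quantile_distance(
    values_i: np.ndarray,
    values_j: np.ndarray,
    grid_size: int = 100,
    kind: str = "mean_abs",
) -> float:
    """Distance between two empirical quantile functions on a midpoint grid.

    Quantiles are evaluated at probabilities (q - 0.5)/Q, q = 1..Q, by
    linear interpolation of the order statistics.  ``kind='mean_abs'``
    (default) is the 1-Wasserstein distance between the two empirical
    distributions; ``kind='rms'`` is the root-mean-square gap.  Both are
    sensitive to pure location shifts: shifting one sample by c changes the
    distance by exactly |c|.
    """
    vi = np.asarray(values_i, dtype=float)
    vj = np.asarray(values_j, dtype=float)
    if vi.size == 0 or vj.size == 0:
        raise ValueError("samples must be non-empty")
    probs = (np.arange(1, grid_size + 1) - 0.5) / grid_size
    qi = np.quantile(vi, probs)
    qj = np.quantile(vj, probs)
    gap = np.abs(qi - qj)
    if kind == "mean_abs":
        return float(gap.mean())
    if kind == "rms":
        return float(np.sqrt(np.mean(gap**2)))
    raise ValueError(f"unknown kind {kind!r}")


@dataclass
class CSMReport:
    """Weighted quantile-distance summary of one covariate over one clustering."""

    k: int
    weights: np.ndarray
    dist: np.ndarray
    d: float
    variable: str = ""
    normalization: str = "minmax"


def csm_weighted_distance(
    labels: np.ndarray,
    values: np.ndarray,
    normalization: str = "minmax",
    grid_size: int = 100,
    kind: str = "mean_abs",
    variable: str = "",
) -> CSMReport:
    """Size-weighted average of pairwise cluster quantile distances.

    ``normalization='minmax'`` rescales the covariate to [0, 1] over the
    full dataset before computing distances (making d comparable across
    covariates); ``'identity'`` uses raw values, in which case d is
    positively homogeneous: scaling all values by c > 0 scales d by c.
    """
    labels = np.asarray(labels)
    values = np.asarray(values, dtype=float)
    if len(labels) != len(values):
        raise ValueError("labels and values must align")
    if normalization == "minmax":
        values = _minmax(values)
    elif normalization != "identity":
        raise ValueError(f"unknown normalization {normalization!r}")
    uniq = np.unique(labels)
    k = uniq.size
    if k < 2:
        raise ValueError("need at least 2 clusters")
    groups = [values[labels == c] for c in uniq]
    weights = np.array([g.size for g in groups], dtype=float)
    weights /= weights.sum()
    dist = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            dist[i, j] = dist[j, i] = quantile_distance(
                groups[i], groups[j], grid_size=grid_size, kind=kind
            )
    d = 0.0
    for i in range(k):
        for j in range(k):
            if i != j:
                d += weights[i] * weights[j] * dist[i, j]
    d /= k * (k - 1)
    return CSMReport(
        k=k, weights=weights, dist=dist, d=float(d),
        variable=variable, normalization=normalization,
    )


def csm_table(
    labels: np.ndarray,
    clinical: pd.DataFrame,
    variables: list[str] | None = None,
    **kwargs,
) -> pd.DataFrame:
    """One row per covariate with its weighted quantile-distance d."""
    variables = variables or [v for v in CLINICAL_VARIABLES if v in clinical.columns]
    rows = [
        (v, csm_weighted_distance(labels, clinical[v].to_numpy(dtype=float),
                                  variable=v, **kwargs).d)
        for v in variables
    ]
    return pd.DataFrame(rows, columns=["variable", "d"])
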