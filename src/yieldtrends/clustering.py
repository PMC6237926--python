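"""Era-wise UPGMA clustering of departments on mean yield levels.

Departments are clustered within ~30-year eras using the Euclidean
distance between era-mean yields as dissimilarity and unweighted
average linkage (UPGMA).  The extreme 1% of departments at each end is
trimmed first so single outliers do not dominate the dendrogram.  The
cluster count k is chosen by exhaustively maximizing the
Calinski-Harabasz index CH(k) = [B/(k-1)] / [W/(n-k)] over a candidate
range, where B and W are between- and within-cluster sums of squares.
Labels are canonicalized by ascending cluster mean yield.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .panel import YieldPanel

__all__ = [
    "DEFAULT_ERAS",
    "ClusterResult",
    "era_mean_yields",
    "trim_extremes",
    "calinski_harabasz",
    "upgma_cluster",
]

#: Four consecutive ~30-year eras spanning the panel.
DEFAULT_ERAS = ((1900, 1929), (1930, 1959), (1960, 1989), (1990, 2016))


@dataclass
class ClusterResult:
    crop: str | None
    era: tuple[int, int] | None
    assignment: dict[str, int]  # department -> 1..k, ordered by cluster mean
    k: int
    ch_curve: dict[int, float]  # candidate k -> CH index
    cluster_means: dict[int, float]
    linkage: np.ndarray | None = None
    unclustered: tuple[str, ...] = ()


def era_mean_yields(
    panel: YieldPanel,
    crop: str,
    era: tuple[int, int],
    season_type: str = "aggregate",
    min_years: int = 5,
) -> pd.Series:
    """Per-department mean of non-missing yields within the era.

    Departments with fewer than ``min_years`` observed years are
    excluded.  Returns a Series indexed by department_id.
    """
    df = panel.df
    m = (
        (df["crop"] == crop)
        & (df["season_type"] == season_type)
        & df["year"].between(*era)
        & df["yield_t_ha"].notna()
    )
    g = df.loc[m].groupby("department_id")["yield_t_ha"]
    means = g.mean()
    counts = g.count()
    return means[counts >= min_years].sort_index()


def trim_extremes(values: pd.Series, fraction: float = 0.01) -> pd.Series:
    """Drop the ceil(fraction*n) smallest and largest values.

    Ties are broken by department ID order so trimming is
    deterministic.  Raises if fewer than 3 values remain.
    """
    if not (0.0 <= fraction < 0.5):
        raise ValueError("trim fraction must be in [0, 0.5)")
    if fraction == 0.0:
        return values.copy()
    n = len(values)
    m = math.ceil(fraction * n)
    ordered = values.sort_index().sort_values(kind="mergesort")  # ID order on ties
    kept = ordered.iloc[m: n - m]
    if len(kept) < 3:
        raise ValueError("fewer than 3 values remain after trimming")
    return kept.sort_index()


def calinski_harabasz(values: np.ndarray, labels: np.ndarray) -> float:
    """CH(k) = [B/(k-1)] / [W/(n-k)] for scalar observations."""
    values = np.asarray(values, float)
    labels = np.asarray(labels)
    n = len(values)
    ks = np.unique(labels)
    k = len(ks)
    if k < 2 or k >= n:
        raise ValueError("CH index requires 2 <= k <= n-1")
    grand = values.mean()
    B = W = 0.0
    for lab in ks:
        v = values[labels == lab]
        B += len(v) * (v.mean() - grand) ** 2
        W += float(np.sum((v - v.mean()) ** 2))
    if W == 0.0:
        return math.inf
    return (B / (k - 1)) / (W / (n - k))


def upgma_cluster(
    values: pd.Series,
    k_range: range | None = None,
    crop: str | None = None,
    era: tuple[int, int] | None = None,
    unclustered: tuple[str, ...] = (),
) -> ClusterResult:
    """UPGMA dendrogram on scalar values with CH-optimal cut.

    ``values`` maps department IDs to era-mean yields.  The dendrogram
    is cut at every k in ``k_range`` (default 2..min(10, n-1)); the k
    with the largest CH index wins.  All-identical values are a
    degenerate case reported as a single cluster with an empty CH
    curve.
    """
    depts = list(values.index)
    x = values.to_numpy(float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 departments to cluster")
    if np.ptp(x) == 0.0:
        return ClusterResult(
            crop, era, {d: 1 for d in depts}, 1, {}, {1: float(x[0])},
            None, unclustered,
        )
    Z = hierarchy.linkage(pdist(x[:, None]), method="average")
    if k_range is None:
        # cap candidate k so clusters average >= 4 members: for scalar
        # data the CH index diverges as clusters shrink toward
        # singletons (W -> 0), which would always favour the largest k
        k_range = range(2, min(10, max(2, n // 4)) + 1)
    ch_curve: dict[int, float] = {}
    labelings: dict[int, np.ndarray] = {}
    for k in k_range:
        if not (2 <= k <= n - 1):
            continue
        labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
        if len(np.unique(labels)) != k:
            continue  # unreachable cut (ties); skip this k
        ch_curve[k] = calinski_harabasz(x, labels)
        labelings[k] = labels
    if not ch_curve:
        raise ValueError("no candidate k produced a valid clustering")
    best_k = max(ch_curve, key=lambda k: (ch_curve[k], -k))
    labels = labelings[best_k]
    # canonicalize: relabel 1..k by ascending cluster mean
    means = {lab: float(x[labels == lab].mean()) for lab in np.unique(labels)}
    order = sorted(means, key=means.get)
    remap = {old: i + 1 for i, old in enumerate(order)}
    assignment = {d: remap[lab] for d, lab in zip(depts, labels)}
    cluster_means = {remap[lab]: means[lab] for lab in order}
    return ClusterResult(
        crop, era, assignment, best_k, ch_curve, cluster_means, Z, unclustered
    )
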