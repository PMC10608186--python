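"""Hierarchical clustering of standardized nocturnal glucose series.

Series are clustered agglomeratively with Ward's minimum-variance criterion
on Euclidean distances between the 72-dimensional standardized vectors.  The
number of clusters is chosen as the silhouette-score maximum over a candidate
range (with an operator override standing in for expert judgement), clusters
are represented by their medoids, and per-cluster glucose summaries are
computed on the original mmol/L series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform, pdist
from sklearn.metrics import silhouette_score as _sklearn_silhouette

from .cgm_io import NocturnalSegment, StandardizedSegment
from .nh_detection import NHEpisode, first_episode_start_time


def as_matrix(data) -> np.ndarray:
    """Stack segments (standardized or raw arrays) into an (n, 72) float matrix."""
    if isinstance(data, np.ndarray):
        return np.atleast_2d(np.asarray(data, dtype=float))
    rows = []
    for item in data:
        if isinstance(item, StandardizedSegment):
            rows.append(item.zvalues)
        elif isinstance(item, NocturnalSegment):
            rows.append(item.values)
        else:
            rows.append(np.asarray(item, dtype=float))
    return np.asarray(rows, dtype=float)


@dataclass
class ClusterSolution:
    """One Ward partition: labels 1..k (1 = largest cluster), linkage tree, silhouette."""

    k: int
    labels: np.ndarray
    linkage: np.ndarray
    silhouette: float
    group: str | None = None


@dataclass
class ClusterSummary:
    """Tables-style summary of one cluster in mmol/L (and decimal hours for NH timing)."""

    cluster_id: int
    n_members: int
    initial_glucose: dict
    final_glucose: dict
    glucose_change: dict
    nh_start_time: dict | None
    medoid_index: int


def _relabel_by_size(raw_labels: np.ndarray) -> np.ndarray:
    """Renumber cluster labels so label 1 is the largest cluster.

    Ties in size break by the smallest first-occurrence index, which keeps
    the numbering deterministic under input permutation up to relabelling.
    """
    ids, first_pos = np.unique(raw_labels, return_index=True)
    sizes = np.array([(raw_labels == i).sum() for i in ids])
    order = sorted(range(len(ids)), key=lambda j: (-sizes[j], first_pos[j]))
    mapping = {ids[j]: rank + 1 for rank, j in enumerate(order)}
    return np.array([mapping[l] for l in raw_labels], dtype=int)


def silhouette(data, labels) -> float:
    """Mean silhouette score on Euclidean distances.

    For each point, a is its mean distance to its own cluster and b the
    smallest mean distance to another cluster; the point scores
    (b - a)/max(a, b), with points in singleton clusters scoring 0.
    """
    X = as_matrix(data)
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("silhouette is undefined for a single cluster")
    if len(X) < 3:
        raise ValueError("silhouette needs at least 3 points")
    if (counts == 0).any():
        raise ValueError("empty cluster")
    return float(_sklearn_silhouette(X, labels, metric="euclidean"))


def hierarchical_cluster(data, k: int, group: str | None = None) -> ClusterSolution:
    """Ward/Euclidean agglomeration cut to exactly ``k`` clusters.

    At each step the pair of clusters whose merge least increases the total
    within-cluster variance is joined; merge heights are guaranteed
    non-decreasing.  Labels are renumbered by decreasing cluster size.
    """
    X = as_matrix(data)
    n = len(X)
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > n:
        raise ValueError(f"cannot form {k} clusters from {n} segments")
    Z = linkage(X, method="ward")
    labels = _relabel_by_size(fcluster(Z, t=k, criterion="maxclust"))
    # all-tie merges can leave fewer than k clusters; silhouette is undefined then
    score = silhouette(X, labels) if len(np.unique(labels)) >= 2 else float("nan")
    return ClusterSolution(k=k, labels=labels, linkage=Z, silhouette=score, group=group)


@dataclass
class KSelection:
    """Result of the silhouette scan over candidate cluster counts."""

    k_best: int
    ks: np.ndarray
    scores: np.ndarray
    solution: ClusterSolution
    overridden: bool = False

    def curve_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"k": self.ks, "silhouette": self.scores})


def select_k(
    data,
    k_min: int = 2,
    k_max: int = 15,
    override: int | None = None,
    tie_tol: float = 0.0,
    group: str | None = None,
) -> KSelection:
    """Scan k in [k_min, k_max], return the silhouette curve and the argmax.

    Ties (scores within ``tie_tol`` of the maximum) resolve to the smallest
    k.  ``override`` pins the returned solution to a specific k — the
    reproducible stand-in for expert review — while the full curve is still
    reported.
    """
    X = as_matrix(data)
    n = len(X)
    k_max = min(k_max, n - 1)
    if k_min < 2 or k_min > k_max:
        raise ValueError(f"empty or invalid k range [{k_min}, {k_max}] for n={n}")
    Z = linkage(X, method="ward")
    ks = np.arange(k_min, k_max + 1)
    scores = np.empty(len(ks))
    labels_by_k = {}
    for i, k in enumerate(ks):
        labels = _relabel_by_size(fcluster(Z, t=int(k), criterion="maxclust"))
        labels_by_k[int(k)] = labels
        scores[i] = silhouette(X, labels)
    best = scores.max()
    k_best = int(ks[np.flatnonzero(scores >= best - tie_tol)[0]])
    k_used = int(override) if override is not None else k_best
    if k_used in labels_by_k:
        labels = labels_by_k[k_used]
        sol = ClusterSolution(
            k=k_used, labels=labels, linkage=Z,
            silhouette=float(scores[list(ks).index(k_used)]), group=group,
        )
    else:
        sol = hierarchical_cluster(X, k_used, group=group)
    return KSelection(
        k_best=k_best, ks=ks, scores=scores, solution=sol,
        overridden=override is not None,
    )


def medoid(members) -> int:
    """Index of the member minimizing the summed Euclidean distance to all
    other members; ties break to the lowest index."""
    X = as_matrix(members)
    if len(X) == 0:
        raise ValueError("empty cluster has no medoid")
    if len(X) == 1:
        return 0
    D = squareform(pdist(X, metric="euclidean"))
    return int(np.argmin(D.sum(axis=1)))


def _five_number(values: np.ndarray) -> dict:
    """median, linear-interpolation quartiles, min, max."""
    values = np.asarray(values, dtype=float)
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "min": float(values.min()),
        "max": float(values.max()),
    }


def summarize_cluster(
    members: list[NocturnalSegment],
    episodes: list[list[NHEpisode]] | None = None,
    cluster_id: int = 1,
    standardized_members=None,
) -> ClusterSummary:
    """Summarize one cluster on the mmol/L scale.

    Per member: initial glucose = mean of slots 0-2, final = mean of slots
    69-71, change = final - initial; for NH clusters the start time of the
    first episode.  Statistics across members are median, quartiles
    (linear interpolation), min and max.  The medoid is computed on the
    standardized members when supplied (matching the clustering geometry),
    otherwise on the raw series.
    """
    if not members:
        raise ValueError("cannot summarize an empty cluster")
    values = as_matrix(members)
    initial = values[:, :3].mean(axis=1)
    final = values[:, -3:].mean(axis=1)
    change = final - initial

    nh_stats = None
    if episodes is not None:
        starts = [
            t for t in (first_episode_start_time(eps) for eps in episodes) if t is not None
        ]
        if starts:
            nh_stats = _five_number(np.array(starts))

    medoid_members = standardized_members if standardized_members is not None else members
    return ClusterSummary(
        cluster_id=cluster_id,
        n_members=len(members),
        initial_glucose=_five_number(initial),
        final_glucose=_five_number(final),
        glucose_change=_five_number(change),
        nh_start_time=nh_stats,
        medoid_index=medoid(medoid_members),
    )


def summaries_to_frame(summaries: list[ClusterSummary]) -> pd.DataFrame:
    """Long-format summary table mirroring the per-cluster parameter layout."""
    rows = []
    for s in summaries:
        params = {
            "initial_glucose_mmol_l": s.initial_glucose,
            "final_glucose_mmol_l": s.final_glucose,
            "glucose_change_mmol_l": s.glucose_change,
        }
        if s.nh_start_time is not None:
            params["nh_start_time_h"] = s.nh_start_time
        for name, stats in params.items():
            rows.append(
                {"cluster": s.cluster_id, "n_members": s.n_members, "parameter": name, **stats}
            )
    return pd.DataFrame(rows)
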