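"""Agglomerative Ward clustering with silhouette-based model selection.

The linkage is computed with the Lance-Williams recurrence on squared
Euclidean distances: at each step the pair of clusters whose merge minimally
increases the total within-cluster sum of squares (dESS) is joined, and the
recorded merge height is sqrt(2 * dESS) — so a merge of two singletons
records their plain Euclidean distance.  Distances are Euclidean on the raw
feature units (mmHg, mmHg, BPM); optional z-scoring is available for
sensitivity analysis.  The number of clusters is chosen as the silhouette
local maximum with the largest mean silhouette over a configurable k range.

``WardSilhouetteClustering`` wraps the procedure as a scikit-learn estimator
(fit / fit_predict, trailing-underscore fitted attributes) so it composes
with sklearn model-selection tooling; the module-level functions are the
thin functional surface over the same code.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_array

__all__ = [
    "Linkage",
    "ClusteringResult",
    "WardSilhouetteClustering",
    "distance_matrix",
    "ward_linkage",
    "cut_tree",
    "silhouette",
    "select_k",
    "cluster_cohort",
]

logger = logging.getLogger(__name__)

HEIGHT_CONVENTION = "sqrt(2*delta_ESS)"


@dataclass(frozen=True)
class Linkage:
    """Ordered merge steps of an agglomerative clustering.

    ``merges[t] = (left_id, right_id, height, size)`` with original points
    numbered 0..n-1 and the cluster created at step t numbered n+t (the
    scipy convention).  Heights are non-decreasing for Ward.
    """

    merges: tuple[tuple[int, int, float, int], ...]
    n: int

    def __post_init__(self) -> None:
        if len(self.merges) != self.n - 1:
            raise ValueError(f"expected {self.n - 1} merges for {self.n} leaves")
        heights = [m[2] for m in self.merges]
        if any(h < -1e-9 for h in heights):
            raise ValueError("merge heights must be non-negative")
        if any(b < a - 1e-9 for a, b in zip(heights, heights[1:])):
            raise ValueError("merge heights must be non-decreasing")

    def to_scipy(self) -> np.ndarray:
        """(n-1, 4) array in scipy.cluster.hierarchy linkage format."""
        return np.array([[l, r, h, s] for l, r, h, s in self.merges], dtype=float)

    def to_json(self) -> str:
        return json.dumps({
            "n": self.n,
            "height_convention": HEIGHT_CONVENTION,
            "merges": [
                {"left": l, "right": r, "height": h, "size": s}
                for l, r, h, s in self.merges
            ],
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "Linkage":
        obj = json.loads(text)
        merges = tuple(
            (int(m["left"]), int(m["right"]), float(m["height"]), int(m["size"]))
            for m in obj["merges"]
        )
        return cls(merges=merges, n=int(obj["n"]))


@dataclass
class ClusteringResult:
    linkage: Linkage
    k: int
    assignments: np.ndarray  # labels 1..k aligned with input rows
    silhouette_profile: dict[int, float]
    subject_ids: list[str] | None = None

    @property
    def silhouette_score(self) -> float:
        return self.silhouette_profile[self.k]

    def assignments_frame(self) -> pd.DataFrame:
        ids = self.subject_ids or [str(i) for i in range(len(self.assignments))]
        return pd.DataFrame({"subject_id": ids, "cluster": self.assignments})


def distance_matrix(features: np.ndarray, subject_ids: list[str] | None = None) -> np.ndarray:
    """Pairwise Euclidean distances on raw feature units."""
    x = np.asarray(features, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D feature matrix with >= 2 rows")
    bad = ~np.isfinite(x)
    if bad.any():
        i = int(np.nonzero(bad.any(axis=1))[0][0])
        who = subject_ids[i] if subject_ids else f"row {i}"
        raise ValueError(f"non-finite feature value for subject {who}")
    sq = np.sum(x**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2 * x @ x.T
    np.fill_diagonal(d2, 0.0)
    return np.sqrt(np.maximum(d2, 0.0))


def ward_linkage(distances: np.ndarray) -> Linkage:
    """Ward's-method linkage via the Lance-Williams recurrence.

    Works on squared distances D2 maintained so that D2[i, j] = 2 * dESS of
    merging clusters i and j (for singletons this is the squared Euclidean
    distance); each step merges the minimal pair, with ties broken by the
    smallest (left, right) cluster-id pair, and records height sqrt(D2).
    """
    d = np.asarray(distances, dtype=float)
    n = d.shape[0]
    if d.ndim != 2 or d.shape != (n, n) or n < 2:
        raise ValueError("distances must be a square matrix with >= 2 items")
    d2 = d**2
    active = list(range(n))  # positions into d2 rows
    ids = list(range(n))  # cluster ids at each active position
    sizes = [1] * n
    big = np.inf
    d2 = d2.copy()
    np.fill_diagonal(d2, big)
    merges: list[tuple[int, int, float, int]] = []
    for step in range(n - 1):
        m = len(active)
        sub = d2[np.ix_(active, active)]
        best = None
        # ties broken on (min cluster id, max cluster id)
        mins = np.min(sub, axis=1)
        vmin = np.min(mins)
        cand = np.argwhere(sub <= vmin + 0.0)
        for a, b in cand:
            if a >= b:
                continue
            l, r = sorted((ids[a], ids[b]))
            key = (l, r)
            if best is None or key < best[0]:
                best = (key, a, b)
        _, a, b = best
        ia, ib = active[a], active[b]
        na, nb = sizes[a], sizes[b]
        l_id, r_id = sorted((ids[a], ids[b]))
        new_size = na + nb
        height = float(np.sqrt(max(d2[ia, ib], 0.0)))
        merges.append((l_id, r_id, height, new_size))
        # Lance-Williams Ward update against every other active cluster
        others = [p for p in range(m) if p not in (a, b)]
        if others:
            io = [active[p] for p in others]
            nk = np.array([sizes[p] for p in others], dtype=float)
            dka = d2[io, ia]
            dkb = d2[io, ib]
            dab = d2[ia, ib]
            upd = ((na + nk) * dka + (nb + nk) * dkb - nk * dab) / (na + nb + nk)
            d2[io, ia] = upd
            d2[ia, io] = upd
        # position a becomes the merged cluster; drop position b
        sizes[a] = new_size
        ids[a] = n + step
        del active[b], ids[b], sizes[b]
    return Linkage(merges=tuple(merges), n=n)


def cut_tree(linkage: Linkage, k: int) -> np.ndarray:
    """Labels 1..k from undoing the last k-1 merges.

    Cluster labels are assigned in order of first leaf appearance: scanning
    leaves 0..n-1, each new component gets the next label.
    """
    n = linkage.n
    if not 1 <= k <= n:
        raise ValueError(f"k must be in 1..{n}, got {k}")
    parent = list(range(n + max(0, n - k)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for t in range(n - k):
        l, r, _, _ = linkage.merges[t]
        new = n + t
        parent[find(l)] = new
        parent[find(r)] = new
    labels = np.zeros(n, dtype=int)
    mapping: dict[int, int] = {}
    for leaf in range(n):
        root = find(leaf)
        if root not in mapping:
            mapping[root] = len(mapping) + 1
        labels[leaf] = mapping[root]
    return labels


def silhouette(distances: np.ndarray, assignments: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean silhouette and per-item scores s_i = (b_i - a_i)/max(a_i, b_i).

    a_i: mean distance to the other members of i's cluster; b_i: smallest
    mean distance to any other cluster.  Items in singleton clusters score 0
    by convention.
    """
    d = np.asarray(distances, dtype=float)
    labels = np.asarray(assignments)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette requires >= 2 clusters")
    n = len(labels)
    s = np.zeros(n)
    members = {c: np.nonzero(labels == c)[0] for c in uniq}
    for i in range(n):
        own = members[labels[i]]
        if len(own) == 1:
            s[i] = 0.0
            continue
        a = np.sum(d[i, own]) / (len(own) - 1)
        b = min(np.mean(d[i, members[c]]) for c in uniq if c != labels[i])
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(np.mean(s)), s


def select_k(
    distances: np.ndarray,
    linkage: Linkage,
    k_range: tuple[int, int] = (2, 15),
) -> tuple[int, dict[int, float]]:
    """Choose k at a silhouette local maximum over the search range.

    Among interior local maxima (s(k) >= s(k-1) and s(k) >= s(k+1)) the one
    with the largest mean silhouette wins (smallest k on ties); if the
    profile has no interior local maximum, the global maximum is returned
    with a logged note.
    """
    lo, hi = k_range
    hi = min(hi, linkage.n - 1)
    if lo < 2 or lo > hi:
        raise ValueError(f"k range ({lo}, {hi}) invalid for n={linkage.n}")
    ks = list(range(lo, hi + 1))
    profile = {k: silhouette(distances, cut_tree(linkage, k))[0] for k in ks}
    local = [
        k for k in ks[1:-1]
        if profile[k] >= profile[k - 1] and profile[k] >= profile[k + 1]
    ]
    if local:
        k_best = max(local, key=lambda k: (profile[k], -k))
    else:
        k_best = max(ks, key=lambda k: (profile[k], -k))
        logger.info("no interior silhouette local maximum; using global maximum k=%d", k_best)
    return k_best, profile


class WardSilhouetteClustering(BaseEstimator, ClusterMixin):
    """Ward agglomerative clustering with silhouette-selected cluster count.

    Parameters
    ----------
    n_clusters : int or "auto"
        Fixed cluster count, or "auto" to pick the silhouette local maximum.
    k_range : tuple of (int, int)
        Search range for n_clusters="auto".
    standardize : bool
        z-score each feature before computing Euclidean distances.  Off by
        default: the three features share comparable numeric ranges and the
        reference analysis clusters the raw changes.

    Attributes
    ----------
    linkage_ : Linkage
    k_ : int
    labels_ : ndarray of shape (n_samples,), cluster labels 1..k
    silhouette_profile_ : dict mapping k -> mean silhouette
    silhouette_score_ : float, mean silhouette at k_
    """

    def __init__(self, n_clusters: int | str = "auto",
                 k_range: tuple[int, int] = (2, 15), standardize: bool = False):
        self.n_clusters = n_clusters
        self.k_range = k_range
        self.standardize = standardize

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_samples=2, ensure_min_features=1)
        self.n_features_in_ = X.shape[1]
        work = X
        if self.standardize:
            sd = X.std(axis=0, ddof=0)
            sd[sd == 0] = 1.0
            work = (X - X.mean(axis=0)) / sd
        d = distance_matrix(work)
        self.linkage_ = ward_linkage(d)
        if self.n_clusters == "auto":
            self.k_, self.silhouette_profile_ = select_k(d, self.linkage_, self.k_range)
        else:
            k = int(self.n_clusters)
            if not 1 <= k <= X.shape[0]:
                raise ValueError(f"n_clusters={k} out of range for n={X.shape[0]}")
            self.k_ = k
            self.silhouette_profile_ = (
                {k: silhouette(d, cut_tree(self.linkage_, k))[0]} if k >= 2 else {}
            )
        self.labels_ = cut_tree(self.linkage_, self.k_)
        self.silhouette_score_ = self.silhouette_profile_.get(self.k_, float("nan"))
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def cluster_cohort(
    features: pd.DataFrame | np.ndarray,
    n_clusters: int | str = "auto",
    k_range: tuple[int, int] = (2, 15),
    standardize: bool = False,
) -> ClusteringResult:
    """Cluster a cohort feature table (columns d_sbp, d_dbp, d_hr).

    Accepts a DataFrame with a ``subject_id`` column or a plain array of
    shape (n, 3); deterministic given the features.
    """
    subject_ids = None
    if isinstance(features, pd.DataFrame):
        required = ["d_sbp", "d_dbp", "d_hr"]
        missing = [c for c in required if c not in features.columns]
        if missing:
            raise ValueError(f"feature table missing column(s): {', '.join(missing)}")
        if "subject_id" in features.columns:
            subject_ids = features["subject_id"].astype(str).tolist()
        X = features[required].to_numpy(float)
    else:
        X = np.asarray(features, dtype=float)
    est = WardSilhouetteClustering(n_clusters=n_clusters, k_range=k_range,
                                   standardize=standardize)
    est.fit(X)
    return ClusteringResult(
        linkage=est.linkage_,
        k=est.k_,
        assignments=est.labels_,
        silhouette_profile=est.silhouette_profile_,
        subject_ids=subject_ids,
    )
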