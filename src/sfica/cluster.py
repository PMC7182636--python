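"""Inter-subject clustering of retained component spatial maps.

Z-scored spatial maps from all subjects are grouped by k-means with the
deterministic Kaufman initialization (first seed: the most central map;
later seeds: maximal gained coverage).  The number of clusters is chosen
by a minimum-description-length criterion on the k-means distortion, maps
first being projected onto their top principal subspace so the penalty
term is well scaled.  Clusters spanning fewer than half the subjects are
discarded; kept clusters are summarized by their centroid map, pairwise
map-correlation statistics, per-feature subject counts and member spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ClusterSummary", "ClusterResult", "zscore_maps", "KaufmanKMeans",
           "kmeans_ka", "mdl_order", "retain_clusters", "summarize_cluster",
           "group_cluster"]


def zscore_maps(maps: np.ndarray) -> np.ndarray:
    """Normalize each spatial map (row) to mean 0, SD 1."""
    maps = np.atleast_2d(np.asarray(maps, dtype=float))
    sd = maps.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"constant spatial map(s) at index {bad.tolist()}")
    return (maps - maps.mean(axis=1, keepdims=True)) / sd[:, None]


class KaufmanKMeans:
    """Deterministic k-means with the Kaufman seeding rule.

    The first seed is the most central point (minimum total distance to
    all others); each further seed is the point with the largest gained
    coverage, ``sum_j max(0, D_j - d(j, candidate))`` where ``D_j`` is
    point j's distance to its nearest seed.  Lloyd iterations then run to
    convergence; identical inputs always give identical assignments.

    Attributes (after ``fit``): ``cluster_centers_``, ``labels_``,
    ``inertia_``, ``n_iter_``.
    """

    def __init__(self, n_clusters: int = 2, max_iter: int = 300):
        self.n_clusters = n_clusters
        self.max_iter = max_iter

    def get_params(self, deep: bool = True) -> dict:
        return {"n_clusters": self.n_clusters, "max_iter": self.max_iter}

    def set_params(self, **params) -> "KaufmanKMeans":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    @staticmethod
    def _dist2(X: np.ndarray, C: np.ndarray) -> np.ndarray:
        return np.maximum(
            (X ** 2).sum(1)[:, None] + (C ** 2).sum(1)[None, :]
            - 2.0 * X @ C.T, 0.0)

    def _init_centers(self, X: np.ndarray) -> np.ndarray:
        n = X.shape[0]
        d = np.sqrt(self._dist2(X, X))
        seeds = [int(np.argmin(d.sum(axis=1)))]
        while len(seeds) < self.n_clusters:
            D = d[:, seeds].min(axis=1)
            gains = np.full(n, -np.inf)
            for i in range(n):
                if i in seeds:
                    continue
                gains[i] = np.maximum(D - d[:, i], 0.0).sum()
            seeds.append(int(np.argmax(gains)))
        return X[seeds].copy()

    def fit(self, X: np.ndarray, y=None) -> "KaufmanKMeans":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        k = self.n_clusters
        if k < 1:
            raise ValueError("n_clusters must be >= 1")
        if k > X.shape[0]:
            raise ValueError("more clusters than points")
        C = self._init_centers(X)
        labels = np.full(X.shape[0], -1)
        it = 0
        for it in range(1, self.max_iter + 1):
            new_labels = np.argmin(self._dist2(X, C), axis=1)
            if np.array_equal(new_labels, labels):
                break
            labels = new_labels
            for j in range(k):
                members = labels == j
                if members.any():          # empty cluster keeps its centroid
                    C[j] = X[members].mean(axis=0)
        self.cluster_centers_ = C
        self.labels_ = labels
        self.inertia_ = float(self._dist2(X, C)[np.arange(X.shape[0]),
                                                labels].sum())
        self.n_iter_ = it
        return self

    def fit_predict(self, X: np.ndarray, y=None) -> np.ndarray:
        return self.fit(X).labels_

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.argmin(self._dist2(X, self.cluster_centers_), axis=1)


def kmeans_ka(maps: np.ndarray, M: int,
              max_iter: int = 300) -> tuple[np.ndarray, np.ndarray]:
    """Functional wrapper: returns ``(assignment, centroids)``."""
    km = KaufmanKMeans(n_clusters=M, max_iter=max_iter).fit(maps)
    return km.labels_, km.cluster_centers_


def mdl_order(maps: np.ndarray, M_max: int, penalty: float = 2.0) -> int:
    """Choose the k-means order by a coding-length criterion.

    Maps are projected onto their top ``d_eff = min(N - 1, 50)`` principal
    directions; for each m in 1..M_max the criterion

        N * d_eff * log(RSS_m / (N * d_eff)) + penalty * m * d_eff * log(N)

    is evaluated on the k-means distortion RSS_m, and the minimizing m is
    returned.
    """
    maps = np.atleast_2d(np.asarray(maps, dtype=float))
    n = maps.shape[0]
    if n < 2:
        raise ValueError("need at least 2 maps")
    if M_max < 2:
        raise ValueError("M_max must be >= 2")
    M_max = min(M_max, n)
    d_eff = min(n - 1, 50, maps.shape[1])
    centered = maps - maps.mean(axis=0)
    # variance-preserving projection to the top principal subspace
    _, _, Vt = np.linalg.svd(centered, full_matrices=False)
    proj = centered @ Vt[:d_eff].T
    best_m, best_score = 1, np.inf
    for m in range(1, M_max + 1):
        km = KaufmanKMeans(n_clusters=m).fit(proj)
        rss = max(km.inertia_, 1e-12)
        score = n * d_eff * np.log(rss / (n * d_eff)) \
            + penalty * m * d_eff * np.log(n)
        if score < best_score:
            best_m, best_score = m, score
    return best_m


def retain_clusters(assignment: np.ndarray, subject_of_component,
                    n_subjects: int) -> np.ndarray:
    """Keep clusters spanning at least half of all subjects.

    Returns a boolean flag per cluster id (0..max(assignment)); a cluster
    is kept iff its distinct-subject count >= ceil(n_subjects / 2).
    """
    assignment = np.asarray(assignment)
    subjects = np.asarray(subject_of_component)
    need = int(np.ceil(n_subjects / 2))
    n_clusters = assignment.max() + 1 if assignment.size else 0
    kept = np.zeros(n_clusters, dtype=bool)
    for m in range(n_clusters):
        kept[m] = len(set(subjects[assignment == m])) >= need
    return kept


@dataclass
class ClusterSummary:
    cluster_id: int
    centroid: np.ndarray
    members: list[int]
    subjects: list
    mean_pairwise_r: float       # NaN for singletons
    sd_pairwise_r: float
    feature_subject_counts: dict[str, int] = field(default_factory=dict)
    member_spectra: np.ndarray | None = None


@dataclass
class ClusterResult:
    M: int
    assignment: np.ndarray
    centroids: np.ndarray
    kept: np.ndarray
    summaries: list[ClusterSummary]


def summarize_cluster(cluster_id: int, maps: np.ndarray, members,
                      subjects, features_of_member=None,
                      spectra: np.ndarray | None = None) -> ClusterSummary:
    """Centroid, pairwise-correlation stats and subject counts per feature.

    ``maps`` are the z-scored maps of the cluster members only; pairwise
    statistics are undefined (NaN) for singletons.
    """
    maps = np.atleast_2d(np.asarray(maps, dtype=float))
    k = maps.shape[0]
    if k > 1:
        r = np.corrcoef(maps)
        iu = np.triu_indices(k, 1)
        mean_r, sd_r = float(r[iu].mean()), float(r[iu].std())
    else:
        mean_r, sd_r = float("nan"), float("nan")
    counts: dict[str, int] = {}
    if features_of_member is not None:
        per_feature: dict[str, set] = {}
        for subj, feats in zip(subjects, features_of_member):
            for f in feats:
                per_feature.setdefault(f, set()).add(subj)
        counts = {f: len(s) for f, s in sorted(per_feature.items())}
    return ClusterSummary(cluster_id=cluster_id, centroid=maps.mean(axis=0),
                          members=list(members), subjects=list(subjects),
                          mean_pairwise_r=mean_r, sd_pairwise_r=sd_r,
                          feature_subject_counts=counts,
                          member_spectra=spectra)


def group_cluster(maps: np.ndarray, subject_of_component, n_subjects: int,
                  M_max: int = 10, features_of_component=None,
                  spectra: np.ndarray | None = None,
                  M: int | None = None) -> ClusterResult:
    """Full group-level analysis: z-score, MDL order, k-means, retention.

    ``maps`` is (n_retained_components, n_sources); ``M`` overrides the
    MDL choice when given.
    """
    Z = zscore_maps(maps)
    if M is None:
        M = mdl_order(Z, M_max)
    assignment, centroids = kmeans_ka(Z, M)
    kept = retain_clusters(assignment, subject_of_component, n_subjects)
    subjects = np.asarray(subject_of_component)
    summaries = []
    for m in range(M):
        members = np.flatnonzero(assignment == m)
        feats = ([features_of_component[i] for i in members]
                 if features_of_component is not None else None)
        summaries.append(summarize_cluster(
            m, Z[members], members, subjects[members].tolist(),
            features_of_member=feats,
            spectra=spectra[members] if spectra is not None else None))
    return ClusterResult(M=M, assignment=assignment, centroids=centroids,
                         kept=kept, summaries=summaries)
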