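"""ICASSO-style stability analysis for complex ICA.

ICA is repeated with random initial conditions; the pooled components are
clustered by the absolute Pearson correlation between their magnitude
vectors, and each cluster's quality index

    Iq = mean intra-cluster similarity - mean extra-cluster similarity

measures how reliably the component is re-estimated (Iq near 1: found in
nearly every run).  The cluster centrotype — the member most similar to
its cluster on average — serves as the representative component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .decomposition import (FourierICADecomposition, complex_fastica,
                            complex_pca, unmix)

__all__ = ["StabilityReport", "similarity_matrix", "cluster_components",
           "iq_index", "run_icasso"]


@dataclass
class StabilityReport:
    n_runs: int
    similarity: np.ndarray       # pooled x pooled, in [0, 1]
    partition: np.ndarray        # cluster id (0-based) per pooled component
    iq: np.ndarray               # per-cluster stability index
    centrotypes: np.ndarray      # pooled-component index per cluster
    run_of_component: np.ndarray  # which run each pooled component came from
    stable: np.ndarray           # iq > threshold per cluster
    iq_threshold: float = 0.7


def similarity_matrix(components: np.ndarray) -> np.ndarray:
    """Absolute correlation between component magnitude vectors.

    ``components`` is (n_components, n_samples), complex or real; entry
    (i, j) is |Pearson r| between |c_i| and |c_j|, so the measure is
    invariant to unit-modulus phase factors.  Zero-variance magnitude
    vectors get zero rows/columns (with a warning) but keep unit diagonal.
    """
    comps = np.abs(np.asarray(components))
    if comps.ndim != 2 or comps.shape[0] < 2:
        raise ValueError("need >= 2 components of equal length")
    sd = comps.std(axis=1)
    bad = sd == 0
    if bad.any():
        warnings.warn(f"{bad.sum()} zero-variance magnitude component(s)")
        comps = comps.copy()
        comps[bad] = np.random.default_rng(0).standard_normal(comps.shape[1])
    sim = np.abs(np.corrcoef(comps))
    sim[bad, :] = 0.0
    sim[:, bad] = 0.0
    np.fill_diagonal(sim, 1.0)
    return np.clip(sim, 0.0, 1.0)


def cluster_components(similarity: np.ndarray, k: int) -> np.ndarray:
    """Average-linkage agglomerative partition on dissimilarity 1 - S.

    Returns 0-based cluster labels, one per component.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = similarity.shape[0]
    if k > n:
        raise ValueError("k exceeds number of components")
    if k == n:
        return np.arange(n)
    dis = 1.0 - np.asarray(similarity, dtype=float)
    dis = np.clip((dis + dis.T) / 2.0, 0.0, None)
    np.fill_diagonal(dis, 0.0)
    link = hierarchy.linkage(squareform(dis, checks=False), method="average")
    return hierarchy.fcluster(link, t=k, criterion="maxclust") - 1


def iq_index(similarity: np.ndarray, partition: np.ndarray) -> np.ndarray:
    """Stability index per cluster: mean intra minus mean extra similarity.

    Intra-cluster similarity averages off-diagonal within-cluster pairs
    (singletons count 1); extra-cluster similarity averages all pairs
    between the cluster's members and every non-member.
    """
    S = np.asarray(similarity, dtype=float)
    partition = np.asarray(partition)
    labels = np.unique(partition)
    iq = np.zeros(labels.size)
    for i, lab in enumerate(labels):
        members = np.flatnonzero(partition == lab)
        others = np.flatnonzero(partition != lab)
        if members.size > 1:
            block = S[np.ix_(members, members)]
            intra = (block.sum() - members.size) / \
                (members.size * (members.size - 1))
        else:
            intra = 1.0
        extra = S[np.ix_(members, others)].mean() if others.size else 0.0
        iq[i] = intra - extra
    return iq


def run_icasso(X0: np.ndarray, order: int = 20, n_runs: int = 100,
               seed: int | None = None, iq_threshold: float = 0.7,
               max_iter: int = 1000, tol: float = 1e-6,
               eps: float = 0.1,
               seeds=None) -> tuple[StabilityReport,
                                    FourierICADecomposition]:
    """Repeat complex FastICA with random initializations and assess Iq.

    Whitening is computed once; ``n_runs`` FastICA fits with distinct
    seeds are pooled, clustered into ``order`` clusters, and each
    cluster's centrotype forms the representative decomposition whose
    mixing columns are taken from the centrotype's own run.  ``seeds``
    overrides the per-run initialization seeds (length ``n_runs``).

    Returns ``(report, representative_decomposition)``.
    """
    Z, K, Kinv, eigvals = complex_pca(X0, order)
    rng = np.random.default_rng(seed)
    if seeds is None:
        seeds = [int(rng.integers(2 ** 31)) for _ in range(n_runs)]
    if len(seeds) != n_runs:
        raise ValueError("seeds must have length n_runs")
    pooled_S: list[np.ndarray] = []
    pooled_W: list[np.ndarray] = []
    run_ids: list[int] = []
    for run in range(n_runs):
        res = complex_fastica(Z, seed=seeds[run],
                              max_iter=max_iter, tol=tol, eps=eps)
        if not res.converged:
            warnings.warn(f"ICA run {run} did not converge; excluded")
            continue
        pooled_S.append(res.matrix @ Z)
        pooled_W.append(res.matrix)
        run_ids.append(run)
    if not pooled_S:
        raise RuntimeError("no ICA run converged")
    S_all = np.vstack(pooled_S)
    sim = similarity_matrix(S_all)
    part = cluster_components(sim, order)
    iq = iq_index(sim, part)

    centrotypes = np.zeros(np.unique(part).size, dtype=int)
    rep_rows = []
    rep_cols = []
    for i, lab in enumerate(np.unique(part)):
        members = np.flatnonzero(part == lab)
        scores = sim[np.ix_(members, members)].mean(axis=1)
        c = members[int(np.argmax(scores))]
        centrotypes[i] = c
        run_idx, comp_idx = divmod(c, order)
        rep_rows.append(S_all[c])
        rep_cols.append(pooled_W[run_idx][comp_idx])
    W_rep = np.vstack(rep_cols)            # rows of the chosen runs' W
    rep = unmix(X0, K, Kinv, W_rep, eigenvalues=eigvals, seed=seed)
    report = StabilityReport(
        n_runs=len(pooled_S), similarity=sim, partition=part, iq=iq,
        centrotypes=centrotypes,
        run_of_component=np.repeat(np.array(run_ids), order),
        stable=iq > iq_threshold, iq_threshold=iq_threshold)
    return report, rep
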