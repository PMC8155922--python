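"""Unsupervised characterization: PCA, parallel-analysis component
selection, shared-nearest-neighbor clustering, UMAP, and cluster markers.

The selection of "non-trivial" principal components follows the
parallel-analysis convention: each metabolite column of the matrix is
permuted independently (marginals preserved, correlation destroyed), and a
component is kept while its eigenvalue exceeds the upper-quantile null
eigenvalue of the permuted ensemble at the same rank.

SNN clustering mirrors the single-cell tooling convention: a k-nearest-
neighbor graph (Euclidean, neighbor sets include the point itself), edges
weighted by the Jaccard overlap of neighbor sets, weak edges pruned, and
Louvain community detection on the weighted graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.decomposition import PCA as _SkPCA
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from .core_data import MetaboliteTable, ValidationError

__all__ = [
    "PCAResult",
    "ClusterResult",
    "ParallelAnalysisPCA",
    "SNNClusterer",
    "pca",
    "select_nontrivial",
    "snn_cluster",
    "snn_graph",
    "embed2d",
    "marker_metabolites",
]


@dataclass
class PCAResult:
    eigenvalues: np.ndarray  # descending
    eigenvectors: np.ndarray  # features x n_components
    scores: np.ndarray  # voxels x n_components
    explained_share: np.ndarray

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)


@dataclass
class ClusterResult:
    labels: np.ndarray  # 1..K, relabeled by decreasing cluster size
    k_neighbors: int
    embedding2d: np.ndarray | None = None

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max())


class ParallelAnalysisPCA(BaseEstimator):
    """PCA with randomized-matrix selection of non-trivial components.

    Fitted attributes: ``eigenvalues_``, ``components_`` (features x k),
    ``scores_``, ``explained_share_``, ``null_eigenvalues_`` (upper-quantile
    permuted spectrum) and ``nontrivial_`` (contiguous leading indices).
    """

    def __init__(self, n_components: int = 30, n_randomizations: int = 20,
                 quantile: float = 0.95, random_state: int = 0):
        self.n_components = n_components
        self.n_randomizations = n_randomizations
        self.quantile = quantile
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        k = min(self.n_components, X.shape[1], X.shape[0] - 1)
        if k < self.n_components:
            warnings.warn(
                f"reducing n_components from {self.n_components} to {k} "
                "(matrix too small)", stacklevel=2)
        p = _SkPCA(n_components=k, svd_solver="full")
        scores = p.fit_transform(X)
        comps = p.components_.T  # features x k
        # deterministic sign: largest-magnitude loading positive
        for j in range(k):
            i = np.argmax(np.abs(comps[:, j]))
            if comps[i, j] < 0:
                comps[:, j] = -comps[:, j]
                scores[:, j] = -scores[:, j]
        self.mean_ = p.mean_
        self.eigenvalues_ = p.explained_variance_
        self.components_ = comps
        self.scores_ = scores
        total_var = X.var(axis=0, ddof=1).sum()
        self.explained_share_ = self.eigenvalues_ / total_var
        self.null_eigenvalues_ = (self._null_spectrum(X, k)
                                  if self.n_randomizations > 0
                                  else np.full(k, np.inf))
        keep = self.eigenvalues_ > self.null_eigenvalues_
        n_keep = 0
        for flag in keep:  # contiguous leading run
            if not flag:
                break
            n_keep += 1
        self.nontrivial_ = list(range(n_keep))
        self.n_features_in_ = X.shape[1]
        return self

    def _null_spectrum(self, X: np.ndarray, k: int) -> np.ndarray:
        """Upper-quantile eigenvalue spectrum of the column-permuted ensemble.

        The 95th percentile (Horn's parallel-analysis convention) rather
        than the ensemble mean: on a pure-noise matrix the observed
        eigenvalues are exchangeable with the permuted ones, so a mean
        threshold flags spurious leading components about half the time.
        """
        rng = np.random.default_rng(self.random_state)
        null = np.empty((self.n_randomizations, k))
        for r in range(self.n_randomizations):
            Xr = np.empty_like(X)
            for j in range(X.shape[1]):
                Xr[:, j] = X[rng.permutation(X.shape[0]), j]
            s = np.linalg.svd(Xr - Xr.mean(axis=0), compute_uv=False)
            ev = s**2 / (X.shape[0] - 1)
            null[r] = ev[:k]
        return np.quantile(null, self.quantile, axis=0)

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return (X - self.mean_) @ self.components_

    def result(self) -> PCAResult:
        return PCAResult(self.eigenvalues_, self.components_, self.scores_,
                         self.explained_share_)


def pca(X: np.ndarray, n_components: int = 30) -> PCAResult:
    """Column-centered PCA with a deterministic sign convention."""
    return ParallelAnalysisPCA(n_components=n_components,
                               n_randomizations=0).fit(X).result()


def select_nontrivial(X: np.ndarray, n_randomizations: int = 20,
                      seed: int = 0, n_components: int = 30) -> list[int]:
    """Indices of leading PCs whose eigenvalues beat the permuted-matrix null."""
    model = ParallelAnalysisPCA(n_components=n_components,
                                n_randomizations=n_randomizations,
                                random_state=seed).fit(X)
    return model.nontrivial_


# ---------------------------------------------------------------------------
# SNN clustering


def snn_graph(scores: np.ndarray, k_neighbors: int = 20,
              prune: float = 1.0 / 15.0):
    """Shared-nearest-neighbor graph as a networkx weighted graph.

    Neighbor sets are the k nearest points by Euclidean distance, including
    the point itself.  Candidate edges connect each point to its neighbors;
    the edge weight is the Jaccard overlap of the two neighbor sets, and
    edges with weight < ``prune`` are dropped.
    """
    import networkx as nx

    X = np.asarray(scores, dtype=float)
    n = X.shape[0]
    k = min(k_neighbors, n)
    nn = NearestNeighbors(n_neighbors=k).fit(X)
    _, idx = nn.kneighbors(X)
    neigh = [set(row) | {i} for i, row in enumerate(idx)]
    pairs = {(min(i, int(j)), max(i, int(j)))
             for i in range(n) for j in idx[i] if int(j) != i}
    G = nx.Graph()
    G.add_nodes_from(range(n))
    for i, j in pairs:
        inter = len(neigh[i] & neigh[j])
        union = len(neigh[i] | neigh[j])
        w = inter / union
        if w >= prune:
            G.add_edge(i, j, weight=w)
    return G


class SNNClusterer(ClusterMixin, BaseEstimator):
    """SNN-graph Louvain clustering with size-ordered labels 1..K.

    The Louvain resolution defaults to 0.2: at the classical resolution of
    1, modularity maximization fragments large, internally homogeneous kNN
    components into arbitrary sub-communities, so a lower resolution is the
    appropriate default when clusters are expected to be tissue-scale.
    """

    def __init__(self, k_neighbors: int = 20, prune: float = 1.0 / 15.0,
                 resolution: float = 0.2, random_state: int = 0):
        self.k_neighbors = k_neighbors
        self.prune = prune
        self.resolution = resolution
        self.random_state = random_state

    def fit(self, X, y=None):
        import networkx as nx

        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] < 1:
            raise ValidationError("scores must be 2-D with >= 1 column")
        if X.shape[0] <= self.k_neighbors:
            raise ValidationError(
                f"need more than k_neighbors={self.k_neighbors} points")
        # canonical (lexicographic) point order: Louvain's local moves depend
        # on node ids, so clustering the canonicalized graph makes the result
        # invariant to the input row order
        order = np.lexsort(X.T[::-1])
        G = snn_graph(X[order], self.k_neighbors, self.prune)
        comms = nx.community.louvain_communities(
            G, weight="weight", resolution=self.resolution,
            seed=int(self.random_state))
        comms = sorted(comms, key=lambda c: (-len(c), min(c)))
        labels = np.zeros(X.shape[0], dtype=int)
        for cid, members in enumerate(comms, start=1):
            for i in members:
                labels[order[i]] = cid
        self.labels_ = labels
        self.graph_ = G
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def snn_cluster(scores: np.ndarray, k_neighbors: int = 20,
                seed: int = 0, prune: float = 1.0 / 15.0,
                resolution: float = 0.2) -> ClusterResult:
    model = SNNClusterer(k_neighbors=k_neighbors, prune=prune,
                         resolution=resolution, random_state=seed).fit(scores)
    return ClusterResult(labels=model.labels_, k_neighbors=k_neighbors)


def embed2d(scores: np.ndarray, seed: int = 0, n_neighbors: int = 15,
            min_dist: float = 0.1) -> np.ndarray:
    """2-D UMAP embedding, deterministic for a fixed seed."""
    import umap

    X = np.asarray(scores, dtype=float)
    nn = min(n_neighbors, max(2, X.shape[0] - 1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        emb = umap.UMAP(n_components=2, n_neighbors=nn, min_dist=min_dist,
                        random_state=int(seed)).fit_transform(X)
    return np.asarray(emb, dtype=float)


# ---------------------------------------------------------------------------
# markers


def marker_metabolites(table: MetaboliteTable | np.ndarray,
                       labels: np.ndarray, alpha: float = 0.05,
                       metabolite_names: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Per-cluster enriched metabolites (rank-sum test, BH adjustment).

    For every (cluster, metabolite) pair, a two-sided Wilcoxon rank-sum
    test compares in-cluster voxels against the rest; effect size is the
    log2 ratio of means.  Benjamini-Hochberg adjustment runs across all
    pairs; a marker is a pair with adjusted p < alpha and positive effect.
    """
    if isinstance(table, MetaboliteTable):
        X = table.values
        names = table.metabolite_names
    else:
        X = np.asarray(table, dtype=float)
        names = tuple(metabolite_names) if metabolite_names else tuple(
            f"m{j}" for j in range(X.shape[1]))
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    if len(clusters) < 2:
        raise ValidationError("need >= 2 clusters for marker testing")

    rows = []
    eps = 1e-12
    for c in clusters:
        inmask = labels == c
        if inmask.sum() < 3 or (~inmask).sum() < 3:
            warnings.warn(f"cluster {c} too small for testing; skipped",
                          stacklevel=2)
            continue
        A, B = X[inmask], X[~inmask]
        for j, met in enumerate(names):
            a, b = A[:, j], B[:, j]
            if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
                p = 1.0
            else:
                p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
            # intensities are non-negative; means are floored at eps so the
            # ratio stays defined on degenerate/centered inputs
            lfc = float(np.log2(max(a.mean(), eps) / max(b.mean(), eps)))
            rows.append((int(c), met, lfc, p))
    df = pd.DataFrame(rows, columns=["cluster", "metabolite", "log2fc", "p"])
    if len(df):
        df["p_adj"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
        df["is_marker"] = (df["p_adj"] < alpha) & (df["log2fc"] > 0)
    else:
        df["p_adj"] = []
        df["is_marker"] = []
    return df
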