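"""Shared-nearest-neighbor graph construction, community detection, and
marker-gene statistics.

Marker detection follows the pairwise scheme used for the single-nucleus
reanalysis: for every gene and cluster, one-sided Welch t-tests of that
cluster against every other cluster ("upregulated compared to any
others"), combined per gene with Simes' method, Benjamini–Hochberg
corrected across genes within the cluster, with the summary log fold
change taken from the pairwise comparison with the lowest p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import igraph
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ClusterAssignment",
    "snn_graph",
    "cluster_graph",
    "SNNGraphClustering",
    "find_markers",
    "marker_score_pseudo_r2",
    "annotate_clusters",
]


@dataclass
class ClusterAssignment:
    labels: np.ndarray
    method: str
    resolution: float
    knn_k: int
    seed: int


def snn_graph(coords: np.ndarray, knn_k: int) -> igraph.Graph:
    """Shared-nearest-neighbor graph.

    Cells are connected when their k-NN lists (self excluded) share at
    least one neighbor, or when one is a neighbor of the other; the edge
    weight is the Jaccard similarity of the two (self-inclusive) neighbor
    sets. No self-loops.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if knn_k >= n:
        raise ValueError("knn_k must be < number of cells")
    nn = NearestNeighbors(n_neighbors=knn_k + 1).fit(coords)
    idx = nn.kneighbors(coords, return_distance=False)
    # drop self if present, keep k neighbors; include self in the set so two
    # mutual neighbors are themselves connected
    rows, cols = [], []
    for i in range(n):
        neigh = [j for j in idx[i] if j != i][:knn_k]
        rows.extend([i] * (len(neigh) + 1))
        cols.extend(neigh + [i])
    S = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    shared = (S @ S.T).tocoo()
    set_size = knn_k + 1
    mask = (shared.row < shared.col) & (shared.data >= 1)
    r, c, d = shared.row[mask], shared.col[mask], shared.data[mask]
    jaccard = d / (2 * set_size - d)
    g = igraph.Graph(n=n, edges=list(zip(r.tolist(), c.tolist())),
                     edge_attrs={"weight": jaccard.tolist()})
    return g


def cluster_graph(graph: igraph.Graph, method: str = "leiden",
                  resolution: float = 5e-3, seed: int = 0) -> ClusterAssignment:
    """Community detection on a weighted SNN graph.

    ``leiden`` optimizes the constant-Potts-model objective at the given
    resolution; ``louvain`` optimizes modularity (RB-configuration null
    model). Both run through leidenalg so a fixed seed is deterministic.
    """
    if graph.vcount() == 0:
        raise ValueError("empty graph")
    if method == "leiden":
        part_type = leidenalg.CPMVertexPartition
    elif method == "louvain":
        part_type = leidenalg.RBConfigurationVertexPartition
    else:
        raise ValueError("method must be 'leiden' or 'louvain'")
    weights = graph.es["weight"] if "weight" in graph.es.attributes() else None
    part = leidenalg.find_partition(
        graph, part_type, weights=weights,
        resolution_parameter=resolution, seed=int(seed), n_iterations=-1)
    labels = np.asarray(part.membership, dtype=int)
    # contiguous relabel (leidenalg is already contiguous, kept as a guard)
    _, labels = np.unique(labels, return_inverse=True)
    return ClusterAssignment(labels=labels, method=method,
                             resolution=resolution,
                             knn_k=-1, seed=seed)


class SNNGraphClustering(BaseEstimator, ClusterMixin):
    """SNN graph + community detection as a scikit-learn clusterer."""

    def __init__(self, knn_k: int = 20, method: str = "leiden",
                 resolution: float = 5e-3, seed: int = 0):
        self.knn_k = knn_k
        self.method = method
        self.resolution = resolution
        self.seed = seed

    def fit(self, X, y=None):
        g = snn_graph(np.asarray(X, float), self.knn_k)
        assign = cluster_graph(g, self.method, self.resolution, self.seed)
        self.graph_ = g
        self.labels_ = assign.labels
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def _cluster_stats(X: np.ndarray, labels: np.ndarray, keep: list):
    stats_ = {}
    for c in keep:
        sub = X[labels == c]
        stats_[c] = (sub.shape[0], sub.mean(axis=0), sub.var(axis=0, ddof=1))
    return stats_


def _welch_one_sided(m1, v1, n1, m2, v2, n2):
    """Vectorized one-sided (greater) Welch t-test; zero-variance ties -> p=1."""
    se2 = v1 / n1 + v2 / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(se2)
        df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        p = stats.t.sf(t, df)
    degenerate = ~np.isfinite(t) | ~np.isfinite(df)
    p = np.where(degenerate, 1.0, p)
    t = np.where(degenerate, 0.0, t)
    return t, df, p


def find_markers(norm, clusters: np.ndarray, gene_names=None,
                 top_n: int = 30, combine: str = "simes") -> pd.DataFrame:
    """Per-cluster marker table from pairwise one-sided Welch t-tests.

    Returns one row per (cluster, gene) with the Simes-combined p over all
    pairwise comparisons, the BH q across genes within the cluster, the
    summary log fold change from the most significant pairwise comparison,
    and the within-cluster significance rank (1 = most significant; rows
    with rank <= ``top_n`` flagged as markers).
    """
    X = np.asarray(norm.todense()) if sp.issparse(norm) else np.asarray(norm, float)
    clusters = np.asarray(clusters)
    uniq, counts = np.unique(clusters, return_counts=True)
    keep = [c for c, n in zip(uniq, counts) if n >= 2]
    dropped = [c for c, n in zip(uniq, counts) if n < 2]
    if dropped:
        warnings.warn(f"clusters with < 2 cells excluded: {dropped}")
    if len(keep) < 2:
        raise ValueError("need >= 2 clusters with >= 2 cells")
    cs = _cluster_stats(X, clusters, keep)
    frames = []
    n_other = len(keep) - 1
    for a in keep:
        pvals = np.empty((n_other, X.shape[1]))
        diffs = np.empty((n_other, X.shape[1]))
        for j, b in enumerate([c for c in keep if c != a]):
            n1, m1, v1 = cs[a]
            n2, m2, v2 = cs[b]
            _, _, p = _welch_one_sided(m1, v1, n1, m2, v2, n2)
            pvals[j] = p
            diffs[j] = m1 - m2
        if combine == "simes":
            srt = np.sort(pvals, axis=0)
            combined = np.min(
                srt * n_other / np.arange(1, n_other + 1)[:, None], axis=0)
            combined = np.minimum(combined, 1.0)
        elif combine == "max":
            combined = pvals.max(axis=0)
        else:
            raise ValueError("combine must be 'simes' or 'max'")
        best_pair = np.argmin(pvals, axis=0)
        summary_lfc = diffs[best_pair, np.arange(X.shape[1])]
        _, bh_q, _, _ = multipletests(combined, method="fdr_bh")
        order = np.argsort(combined, kind="stable")
        rank = np.empty_like(order)
        rank[order] = np.arange(1, X.shape[1] + 1)
        names = (list(gene_names) if gene_names is not None
                 else [f"g{i}" for i in range(X.shape[1])])
        frames.append(pd.DataFrame({
            "cluster": a, "gene": names, "combined_p": combined,
            "bh_q": bh_q, "summary_lfc": summary_lfc, "rank": rank,
            "is_marker": rank <= top_n,
        }))
    return pd.concat(frames, ignore_index=True)


def _mcfadden(y: np.ndarray, x: np.ndarray, ridge: float = 1e-4) -> float:
    """McFadden pseudo-R^2 of a one-feature ridge logistic regression."""
    n = y.size
    p_hat = y.mean()
    if p_hat in (0.0, 1.0):
        raise ValueError("single-class input")
    ll_null = n * (p_hat * np.log(p_hat) + (1 - p_hat) * np.log(1 - p_hat))
    if x.std() == 0:
        return 0.0
    clf = LogisticRegression(C=1.0 / ridge, solver="lbfgs", max_iter=2000)
    clf.fit(x.reshape(-1, 1), y)
    proba = np.clip(clf.predict_proba(x.reshape(-1, 1))[:, 1], 1e-12, 1 - 1e-12)
    ll_fit = float(np.sum(y * np.log(proba) + (1 - y) * np.log(1 - proba)))
    return float(np.clip(1.0 - ll_fit / ll_null, 0.0, 1.0))


def marker_score_pseudo_r2(norm, clusters: np.ndarray, gene_names=None,
                           genes=None, ridge: float = 1e-4) -> pd.DataFrame:
    """Pseudo-R^2 marker scores: per (gene, cluster), the McFadden
    pseudo-R^2 of a one-vs-rest L2-regularized logistic regression of
    cluster membership on the gene's normalized expression."""
    X = np.asarray(norm.todense()) if sp.issparse(norm) else np.asarray(norm, float)
    clusters = np.asarray(clusters)
    names = (list(gene_names) if gene_names is not None
             else [f"g{i}" for i in range(X.shape[1])])
    if genes is not None:
        idx = [names.index(g) for g in genes]
    else:
        idx = list(range(X.shape[1]))
    uniq = np.unique(clusters)
    if uniq.size < 2:
        raise ValueError("single-class input")
    rows = []
    for c in uniq:
        y = (clusters == c).astype(int)
        for gi in idx:
            rows.append((c, names[gi], _mcfadden(y, X[:, gi], ridge)))
    return pd.DataFrame(rows, columns=["cluster", "gene", "pseudo_r2"])


def annotate_clusters(norm, clusters: np.ndarray, signature_sets=None,
                      gene_names=None, margin: float = 0.25) -> dict:
    """Assign each cluster the signature label with the highest mean
    z-scaled expression, requiring a margin (default 0.25 z-units) over the
    runner-up; otherwise ``"unassigned"``."""
    from .genes import DEFAULT_SIGNATURES
    if signature_sets is None:
        signature_sets = DEFAULT_SIGNATURES
    if any(len(s) == 0 for s in signature_sets.values()):
        raise ValueError("empty signature set")
    X = np.asarray(norm.todense()) if sp.issparse(norm) else np.asarray(norm, float)
    names = list(gene_names) if gene_names is not None else \
        [f"g{i}" for i in range(X.shape[1])]
    name_idx = {g: i for i, g in enumerate(names)}
    sd = X.std(axis=0)
    mu = X.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = np.where(sd > 0, (X - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    sig_idx = {}
    for label, genes_ in signature_sets.items():
        present = [name_idx[g] for g in genes_ if g in name_idx]
        missing = [g for g in genes_ if g not in name_idx]
        if missing:
            warnings.warn(f"signature {label!r}: missing genes {missing}")
        sig_idx[label] = present
    clusters = np.asarray(clusters)
    out = {}
    for c in np.unique(clusters):
        mask = clusters == c
        scores = {}
        for label, idx in sig_idx.items():
            scores[label] = float(Z[np.ix_(mask, idx)].mean()) if idx else -np.inf
        ranked = sorted(scores.items(), key=lambda kv: kv[1], reverse=True)
        if len(ranked) == 1 or ranked[0][1] - ranked[1][1] >= margin:
            out[int(c) if np.issubdtype(clusters.dtype, np.integer) else c] = ranked[0][0]
        else:
            out[int(c) if np.issubdtype(clusters.dtype, np.integer) else c] = "unassigned"
    return out
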