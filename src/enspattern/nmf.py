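"""Non-negative pattern discovery and cell-type-specific pattern selection.

The log-normalized expression matrix V (cells x genes) is factorized as
V ~ W H with W, H >= 0 by minimizing the half squared Frobenius error with
hierarchical alternating least squares (HALS). Columns of the gene-
amplitude matrix A = H^T are the "patterns"; the corresponding columns of
W are each cell's pattern usage. Specificity of a pattern for a cell
cluster is scored as the AUROC of the pattern's cell weights as a
classifier of cluster membership, and the most specific patterns for a
target lineage (four, by default) are selected for downstream projection.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.cluster.hierarchy import leaves_list, linkage as scipy_linkage
from scipy.optimize import nnls as _nnls
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.metrics import roc_auc_score

__all__ = [
    "PatternNMF",
    "nmf_fit",
    "pattern_specificity",
    "select_specific_patterns",
    "hcluster_patterns",
]


def _objective(V, W, H, v_sqnorm):
    WtV_H = np.trace((W.T @ (V @ H.T)) if not sp.issparse(V)
                     else (W.T @ (V @ H.T)))
    return 0.5 * (v_sqnorm - 2.0 * WtV_H + np.sum((W.T @ W) * (H @ H.T)))


class PatternNMF(BaseEstimator, TransformerMixin):
    """HALS non-negative matrix factorization with restarts.

    Parameters
    ----------
    k : number of patterns (the study default is 50).
    max_iter, tol : HALS sweeps stop when the relative objective change
        falls below ``tol`` or at ``max_iter``.
    n_restarts : independent random initializations; the factorization
        with the best final objective is kept.
    random_state : master seed for the uniform non-negative init.

    Attributes
    ----------
    A_ : genes x k amplitude matrix, columns scaled to unit L2 norm
        (the scale is absorbed into the cell weights).
    components_ : k x genes (``A_.T``), scikit-learn orientation.
    objective_trace_ : per-sweep half squared Frobenius error of the kept
        restart; non-increasing.
    """

    def __init__(self, k: int = 50, max_iter: int = 500, tol: float = 1e-6,
                 n_restarts: int = 3, random_state: int = 0):
        self.k = k
        self.max_iter = max_iter
        self.tol = tol
        self.n_restarts = n_restarts
        self.random_state = random_state

    def _hals(self, V, rng):
        n, g = V.shape
        k = self.k
        mean = V.mean() if not sp.issparse(V) else V.sum() / (n * g)
        scale = np.sqrt(max(mean, 1e-12) / k)
        W = rng.uniform(0.0, 1.0, (n, k)) * scale
        H = rng.uniform(0.0, 1.0, (k, g)) * scale
        v_sqnorm = (V.power(2).sum() if sp.issparse(V)
                    else float(np.sum(V * V)))
        trace = [_objective(V, W, H, v_sqnorm)]
        for _ in range(self.max_iter):
            WtW = W.T @ W
            WtV = (W.T @ V) if not sp.issparse(V) else np.asarray(
                (sp.csr_matrix(W.T) @ V).todense())
            for j in range(k):
                denom = WtW[j, j]
                if denom <= 0:
                    H[j] = 0.0
                    continue
                H[j] = np.maximum(0.0, H[j] + (WtV[j] - WtW[j] @ H) / denom)
            HHt = H @ H.T
            VHt = (V @ H.T) if not sp.issparse(V) else np.asarray(
                (V @ sp.csr_matrix(H.T)).todense())
            for j in range(k):
                denom = HHt[j, j]
                if denom <= 0:
                    W[:, j] = 0.0
                    continue
                W[:, j] = np.maximum(
                    0.0, W[:, j] + (VHt[:, j] - W @ HHt[:, j]) / denom)
            obj = _objective(V, W, H, v_sqnorm)
            trace.append(obj)
            prev = trace[-2]
            if prev > 0 and (prev - obj) / max(prev, 1e-300) < self.tol:
                break
        return W, H, trace

    def fit(self, X, y=None):
        self.fit_transform(X)
        return self

    def fit_transform(self, X, y=None):
        V = X if sp.issparse(X) else np.asarray(X, dtype=float)
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.k > min(V.shape):
            raise ValueError(f"k={self.k} exceeds min(matrix dims)={min(V.shape)}")
        if (V.data if sp.issparse(V) else V).min(initial=0.0) < 0:
            raise ValueError("input matrix must be non-negative")
        best = None
        for r in range(self.n_restarts):
            rng = np.random.default_rng(
                np.random.SeedSequence([int(self.random_state) & 0x7FFFFFFF, r]))
            W, H, trace = self._hals(V, rng)
            if best is None or trace[-1] < best[2][-1]:
                best = (W, H, trace)
        W, H, trace = best
        norms = np.linalg.norm(H, axis=1)
        pos = norms > 0
        H[pos] /= norms[pos, None]
        W[:, pos] *= norms[pos][None, :]
        self.components_ = H
        self.A_ = H.T
        self.objective_trace_ = np.asarray(trace)
        self.reconstruction_err_ = float(trace[-1])
        self.n_iter_ = len(trace) - 1
        return W

    def transform(self, X):
        """Non-negative least-squares projection of new cells onto the
        fitted patterns."""
        V = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X, float)
        A = self.A_
        out = np.empty((V.shape[0], A.shape[1]))
        for i in range(V.shape[0]):
            out[i], _ = _nnls(A, V[i])
        return out


def nmf_fit(norm, k: int, seed: int = 0, max_iter: int = 500,
            tol: float = 1e-6, n_restarts: int = 3) -> PatternNMF:
    """Fit a :class:`PatternNMF` and return the fitted estimator together
    with the cell weights in ``model.P_`` (k x cells)."""
    model = PatternNMF(k=k, max_iter=max_iter, tol=tol,
                       n_restarts=n_restarts, random_state=seed)
    W = model.fit_transform(norm)
    model.P_ = W.T
    return model


def pattern_specificity(weights: np.ndarray, clusters) -> pd.DataFrame:
    """AUROC specificity of each pattern's cell weights for each cluster.

    ``weights`` is cells x k. Clusters with no cells are skipped. Returns
    rows (pattern, cluster, auroc, mean_in, mean_out).
    """
    W = np.asarray(weights, dtype=float)
    clusters = np.asarray(clusters)
    rows = []
    for c in pd.unique(clusters):
        mask = clusters == c
        if mask.sum() == 0 or mask.all():
            continue
        y = mask.astype(int)
        for j in range(W.shape[1]):
            w = W[:, j]
            auroc = 0.5 if np.ptp(w) == 0 else float(roc_auc_score(y, w))
            rows.append((j, c, auroc, float(w[mask].mean()),
                         float(w[~mask].mean())))
    return pd.DataFrame(rows, columns=["pattern", "cluster", "auroc",
                                       "mean_in", "mean_out"])


def select_specific_patterns(spec: pd.DataFrame, target_label,
                             m: int = 4, min_auroc: float = 0.9,
                             cluster_annotations=None) -> list[int]:
    """Patterns most specific to ``target_label``: those whose best cluster
    (highest AUROC) is the target, ranked by AUROC, top ``m`` with AUROC at
    least ``min_auroc``.

    When clusters are finer than lineages (e.g. two MEN subtype clusters),
    pass ``cluster_annotations`` mapping cluster id -> lineage label; a
    pattern is then on-target when its best cluster annotates to
    ``target_label``.
    """
    best = spec.loc[spec.groupby("pattern")["auroc"].idxmax()]
    if cluster_annotations is not None:
        target_mask = best["cluster"].map(
            lambda c: cluster_annotations.get(c, c) == target_label)
    else:
        target_mask = best["cluster"] == target_label
    on_target = best[target_mask].sort_values("auroc", ascending=False)
    if on_target.empty:
        warnings.warn(f"no pattern peaks on {target_label!r}")
        return []
    qualified = on_target[on_target["auroc"] >= min_auroc]
    if len(qualified) < m:
        warnings.warn(
            f"only {len(qualified)} patterns reach AUROC >= {min_auroc} "
            f"for {target_label!r} (requested {m})")
        return qualified["pattern"].astype(int).tolist()
    return qualified["pattern"].astype(int).head(m).tolist()


def hcluster_patterns(P: np.ndarray, distance: str = "euclidean",
                      linkage: str = "average") -> np.ndarray:
    """Dendrogram leaf order of pattern weight rows for heatmap display."""
    P = np.asarray(P, dtype=float)
    if P.shape[0] < 2:
        raise ValueError("need >= 2 patterns")
    Z = scipy_linkage(pdist(P, metric=distance), method=linkage)
    return leaves_list(Z)
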