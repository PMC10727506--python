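"""Linear embedding and mutual-nearest-neighbors batch correction."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

__all__ = ["Embedding", "HVGPCA", "pca_embed", "MNNCorrector", "mnn_correct"]


@dataclass
class Embedding:
    coords: np.ndarray          # cells x d
    loadings: np.ndarray        # feature genes x d
    feature_genes: list[str]
    explained_variance_ratio: np.ndarray | None = None


class HVGPCA(BaseEstimator, TransformerMixin):
    """PCA on the top variable genes of a log-normalized matrix.

    Genes are ranked by variance of the normalized values and the top
    ``n_hvg`` retained (``n_hvg=None`` keeps all genes), centered, and
    projected onto the top ``d`` principal directions.
    """

    def __init__(self, d: int = 50, n_hvg: int | None = 2000):
        self.d = d
        self.n_hvg = n_hvg

    def fit(self, X, y=None):
        self.fit_transform(X)
        return self

    def fit_transform(self, X, y=None):
        if self.d < 2:
            raise ValueError("d must be >= 2")
        Xd = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X, float)
        n, g = Xd.shape
        var = Xd.var(axis=0)
        if self.n_hvg is not None and self.n_hvg < g:
            order = np.argsort(var)[::-1]
            keep = np.sort(order[: self.n_hvg])
        else:
            keep = np.arange(g)
        if self.d > min(n, keep.size):
            raise ValueError(
                f"d={self.d} exceeds min(n_cells, n_features)={min(n, keep.size)}")
        self.feature_index_ = keep
        pca = PCA(n_components=self.d, svd_solver="auto", random_state=0)
        coords = pca.fit_transform(Xd[:, keep])
        self.mean_ = pca.mean_
        self.loadings_ = pca.components_.T          # features x d
        self.explained_variance_ratio_ = pca.explained_variance_ratio_
        self.singular_values_ = pca.singular_values_
        return coords

    def transform(self, X):
        Xd = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X, float)
        return (Xd[:, self.feature_index_] - self.mean_) @ self.loadings_


def pca_embed(norm, d: int, n_hvg: int | None = 2000,
              gene_names: list[str] | None = None) -> Embedding:
    """Top-``n_hvg``-variance feature selection, centering, and a ``d``-
    dimensional PCA embedding."""
    est = HVGPCA(d=d, n_hvg=n_hvg)
    coords = est.fit_transform(norm)
    names = (list(np.asarray(gene_names)[est.feature_index_])
             if gene_names is not None
             else [str(i) for i in est.feature_index_])
    return Embedding(coords=coords, loadings=est.loadings_, feature_genes=names,
                     explained_variance_ratio=est.explained_variance_ratio_)


class MNNCorrector(BaseEstimator, TransformerMixin):
    """Sequential mutual-nearest-neighbors batch correction in embedding
    space.

    Batches are merged in order of first appearance. For each incoming
    batch, mutual k-nearest-neighbor pairs against the already-merged
    reference define candidate correspondences; each incoming cell's
    closest mutual pair is kept as its correspondence (vector = reference
    minus incoming), and every incoming cell is then shifted by a
    Gaussian-kernel-weighted average of these correspondence vectors, the
    kernel evaluated at the cell's distance to each pair's midpoint with
    bandwidth equal to the median kept-pair distance. Filtering to
    best-match pairs removes the large tangential vectors that plain
    pair averaging accumulates, so coinciding batches receive exactly
    zero correction and a pure translation smaller than the data's
    nearest-neighbor spacing is removed exactly. Output dimensionality is
    unchanged; a single batch passes through untouched.
    """

    def __init__(self, k_mnn: int = 20):
        self.k_mnn = k_mnn

    def fit_transform(self, X, y=None, batch=None):
        if batch is None:
            raise ValueError("batch labels are required")
        X = np.asarray(X, dtype=float)
        batch = np.asarray(batch)
        labels = list(dict.fromkeys(batch))          # order of first appearance
        for lab in labels:
            if (batch == lab).sum() < self.k_mnn:
                raise ValueError(
                    f"batch {lab!r} has fewer than k_mnn={self.k_mnn} cells")
        out = X.copy()
        if len(labels) == 1:
            self.batch_order_ = labels
            return out
        merged = np.flatnonzero(batch == labels[0])
        for lab in labels[1:]:
            incoming = np.flatnonzero(batch == lab)
            ref = out[merged]
            new = out[incoming]
            k = min(self.k_mnn, len(merged), len(incoming))
            nn_ref = NearestNeighbors(n_neighbors=k).fit(ref)
            nn_new = NearestNeighbors(n_neighbors=k).fit(new)
            dist_rn, ref_of_new = nn_ref.kneighbors(new)
            new_of_ref = nn_new.kneighbors(ref, return_distance=False)
            ref_sets = [set(row) for row in new_of_ref]
            # closest mutual pair per incoming cell
            pr, pn, pdist = [], [], []
            for n_i in range(len(new)):
                for j, r in enumerate(ref_of_new[n_i]):   # ascending distance
                    if n_i in ref_sets[r]:
                        pr.append(r)
                        pn.append(n_i)
                        pdist.append(dist_rn[n_i, j])
                        break
            if not pr:
                merged = np.concatenate([merged, incoming])
                continue
            pr = np.asarray(pr)
            pn = np.asarray(pn)
            vectors = ref[pr] - new[pn]
            anchors = 0.5 * (ref[pr] + new[pn])   # pair midpoints
            sigma = float(np.median(pdist))
            # chunk the cell x anchor distance computation
            d2 = np.empty((len(new), len(anchors)))
            step = max(1, 4_000_000 // max(len(anchors), 1))
            for i0 in range(0, len(new), step):
                blk = new[i0:i0 + step]
                d2[i0:i0 + step] = (
                    (blk[:, None, :] - anchors[None, :, :]) ** 2).sum(-1)
            if sigma > 0:
                d2 = d2 - d2.min(axis=1, keepdims=True)  # stable exponent
                w = np.exp(-d2 / (2.0 * sigma ** 2))
            else:
                w = np.ones_like(d2)                      # degenerate: uniform
            w /= w.sum(axis=1, keepdims=True)
            out[incoming] = new + w @ vectors
            merged = np.concatenate([merged, incoming])
        self.batch_order_ = labels
        return out

    def fit(self, X, y=None, batch=None):
        self.fit_transform(X, batch=batch)
        return self


def mnn_correct(embedding: Embedding | np.ndarray, batch_labels,
                k_mnn: int = 20):
    """Functional wrapper over :class:`MNNCorrector`; accepts either an
    :class:`Embedding` (returns a corrected copy) or a coordinate array."""
    if isinstance(embedding, Embedding):
        corrected = MNNCorrector(k_mnn=k_mnn).fit_transform(
            embedding.coords, batch=batch_labels)
        return Embedding(coords=corrected, loadings=embedding.loadings,
                         feature_genes=embedding.feature_genes,
                         explained_variance_ratio=embedding.explained_variance_ratio)
    return MNNCorrector(k_mnn=k_mnn).fit_transform(
        np.asarray(embedding), batch=batch_labels)
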