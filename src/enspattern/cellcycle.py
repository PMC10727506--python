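"""Continuous cell-cycle position inference.

Cells are projected into a 2-D cell-cycle reference space (the top two
principal components of the centered cell-cycle-gene submatrix of a
reference cohort). The cell-cycle position theta is the angle of the cell
in that plane measured from the origin; cells with theta in the arc
[0.5pi, 1.5pi) are binarized as "cycling" (S through G2/M), the rest as
"non-cycling" (G1/G0). Periodic gene-expression dynamics over theta are
summarized with a wrapped tricube local-linear (loess-style) smoother.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "CCReference",
    "CellCycleScorer",
    "build_cc_reference",
    "cc_position",
    "classify_cycling",
    "periodic_loess",
    "cycling_summary",
    "circular_correlation",
]


@dataclass
class CCReference:
    loadings: np.ndarray         # cc genes x 2, orthogonal columns
    cc_genes: list[str]
    center: np.ndarray           # per-gene centering vector


class CellCycleScorer(BaseEstimator, TransformerMixin):
    """Build a 2-D cell-cycle reference on fit(); transform() returns
    (e1, e2, theta) per cell."""

    def __init__(self, cc_genes=None):
        self.cc_genes = cc_genes

    def _subset(self, X, gene_names, wanted):
        lut = {g.lower(): i for i, g in enumerate(gene_names)}
        idx = [lut[g.lower()] for g in wanted if g.lower() in lut]
        if len(idx) < 4:
            raise ValueError(
                f"only {len(idx)} cell-cycle genes matched; need >= 4")
        Xd = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X, float)
        return Xd[:, idx], [gene_names[i] for i in idx]

    def fit(self, X, y=None, gene_names=None, ref_theta=None):
        """Build the 2-D reference space from reference cells.

        A PCA basis fixes the plane but not the phase origin or the sense
        of rotation. When ``ref_theta`` (known cell-cycle angles of the
        reference cells, NaN allowed) is given, the loadings are reflected
        and rotated once so the embedding angles agree with it — the
        analog of shipping a pretrained, consistently oriented reference.
        """
        from .genes import default_cc_genes
        wanted = self.cc_genes if self.cc_genes is not None else default_cc_genes()
        if gene_names is None:
            raise ValueError("gene_names are required")
        sub, matched = self._subset(X, list(gene_names), wanted)
        if sub.shape[0] < 10:
            raise ValueError("need >= 10 reference cells")
        center = sub.mean(axis=0)
        centered = sub - center
        if np.allclose(centered, 0.0):
            raise ValueError("zero variance in cell-cycle genes")
        # PCs 1-2 of the cc-gene submatrix
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        loadings = vt[:2].T
        if ref_theta is not None:
            ref_theta = np.asarray(ref_theta, dtype=float)
            ok = ~np.isnan(ref_theta)
            e = centered[ok] @ loadings
            est = np.arctan2(e[:, 1], e[:, 0])
            best = None
            for sign in (1.0, -1.0):
                z = np.exp(1j * (ref_theta[ok] - np.arctan2(sign * e[:, 1],
                                                            e[:, 0])))
                resultant = z.mean()
                if best is None or abs(resultant) > best[0]:
                    best = (abs(resultant), sign, np.angle(resultant))
            _, sign, offset = best
            # row-vector rotation by +offset: e' = e @ rot
            rot = np.array([[math.cos(offset), math.sin(offset)],
                            [-math.sin(offset), math.cos(offset)]])
            loadings = (loadings * np.array([1.0, sign])) @ rot
        self.reference_ = CCReference(loadings=loadings, cc_genes=matched,
                                      center=center)
        return self

    def transform(self, X, gene_names=None):
        if gene_names is None:
            raise ValueError("gene_names are required")
        ref = self.reference_
        sub, matched = self._subset(X, list(gene_names), ref.cc_genes)
        if matched != ref.cc_genes:
            # align on the genes present in both, in reference order
            keep = [i for i, g in enumerate(ref.cc_genes) if g in set(matched)]
            if len(keep) < 4:
                raise ValueError("fewer than 4 cell-cycle genes matched")
            lut = {g: j for j, g in enumerate(matched)}
            sub = sub[:, [lut[ref.cc_genes[i]] for i in keep]]
            loadings = ref.loadings[keep]
            center = ref.center[keep]
        else:
            loadings, center = ref.loadings, ref.center
        e = (sub - center) @ loadings
        theta = np.mod(np.arctan2(e[:, 1], e[:, 0]), 2.0 * math.pi)
        low_conf = ~np.any(sub > 0, axis=1)
        return pd.DataFrame({"e1": e[:, 0], "e2": e[:, 1], "theta": theta,
                             "cycling": classify_cycling(theta),
                             "low_confidence": low_conf})


def build_cc_reference(ref_norm, cc_genes, gene_names,
                       ref_theta=None) -> CCReference:
    """PCA (top 2 components) on the centered cell-cycle-gene submatrix of a
    normalized reference cohort; optionally oriented against known
    reference angles (see :meth:`CellCycleScorer.fit`)."""
    scorer = CellCycleScorer(cc_genes=cc_genes)
    scorer.fit(ref_norm, gene_names=gene_names, ref_theta=ref_theta)
    return scorer.reference_


def cc_position(norm, reference: CCReference, gene_names) -> pd.DataFrame:
    """Per-cell 2-D embedding coordinates and theta = atan2(e2, e1) mod 2pi.

    Cells with zero cell-cycle-gene expression are flagged low-confidence.
    """
    scorer = CellCycleScorer(cc_genes=reference.cc_genes)
    scorer.reference_ = reference
    return scorer.transform(norm, gene_names=gene_names)


def classify_cycling(theta) -> np.ndarray | bool:
    """Cycling iff 0.5pi <= theta < 1.5pi (half-open; the boundary angle
    belongs to the cycling arc)."""
    th = np.asarray(theta, dtype=float)
    out = (th >= 0.5 * math.pi) & (th < 1.5 * math.pi)
    return bool(out) if np.isscalar(theta) else out


def periodic_loess(theta, y, span: float = 0.3, grid_n: int = 100):
    """Loess-style periodic smoother on the circle.

    Local linear regression with tricube weights on circular distance
    min(|dtheta|, 2pi - |dtheta|); the fit wraps at 0/2pi. Returns
    (grid, fitted) with ``grid_n`` equally spaced angles on [0, 2pi).
    """
    theta = np.mod(np.asarray(theta, dtype=float), 2.0 * math.pi)
    y = np.asarray(y, dtype=float)
    if theta.size < 10:
        raise ValueError("need >= 10 points")
    if not 0.0 < span <= 1.0:
        raise ValueError("span must be in (0, 1]")
    if np.ptp(theta) == 0:
        raise ValueError("all theta identical")
    n = theta.size
    q = max(2, int(math.ceil(span * n)))
    grid = np.linspace(0.0, 2.0 * math.pi, grid_n, endpoint=False)
    fitted = np.empty(grid_n)
    for gi, t0 in enumerate(grid):
        delta = theta - t0
        delta = np.mod(delta + math.pi, 2.0 * math.pi) - math.pi  # signed, wrapped
        dist = np.abs(delta)
        idx = np.argpartition(dist, q - 1)[:q]
        dmax = dist[idx].max()
        if dmax == 0:
            fitted[gi] = y[idx].mean()
            continue
        w = (1.0 - (dist[idx] / dmax) ** 3) ** 3
        w = np.maximum(w, 1e-9)
        X = np.column_stack([np.ones(q), delta[idx]])
        WX = X * w[:, None]
        beta, *_ = np.linalg.lstsq(WX.T @ X, WX.T @ y[idx], rcond=None)
        fitted[gi] = beta[0]
    return grid, fitted


def cycling_summary(positions, cell_subset=None):
    """(n_cycling, n_total, fraction) of cycling cells within a subset.

    ``positions`` is the table from :func:`cc_position` (or anything with a
    ``cycling`` column); ``cell_subset`` is a boolean/index mask.
    """
    cyc = positions["cycling"] if hasattr(positions, "columns") else positions
    cyc = np.asarray(cyc, dtype=bool)
    if cell_subset is not None:
        cyc = cyc[np.asarray(cell_subset)]
    if cyc.size == 0:
        raise ValueError("empty cell subset")
    n_cyc = int(cyc.sum())
    return n_cyc, int(cyc.size), n_cyc / cyc.size


def circular_correlation(a, b) -> float:
    """Fisher–Lee circular correlation between two angle vectors.

    Invariant to rotation of either variable; reflection flips the sign.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError("length mismatch")
    da = a[:, None] - a[None, :]
    db = b[:, None] - b[None, :]
    num = np.sum(np.sin(da) * np.sin(db))
    den = math.sqrt(np.sum(np.sin(da) ** 2) * np.sum(np.sin(db) ** 2))
    if den == 0:
        return 0.0
    return float(num / den)
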