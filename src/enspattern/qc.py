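"""Droplet and cell quality control, barcode-rank statistics, size factors,
and log normalization.

Filtering follows the two presets used for the murine LM-MP libraries:
a minimum-UMI threshold (200 for the adult P180 libraries, 600 for the P21
libraries) combined with a mitochondrial read ratio strictly below 20%,
where mitochondrial counts are the sum over the 37 genes of the
mitochondrial genome. Droplet calling for unfiltered pools uses knee and
inflection landmarks of the log-log barcode-rank curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.interpolate import UnivariateSpline
from sklearn.base import BaseEstimator, TransformerMixin

from .genes import MOUSE_MITO_GENES

__all__ = [
    "QC_PRESETS",
    "BarcodeRankStats",
    "compute_qc_metrics",
    "barcode_rank_stats",
    "filter_cells",
    "size_factors",
    "normalize",
    "log_normalize",
    "LogNormalizer",
]

#: Filtering presets: adult (P180) and juvenile (P21) LM-MP libraries.
QC_PRESETS = {
    "p180": {"min_umi": 200, "max_mito": 0.20},
    "p21": {"min_umi": 600, "max_mito": 0.20},
}


def _totals(X) -> np.ndarray:
    return np.asarray(X.sum(axis=1)).ravel() if sp.issparse(X) else X.sum(axis=1)


def compute_qc_metrics(
    adata: ad.AnnData,
    mito_genes: set[str] | None = None,
) -> pd.DataFrame:
    """Per-cell totals, mitochondrial totals and ratios.

    ``mito_genes`` defaults to the ``is_mito`` column of ``adata.var`` when
    present, else the bundled 37-gene murine mitochondrial annotation.
    Missing mito genes only warn. A cell with zero total gets ratio 0 and a
    ``degenerate`` flag (such cells can never pass a positive UMI filter).
    """
    if adata.n_obs == 0 or adata.n_vars == 0:
        raise ValueError("empty count matrix")
    if mito_genes is None and "is_mito" in adata.var:
        mask = adata.var["is_mito"].to_numpy(dtype=bool)
    else:
        wanted = set(mito_genes) if mito_genes is not None else set(MOUSE_MITO_GENES)
        present = wanted & set(adata.var_names)
        if len(present) < len(wanted):
            import warnings
            warnings.warn(
                f"{len(wanted) - len(present)} of {len(wanted)} mitochondrial "
                "genes absent from the matrix")
        mask = adata.var_names.isin(present)
    total = _totals(adata.X)
    mito = _totals(adata[:, mask].X) if mask.any() else np.zeros(adata.n_obs)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(total > 0, mito / np.maximum(total, 1e-300), 0.0)
    return pd.DataFrame(
        {
            "total_umi": total.astype(np.int64),
            "mito_umi": mito.astype(np.int64),
            "mito_ratio": ratio,
            "degenerate": total == 0,
        },
        index=adata.obs_names,
    )


@dataclass
class BarcodeRankStats:
    """Knee and inflection landmarks of the log-log barcode-rank curve."""

    knee_rank: int
    knee_total: int
    inflection_rank: int
    inflection_total: int
    curve: pd.DataFrame          # unique (rank, total, log_rank, log_total, smooth)
    low_confidence: bool = False


def barcode_rank_stats(totals: np.ndarray) -> BarcodeRankStats:
    """Knee/inflection statistics of a barcode-rank curve.

    Totals are sorted descending and ties collapsed to unique
    (rank, total) points with the rank of a tie group taken as its last
    (largest) rank. A cubic smoothing spline is fit to log10(total) as a
    function of log10(rank); the inflection is the point of most negative
    first derivative to the right of the curve's upper plateau, and the
    knee the point of minimum signed curvature left of the inflection.
    A curve with no drop steeper than a plain power law is flagged
    low-confidence.
    """
    totals = np.asarray(totals, dtype=float)
    totals = totals[totals > 0]
    if totals.size < 100:
        raise ValueError("need >= 100 barcodes with positive totals")
    if np.unique(totals).size < 2:
        raise ValueError("degenerate barcode-rank curve: all totals equal")
    order = np.sort(totals)[::-1]
    uniq, counts = np.unique(order, return_counts=True)
    uniq = uniq[::-1]
    counts = counts[::-1]
    rank = np.cumsum(counts)            # last rank of each tie group
    x = np.log10(rank.astype(float))
    y = np.log10(uniq)

    # smoothing proportional to the curve's scale; k=3 needs >= 4 points
    if x.size >= 4:
        w = np.ones_like(x)
        spl = UnivariateSpline(x, y, w=w, k=3, s=float(x.size) * 1e-3)
        smooth = spl(x)
        d1 = spl.derivative(1)(x)
        d2 = spl.derivative(2)(x)
    else:
        smooth = y
        d1 = np.gradient(y, x)
        d2 = np.gradient(d1, x)

    # upper plateau: leading points still within 5% (log-range) of the top
    y_span = y[0] - y[-1]
    plateau = y > y[0] - 0.05 * y_span
    right = ~plateau
    if not right.any():
        right = np.ones_like(plateau)
    idx_right = np.where(right)[0]
    infl = idx_right[np.argmin(d1[idx_right])]

    curvature = d2 / np.power(1.0 + d1 ** 2, 1.5)
    left = np.arange(x.size) <= infl
    idx_left = np.where(left)[0]
    knee = idx_left[np.argmin(curvature[idx_left])]
    if knee > infl:
        knee = infl

    low_confidence = d1[infl] > -2.0
    curve = pd.DataFrame(
        {"rank": rank, "total": uniq, "log_rank": x, "log_total": y,
         "smooth_log_total": smooth})
    return BarcodeRankStats(
        knee_rank=int(rank[knee]), knee_total=int(uniq[knee]),
        inflection_rank=int(rank[infl]), inflection_total=int(uniq[infl]),
        curve=curve, low_confidence=bool(low_confidence),
    )


def filter_cells(
    adata: ad.AnnData,
    min_umi: int = 200,
    max_mito: float = 0.20,
    mito_genes: set[str] | None = None,
) -> tuple[np.ndarray, ad.AnnData]:
    """Boolean pass mask and the filtered matrix.

    A cell passes iff total UMI >= ``min_umi`` (inclusive: a minimum
    threshold) and mitochondrial ratio < ``max_mito`` (strict: "less
    than"). Idempotent.
    """
    if min_umi < 0:
        raise ValueError("min_umi must be >= 0")
    if not 0.0 < max_mito <= 1.0:
        raise ValueError("max_mito must be in (0, 1]")
    qc = compute_qc_metrics(adata, mito_genes=mito_genes)
    mask = (qc["total_umi"].to_numpy() >= min_umi) & \
           (qc["mito_ratio"].to_numpy() < max_mito)
    return mask, adata[mask].copy()


def size_factors(totals: np.ndarray) -> np.ndarray:
    """Cell-size scaling factors: library size over its geometric mean, so
    the log factors average to zero and their product is 1."""
    totals = np.asarray(totals, dtype=float)
    if (totals <= 0).any():
        raise ValueError("all totals must be > 0; filter cells first")
    log_t = np.log(totals)
    return np.exp(log_t - log_t.mean())


def normalize(X, sf: np.ndarray, log_base: int = 10, pseudo: float = 1.0):
    """log_base(count / sf + pseudo) with sparse zeros preserved exactly.

    base 10 matches the LM-MP processing; base 2 matches the
    single-nucleus reanalysis convention.
    """
    if log_base not in (2, 10):
        raise ValueError("log_base must be 2 or 10")
    sf = np.asarray(sf, dtype=float)
    if (sf <= 0).any():
        raise ValueError("size factors must be > 0")
    denom = np.log(log_base)
    if sp.issparse(X):
        X = X.tocsr().astype(float)
        out = X.copy()
        row = np.repeat(np.arange(X.shape[0]), np.diff(X.indptr))
        out.data = np.log(X.data / sf[row] + pseudo) / denom
        return out
    return np.log(np.asarray(X, dtype=float) / sf[:, None] + pseudo) / denom


class LogNormalizer(BaseEstimator, TransformerMixin):
    """Size-factor log normalization as a scikit-learn transformer.

    fit() learns per-cell size factors from row totals; transform()
    returns log_base(count/sf + 1). Because factors are per-row, transform
    must be applied to the matrix it was fit on (or pass ``sf`` yourself
    via :func:`normalize`).
    """

    def __init__(self, log_base: int = 10, pseudo: float = 1.0):
        self.log_base = log_base
        self.pseudo = pseudo

    def fit(self, X, y=None):
        totals = _totals(X)
        self.size_factors_ = size_factors(totals)
        return self

    def transform(self, X):
        return normalize(X, self.size_factors_, self.log_base, self.pseudo)


def log_normalize(adata: ad.AnnData, log_base: int = 10) -> ad.AnnData:
    """Convenience: attach ``obs['size_factor']`` and a ``lognorm`` layer."""
    norm = LogNormalizer(log_base=log_base).fit(adata.X)
    adata.obs["size_factor"] = norm.size_factors_
    adata.layers["lognorm"] = norm.transform(adata.X)
    return adata
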