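"""Transfer learning: project external expression data into a fixed
pattern space and test differential pattern usage across groups.

New profiles (single cells, single nuclei, or bulk samples, on a log
scale) are regressed onto the fixed gene-amplitude matrix of selected
patterns by non-negative least squares; per-cell weights are aggregated
to per-sample means before group testing to avoid pseudoreplication.
Two groups are compared with Student's t-test (equal variance by
default), three or more with one-way ANOVA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from scipy.optimize import nnls as _nnls
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ProjectionResult",
    "match_features",
    "project",
    "cluster_on_projection",
    "aggregate_by_sample",
    "assign_age_group",
    "differential_usage",
]

#: Inclusive age bins (years) used to pool human samples into cohorts.
AGE_GROUPS = {"Juvenile": (4.0, 12.0), "Adult": (20.0, 50.0),
              "Aged": (60.0, 75.0)}


@dataclass
class ProjectionResult:
    weights: pd.DataFrame        # targets x m, non-negative in NNLS mode
    r2: pd.Series                # per-target R^2
    matched_gene_count: int
    target_kind: str = "cell"


def match_features(ref_genes, target_genes, ortholog_map=None,
                   min_match_frac: float = 0.5):
    """Case-insensitive symbol matching between a reference gene list and a
    target gene list, optionally translating target symbols through a 1:1
    ortholog map first (ambiguous rows dropped with a warning).

    Returns (ref_idx, target_idx) index arrays. Raises when fewer than
    ``min_match_frac`` of the reference genes match.
    """
    ref_genes = list(ref_genes)
    target_genes = list(target_genes)
    if not ref_genes or not target_genes:
        raise ValueError("gene lists must be non-empty")
    translated = target_genes
    if ortholog_map is not None:
        if isinstance(ortholog_map, pd.DataFrame):
            pairs = list(zip(ortholog_map.iloc[:, 0], ortholog_map.iloc[:, 1]))
        else:
            pairs = list(ortholog_map.items())
        src_counts = pd.Series([p[0].lower() for p in pairs]).value_counts()
        dst_counts = pd.Series([p[1].lower() for p in pairs]).value_counts()
        ambiguous = {s for s, c in src_counts.items() if c > 1} | set()
        amb_dst = {d for d, c in dst_counts.items() if c > 1}
        table = {}
        dropped = 0
        for src, dst in pairs:
            if src.lower() in ambiguous or dst.lower() in amb_dst:
                dropped += 1
                continue
            table[src.lower()] = dst
        if dropped:
            warnings.warn(f"{dropped} ambiguous ortholog rows dropped")
        translated = [table.get(g.lower(), g) for g in target_genes]
    target_lut = {}
    for i, g in enumerate(translated):
        target_lut.setdefault(g.lower(), i)
    ref_idx, tgt_idx = [], []
    for i, g in enumerate(ref_genes):
        j = target_lut.get(g.lower())
        if j is not None:
            ref_idx.append(i)
            tgt_idx.append(j)
    frac = len(ref_idx) / len(ref_genes)
    if frac < min_match_frac:
        raise ValueError(
            f"only {frac:.1%} of reference genes matched the target "
            f"(minimum {min_match_frac:.0%})")
    return np.asarray(ref_idx), np.asarray(tgt_idx)


def project(target_norm, A_sel: np.ndarray, nonneg: bool = True,
            pattern_names=None, target_names=None,
            target_kind: str = "cell") -> ProjectionResult:
    """Project target profiles onto fixed pattern amplitudes.

    ``target_norm`` is targets x genes (log scale), ``A_sel`` genes x m
    restricted to the matched genes. Each target row y gets weights
    p* = argmin_{p>=0} ||y - A_sel p||^2 (NNLS; ordinary least squares
    when ``nonneg=False``, with a minimum-norm solution and a warning if
    ``A_sel`` is rank-deficient). R^2 = 1 - RSS / total sum of squares
    about the target's mean.
    """
    Y = (np.asarray(target_norm.todense()) if sp.issparse(target_norm)
         else np.asarray(target_norm, dtype=float))
    if Y.ndim == 1:
        Y = Y[None, :]
    A = np.asarray(A_sel, dtype=float)
    if A.shape[0] != Y.shape[1]:
        raise ValueError("A_sel rows must equal target gene count")
    m = A.shape[1]
    if m < 1:
        raise ValueError("need at least one pattern")
    n = Y.shape[0]
    W = np.empty((n, m))
    if nonneg:
        for i in range(n):
            W[i], _ = _nnls(A, Y[i])
    else:
        if np.linalg.matrix_rank(A) < m:
            warnings.warn("rank-deficient amplitudes: minimum-norm OLS solution")
        W = np.linalg.lstsq(A, Y.T, rcond=None)[0].T
    resid = Y - W @ A.T
    rss = np.sum(resid ** 2, axis=1)
    tss = np.sum((Y - Y.mean(axis=1, keepdims=True)) ** 2, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(tss > 0, 1.0 - rss / np.maximum(tss, 1e-300), np.nan)
    cols = (list(pattern_names) if pattern_names is not None
            else [f"pattern_{j}" for j in range(m)])
    idx = (list(target_names) if target_names is not None
           else [f"target_{i}" for i in range(n)])
    return ProjectionResult(
        weights=pd.DataFrame(W, index=idx, columns=cols),
        r2=pd.Series(r2, index=idx, name="r2"),
        matched_gene_count=A.shape[0],
        target_kind=target_kind,
    )


def cluster_on_projection(weights, knn_k: int = 10, resolution: float = 5e-3,
                          seed: int = 0, method: str = "leiden"):
    """Graph clustering of targets in pattern-weight space."""
    from .clustering import cluster_graph, snn_graph
    W = weights.values if isinstance(weights, pd.DataFrame) else np.asarray(weights)
    if W.shape[1] < 2:
        raise ValueError("need >= 2 patterns to cluster on")
    g = snn_graph(W, knn_k)
    return cluster_graph(g, method=method, resolution=resolution, seed=seed)


def aggregate_by_sample(weights: pd.DataFrame, sample_ids) -> pd.DataFrame:
    """Arithmetic mean pattern weight per (sample, pattern); cell count per
    sample recorded in the ``n_cells`` column."""
    sample_ids = pd.Series(np.asarray(sample_ids), index=weights.index,
                           name="sample")
    if sample_ids.isna().any():
        raise ValueError("every target needs a sample id")
    grouped = weights.groupby(sample_ids, sort=False)
    means = grouped.mean()
    means["n_cells"] = grouped.size()
    return means


def assign_age_group(age_years: float) -> str:
    """Juvenile = [4, 12], Adult = [20, 50], Aged = [60, 75] years,
    boundaries inclusive; ages in the gaps are ``"unassigned"``."""
    if age_years < 0:
        raise ValueError("age must be >= 0")
    for label, (lo, hi) in AGE_GROUPS.items():
        if lo <= age_years <= hi:
            return label
    return "unassigned"


def differential_usage(sample_weights: pd.DataFrame, group_labels,
                       test: str = "auto",
                       equal_var: bool = True) -> pd.DataFrame:
    """Per-pattern group comparison of per-sample mean weights.

    Two groups: two-sided Student t (equal variance unless
    ``equal_var=False`` for Welch). Three or more: one-way ANOVA with F
    and (DFn, DFd) = (n_groups - 1, n_samples - n_groups). BH-adjusted q
    across patterns is reported alongside the raw p.
    """
    W = sample_weights.drop(columns=["n_cells"], errors="ignore")
    groups = pd.Series(np.asarray(group_labels), index=W.index, name="group")
    uniq = list(pd.unique(groups))
    if len(uniq) < 2:
        raise ValueError("need >= 2 groups")
    sizes = groups.value_counts()
    if (sizes < 2).any():
        small = sizes[sizes < 2].index.tolist()
        raise ValueError(f"groups with < 2 samples: {small}")
    if test == "auto":
        test = "t" if len(uniq) == 2 else "anova"
    rows = []
    for pat in W.columns:
        arrays = [W.loc[groups == g, pat].to_numpy(dtype=float) for g in uniq]
        means = {f"mean_{g}": float(a.mean()) for g, a in zip(uniq, arrays)}
        sems = {f"sem_{g}": float(stats.sem(a)) if a.size > 1 else np.nan
                for g, a in zip(uniq, arrays)}
        if test == "t":
            if len(uniq) != 2:
                raise ValueError("t-test requires exactly 2 groups")
            res = stats.ttest_ind(arrays[0], arrays[1], equal_var=equal_var)
            statistic, p = float(res.statistic), float(res.pvalue)
            df = (arrays[0].size + arrays[1].size - 2) if equal_var \
                else float(res.df)
            dfn = dfd = None
        elif test == "anova":
            dfn = len(uniq) - 1
            dfd = sum(a.size for a in arrays) - len(uniq)
            if np.ptp(np.concatenate(arrays)) == 0:
                statistic, p = 0.0, 1.0
            else:
                f_res = stats.f_oneway(*arrays)
                statistic, p = float(f_res.statistic), float(f_res.pvalue)
                if not np.isfinite(statistic):       # identical groups
                    statistic, p = 0.0, 1.0
            df = None
        else:
            raise ValueError("test must be 'auto', 't', or 'anova'")
        rows.append({"pattern": pat, "test": test, "statistic": statistic,
                     "df": df, "dfn": dfn, "dfd": dfd, "p": p,
                     **means, **sems})
    out = pd.DataFrame(rows)
    out["bh_q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out
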