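"""Synthetic LM-MP-style cohorts for exercising the analysis pipeline.

The generator emulates the statistical structure the pipeline assumes:
cells whose expression arises from a small number of non-negative gene
programs (two of them MEN-like), negative-binomial counts with log-normal
library sizes, per-cell mitochondrial mass, gene-wise multiplicative batch
effects, an age-structured cohort whose MEN-like composition follows the
measured lineage proportions, empty-droplet background, platform-shifted
target datasets, bulk mixtures with a planted disease shift, and a
subpopulation carrying circular cell-cycle structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.interpolate import PchipInterpolator

from ._rng import child_rng
from .genes import MOUSE_MITO_GENES, default_cc_genes

__all__ = [
    "CellType",
    "SimConfig",
    "GroundTruth",
    "composition_curve",
    "default_cell_types",
    "simulate_reference_cohort",
    "simulate_target_dataset",
    "simulate_bulk_cohort",
    "simulate_cellcycle_cohort",
    "simulate_droplet_pool",
    "expected_profile_matrix",
]

#: Measured MEN-like lineage proportions by post-natal age (days) used to
#: anchor the default composition curve.
COMPOSITION_ANCHORS: tuple[tuple[float, float], ...] = (
    (11.0, 0.0412),
    (22.0, 0.2963),
    (60.0, 0.4638),
    (180.0, 0.5729),
    (510.0, 0.9599),
)

LINEAGES = ("MEN-like", "NEN-like", "glia-like", "other")

#: Lineage marker genes planted on the dominant pattern(s) of each lineage so
#: that signature-based cluster annotation is exercisable end to end.
_LINEAGE_MARKERS: Mapping[str, tuple[str, ...]] = {
    "MEN-like": ("Calcb", "Met", "Cdh3"),
    "NEN-like": ("Ret",),
    "glia-like": ("Sox10", "Ncam1"),
}


@dataclass(frozen=True)
class CellType:
    """One generated cell type: a label, a lineage, and its program mixture."""

    label: str
    lineage: str
    mixture: tuple[float, ...]
    base_weight: float = 1.0  # share of the non-MEN mass (ignored for MEN-like)


def default_cell_types(k_true: int = 6) -> tuple[CellType, ...]:
    """Six cell types over ``k_true`` programs: two MEN-like, one NEN-like,
    one glia-like, two other mesenchymal/immune types.

    Each type loads 0.85 on its own program and spreads the rest uniformly,
    so programs are distinct but cells are not pure single-program mixtures.
    """
    if k_true < 6:
        raise ValueError("default cell types require k_true >= 6")
    labels = [
        ("MEN-1", "MEN-like", 1.0),
        ("MEN-2", "MEN-like", 1.0),
        ("NEN", "NEN-like", 0.45),
        ("neuroglia", "glia-like", 0.30),
        ("fibroblast", "other", 0.15),
        ("immune", "other", 0.10),
    ]
    out = []
    for i, (label, lineage, w) in enumerate(labels):
        mix = np.full(k_true, 0.15 / (k_true - 1))
        mix[i] = 0.85
        out.append(CellType(label, lineage, tuple(mix), w))
    return tuple(out)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults are the study conditions: 500 non-mitochondrial genes, six
    generating programs (two MEN-like), five aged samples of 400 cells
    (ages 11–510 days) whose MEN-like composition follows the anchored
    curve, NB dispersion phi = 10, and log-normal library sizes around
    2,000 UMI.
    """

    n_genes: int = 500
    n_true_patterns: int = 6
    cell_types: tuple[CellType, ...] | None = None
    cells_per_sample: int = 400
    library_size_meanlog: float = math.log(2000.0)
    library_size_sdlog: float = 0.35
    nb_dispersion: float = 10.0
    mito_gene_count: int = 37
    mito_beta: tuple[float, float] = (2.0, 18.0)
    damaged_fraction: float = 0.05
    damaged_beta: tuple[float, float] = (8.0, 12.0)
    batch_effect_sd: float = 0.15
    n_batches: int = 2
    age_points: tuple[tuple[str, float], ...] = (
        ("P11", 11.0), ("P22", 22.0), ("P60", 60.0),
        ("P180", 180.0), ("P510", 510.0),
    )
    composition_anchors: tuple[tuple[float, float], ...] = COMPOSITION_ANCHORS
    composition_flat: float | None = None  # overrides the curve (null cohorts)
    n_empty_droplets: int = 5000
    ambient_scale: float = 20.0
    seed: int = 0

    def resolved_cell_types(self) -> tuple[CellType, ...]:
        return self.cell_types or default_cell_types(self.n_true_patterns)

    def validate(self) -> None:
        if self.n_genes <= 0 or self.cells_per_sample <= 0:
            raise ValueError("n_genes and cells_per_sample must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if not (math.isfinite(self.library_size_meanlog)
                and math.isfinite(self.library_size_sdlog)):
            raise ValueError("library size parameters must be finite")
        if self.n_empty_droplets < 0:
            raise ValueError("n_empty_droplets must be >= 0")
        if self.batch_effect_sd < 0:
            raise ValueError("batch_effect_sd must be >= 0")
        for ct in self.resolved_cell_types():
            mix = np.asarray(ct.mixture, dtype=float)
            if mix.shape != (self.n_true_patterns,):
                raise ValueError(
                    f"cell type {ct.label!r}: mixture length {mix.size} != "
                    f"k_true {self.n_true_patterns}")
            if (mix < 0).any() or abs(mix.sum() - 1.0) > 1e-12:
                raise ValueError(
                    f"cell type {ct.label!r}: mixture must be >= 0 and sum to 1")
            if ct.lineage not in LINEAGES:
                raise ValueError(f"unknown lineage {ct.lineage!r}")


@dataclass
class GroundTruth:
    """Generating truth for a synthetic cohort."""

    A_true: np.ndarray              # somatic genes x k_true, columns sum to 1
    gene_symbols: list[str]         # somatic gene symbols (rows of A_true)
    cell_types: tuple[CellType, ...]
    cells: pd.DataFrame             # per-cell labels and latent values
    p_true: np.ndarray              # cells x k_true mixture weights
    men_fraction_by_sample: pd.Series
    theta_true: np.ndarray | None = None
    group_labels: pd.Series | None = None
    config: SimConfig | None = None

    @property
    def men_pattern_ids(self) -> list[int]:
        """Indices of programs dominated by a MEN-like cell type."""
        ids = []
        for ct in self.cell_types:
            if ct.lineage == "MEN-like":
                ids.append(int(np.argmax(ct.mixture)))
        return sorted(set(ids))


def composition_curve(
    age_days: np.ndarray | float,
    anchors: Sequence[tuple[float, float]] = COMPOSITION_ANCHORS,
) -> np.ndarray | float:
    """MEN-like fraction as a function of age in days.

    Monotone PCHIP interpolant in log-age through the measured anchor
    proportions; exact at the anchors, clamped to the endpoint values
    outside the anchored age range.
    """
    anchors = sorted(anchors)
    x = np.log(np.array([a for a, _ in anchors], dtype=float))
    y = np.array([f for _, f in anchors], dtype=float)
    interp = PchipInterpolator(x, y, extrapolate=False)
    t = np.log(np.clip(np.asarray(age_days, dtype=float), 1e-9, None))
    out = interp(np.clip(t, x[0], x[-1]))
    out = np.clip(out, 0.0, 1.0)
    return float(out) if np.isscalar(age_days) else out


def _build_A_true(config: SimConfig, rng: np.random.Generator):
    """Gene-program amplitude matrix plus gene symbols with planted markers."""
    g, k = config.n_genes, config.n_true_patterns
    A = rng.gamma(0.3, 1.0, size=(g, k))
    block = max(g // k, 1)
    for j in range(k):
        rows = slice(j * block, min((j + 1) * block, g))
        A[rows, j] += rng.gamma(4.0, 1.0, size=A[rows, j].shape) * 3.0

    symbols = [f"gene_{i + 1:04d}" for i in range(g)]
    types = config.resolved_cell_types()
    for lineage, markers in _LINEAGE_MARKERS.items():
        patterns = [int(np.argmax(ct.mixture)) for ct in types
                    if ct.lineage == lineage]
        if not patterns:
            continue
        home = patterns[0] * block
        for m_i, name in enumerate(markers):
            row = home + m_i
            if row >= g:
                break
            symbols[row] = name
            for j in patterns:
                A[row, j] = max(A[row, j], 10.0)
    A /= A.sum(axis=0, keepdims=True)
    return A, symbols


def _type_probabilities(types: Sequence[CellType], men_fraction: float) -> np.ndarray:
    """Per-type sampling probabilities at a given MEN-like fraction."""
    men_idx = [i for i, ct in enumerate(types) if ct.lineage == "MEN-like"]
    other_idx = [i for i, ct in enumerate(types) if ct.lineage != "MEN-like"]
    p = np.zeros(len(types))
    if men_idx:
        p[men_idx] = men_fraction / len(men_idx)
    w = np.array([types[i].base_weight for i in other_idx], dtype=float)
    if other_idx:
        p[other_idx] = (1.0 - men_fraction) * w / w.sum()
    return p


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    """NB(mu, phi) with variance mu + mu^2/phi via the gamma-Poisson mixture."""
    lam = np.zeros_like(mu)
    pos = mu > 0
    lam[pos] = rng.gamma(phi, mu[pos] / phi)
    return rng.poisson(lam)


def simulate_reference_cohort(config: SimConfig) -> tuple[ad.AnnData, GroundTruth]:
    """Generate the age-structured reference cohort.

    Counts are NB(mean = s_c * profile, dispersion phi) where each cell's
    profile is the convex program mixture of its type (renormalized to sum
    to 1 after batch effects and mitochondrial mass), so a cell's expected
    total equals its library-size draw s_c. Cell types are drawn per sample
    with MEN-like probability given by the composition curve at the
    sample's age. Deterministic given ``config.seed``.
    """
    config.validate()
    rng = child_rng(config.seed, "reference")
    types = config.resolved_cell_types()
    k = config.n_true_patterns
    A, symbols = _build_A_true(config, child_rng(config.seed, "patterns"))

    n_mito = int(config.mito_gene_count)
    mito_names = list(MOUSE_MITO_GENES[:n_mito])
    if n_mito > len(MOUSE_MITO_GENES):
        mito_names += [f"mt-extra{i}" for i in range(n_mito - len(MOUSE_MITO_GENES))]
    mito_profile = child_rng(config.seed, "mito_profile").gamma(5.0, 1.0, n_mito)
    mito_profile = mito_profile / mito_profile.sum() if n_mito else mito_profile

    batch_rng = child_rng(config.seed, "batch_effects")
    batch_factors = np.exp(batch_rng.normal(
        0.0, config.batch_effect_sd, size=(config.n_batches, config.n_genes)))

    rows = []
    profiles = []
    p_cols = []
    n = config.cells_per_sample
    for s_i, (sample_id, age) in enumerate(config.age_points):
        men_p = (config.composition_flat if config.composition_flat is not None
                 else composition_curve(age, config.composition_anchors))
        probs = _type_probabilities(types, float(men_p))
        t_idx = rng.choice(len(types), size=n, p=probs)
        batch = s_i % config.n_batches
        for ci in range(n):
            ct = types[t_idx[ci]]
            rows.append((sample_id, float(age), f"batch{batch}", ct.label, ct.lineage))
        mix = np.array([types[i].mixture for i in t_idx], dtype=float)  # n x k
        p_cols.append(mix)
        m = mix @ A.T                                   # n x genes, rows sum to 1
        m = m * batch_factors[batch][None, :]
        m /= m.sum(axis=1, keepdims=True)
        profiles.append(m)

    profile = np.vstack(profiles)
    p_true = np.vstack(p_cols)
    n_cells = profile.shape[0]
    cells = pd.DataFrame(
        rows, columns=["sample", "age_days", "batch", "cell_type", "lineage"])
    cells.index = [f"cell_{i + 1:05d}" for i in range(n_cells)]

    damaged = rng.random(n_cells) < config.damaged_fraction
    a0, b0 = config.mito_beta
    a1, b1 = config.damaged_beta
    mito_frac = np.where(damaged,
                         rng.beta(a1, b1, n_cells),
                         rng.beta(a0, b0, n_cells))
    if n_mito == 0:
        mito_frac = np.zeros(n_cells)
    full = np.hstack([
        profile * (1.0 - mito_frac)[:, None],
        np.outer(mito_frac, mito_profile) if n_mito else np.zeros((n_cells, 0)),
    ])

    s = rng.lognormal(config.library_size_meanlog, config.library_size_sdlog, n_cells)
    counts = _nb_sample(rng, s[:, None] * full, config.nb_dispersion)

    cells["damaged"] = damaged
    cells["mito_fraction_true"] = mito_frac
    cells["library_target"] = s

    var = pd.DataFrame(index=symbols + mito_names)
    var.index.name = "gene_symbol"
    var["gene_id"] = [f"ENSMUSG{i:011d}" for i in range(len(var))]
    var["is_mito"] = [False] * len(symbols) + [True] * n_mito

    adata = ad.AnnData(
        X=sp.csr_matrix(counts.astype(np.int64)),
        obs=cells.copy(),
        var=var,
    )
    men_frac = (cells.assign(is_men=cells["lineage"] == "MEN-like")
                .groupby("sample", sort=False)["is_men"].mean())
    truth = GroundTruth(
        A_true=A, gene_symbols=list(symbols), cell_types=types,
        cells=cells, p_true=p_true, men_fraction_by_sample=men_frac,
        config=config,
    )
    return adata, truth


def expected_profile_matrix(truth: GroundTruth) -> np.ndarray:
    """Noiseless expected somatic profile matrix (cells x genes), rows
    summing to 1; rank <= k_true when batch effects are disabled."""
    return truth.p_true @ truth.A_true.T


def simulate_target_dataset(
    counts: ad.AnnData,
    depth_fraction: float,
    gene_subset_fraction: float = 1.0,
    rename_map: Mapping[str, str] | None = None,
    seed: int = 0,
) -> ad.AnnData:
    """Platform-shifted copy of a cohort: binomially depth-thinned, gene
    down-sampled, and optionally symbol-renamed to exercise feature matching.
    Cell labels are carried over unchanged."""
    if not 0.0 < depth_fraction <= 1.0:
        raise ValueError("depth_fraction must be in (0, 1]")
    if not 0.0 < gene_subset_fraction <= 1.0:
        raise ValueError("gene_subset_fraction must be in (0, 1]")
    rng = child_rng(seed, "target")
    out = counts.copy()
    X = out.X.tocsr().astype(np.int64)
    if depth_fraction < 1.0:
        X.data = rng.binomial(X.data, depth_fraction)
        X.eliminate_zeros()
    out.X = X
    if gene_subset_fraction < 1.0:
        n_keep = max(1, int(round(gene_subset_fraction * out.n_vars)))
        keep = np.sort(rng.choice(out.n_vars, size=n_keep, replace=False))
        out = out[:, keep].copy()
    if rename_map:
        out.var.index = [rename_map.get(g, g) for g in out.var.index]
    return out


def simulate_bulk_cohort(
    truth: GroundTruth,
    n_per_group: int = 3,
    men_shift: float = 0.3,
    noise_sd: float = 0.1,
    seed: int = 0,
    baseline_fractions: Mapping[str, float] | None = None,
    scale: float = 1.0e4,
) -> tuple[pd.DataFrame, pd.Series]:
    """Two-group bulk cohort (control vs disease) of tissue mixtures.

    Each sample's linear-scale expression is a convex mixture of cell-type
    mean profiles; the disease group's total MEN-like fraction is raised by
    ``men_shift`` with non-MEN fractions rescaled proportionally. Gene-wise
    log-normal noise with sd ``noise_sd``; returned on the log2(x + 1) scale
    as samples x genes.
    """
    types = truth.cell_types
    profiles = {ct.label: np.asarray(ct.mixture) @ truth.A_true.T for ct in types}
    if baseline_fractions is None:
        men = [ct.label for ct in types if ct.lineage == "MEN-like"]
        other = [ct for ct in types if ct.lineage != "MEN-like"]
        w = np.array([ct.base_weight for ct in other], dtype=float)
        baseline_fractions = {lbl: 0.3 / len(men) for lbl in men}
        for ct, wi in zip(other, 0.7 * w / w.sum()):
            baseline_fractions[ct.label] = wi
    base = pd.Series(baseline_fractions, dtype=float)
    if abs(base.sum() - 1.0) > 1e-9 or (base < 0).any():
        raise ValueError("baseline fractions must be >= 0 and sum to 1")

    men_labels = [ct.label for ct in types if ct.lineage == "MEN-like"]
    men_total = base[men_labels].sum()
    if not 0.0 <= men_total + men_shift <= 1.0:
        raise ValueError("men_shift pushes the MEN-like fraction outside [0, 1]")
    shifted = base.copy()
    shifted[men_labels] += men_shift * base[men_labels] / men_total
    non_men = [l for l in base.index if l not in men_labels]
    if base[non_men].sum() > 0:
        shifted[non_men] *= (1.0 - men_total - men_shift) / base[non_men].sum()

    rng = child_rng(seed, "bulk")
    rows, labels, names = [], [], []
    for group, frac in (("control", base), ("disease", shifted)):
        mean = sum(frac[lbl] * profiles[lbl] for lbl in frac.index) * scale
        for i in range(n_per_group):
            noise = (np.exp(rng.normal(0.0, noise_sd, mean.size))
                     if noise_sd > 0 else 1.0)
            rows.append(np.log2(mean * noise + 1.0))
            labels.append(group)
            names.append(f"{group}_{i + 1}")
    bulk = pd.DataFrame(np.vstack(rows), index=names, columns=truth.gene_symbols)
    return bulk, pd.Series(labels, index=names, name="group")


def simulate_cellcycle_cohort(
    config: SimConfig,
    n_cc_genes: int = 500,
    seed: int | None = None,
    theta_fraction: float = 1.0,
    theta_mode: str = "uniform",
    cycling_fraction: float = 0.4,
    boundary_margin: float = 0.1 * math.pi,
    amplitude: float = 1.0,
    cc_library_fraction: float = 0.3,
) -> tuple[ad.AnnData, GroundTruth]:
    """Reference cohort augmented with cell-cycle genes carrying a planted
    circular signal.

    A fraction ``theta_fraction`` of cells receives a true angle theta;
    cell-cycle gene g then has mean expression proportional to
    exp(a_g + b_g cos(theta - phase_g)), while cells without theta get the
    b-independent baseline exp(a_g). ``theta_mode='uniform'`` draws theta
    uniformly on the circle; ``'arcs'`` plants ``cycling_fraction`` of the
    theta-cells inside the cycling arc [0.5pi, 1.5pi) at least
    ``boundary_margin`` from its boundaries and the rest in the quiescent
    arc. ``amplitude`` scales b_g (0 removes all angular signal).
    """
    if n_cc_genes < 4:
        raise ValueError("n_cc_genes must be >= 4")
    adata, truth = simulate_reference_cohort(config)
    rng = child_rng(config.seed if seed is None else seed, "cellcycle")
    n = adata.n_obs

    has_theta = rng.random(n) < theta_fraction
    theta = np.full(n, np.nan)
    if theta_mode == "uniform":
        theta[has_theta] = rng.uniform(0.0, 2.0 * math.pi, has_theta.sum())
    elif theta_mode == "arcs":
        m = int(has_theta.sum())
        cyc = rng.random(m) < cycling_fraction
        lo_c, hi_c = 0.5 * math.pi + boundary_margin, 1.5 * math.pi - boundary_margin
        draw = np.where(
            cyc,
            rng.uniform(lo_c, hi_c, m),
            np.mod(rng.uniform(1.5 * math.pi + boundary_margin,
                               2.5 * math.pi - boundary_margin, m), 2.0 * math.pi),
        )
        theta[has_theta] = draw
    else:
        raise ValueError("theta_mode must be 'uniform' or 'arcs'")

    a = rng.normal(0.0, 0.5, n_cc_genes)
    b = amplitude * rng.uniform(0.5, 1.5, n_cc_genes)
    phase = rng.uniform(0.0, 2.0 * math.pi, n_cc_genes)

    log_mu = np.tile(a, (n, 1))
    th = np.where(np.isnan(theta), 0.0, theta)
    log_mu = log_mu + np.where(np.isnan(theta)[:, None], 0.0,
                               b[None, :] * np.cos(th[:, None] - phase[None, :]))
    mu = np.exp(log_mu)
    mu /= mu.sum(axis=1, keepdims=True)
    s = truth.cells["library_target"].to_numpy()
    cc_counts = _nb_sample(rng, cc_library_fraction * s[:, None] * mu,
                           config.nb_dispersion)

    cc_names = default_cc_genes(n_cc_genes)
    var_cc = pd.DataFrame(index=cc_names)
    var_cc.index.name = "gene_symbol"
    var_cc["gene_id"] = [f"ENSMUSGCC{i:08d}" for i in range(n_cc_genes)]
    var_cc["is_mito"] = False
    var_cc["cc_baseline"] = a       # planted gene parameters (truth)
    var_cc["cc_amplitude"] = b
    var_cc["cc_phase"] = phase
    var = pd.concat([adata.var.assign(is_cc=False), var_cc.assign(is_cc=True)])

    X = sp.hstack([adata.X, sp.csr_matrix(cc_counts.astype(np.int64))]).tocsr()
    obs = adata.obs.copy()
    obs["theta_true"] = theta
    out = ad.AnnData(X=X, obs=obs, var=var)
    truth.theta_true = theta
    truth.cells = obs
    return out, truth


def simulate_droplet_pool(config: SimConfig) -> ad.AnnData:
    """Unfiltered barcode pool: real cells plus empty droplets whose totals
    are Poisson(ambient_scale) with the ambient profile proportional to the
    mean cell profile. Barcodes are shuffled; ``obs['is_cell']`` records the
    truth."""
    if config.n_empty_droplets <= 0:
        raise ValueError("n_empty_droplets must be > 0 for a droplet pool")
    adata, _ = simulate_reference_cohort(config)
    rng = child_rng(config.seed, "droplets")
    totals = np.asarray(adata.X.sum(axis=0)).ravel()
    ambient = totals / max(totals.sum(), 1.0)
    empty = rng.poisson(config.ambient_scale * ambient[None, :],
                        size=(config.n_empty_droplets, adata.n_vars))
    obs_cells = adata.obs.copy()
    obs_cells["is_cell"] = True
    obs_empty = pd.DataFrame(
        index=[f"empty_{i + 1:05d}" for i in range(config.n_empty_droplets)])
    obs_empty["is_cell"] = False
    obs = pd.concat([obs_cells, obs_empty])
    X = sp.vstack([adata.X, sp.csr_matrix(empty.astype(np.int64))]).tocsr()
    order = rng.permutation(X.shape[0])
    pool = ad.AnnData(X=X[order], obs=obs.iloc[order].copy(), var=adata.var.copy())
    return pool
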