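"""End-to-end orchestration of the synthetic-cohort analysis pipeline.

Stages: simulate -> QC -> normalize -> embed/batch-correct/cluster/annotate
-> NMF pattern discovery -> lineage-specific pattern selection -> projection
of a platform-shifted target cohort -> bulk-cohort differential pattern
usage -> cell-cycle position inference. Produces a JSON run report with
versions, seeds, parameters, and per-stage summaries.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cellcycle import (CellCycleScorer, circular_correlation, cycling_summary)
from .clustering import SNNGraphClustering, annotate_clusters, find_markers
from .embedding import HVGPCA, MNNCorrector
from .nmf import nmf_fit, pattern_specificity, select_specific_patterns
from .projection import differential_usage, match_features, project
from .qc import QC_PRESETS, LogNormalizer, filter_cells
from .simulate import (SimConfig, simulate_bulk_cohort, simulate_cellcycle_cohort,
                       simulate_reference_cohort, simulate_target_dataset)

log = logging.getLogger("enspattern")

__all__ = ["PipelineConfig", "run_pipeline", "MEN_SUBSET_PRESET"]

#: Re-embedding parameters for subsetted lineage analyses (e.g. the MEN
#: subset): reduced PCA dimensionality with a fine-grained community scan.
MEN_SUBSET_PRESET = {"d": 20, "knn_k": 10, "resolution": 5e-4}


@dataclass
class PipelineConfig:
    """Stage-block configuration with the two library presets.

    ``preset='p180'`` expands to min_umi 200, ``'p21'`` to min_umi 600;
    both use max_mito 0.20 and NMF k = 50. ``'custom'`` leaves the stage
    blocks as given.
    """

    preset: str = "custom"
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    qc: dict = field(default_factory=lambda: {"min_umi": 200, "max_mito": 0.20})
    cluster: dict = field(default_factory=lambda: {
        "d": 50, "n_hvg": 2000, "knn_k": 20, "method": "leiden",
        "resolution": 5e-3, "batch_key": "batch"})
    nmf: dict = field(default_factory=lambda: {
        "k": 50, "n_restarts": 3, "max_iter": 500, "tol": 1e-6})
    project: dict = field(default_factory=lambda: {
        "m": 4, "min_auroc": 0.9, "depth_fraction": 0.5,
        "gene_subset_fraction": 0.7})
    cellcycle: dict = field(default_factory=lambda: {
        "n_cc_genes": 500, "enabled": True})

    def __post_init__(self):
        if self.preset not in ("p180", "p21", "custom"):
            raise ValueError("preset must be 'p180', 'p21', or 'custom'")
        if self.preset in QC_PRESETS:
            self.qc = {**self.qc, **QC_PRESETS[self.preset]}
            self.nmf = {**self.nmf, "k": 50}
        self.sim = dataclasses.replace(self.sim, seed=self.seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["cell_types"] = (
            None if self.sim.cell_types is None
            else [dataclasses.asdict(ct) for ct in self.sim.cell_types])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("sim", {})
        if isinstance(sim, dict):
            sim = dict(sim)
            cts = sim.pop("cell_types", None)
            if cts is not None:
                from .simulate import CellType
                cts = tuple(CellType(label=c["label"], lineage=c["lineage"],
                                     mixture=tuple(c["mixture"]),
                                     base_weight=c.get("base_weight", 1.0))
                            for c in cts)
            for key in ("library_size", "age_points", "composition_anchors",
                        "mito_beta", "damaged_beta"):
                if key in sim and sim[key] is not None and key != "library_size":
                    sim[key] = tuple(tuple(x) if isinstance(x, (list, tuple))
                                     else x for x in sim[key])
            sim = SimConfig(cell_types=cts, **sim)
        return cls(sim=sim, **d)


def run_pipeline(config: PipelineConfig, out_dir=None) -> dict:
    """Run all stages on a synthetic cohort; return (and optionally write)
    the run report."""
    report: dict = {"version": __version__, "seed": config.seed,
                    "preset": config.preset, "stages": {}}
    stage = "simulate"
    try:
        adata, truth = simulate_reference_cohort(config.sim)
        report["stages"]["simulate"] = {
            "n_cells": int(adata.n_obs), "n_genes": int(adata.n_vars),
            "men_fraction_by_sample":
                truth.men_fraction_by_sample.round(6).to_dict()}
        log.info("simulate: %d cells x %d genes", adata.n_obs, adata.n_vars)

        stage = "qc"
        mask, filtered = filter_cells(adata, **config.qc)
        report["stages"]["qc"] = {"n_pass": int(mask.sum()),
                                  "n_fail": int((~mask).sum()), **config.qc}
        log.info("qc: %d/%d cells pass", mask.sum(), mask.size)

        stage = "normalize"
        norm_t = LogNormalizer(log_base=10).fit(filtered.X)
        lognorm = np.asarray(norm_t.transform(filtered.X).todense())
        report["stages"]["normalize"] = {"log_base": 10}

        stage = "cluster"
        cl_cfg = config.cluster
        d = min(cl_cfg["d"], min(lognorm.shape) - 1)
        pca = HVGPCA(d=d, n_hvg=cl_cfg["n_hvg"])
        coords = pca.fit_transform(lognorm)
        batches = filtered.obs[cl_cfg["batch_key"]].to_numpy()
        if len(set(batches)) > 1:
            coords = MNNCorrector(k_mnn=min(20, min(
                np.bincount(pd.factorize(batches)[0])) - 1)).fit_transform(
                coords, batch=batches)
        clu = SNNGraphClustering(
            knn_k=cl_cfg["knn_k"], method=cl_cfg["method"],
            resolution=cl_cfg["resolution"], seed=config.seed).fit(coords)
        gene_names = list(filtered.var_names)
        labels_map = annotate_clusters(lognorm, clu.labels_,
                                       gene_names=gene_names)
        annotated = np.array([labels_map[c] for c in clu.labels_])
        report["stages"]["cluster"] = {
            "n_clusters": int(clu.labels_.max() + 1),
            "annotations": {str(k): v for k, v in labels_map.items()}}
        log.info("cluster: %d communities", clu.labels_.max() + 1)

        stage = "nmf"
        somatic = ~filtered.var["is_mito"].to_numpy(dtype=bool) \
            if "is_mito" in filtered.var else np.ones(filtered.n_vars, bool)
        V = lognorm[:, somatic]
        k = min(config.nmf["k"], min(V.shape))
        model = nmf_fit(V, k=k, seed=config.seed,
                        max_iter=config.nmf["max_iter"],
                        tol=config.nmf["tol"],
                        n_restarts=config.nmf["n_restarts"])
        W = model.P_.T
        report["stages"]["nmf"] = {
            "k": k, "n_iter": int(model.n_iter_),
            "objective": float(model.reconstruction_err_)}

        stage = "select"
        spec_table = pattern_specificity(W, clu.labels_)
        selected = select_specific_patterns(
            spec_table, "MEN", m=config.project["m"],
            min_auroc=config.project["min_auroc"],
            cluster_annotations=labels_map)
        report["stages"]["select"] = {"selected_patterns": selected}
        log.info("select: MEN-specific patterns %s", selected)

        stage = "project"
        if selected:
            target = simulate_target_dataset(
                filtered, config.project["depth_fraction"],
                config.project["gene_subset_fraction"], seed=config.seed)
            t_norm = LogNormalizer(log_base=10).fit(target.X)
            t_log = np.asarray(t_norm.transform(target.X).todense())
            ref_genes = [gene_names[i] for i in np.flatnonzero(somatic)]
            ridx, tidx = match_features(ref_genes, list(target.var_names))
            res = project(t_log[:, tidx], model.A_[ridx][:, selected],
                          pattern_names=[f"pattern_{j}" for j in selected],
                          target_names=list(target.obs_names))
            report["stages"]["project"] = {
                "n_targets": int(res.weights.shape[0]),
                "matched_genes": int(res.matched_gene_count),
                "mean_r2": float(np.nanmean(res.r2.to_numpy()))}
        else:
            report["stages"]["project"] = {"skipped": "no selected patterns"}

        stage = "test"
        if selected:
            bulk, groups = simulate_bulk_cohort(truth, seed=config.seed)
            bridx, btidx = match_features(ref_genes, list(bulk.columns))
            bres = project(bulk.to_numpy()[:, btidx],
                           model.A_[bridx][:, selected],
                           pattern_names=[f"pattern_{j}" for j in selected],
                           target_names=list(bulk.index), target_kind="bulk-sample")
            tests = differential_usage(bres.weights, groups)
            report["stages"]["test"] = {
                "min_p": float(tests["p"].min()),
                "n_significant": int((tests["p"] < 0.05).sum())}
        else:
            report["stages"]["test"] = {"skipped": "no selected patterns"}

        stage = "cellcycle"
        if config.cellcycle.get("enabled", True):
            cc_adata, cc_truth = simulate_cellcycle_cohort(
                config.sim, n_cc_genes=config.cellcycle["n_cc_genes"])
            cc_norm = LogNormalizer(log_base=10).fit(cc_adata.X)
            cc_log = np.asarray(cc_norm.transform(cc_adata.X).todense())
            cc_genes = list(cc_adata.var_names[
                cc_adata.var["is_cc"].to_numpy(dtype=bool)])
            scorer = CellCycleScorer(cc_genes=cc_genes).fit(
                cc_log, gene_names=list(cc_adata.var_names),
                ref_theta=cc_truth.theta_true)
            pos = scorer.transform(cc_log, gene_names=list(cc_adata.var_names))
            ok = ~np.isnan(cc_truth.theta_true)
            rho = circular_correlation(pos["theta"].to_numpy()[ok],
                                       cc_truth.theta_true[ok])
            n_cyc, n_tot, frac = cycling_summary(pos)
            report["stages"]["cellcycle"] = {
                "circular_correlation_abs": abs(float(rho)),
                "cycling_fraction": float(frac), "n_cells": n_tot}
        else:
            report["stages"]["cellcycle"] = {"skipped": "disabled"}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "wt") as fh:
            json.dump({"config": config.to_dict(), **report}, fh, indent=2,
                      default=str)
    return report
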