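# enspattern

Transcriptomic pattern discovery and transfer learning for the enteric
nervous system (ENS).

The adult gut wall contains two neuronal lineages: canonical neural-crest-
derived enteric neurons (NENs, marked by *Ret*) and a mesoderm-derived
population (MENs, co-expressing *Calcb*, *Met*, *Cdh3*). Identifying MENs
from droplet single-cell RNA-seq of the longitudinal muscle–myenteric
plexus (LM-MP), and then finding their signature in other single-cell,
single-nucleus, and bulk datasets, requires a specific chain of analyses.
This package implements that chain as a tested, reusable library with a
command-line interface:

- **Droplet QC and normalization** — barcode-rank knee/inflection
  statistics for calling cells in unfiltered pools; minimum-UMI plus
  mitochondrial-ratio filtering (presets: 200 UMI for adult P180
  libraries, 600 UMI for juvenile P21 libraries, both with mito ratio
  < 20% over the 37 mitochondrial genes); size-factor scaling with
  log10(x/sf + 1) normalization.
- **Batch-corrected graph clustering** — PCA on variable genes, mutual-
  nearest-neighbors (MNN) batch correction, shared-nearest-neighbor graph
  with Jaccard weights, Leiden/Louvain community detection, marker genes
  by pairwise one-sided Welch t-tests (Simes-combined, BH-corrected) and
  McFadden pseudo-R² scores, and signature-based lineage annotation.
- **NMF pattern discovery** — V ≈ A·P with A, P ≥ 0 fit by hierarchical
  alternating least squares (HALS) with restarts; each column of A is a
  gene program ("pattern"), each row of P its per-cell usage. Pattern
  specificity for a cluster is the AUROC of its cell weights; the most
  MEN-specific patterns (four by default) are selected for transfer.
- **Transfer-learning projection** — new profiles y (cells, nuclei, or
  bulk samples) get non-negative weights p\* = argmin_{p≥0} ‖y − A·p‖²,
  after case-insensitive (optionally ortholog-mapped) gene matching.
  Per-cell weights are averaged per sample, and pattern usage is compared
  across groups by Student's t (2 groups) or one-way ANOVA (≥ 3 groups).
- **Continuous cell-cycle position** — cells are projected into a 2-D
  cell-cycle reference space built from ~500 cycle-correlated genes;
  theta = atan2(e₂, e₁) ∈ [0, 2π), binarized as "cycling" on
  [0.5π, 1.5π), with periodic tricube loess for expression dynamics.
- **Synthetic cohorts** — a first-class generator that emulates the
  statistical structure all of the above assumes: negative-binomial
  counts from non-negative gene programs (two MEN-like), log-normal
  library sizes, mitochondrial mass, batch effects, empty droplets, an
  age-structured cohort whose MEN-like fraction follows the measured
  proportions (4.12% at P11 up to 95.99% at P510), platform-shifted
  targets, bulk mixtures with a planted disease shift, and planted
  circular cell-cycle structure.

## Worked example

Discover MEN-specific patterns in a synthetic reference cohort and test
their usage in a bulk disease cohort with a planted +0.3 MEN-fraction
shift:

```python
import numpy as np
import enspattern as ep

cfg = ep.SimConfig(seed=1)                      # 5 aged samples x 400 cells
adata, truth = ep.simulate_reference_cohort(cfg)
mask, cells = ep.filter_cells(adata, min_umi=200, max_mito=0.20)

norm = ep.LogNormalizer(log_base=10).fit(cells.X)
L = np.asarray(norm.transform(cells.X).todense())
somatic = ~cells.var["is_mito"].to_numpy(bool)

model = ep.nmf_fit(L[:, somatic], k=6, seed=1, n_restarts=1)
spec = ep.pattern_specificity(model.P_.T, cells.obs["cell_type"].to_numpy())
lineage = {ct.label: ct.lineage for ct in truth.cell_types}
men = ep.select_specific_patterns(spec, "MEN-like", m=4,
                                  cluster_annotations=lineage)

bulk, groups = ep.simulate_bulk_cohort(truth, n_per_group=3,
                                       men_shift=0.3, noise_sd=0.1, seed=1)
ridx, tidx = ep.match_features(list(cells.var_names[somatic]),
                               list(bulk.columns))
proj = ep.project(bulk.to_numpy()[:, tidx], model.A_[ridx][:, men],
                  pattern_names=[f"pattern_{j}" for j in men],
                  target_names=list(bulk.index), target_kind="bulk-sample")
tests = ep.differential_usage(proj.weights, groups)
print(tests[["pattern", "statistic", "p", "bh_q"]].to_string(index=False))
```

Output:

```
QC: 1761/2000 cells pass
MEN-specific patterns: [2, 3]
  pattern  statistic        p     bh_q
pattern_2 -27.596254 0.000010 0.000010
pattern_3 -35.598803 0.000004 0.000007
```

The cohort passes 1,761 of 2,000 droplets through QC; of the six learned
patterns, exactly the two whose cell weights mark the MEN-like clusters
are selected (AUROC ≥ 0.9), and both show significantly higher usage in
the disease group (negative t: control mean below disease mean), i.e. the
planted expansion of the MEN compartment is detected from bulk mixtures
with n = 3 per group.

The same stages are available from the shell:

```sh
enspattern simulate --out sim/ --seed 1
enspattern qc --in sim/ --out qc/ --min-umi 200 --max-mito 0.20 --rank-stats
enspattern nmf --in qc/filtered --k 50 --out patterns/ --seed 1
enspattern run --preset p180 --seed 1 --out run/
```

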