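# Methods

This note documents the models implemented in `enspattern`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions that affect results.

## Synthetic cohorts

**Count model.** A cell of type *t* draws its expression profile from the
convex program mixture m = A·p_t, where A (genes × k_true) is a
non-negative amplitude matrix with one dominant gene block per program
plus a gamma-distributed background, and p_t loads 0.85 on the type's own
program with the remainder spread uniformly. Profiles are renormalized to
sum to 1 after gene-wise multiplicative batch effects
(exp N(0, 0.15) per batch, two batches by default) and after blending in
a per-cell mitochondrial fraction (Beta(2, 18), mean 10%; a 5% "damaged"
subpopulation at Beta(8, 12) exercises the 20% mito filter). Counts are
negative binomial with variance μ + μ²/φ (φ = 10, a single overdispersion
knob) via the gamma–Poisson mixture, with per-cell library size
s ~ logN(log 2000, 0.35), so a cell's expected total equals its library
draw. Defaults are the study conditions used throughout the tests:
500 non-mitochondrial genes plus the 37 mitochondrial genes, k_true = 6
programs of which two are MEN-like, five samples of 400 cells.

**Marker genes.** The dominant block of each lineage's program renames a
few genes to the field's markers (*Calcb*, *Met*, *Cdh3* for MEN-like;
*Ret* for NEN-like; *Sox10*, *Ncam1* for glia-like), with elevated
amplitude in every program of that lineage, so signature-based cluster
annotation is exercisable end to end.

**Age composition.** The MEN-like fraction of each sample follows a
monotone PCHIP interpolant in log-age through the five measured anchor
proportions — (11 d, 4.12%), (22 d, 29.63%), (60 d, 46.38%),
(180 d, 57.29%), (510 d, 95.99%) — clamped outside the anchored range. A
symmetric four-parameter logistic cannot pass through these points (the
series rises sharply, plateaus in adulthood, then rises again), and the
interpolant reproduces them exactly, which is the property the generator
is calibrated to. A `composition_flat` override generates null cohorts
with age-independent composition. The anchors are image-based lineage
counts treated here as cell-composition targets — an interpretive choice.

**Other cohorts.** Target datasets are binomial depth-thinnings with a
random gene subset and optional symbol renaming (labels carried over).
Bulk cohorts are convex mixtures of cell-type mean profiles on the linear
scale, with the disease group's MEN-like fraction raised by a configured
shift (non-MEN fractions rescaled), gene-wise log-normal noise, returned
as log2(x + 1). The cell-cycle cohort appends cycle genes whose means
follow exp(a_g + b_g·cos(θ − φ_g)) for cells with a planted angle θ
(uniform on the circle, or placed in the cycling/quiescent arcs with a
boundary margin); cc genes carry ~30% of each cell's library. Droplet
pools concatenate real cells with empty droplets whose totals are
Poisson(ambient mean 20) on the mean-cell ambient profile.

**What is not emulated.** Read-level structure (UMI collisions, barcode
errors), doublets, spliced/unspliced channels, gene–gene correlation
beyond the program structure, ambient contamination *inside* cell-
containing droplets, and cross-species divergence beyond symbol renaming.
Tests passing on these cohorts show the pipeline recovers planted
structure under its own model assumptions; they do not certify behavior
on real data violating them.

**Seeds.** One master seed; each stochastic operation derives a child
generator keyed by a CRC32 hash of its name, so stages rerun reproducibly
and independently.

## QC and normalization

Pass criteria: total UMI ≥ threshold (inclusive — it is a *minimum*
threshold) and mitochondrial ratio strictly < 0.20 ("less than 20%").
Presets: `p180` → 200 UMI, `p21` → 600 UMI. A zero-total cell gets ratio
0 with a degenerate flag (it can never pass a positive UMI filter).
Size factors are library size over its geometric mean — the named
"cell-size scaling factor" is not specified further, and this convention
makes log factors mean-zero; pooled-deconvolution factors are
deliberately not implemented and the convention is documented so
replications can swap it. Normalization is log_base(count/sf + 1) with
base 10 (base 2 for the single-nucleus-style variant); sparse zeros map
to exact zeros.

**Barcode ranks.** Totals are sorted descending, ties collapsed to unique
(rank, total) points (rank = last index of the tie group), and a cubic
smoothing spline fit to log10 total vs log10 rank. The inflection is the
point of most negative first derivative right of the upper plateau
(points within 5% of the top of the log-range); the knee is the minimum
signed curvature left of the inflection. The estimator is an operational
definition — the landmarks are standard but no reference estimator is
normative. A curve whose steepest slope is shallower than −2 (no cliff
beyond a plain power law) is flagged low-confidence.

## Embedding, batch correction, clustering

PCA runs on the top-2,000-variance genes by default (configurable to all
genes; the full-data analysis keeps all non-zero genes but an embedding
needs features), centered, d = 50 components for the full dataset and
d = 20 for subset re-embeddings. MNN correction merges batches in order
of first appearance: mutual k-NN pairs (k = 20) between the merged
reference and the incoming batch are filtered to each incoming cell's
*closest* mutual pair, and every incoming cell is shifted by a Gaussian-
kernel-weighted average of these correspondence vectors, the kernel
evaluated at the distance to each pair's midpoint with bandwidth the
median kept-pair distance. Best-match filtering discards the large
tangential vectors that plain pair averaging accumulates; with it,
coinciding batches receive exactly zero correction and a pure translation
smaller than the data's neighbor spacing is removed exactly. Shifts larger
than the biological structure remain out of scope, as for any MNN scheme.

The SNN graph connects cells sharing at least one of their k nearest
neighbors, weighted by the Jaccard similarity of (self-inclusive)
neighbor sets. Community detection runs through leidenalg for seed
determinism: `leiden` optimizes the constant Potts model, `louvain` the
RB-configuration modularity. On Jaccard-weighted SNN graphs the CPM
resolution must be small; the default 5e-3 recovers the generating cell
types over a wide band (5e-4 to 2e-2 behave identically on the reference
cohort), and the printed subset parameters (k = 10, resolution 5e-4) are
kept as a preset.

**Markers.** For each gene and cluster, one-sided Welch t-tests against
every other cluster; per-gene combination by Simes (a gene upregulated
against *any* other cluster scores well; a max-combination mode requires
upregulation against *all*); BH correction across genes within cluster;
summary log fold change from the pairwise comparison with the smallest p;
top 30 by combined p flagged. Zero-variance ties give p = 1 by
convention, so constant genes can never be markers. Pseudo-R² scores are
McFadden's 1 − ℓ_fit/ℓ_null from one-vs-rest logistic regression with L2
ridge 1e-4, clipped to [0, 1]. Cluster annotation takes the signature
(NEN = {Ret}, neuroglia = {Sox10, Ncam1}, MEN = {Calcb, Met, Cdh3}) with
the highest mean z-scaled expression, requiring a 0.25 z-unit margin over
the runner-up, else "unassigned".

## Pattern discovery and selection

NMF minimizes ½‖V − W·H‖²_F over W, H ≥ 0 by HALS with uniform
non-negative initialization, per-sweep objective tracking (the trace is
non-increasing), relative-change tolerance 1e-6, at most 500 sweeps, and
3 restarts keeping the best objective (NMF is non-convex; restarts tame
local optima). Post fit, columns of A = Hᵀ are scaled to unit L2 norm
with the scale absorbed into the cell weights — no convention is
normative, and unit-norm amplitudes make projection weights comparable
across patterns. k = 50 is the full-scale default; the synthetic
acceptance conditions use k = k_true = 6. Patterns are learned on all
genes passed in (the pipeline uses the non-mitochondrial submatrix).

Specificity of pattern j for cluster c is the AUROC of row j of the cell
weights as a classifier of membership in c — an explicit criterion
standing in for by-eye heatmap selection. A pattern is MEN-specific when
its best cluster annotates to the MEN lineage; the top m = 4 with
AUROC ≥ 0.9 are selected (fewer, with a warning, if fewer qualify — the
default synthetic cohort plants exactly two MEN programs). Pattern
hierarchies for display use average-linkage clustering on Euclidean
distances.

## Projection and differential usage

Gene matching is case-insensitive on symbols, optionally translating
through a strictly 1:1 ortholog table (ambiguous rows dropped for
determinism); below 50% reference-gene coverage is an error. Projection
solves non-negative least squares per target column (Lawson–Hanson;
verified in tests against exhaustive active-set enumeration), respecting
the cone geometry of NMF; an OLS mode exists for parity checks. R² is
reported per target against its own mean. Per-cell weights are averaged
to per-sample means *before* testing — cells are pseudoreplicates of
their donor, so cell-level tests are deliberately not offered. Two groups
are compared by equal-variance Student t (Welch switchable), three or
more by one-way ANOVA with (DFn, DFd) = (groups − 1, samples − groups);
BH-adjusted q across patterns is reported alongside raw p. Human age
groups are Juvenile [4, 12], Adult [20, 50], Aged [60, 75] years,
boundaries inclusive, gaps "unassigned".

## Cell-cycle position

The reference space is the top two principal components of the centered
cell-cycle-gene submatrix of a reference cohort (≥ 4 matched genes, ≥ 10
cells). A PCA basis fixes the plane but not the phase origin or the
rotation sense, so the reference can be oriented once against known
angles of the reference cells (rotation plus optional reflection chosen
to maximize the mean resultant) — the analog of shipping a pretrained,
consistently oriented reference; without orientation, theta is defined up
to rotation/reflection and is compared by circular correlation
(Fisher–Lee, rotation-invariant; reflection flips its sign). Theta is
atan2(e₂, e₁) mod 2π; cells with zero cc-gene expression are flagged
low-confidence. "Cycling" is the half-open arc [0.5π, 1.5π) — the
interval notation is ambiguous at the boundary and the boundary angle is
assigned to cycling. Periodic loess is local-linear with tricube weights
on wrapped circular distance and a fixed span (no robustness iterations);
span 0.3 by default, 0.15–0.2 in tests of sharp features. The bundled
500-gene cycle list is a synthetic stand-in (canonical murine cycle
symbols padded with systematic names) matching the genes the simulator
plants its signal on; real-data analyses should supply a curated list.

## Problem sizes and tolerances

The test suite and `scripts/acceptance.py` run the pipeline at the
default study conditions: 2,000-cell reference cohorts (500 somatic
genes, φ = 10, k = 6 over 5 seeds for pattern recovery, achieving matched
cosine ≈ 0.92); depth-halved 70%-gene targets (top-pattern match 100%);
an 11-sample, 3-age-group trend cohort of 120 cells/sample with a
200-replicate flat-composition null at 40 cells/sample (rejection rate
≈ 0.05 at α = 0.05); 100 bulk simulations at n = 3/group with shift 0.3;
a 2,000-cell planted-theta cohort with 500 cycle genes (circular
correlation ≈ 0.99, boundary-margin classification accuracy 100%); and a
10,100-barcode droplet toy (100 cells at ~10,000 UMI over 10,000 empties
at ~20 UMI). NNLS is checked on 200 random problems with up to 6 patterns
at 1e-8; closed-form statistics (Welch t = −3.6742, df = 4; F = 21.0,
df (2, 6); BH step-up) are asserted at print precision.

## Known limitations

Library-size factors ignore composition bias (pooled deconvolution would
be needed for strongly composition-skewed real data). The MNN estimator
corrects translations well but, like all MNN variants, cannot separate a
batch effect larger than the biological structure. HALS can park a
component at zero on adversarial inputs; restarts mitigate but do not
eliminate this. AUROC-based pattern selection assumes clusters are
available and reasonably pure. The cell-cycle reference built from data
requires either known reference angles or downstream rotation-invariant
interpretation. The CLI covers the pipeline stages but not figure
reproduction.
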