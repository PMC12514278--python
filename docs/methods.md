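# Methods

`plaquemap` re-implements, as a tested library, a combined spatial
transcriptomics workflow for human coronary arteries: single-cell
imaging data (cell-by-target probe counts with negative-probe controls,
µm coordinates, FOV tiling) and whole-transcriptome segment profiles
(target-by-ROI counts). Because the analyses are defined by procedures
rather than by one dataset, every stage is exercised on a synthetic
layered-artery generator with planted ground truth.

## The synthetic artery

A cross-section is a 2D annulus around a cell-free lumen with four
concentric layers — intima/plaque, media, adventitia, perivascular
tissue — with outer radii 350/450/550/650 µm (lumen 200 µm) by default.
Cells are placed uniformly within their layer (area-uniform radial
sampling); there is no overlap constraint, since none of the downstream
analyses require one. Default densities are ~0.010 cells/µm²
(11,600 cells per section), in the upper range of what contiguous cell
segmentation yields on imaging platforms; at this density a 20 µm disc
holds ~11 neighbours.

Cell types are drawn per (severity, layer) from mixture tables over 11
populations (two smooth muscle states, two endothelial states,
myofibroblasts, macrophages, NK, B, CD8 and two CD4 T states). The
"near normal" and "severe" tables are anchors; "mild" and "moderate"
are linear blends, so immune infiltration rises monotonically with
severity. Each layer has a hallmark population (plaque: macrophages in
severe lesions, smooth muscle when near normal; media: smooth muscle;
adventitia: myofibroblasts plus adaptive immune cells; perivascular:
endothelium/myofibroblasts), reflecting the observation that cellular
neighbourhoods in this tissue are mostly composed of a single type.
Advanced lesions (moderate/severe) carry one planted adventitial
lymphoid aggregate (ATLO): a dense 80 µm disc whose cells are ~90%
B/CD4, recorded in the ground-truth ledger.

Counts are negative binomial with a shared dispersion (size 2) around
per-gene baseline means drawn log-normally (median 0.5 per gene, log-SD
1); each type's 8 marker genes are up-shifted by 3 log2 units on the NB
mean. A healthy cell totals ~200 counts over the 250-gene panel.
Twenty negative probes add Poisson background (mean 0.03 per probe per
cell). Cell areas are log-normal (median ~150 µm², log-SD 0.3). FOVs
are an axis-aligned square grid (450 µm edge) clipped to the tissue.

Planted QC failures are first-class outputs in a ledger: low-count
cells (totals resampled below 20), background-dominated cells
(negative probes inflated far past the 10% proportion limit), area
outliers (area ×15, ~9 SD in log-area), and dead FOVs (per-cell totals
resampled to 25–60 so the FOV mean falls below 35 while each cell still
clears the per-cell floor — the FOV screen alone removes them). The
baseline depth is chosen so healthy cells clear every QC margin widely,
which is what makes the ledger an exact oracle rather than a
statistical one. The one deliberately stochastic element is the Grubbs
area test, which flags ~1% of clean FOVs by construction; exactness
tests therefore run on seeded cohorts.

What the generator does not emulate: real segmentation errors, spatial
autocorrelation of expression within a type, transcript-level spots,
batch chemistry, 3D structure. Passing tests show the *procedures* are
correct on data satisfying their assumptions, not that any biological
conclusion transfers.

## Single-cell QC

Four per-cell criteria and one per-FOV criterion, all boundaries
inclusive:

* total counts ≥ 20;
* negative-probe counts ≤ 0.1 of the total (a zero-count cell gets
  proportion 0 and fails the count floor instead);
* a signal-to-background statistic
  `d = log2(mean endogenous counts per target / mean negative-probe
  counts per probe)` with pass `d ≥ 1`. The conventional configuration
  value −1 for the "count distribution" screen is under-documented
  upstream; it is interpreted here as a flag code meaning `d ≥ 1`, the
  metric and threshold are both exposed, and `None` disables the
  screen;
* an iterative two-sided Grubbs test (α = 0.01) on log cell area, run
  within each FOV, since area distributions are FOV-dependent and
  log-normal under the generator's model. The critical value is
  `((n−1)/√n)·√(t²/(n−2+t²))` with `t` the `1−α/(2n)` Student-t
  quantile at `n−2` df; as α→0 it approaches the attainable supremum
  `(n−1)/√n`, at which point nothing can be flagged.

A FOV passes when its mean total counts per cell — computed on all its
cells, before any cell filtering, because field quality is a property
of the raw image — is ≥ 35. A cell is retained iff all four flags pass
and its FOV passes.

## Normalization, embedding, typing

Counts are depth-normalized per cell and log-transformed
(`ln(1 + count/total × 10⁴)`, endogenous targets only). PCA runs on
gene-centered (optionally unit-scaled) values with a deterministic sign
convention (largest-magnitude loading positive). Cell typing is
nearest-centroid: the reference is the mean log-normalized expression
per labelled type, and each cell receives the type of the centroid it
correlates with best (Pearson, shared genes, ties broken by type name).
This is a transparent stand-in for pre-trained annotation models; users
can inject external labels instead. Fewer than 50 shared genes is an
error, mirroring the known cross-panel failure mode. Batch handling is
limited to optional per-slide gene centering; full integration methods
are out of scope.

## Neighbourhood analysis

Neighbours are all cells within 20 µm (inclusive, Euclidean, KD-tree
backed, same tissue section only). Each cell's composition vector is
the frequency of cell types among its neighbours, including itself by
default so isolated cells remain defined (both choices exposed).
Vectors are clustered with seeded k-means (k-means++ init, 10 restarts)
on raw frequencies — they are already commensurate, so no re-scaling.
Summaries: niche frequency per severity (columns sum to 1) and a
type-by-niche enrichment z-matrix, each type's mean member composition
standardized across niches (population SD, so rows have mean 0, SD 1).

Per-FOV immune density: percentage of each type per FOV, compared
across severities with a tie-corrected Kruskal–Wallis test and Dunn's
pairwise z (pooled tie-corrected rank variance), Holm-adjusted within
each cell type — the multiplicity adjustment is not fixed upstream, so
a conservative standard was chosen.

## Segment pipeline

* **Technical QC** — a segment fails below 20 nuclei, 1600 µm² surface,
  or 1000 raw reads (all configurable; the upstream workflow leaves the
  numbers to the vendor software, so explicit defaults are adopted).
* **LOQ filter** — per segment, LOQ = geomean(negative probes) ×
  geoSD², with a 0.5 floor on zero probe counts before the geometric
  mean. Targets must exceed the LOQ in ≥10% of segments; segments must
  have ≥5% of targets above their LOQ. Negative probes are dropped
  afterwards.
* **Q3 normalization** — each segment scaled by its third-quartile
  count relative to the cohort geometric mean of third quartiles;
  normalized third quartiles are exactly equal across segments, and
  within-segment ranks are unchanged. Q3 = 0 marks a segment
  unnormalizable (dropped with a warning).
* **Clustering** — agglomerative, distance 1 − Pearson correlation,
  average linkage (the distance is prescribed, the linkage was an open
  choice), scipy's deterministic merge order; exported as Newick.
* **Differential expression** — per target, on log2(normalized + 1):
  `y = β₀ + β₁·group + u_slide + ε`, `u ~ N(0, σ_u²)`. The variance
  ratio σ_u²/σ_ε² is profiled by REML with a bounded one-dimensional
  optimization; the grouping structure is eigendecomposed once and
  shared across targets, so thousands of genes fit in seconds. Wald t
  uses containment-style residual df `n − rank([X Z])`, which reduces
  exactly to the OLS df when there is a single slide (and the whole fit
  reduces to OLS, with a logged notice). Benjamini–Hochberg across
  converged targets. Satterthwaite df would be the heavier alternative;
  the simulation calibration (type-I error within the binomial CI of
  0.05 over 2000 null genes with 3 slides) supports the approximation
  at these design sizes.
* **GSEA** — preranked, weighted running-sum enrichment score (weight
  exponent 1), sets filtered to 15–500 members and ≥20% coverage after
  intersection with the ranking. The null permutes gene labels (random
  same-size sets; one shared null per set size). NES divides ES by the
  mean |null ES| of the same sign. The empirical p is two-sided on
  |ES| over all permutations with a +1 correction — its floor is
  exactly 1/(n_perm+1) and it is uniform under a null ranking; a
  sign-conditional p cannot satisfy both properties at once.
* **Pathway z** — (significant up − significant down)/√(members
  tested), at FDR ≤ 0.05 by default; an empty intersection is reported
  missing (NaN).

## Deconvolution

Segment profiles are decomposed against the single-cell centroid
signature by non-negative least squares over the shared genes, then
renormalized to proportions; mixing is linear in counts, so log-scale
centroids are back-transformed (expm1) first. The solver replaces the
ν-SVR machinery of vendor tools deliberately: the workflow contribution
is the matched single-cell reference, and NNLS is transparent and
exactly testable (noiseless mixtures recover to machine precision). A
concordance report scores, per marker-annotation class (CD45+CD4+,
CD45+CD4−, CD45−CD4−), the mean estimated proportion of the matching
type group and the fraction of segments whose top estimated group
matches. Shrinking the shared panel (the few-hundred-gene overlap
regime of cross-platform panels) measurably degrades recovery, which
the tests assert as a monotone trend.

## Problem sizes and determinism

Test and acceptance runs use: a ~23,700-cell, 16-FOV cohort for exact
QC bookkeeping; one 12,100-cell severe section for niche recovery
(adjusted Rand index vs the five planted niches ≥ 0.8 at k = 5);
2000-gene simulated segment studies (12 segments/group, 3 slides) for
mixed-model calibration and power; 1000–2000 permutations and up to
2000 random sets for GSEA behaviour. All randomness flows from explicit
seeds; identical config and seed reproduce outputs bit for bit.

## Known limitations

The typing stand-in assumes the reference and data share a panel and a
normalization; it does not transfer across modalities. The LMM supports
one random intercept (the slide); crossed or nested designs are out of
scope. GSEA's gene-label null ignores inter-gene correlation, as all
preranked permutation schemes do. The generator's planted niches are
spatially compact by construction; niche methods that exploit
non-compact structure are not evaluated. Dunn's test with very few FOVs
per severity is low-powered and is flagged, not prevented.
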