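# plaquemap

Spatial transcriptomics analysis of atherosclerotic coronary arteries:
a tested re-implementation of a combined single-cell imaging (CosMx-style)
and whole-transcriptome segment (GeoMx-style) workflow, exercised
end-to-end on a synthetic layered-artery generator with planted ground
truth.

The package is for computational biologists who want the analysis
machinery of such studies as reusable, verifiable functions rather than
one-off notebook code:

* **Single-cell QC** — per-cell count floor (≥20), negative-probe
  proportion cap (≤0.1), a log2 signal-to-background screen, an
  iterative two-sided Grubbs test on log cell area per FOV (α=0.01),
  and a FOV screen on mean counts (≥35), with a retention report.
* **Typing & embedding** — `ln(1 + count/total·10⁴)` normalization,
  PCA, and nearest-centroid cell typing by Pearson correlation against
  a mean-expression reference matrix.
* **Neighbourhood analysis** — for each cell the frequency vector of
  cell types within 20 µm, k-means niches on those vectors, niche
  frequency by lesion severity, a type-by-niche enrichment z-matrix,
  and per-FOV immune density compared across severities with
  Kruskal–Wallis + Dunn (Holm-adjusted).
* **Segment pipeline** — segment QC, limit-of-quantification filtering
  (LOQ = geomean(neg probes)·geoSD²), Q3 normalization, Pearson-distance
  hierarchical clustering, random-intercept linear-mixed-model
  differential expression (REML, slide as the grouping factor) with
  Benjamini–Hochberg correction, preranked GSEA (sets of 15–500 genes,
  ≥20% coverage, gene-label permutation null), and the pathway score
  z = (n_up − n_down)/√n_total.
* **Deconvolution** — non-negative least squares of segment profiles
  against the single-cell centroid signature over shared genes, with a
  concordance report against marker-based segment annotations.
* **Synthetic tissue** — annular artery sections with
  severity-dependent cell mixtures, a planted adventitial lymphoid
  aggregate (ATLO) in advanced lesions, negative-binomial counts with
  marker signatures, negative probes, FOV grids, pseudobulk ROI
  segments, and a ledger of planted QC failures so QC tests are exact.

See `docs/methods.md` for the models, defaults and design choices.

## Worked example

```python
import plaquemap as pm
from sklearn.metrics import adjusted_rand_score

cells, expr, truth = pm.generate_artery(pm.TissueConfig(seed=2), "severe")
neighbors = pm.radius_neighbors(cells, radius=20.0)
vectors, types, valid = pm.composition_vectors(
    neighbors, cells["true_type"].to_numpy())
model = pm.kmeans_neighbourhoods(
    vectors, pm.NeighbourhoodParams(k=5, seed=0), types, valid)
print(adjusted_rand_score(cells["niche"][valid], model.assignments[valid]))
```

prints `0.853...`: k-means on 20 µm composition vectors recovers the
five planted niches (plaque macrophage core, media, adventitia,
perivascular tissue, and the B/CD4 aggregate) with adjusted Rand index
0.85 against ground truth. The enrichment z-matrix of the same model
(`model.enrichment_z`) shows each niche dominated by its hallmark
population, e.g. B cells at z ≈ +1.9 in the aggregate niche and smooth
muscle at z ≈ +2.0 in the media niche.

The `examples/` directory holds one short script per capability:

| script | what it shows |
| --- | --- |
| `01_simulate_and_qc.py` | cohort simulation, QC cascade, ledger check (retains 88.2% of cells, 89% of FOVs on the example cohort) |
| `02_cell_typing.py` | normalization, PCA, centroid typing (98.6% accuracy vs ground truth) |
| `03_neighbourhoods.py` | niches, enrichment z, Kruskal–Wallis/Dunn density tests |
| `04_segment_profiles.py` | pseudobulk ROIs, LOQ/Q3, mixed-model DE, GSEA, pathway z |
| `05_deconvolution.py` | NNLS proportions (MAE 0.029 vs truth) and overlap degradation |

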