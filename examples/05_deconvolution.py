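"""Cross-platform deconvolution of segments with a single-cell reference.

Builds a centroid signature from the imaging-platform cells, estimates
cell-type proportions in pseudobulk segments by non-negative least
squares over the shared genes, and reports concordance with the
marker-based segment annotations — including the degradation seen when
the shared gene panel shrinks.
"""

import numpy as np

import plaquemap as pm

cells, expr, _ = pm.generate_artery(pm.TissueConfig(seed=13), "severe")
reference = pm.build_centroid_reference(
    pm.lognormalize(expr), cells["true_type"].to_numpy())

rng = np.random.default_rng(4)
rois = []
for j in range(8):
    ang, r = rng.uniform(0, 2 * np.pi), rng.uniform(250, 600)
    rois.append(pm.ROISpec(f"roi{j}", (r * np.cos(ang), r * np.sin(ang)),
                           radius=120.0))
segments = pm.pseudobulk_segments(cells, expr, rois)
segments.normalized = True  # linear counts, comparable to the reference

result = pm.deconvolve_segments(segments, reference)
print(f"gene overlap used: {result.gene_overlap}")
print("estimated proportions, first segment:")
print(result.proportions.iloc[0].round(3).sort_values(ascending=False)
      .head(4).to_string())

pos = cells[["x", "y"]].to_numpy()
truths = []
for roi in rois:
    sel = np.hypot(pos[:, 0] - roi.center[0],
                   pos[:, 1] - roi.center[1]) <= roi.radius
    truths.append(cells["true_type"][sel].value_counts(normalize=True)
                  .reindex(reference.cell_types).fillna(0.0).to_numpy())
truths = np.vstack(truths)
mae = np.abs(result.proportions.to_numpy() - truths).mean()
print(f"mean absolute proportion error vs ground truth: {mae:.3f}")

for n_genes in (250, 100, 50):
    sub = list(rng.choice(reference.genes, n_genes, replace=False))
    r = pm.deconvolve_segments(segments, reference, min_overlap=20,
                               genes=sub)
    e = np.abs(r.proportions.to_numpy() - truths).mean()
    print(f"overlap {n_genes:3d} genes -> MAE {e:.3f}")
# error grows as the shared panel shrinks: the failure mode of
# cross-panel deconvolution with a few hundred shared genes
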