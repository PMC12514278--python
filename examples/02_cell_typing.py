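"""Log-normalize, embed and type cells with a centroid reference.

Builds the cell-type signature matrix (mean log-normalized expression
per type) from labelled cells, then assigns each cell the type of its
best-correlated centroid and scores the result against the generator's
true labels.
"""

import numpy as np

import plaquemap as pm

cells, expr, _ = pm.generate_cohort(pm.TissueConfig(seed=1))
norm = pm.lognormalize(expr, scale_factor=1e4)

embedding = pm.pca_embed(norm, n_pc=20)
print("variance explained by the first 5 PCs:",
      np.round(embedding.explained_variance_ratio[:5], 3))

reference = pm.build_centroid_reference(norm, cells["true_type"].to_numpy())
print(f"reference: {len(reference.cell_types)} cell types x "
      f"{len(reference.genes)} genes")

assignment = pm.classify_nearest_centroid(norm, reference)
accuracy = (assignment["assigned_type"].to_numpy()
            == cells["true_type"].to_numpy()).mean()
print(f"typing accuracy vs ground truth: {100 * accuracy:.1f}% "
      f"(median correlation {assignment['score'].median():.3f})")
# accuracy near 100% reflects the strong marker signatures planted by
# the generator; weaker signatures degrade it toward chance.
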