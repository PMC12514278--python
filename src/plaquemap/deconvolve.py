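"""Cross-platform deconvolution of segment profiles.

A single-cell-derived centroid signature (mean expression per cell type,
from the imaging platform) is used to estimate cell-type proportions in
whole-transcriptome segment profiles: for each segment, non-negative
least squares of the segment profile against the reference columns over
the genes shared by both panels, renormalized to sum to one. Mixing is
linear in counts, so both sides are compared on the linear scale
(log-scale centroids are back-transformed first).

A concordance report compares the estimates with the marker-based
segment annotations (e.g. CD45+CD4+ segments should be dominated by CD4
T-cell estimates); the shrinking-gene-overlap failure mode can be probed
by subsetting the shared genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .datatypes import ReferenceMatrix, SegmentTable
from .errors import DataError

#: default grouping of reference cell types into marker-segment classes
DEFAULT_TYPE_GROUPS = {
    "CD45+CD4+": ["CD4 memory T cell", "CD4 helper T cell"],
    "CD45+CD4-": ["B cell", "CD8 cytotoxic T cell", "macrophage", "NK cell"],
    "CD45-CD4-": ["smooth muscle 1", "smooth muscle 2", "endothelial 1",
                  "endothelial 2", "myofibroblast"],
}


@dataclass
class DeconvolutionResult:
    proportions: pd.DataFrame  # segments x cell types, rows sum to 1
    residual_norm: pd.Series  # per segment
    gene_overlap: int


def deconvolve_segments(
    segments: SegmentTable,
    ref: ReferenceMatrix,
    min_overlap: int = 50,
    genes: list[str] | None = None,
) -> DeconvolutionResult:
    """NNLS cell-type proportion estimates per segment.

    ``genes`` optionally restricts the shared panel further (to study
    the effect of shrinking overlap). Raises when fewer than
    ``min_overlap`` genes are shared — the regime in which cross-panel
    deconvolution is known to break down.
    """
    linear_ref = ref.to_linear()
    shared = segments.targets.intersection(linear_ref.genes)
    if genes is not None:
        shared = shared.intersection(pd.Index(genes))
    if len(shared) < min_overlap:
        raise DataError(
            f"gene overlap between segments and reference is {len(shared)} "
            f"(minimum {min_overlap}); deconvolution would be unreliable")
    A = linear_ref.profiles.loc[:, shared].to_numpy(dtype=float).T  # genes x types
    B = segments.counts.loc[shared].to_numpy(dtype=float)  # genes x segments
    props, resid = [], []
    for j in range(B.shape[1]):
        coef, r = nnls(A, B[:, j])
        total = coef.sum()
        props.append(coef / total if total > 0 else
                     np.full_like(coef, 1.0 / len(coef)))
        resid.append(r)
    proportions = pd.DataFrame(props, index=segments.segments,
                               columns=linear_ref.cell_types)
    return DeconvolutionResult(
        proportions=proportions,
        residual_norm=pd.Series(resid, index=segments.segments,
                                name="residual_norm"),
        gene_overlap=int(len(shared)),
    )


def concordance_report(
    result: DeconvolutionResult,
    segments: SegmentTable,
    type_groups: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Agreement between estimates and marker-segment annotations.

    For each annotation class: the mean estimated proportion of the
    matching type group, and the rank agreement — the fraction of
    segments of that class whose top estimated group matches it.
    """
    type_groups = type_groups or DEFAULT_TYPE_GROUPS
    if "marker_segment" not in segments.meta.columns:
        raise DataError("segment metadata has no marker_segment annotations")
    group_prop = pd.DataFrame({
        g: result.proportions[[t for t in ts
                               if t in result.proportions.columns]].sum(axis=1)
        for g, ts in type_groups.items()
    })
    top_group = group_prop.idxmax(axis=1)
    rows = []
    for cls in type_groups:
        sel = segments.meta["marker_segment"] == cls
        if not sel.any():
            warnings.warn(f"annotation class {cls!r} absent; skipped")
            continue
        segs = segments.meta.index[sel]
        rows.append({
            "annotation": cls,
            "n_segments": int(sel.sum()),
            "mean_matching_proportion": float(group_prop.loc[segs, cls].mean()),
            "rank_agreement": float((top_group.loc[segs] == cls).mean()),
        })
    return pd.DataFrame(rows).set_index("annotation")
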