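"""Normalization, embedding, and reference-centroid cell typing.

Counts are log-normalized per cell (``ln(1 + count/total * scale_factor)``
over endogenous targets only), optionally embedded with PCA, and typed by
nearest centroid: each cell is assigned the reference cell type whose
mean profile it correlates with best (Pearson, over shared genes). The
centroid reference is built from labelled cells of the same platform, so
the same machinery provides both the automatic typing stand-in and the
signature matrix later used for segment deconvolution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

from .datatypes import ExpressionMatrix, ReferenceMatrix
from .errors import DataError, ParameterError

UNCLASSIFIED = "unclassified"


@dataclass
class NormalizedMatrix:
    """Log-normalized cell x gene matrix (endogenous targets only)."""

    values: sparse.csr_matrix
    cell_ids: np.ndarray
    genes: np.ndarray
    scale_factor: float

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values.toarray(), index=self.cell_ids,
                            columns=self.genes)


@dataclass
class EmbeddingResult:
    coordinates: np.ndarray  # cells x n_pc
    explained_variance_ratio: np.ndarray
    loadings: np.ndarray  # genes x n_pc


def lognormalize(expr: ExpressionMatrix,
                 scale_factor: float = 1e4) -> NormalizedMatrix:
    """Per-cell depth normalization followed by log1p.

    value = ln(1 + count / cell_total * scale_factor), with totals over
    endogenous targets; negative probes are dropped. Zero stays zero, so
    the sparsity pattern is preserved.
    """
    if scale_factor <= 0:
        raise ParameterError("scale_factor must be positive")
    endo = sparse.csr_matrix(expr.counts[:, expr.endogenous_mask], dtype=float)
    totals = np.asarray(endo.sum(axis=1)).ravel()
    if (totals == 0).any():
        raise DataError(
            f"{int((totals == 0).sum())} cells have zero endogenous counts; "
            "run QC before normalizing")
    out = endo.copy()
    row = np.repeat(np.arange(out.shape[0]), np.diff(out.indptr))
    out.data = np.log1p(out.data / totals[row] * scale_factor)
    return NormalizedMatrix(values=out, cell_ids=expr.cell_ids,
                            genes=expr.targets[expr.endogenous_mask],
                            scale_factor=float(scale_factor))


def pca_embed(norm: NormalizedMatrix, n_pc: int = 30,
              scale: bool = True) -> EmbeddingResult:
    """PCA on gene-centered (optionally unit-scaled) normalized values.

    Deterministic sign convention: each component's largest-magnitude
    gene loading is made positive.
    """
    if n_pc <= 0:
        raise ParameterError("n_pc must be positive")
    X = norm.values.toarray()
    n_pc = int(n_pc)
    if n_pc > min(X.shape):
        raise ParameterError(f"n_pc={n_pc} exceeds min(cells, genes)")
    X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = X / sd
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    v = vt[:n_pc].T  # genes x n_pc
    flip = np.sign(v[np.argmax(np.abs(v), axis=0), np.arange(n_pc)])
    flip[flip == 0] = 1.0
    v = v * flip
    coords = X @ v
    var = s ** 2
    return EmbeddingResult(
        coordinates=coords,
        explained_variance_ratio=var[:n_pc] / var.sum(),
        loadings=v,
    )


def center_by_slide(norm: NormalizedMatrix, slide_ids: np.ndarray) -> np.ndarray:
    """Optional gene-wise centering within each slide (coarse batch control)."""
    X = norm.values.toarray()
    for s in np.unique(slide_ids):
        sel = slide_ids == s
        X[sel] -= X[sel].mean(axis=0)
    return X


def build_centroid_reference(norm: NormalizedMatrix,
                             labels: np.ndarray) -> ReferenceMatrix:
    """Mean normalized expression per cell type (the signature matrix)."""
    labels = np.asarray(labels)
    if len(labels) != norm.n_cells:
        raise ParameterError("labels length must match the number of cells")
    types = sorted(pd.unique(labels))
    rows, counts, kept = [], [], []
    for t in types:
        sel = labels == t
        if not sel.any():
            warnings.warn(f"cell type {t!r} has no cells; excluded")
            continue
        rows.append(np.asarray(norm.values[sel].mean(axis=0)).ravel())
        counts.append(int(sel.sum()))
        kept.append(t)
    profiles = pd.DataFrame(rows, index=kept, columns=norm.genes)
    return ReferenceMatrix(profiles=profiles,
                           n_cells=pd.Series(counts, index=profiles.index),
                           scale="log")


def classify_nearest_centroid(
    norm: NormalizedMatrix, ref: ReferenceMatrix, min_overlap: int = 50,
) -> pd.DataFrame:
    """Assign each cell the type of its best-correlated centroid.

    Pearson correlation over the genes shared between the data and the
    reference; ties broken by type name order. Cells with zero variance
    over the shared genes cannot be correlated and come back as
    ``"unclassified"`` with NaN score.
    """
    shared = pd.Index(norm.genes).intersection(ref.genes)
    if len(shared) < min_overlap:
        raise DataError(
            f"only {len(shared)} genes shared between data and reference "
            f"(minimum {min_overlap}); typing would not be reliable")
    gi = pd.Index(norm.genes).get_indexer(shared)
    X = norm.values[:, gi].toarray()
    C = ref.profiles.loc[:, shared].to_numpy(dtype=float)
    types = np.asarray(ref.cell_types)  # sorted order = tie-break order
    order = np.argsort(types, kind="stable")
    types, C = types[order], C[order]

    Xc = X - X.mean(axis=1, keepdims=True)
    Cc = C - C.mean(axis=1, keepdims=True)
    xs = np.linalg.norm(Xc, axis=1)
    cs = np.linalg.norm(Cc, axis=1)
    degenerate_cell = xs == 0
    degenerate_ref = cs == 0
    corr = (Xc @ Cc.T) / np.outer(np.where(xs == 0, 1.0, xs),
                                  np.where(cs == 0, 1.0, cs))
    corr[:, degenerate_ref] = -np.inf
    best = np.argmax(corr, axis=1)  # argmax takes the first max: name order
    assigned = types[best].astype(object)
    score = corr[np.arange(len(best)), best]
    assigned[degenerate_cell] = UNCLASSIFIED
    score = np.where(degenerate_cell, np.nan, score)
    return pd.DataFrame({"assigned_type": assigned, "score": score},
                        index=pd.Index(norm.cell_ids, name="cell_id"))
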