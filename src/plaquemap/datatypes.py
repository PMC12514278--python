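"""Core in-memory containers shared across the pipeline.

The package moves four kinds of data around:

* per-cell spatial records (:class:`CellTable` is a plain
  :class:`pandas.DataFrame` with a required column contract, validated by
  :func:`validate_cell_table`),
* a sparse cell-by-target count matrix with endogenous / negative-probe
  target flags (:class:`ExpressionMatrix`),
* target-by-segment pseudobulk profiles with segment annotations
  (:class:`SegmentTable`),
* a cell-type-by-gene centroid signature (:class:`ReferenceMatrix`).

Negative probes are control targets with no transcript complement; their
counts estimate instrument background and drive both the single-cell QC
flags and the segment limit of quantification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

ENDOGENOUS = "endogenous"
NEGATIVE_PROBE = "negative_probe"

SEVERITY_LEVELS = ("near normal", "mild", "moderate", "severe")

#: required columns of a cell table, in canonical order
CELL_TABLE_COLUMNS = (
    "cell_id",
    "x",
    "y",
    "fov_id",
    "area",
    "slide_id",
    "severity",
    "layer",
    "true_type",
)


def validate_cell_table(cells: pd.DataFrame) -> pd.DataFrame:
    """Check the cell-table column contract and basic invariants.

    Returns the table unchanged so calls can be chained. Extra columns
    (``section_id``, ``niche``, ``assigned_type`` ...) are allowed.
    """
    missing = [c for c in CELL_TABLE_COLUMNS if c not in cells.columns]
    if missing:
        raise ValueError(f"cell table is missing required columns: {missing}")
    if cells["cell_id"].duplicated().any():
        raise ValueError("cell_id values must be unique")
    if (cells["area"] <= 0).any():
        raise ValueError("cell areas must be positive")
    return cells


@dataclass
class ExpressionMatrix:
    """Sparse cell x target count matrix with per-target class flags."""

    counts: sparse.csr_matrix  # cells x targets, non-negative integers
    cell_ids: np.ndarray
    targets: np.ndarray
    target_class: np.ndarray  # ENDOGENOUS or NEGATIVE_PROBE per target

    def __post_init__(self) -> None:
        self.counts = sparse.csr_matrix(self.counts)
        self.cell_ids = np.asarray(self.cell_ids)
        self.targets = np.asarray(self.targets)
        self.target_class = np.asarray(self.target_class)
        n_cells, n_targets = self.counts.shape
        if len(self.cell_ids) != n_cells:
            raise ValueError("cell_ids length does not match count matrix rows")
        if len(self.targets) != n_targets or len(self.target_class) != n_targets:
            raise ValueError("targets/target_class length does not match columns")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_targets(self) -> int:
        return self.counts.shape[1]

    @property
    def endogenous_mask(self) -> np.ndarray:
        return self.target_class == ENDOGENOUS

    @property
    def negprobe_mask(self) -> np.ndarray:
        return self.target_class == NEGATIVE_PROBE

    def subset_cells(self, keep: np.ndarray) -> "ExpressionMatrix":
        """Row subset by boolean mask or integer index array."""
        return ExpressionMatrix(
            counts=self.counts[keep],
            cell_ids=self.cell_ids[keep],
            targets=self.targets,
            target_class=self.target_class,
        )

    def subset_targets(self, keep: np.ndarray) -> "ExpressionMatrix":
        return ExpressionMatrix(
            counts=self.counts[:, keep],
            cell_ids=self.cell_ids,
            targets=self.targets[keep],
            target_class=self.target_class[keep],
        )


#: required per-segment metadata columns
SEGMENT_META_COLUMNS = (
    "slide_id",
    "severity",
    "location",
    "marker_segment",
    "nuclei_count",
    "surface_area",
)


@dataclass
class SegmentTable:
    """Target x segment profile table (GeoMx-style ROI segments).

    ``counts`` is a DataFrame indexed by target name with one column per
    segment id; ``meta`` is indexed by segment id. ``normalized`` records
    whether the values are raw counts or Q3-normalized.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame
    target_class: pd.Series  # indexed like counts.index
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.counts.columns.duplicated().any():
            raise ValueError("segment ids must be unique")
        if not self.counts.columns.equals(self.meta.index):
            self.meta = self.meta.loc[self.counts.columns]
        self.target_class = self.target_class.loc[self.counts.index]
        if not self.normalized:
            vals = self.counts.to_numpy()
            if (vals < 0).any():
                raise ValueError("raw counts must be non-negative")

    @property
    def segments(self) -> pd.Index:
        return self.counts.columns

    @property
    def targets(self) -> pd.Index:
        return self.counts.index

    @property
    def endogenous_mask(self) -> pd.Series:
        return self.target_class == ENDOGENOUS

    @property
    def negprobe_mask(self) -> pd.Series:
        return self.target_class == NEGATIVE_PROBE


@dataclass
class ReferenceMatrix:
    """Cell-type x gene centroid signature.

    ``profiles`` rows are cell types, columns genes. ``scale`` records
    whether centroids are means of log-normalized ("log") or linear
    ("linear") expression; deconvolution needs linear mixing.
    """

    profiles: pd.DataFrame
    n_cells: pd.Series = field(default=None)  # cells per type used
    scale: str = "log"

    def __post_init__(self) -> None:
        if self.n_cells is None:
            self.n_cells = pd.Series(0, index=self.profiles.index)
        if self.profiles.index.duplicated().any():
            raise ValueError("one row per cell type required")

    @property
    def cell_types(self) -> pd.Index:
        return self.profiles.index

    @property
    def genes(self) -> pd.Index:
        return self.profiles.columns

    def to_linear(self) -> "ReferenceMatrix":
        """Back-transform log1p-scale centroids to linear expression."""
        if self.scale == "linear":
            return self
        return ReferenceMatrix(
            profiles=np.expm1(self.profiles), n_cells=self.n_cells, scale="linear"
        )
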