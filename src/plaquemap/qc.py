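"""Cell- and FOV-level quality control for single-cell spatial data.

The QC cascade applies four per-cell criteria and one per-FOV criterion:

* total counts per cell at least ``min_counts_per_cell`` (default 20);
* negative-probe counts at most ``max_negprobe_proportion`` of the cell's
  total (default 0.1);
* a count-distribution (signal-to-background) statistic
  ``d = log2(mean endogenous counts per target / mean negative-probe
  counts per probe)`` at least ``|count_distribution_max|`` — the
  conventional threshold code −1 means "require d >= 1" (see methods);
* not flagged by an iterative two-sided Grubbs outlier test on
  log-transformed cell area, run within each FOV (default alpha 0.01);

and a FOV passes when its mean total counts per cell, computed before any
cell filtering, is at least ``min_fov_mean_counts`` (default 35). A cell
is retained iff all four cell flags pass and its FOV passes. All boundary
comparisons are inclusive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix
from .errors import ParameterError

CELL_CRITERIA = ("min_counts", "negprobe_proportion", "count_distribution",
                 "area_outlier")


@dataclass
class QCThresholds:
    """``count_distribution_max=None`` disables the signal/background screen."""

    min_counts_per_cell: int = 20
    max_negprobe_proportion: float = 0.1
    count_distribution_max: float | None = -1.0
    grubbs_alpha: float = 0.01
    min_fov_mean_counts: float = 35.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_negprobe_proportion <= 1.0:
            raise ParameterError("max_negprobe_proportion must be in [0, 1]")
        if not 0.0 < self.grubbs_alpha < 1.0:
            raise ParameterError("grubbs_alpha must be in (0, 1)")
        if self.min_counts_per_cell < 0 or self.min_fov_mean_counts < 0:
            raise ParameterError("minimum thresholds must be non-negative")

    @property
    def min_signal_log2(self) -> float:
        """Count-distribution cut-off on the log2 signal/background scale."""
        if self.count_distribution_max is None:
            return -np.inf
        return abs(self.count_distribution_max)


@dataclass
class QCReport:
    cell_flags: pd.DataFrame  # boolean, True = pass, one column per criterion
    fov_pass: pd.Series  # boolean per FOV
    cells_retained_fraction: float
    fovs_retained_fraction: float
    thresholds: QCThresholds
    status: str = "ok"
    attrition: dict = field(default_factory=dict)  # cells failing each criterion

    def to_dict(self) -> dict:
        return {
            "status": self.status,
            "cells_retained_fraction": self.cells_retained_fraction,
            "fovs_retained_fraction": self.fovs_retained_fraction,
            "attrition": self.attrition,
            "thresholds": vars(self.thresholds),
            "failed_fovs": self.fov_pass.index[~self.fov_pass].tolist(),
        }


def grubbs_critical_value(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value from the Student-t quantile.

    As alpha -> 0 the critical value approaches the largest attainable
    statistic, (n-1)/sqrt(n); once the t quantile overflows, that
    supremum is returned (no value can exceed it, so nothing is flagged).
    """
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    if not np.isfinite(t):
        return (n - 1) / np.sqrt(n)
    return (n - 1) / np.sqrt(n) * np.sqrt(t * t / (n - 2 + t * t))


def grubbs_outliers(values: np.ndarray, alpha: float = 0.01) -> np.ndarray:
    """Iterative two-sided Grubbs test; True marks outliers.

    At each step the most extreme value (max |x - mean| / sd) is compared
    to the critical value at ``alpha``; if rejected it is removed and the
    test repeats on the remainder. Fewer than 3 values, or zero variance,
    yields no flags.
    """
    values = np.asarray(values, dtype=float)
    flags = np.zeros(len(values), dtype=bool)
    if len(values) < 3:
        warnings.warn("Grubbs test needs at least 3 values; no flags raised")
        return flags
    active = np.arange(len(values))
    while len(active) >= 3:
        v = values[active]
        sd = v.std(ddof=1)
        if sd == 0:
            break
        z = np.abs(v - v.mean()) / sd
        i = int(np.argmax(z))
        if z[i] > grubbs_critical_value(len(v), alpha):
            flags[active[i]] = True
            active = np.delete(active, i)
        else:
            break
    return flags


def _totals(expr: ExpressionMatrix) -> tuple[np.ndarray, np.ndarray]:
    endo = np.asarray(expr.counts[:, expr.endogenous_mask].sum(axis=1)).ravel()
    neg = np.asarray(expr.counts[:, expr.negprobe_mask].sum(axis=1)).ravel()
    return endo, neg


def cell_qc_flags(
    expr: ExpressionMatrix, cells: pd.DataFrame, thr: QCThresholds | None = None,
) -> pd.DataFrame:
    """Per-cell boolean pass flags (True = pass) for the four criteria."""
    thr = thr or QCThresholds()
    if not expr.negprobe_mask.any():
        raise ParameterError("no negative-probe targets present; QC needs them")
    endo, neg = _totals(expr)
    total = endo + neg

    pass_counts = total >= thr.min_counts_per_cell
    with np.errstate(invalid="ignore"):
        prop = np.where(total > 0, neg / np.maximum(total, 1), 0.0)
    pass_neg = prop <= thr.max_negprobe_proportion

    n_endo = int(expr.endogenous_mask.sum())
    n_neg = int(expr.negprobe_mask.sum())
    mean_endo = endo / n_endo
    mean_neg = neg / n_neg
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.log2(mean_endo / mean_neg)  # inf when background is zero
    d = np.where(mean_neg == 0, np.inf, d)
    d = np.where(mean_endo == 0, -np.inf, d)
    if np.isneginf(thr.min_signal_log2):
        pass_dist = np.ones(expr.n_cells, dtype=bool)
    else:
        pass_dist = d >= thr.min_signal_log2

    pass_area = np.ones(expr.n_cells, dtype=bool)
    log_area = np.log(cells["area"].to_numpy(dtype=float))
    for _, idx in cells.groupby("fov_id", sort=False).indices.items():
        if len(idx) < 3:
            continue
        out = grubbs_outliers(log_area[idx], thr.grubbs_alpha)
        pass_area[idx] = ~out

    return pd.DataFrame(
        {"min_counts": pass_counts, "negprobe_proportion": pass_neg,
         "count_distribution": pass_dist, "area_outlier": pass_area},
        index=pd.Index(expr.cell_ids, name="cell_id"),
    )


def fov_qc(
    expr: ExpressionMatrix, cells: pd.DataFrame, thr: QCThresholds | None = None,
) -> pd.Series:
    """Per-FOV pass flags: mean total counts per cell >= threshold.

    The mean is computed on all cells of the FOV, before cell filtering:
    FOV quality is a property of the raw imaging field. An empty FOV
    fails.
    """
    thr = thr or QCThresholds()
    endo, neg = _totals(expr)
    total = pd.Series(endo + neg, index=cells["fov_id"].to_numpy())
    mean = total.groupby(level=0).mean()
    return (mean >= thr.min_fov_mean_counts).rename("fov_pass")


def apply_qc(
    expr: ExpressionMatrix, cells: pd.DataFrame, thr: QCThresholds | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame, QCReport]:
    """Run the full QC cascade and return filtered data plus a report."""
    thr = thr or QCThresholds()
    flags = cell_qc_flags(expr, cells, thr)
    fov_pass = fov_qc(expr, cells, thr)
    cell_pass = flags.all(axis=1).to_numpy()
    cell_fov_ok = fov_pass.reindex(cells["fov_id"]).fillna(False).to_numpy()
    keep = cell_pass & cell_fov_ok

    attrition = {c: int((~flags[c]).sum()) for c in flags.columns}
    attrition["fov"] = int((cell_pass & ~cell_fov_ok).sum())
    report = QCReport(
        cell_flags=flags,
        fov_pass=fov_pass,
        cells_retained_fraction=float(keep.mean()) if len(keep) else 0.0,
        fovs_retained_fraction=float(fov_pass.mean()) if len(fov_pass) else 0.0,
        thresholds=thr,
        status="ok" if keep.any() else "all cells removed",
        attrition=attrition,
    )
    filtered_cells = cells.loc[keep].reset_index(drop=True)
    return expr.subset_cells(keep), filtered_cells, report
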