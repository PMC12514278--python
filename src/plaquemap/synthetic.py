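"""Virtual coronary-artery cross-sections with known ground truth.

The generator emulates the structure that single-cell spatial platforms
report on atherosclerotic arteries: concentric tissue layers
(intima/plaque, media, adventitia, perivascular tissue) around a lumen,
severity-dependent cell-type mixtures (immune infiltration grows from
"near normal" to "severe" lesions), an optional organised B/CD4 aggregate
in the adventitia of advanced lesions (an arterial tertiary lymphoid
organ, ATLO), negative-binomial probe counts with per-type marker-gene
signatures, Poisson negative-probe background, a square FOV imaging grid,
and log-normal cell areas.

Planted QC failures (low-count cells, negative-probe-dominated cells,
area outliers, dead FOVs) are recorded in a :class:`GroundTruth` ledger
so that QC tests can be exact rather than statistical. Pseudobulk
segments cut from the cell data emulate ROI segment collection on the
companion whole-transcriptome platform.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from .datatypes import (
    ENDOGENOUS,
    NEGATIVE_PROBE,
    SEVERITY_LEVELS,
    ExpressionMatrix,
    SegmentTable,
)
from .errors import ConfigurationError

LAYERS = ("plaque", "media", "adventitia", "perivascular")

#: default label alphabet: the major mural, endothelial and immune
#: populations of the arterial wall
DEFAULT_CELL_TYPES = (
    "B cell",
    "CD4 memory T cell",
    "CD4 helper T cell",
    "CD8 cytotoxic T cell",
    "macrophage",
    "NK cell",
    "smooth muscle 1",
    "smooth muscle 2",
    "endothelial 1",
    "endothelial 2",
    "myofibroblast",
)

IMMUNE_TYPES = (
    "B cell",
    "CD4 memory T cell",
    "CD4 helper T cell",
    "CD8 cytotoxic T cell",
    "macrophage",
    "NK cell",
)

# Layer mixtures at the two severity extremes; "mild" and "moderate" are
# linear blends. Immune fractions grow with severity in the plaque and
# adventitia, mirroring the increased infiltrate of advanced lesions.
_NEAR_NORMAL_MIX = {
    "plaque": {
        "smooth muscle 1": 0.45, "smooth muscle 2": 0.15, "endothelial 1": 0.22,
        "myofibroblast": 0.08, "macrophage": 0.06, "CD8 cytotoxic T cell": 0.02,
        "NK cell": 0.02,
    },
    "media": {
        "smooth muscle 1": 0.60, "smooth muscle 2": 0.30, "myofibroblast": 0.07,
        "macrophage": 0.03,
    },
    "adventitia": {
        "myofibroblast": 0.48, "endothelial 1": 0.14, "B cell": 0.07,
        "CD4 memory T cell": 0.06, "CD4 helper T cell": 0.04, "macrophage": 0.12,
        "NK cell": 0.05, "CD8 cytotoxic T cell": 0.04,
    },
    "perivascular": {
        "endothelial 2": 0.34, "myofibroblast": 0.34, "endothelial 1": 0.10,
        "NK cell": 0.08, "CD8 cytotoxic T cell": 0.07, "macrophage": 0.07,
    },
}

_SEVERE_MIX = {
    "plaque": {
        "macrophage": 0.65, "CD8 cytotoxic T cell": 0.08, "endothelial 2": 0.06,
        "smooth muscle 1": 0.06, "smooth muscle 2": 0.04, "myofibroblast": 0.04,
        "CD4 memory T cell": 0.04, "NK cell": 0.03,
    },
    "media": {
        "smooth muscle 1": 0.60, "smooth muscle 2": 0.28, "myofibroblast": 0.06,
        "macrophage": 0.04, "CD8 cytotoxic T cell": 0.02,
    },
    "adventitia": {
        "myofibroblast": 0.40, "B cell": 0.15, "CD4 memory T cell": 0.11,
        "CD4 helper T cell": 0.07, "macrophage": 0.12, "endothelial 1": 0.09,
        "NK cell": 0.03, "CD8 cytotoxic T cell": 0.03,
    },
    "perivascular": {
        "endothelial 2": 0.48, "myofibroblast": 0.26, "endothelial 1": 0.08,
        "NK cell": 0.06, "CD8 cytotoxic T cell": 0.04, "macrophage": 0.04,
        "B cell": 0.02, "CD4 memory T cell": 0.02,
    },
}

_SEVERITY_BLEND = {"near normal": 0.0, "mild": 1.0 / 3.0, "moderate": 2.0 / 3.0,
                   "severe": 1.0}


def default_type_mixture(
    cell_types: Sequence[str] = DEFAULT_CELL_TYPES,
) -> dict[str, dict[str, dict[str, float]]]:
    """Severity -> layer -> type -> probability, blending the two extremes."""
    out: dict[str, dict[str, dict[str, float]]] = {}
    for sev, w in _SEVERITY_BLEND.items():
        out[sev] = {}
        for layer in LAYERS:
            mix = {}
            for t in cell_types:
                p = (1 - w) * _NEAR_NORMAL_MIX[layer].get(t, 0.0) + \
                    w * _SEVERE_MIX[layer].get(t, 0.0)
                if p > 0:
                    mix[t] = p
            out[sev][layer] = mix
    return out


@dataclass
class AtloSpec:
    """Planted adventitial lymphoid aggregate (ATLO)."""

    radius: float = 80.0  # µm
    center_radius: float = 500.0  # radial position of the disc center, µm
    mixture: Mapping[str, float] = field(
        default_factory=lambda: {
            "B cell": 0.60, "CD4 memory T cell": 0.18, "CD4 helper T cell": 0.12,
            "CD8 cytotoxic T cell": 0.05, "macrophage": 0.05,
        }
    )
    extra_cells: int = 250  # aggregates are denser than the surrounding layer
    severities: tuple[str, ...] = ("moderate", "severe")


@dataclass
class PlantedFailures:
    """Counts of QC failures to inject per artery section."""

    low_count_cells: int = 0
    high_negprobe_cells: int = 0
    area_outliers: int = 0
    dead_fovs: int = 0


@dataclass
class GroundTruth:
    """Ledger of planted structure; the oracle for exact QC tests."""

    low_count_cells: list[str] = field(default_factory=list)
    high_negprobe_cells: list[str] = field(default_factory=list)
    area_outlier_cells: list[str] = field(default_factory=list)
    dead_fovs: list[str] = field(default_factory=list)
    #: (section_id, x, y, radius) of each planted lymphoid aggregate
    atlo_discs: list[tuple[str, float, float, float]] = field(default_factory=list)

    @property
    def failing_cells(self) -> set[str]:
        return (set(self.low_count_cells) | set(self.high_negprobe_cells)
                | set(self.area_outlier_cells))

    @property
    def empty(self) -> bool:
        return not (self.low_count_cells or self.high_negprobe_cells
                    or self.area_outlier_cells or self.dead_fovs)

    def merged_with(self, other: "GroundTruth") -> "GroundTruth":
        return GroundTruth(
            self.low_count_cells + other.low_count_cells,
            self.high_negprobe_cells + other.high_negprobe_cells,
            self.area_outlier_cells + other.area_outlier_cells,
            self.dead_fovs + other.dead_fovs,
            self.atlo_discs + other.atlo_discs,
        )


@dataclass
class TissueConfig:
    """Parameters of the virtual artery.

    Distances are µm, areas µm². ``layer_boundaries`` are the outer radii
    of plaque/intima, media, adventitia and perivascular tissue; the lumen
    (cell-free) ends at ``lumen_radius``.
    """

    lumen_radius: float = 200.0
    layer_boundaries: tuple[float, ...] = (350.0, 450.0, 550.0, 650.0)
    cells_per_layer: Mapping[str, int] = field(
        default_factory=lambda: {"plaque": 3600, "media": 3000,
                                 "adventitia": 2800, "perivascular": 2200}
    )
    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES
    type_mixture: Mapping[str, Mapping[str, Mapping[str, float]]] = None
    atlo: AtloSpec | None = field(default_factory=AtloSpec)
    n_genes: int = 250
    n_markers_per_type: int = 8
    marker_log2fc: float = 3.0
    signature_spec: Mapping[str, tuple[Sequence[str], float]] | None = None
    base_mean_log_mu: float = np.log(0.5)  # lognormal model of per-gene means
    base_mean_log_sd: float = 1.0
    nb_dispersion: float = 2.0  # NB size parameter (smaller = noisier)
    negprobe_count: int = 20
    negprobe_rate: float = 0.03  # Poisson mean per probe per cell
    fov_grid: float = 450.0  # FOV edge length, µm
    area_log_mean: float = 5.0  # cell area ~ lognormal, ~150 µm² median
    area_log_sd: float = 0.3
    mixing: float = 0.0  # prob. a cell's type is drawn from the layer-average mixture
    planted_failures: PlantedFailures = field(default_factory=PlantedFailures)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.type_mixture is None:
            self.type_mixture = default_type_mixture(self.cell_types)
        radii = (self.lumen_radius, *self.layer_boundaries)
        if len(self.layer_boundaries) != len(LAYERS):
            raise ConfigurationError(
                f"need {len(LAYERS)} layer boundaries, got {len(self.layer_boundaries)}")
        if any(b <= a for a, b in zip(radii, radii[1:])):
            raise ConfigurationError("layer radii must be strictly increasing")
        if any(n < 0 for n in self.cells_per_layer.values()):
            raise ConfigurationError("cells_per_layer must be non-negative")
        if self.n_genes <= 0 or self.negprobe_count < 0:
            raise ConfigurationError("gene/probe counts must be positive")
        for sev, by_layer in self.type_mixture.items():
            for layer, mix in by_layer.items():
                unknown = set(mix) - set(self.cell_types)
                if unknown:
                    raise ConfigurationError(
                        f"mixture ({sev}, {layer}) references undefined cell "
                        f"types: {sorted(unknown)}")
                total = float(sum(mix.values()))
                if abs(total - 1.0) > 1e-9:
                    raise ConfigurationError(
                        f"mixture ({sev}, {layer}) sums to {total}, not 1")
        if self.atlo is not None:
            unknown = set(self.atlo.mixture) - set(self.cell_types)
            if unknown:
                raise ConfigurationError(
                    f"ATLO mixture references undefined cell types: {sorted(unknown)}")

    # -- derived gene model, deterministic given the seed -----------------

    def gene_names(self) -> np.ndarray:
        endo = [f"GENE{i:04d}" for i in range(self.n_genes)]
        neg = [f"NegPrb{i:02d}" for i in range(self.negprobe_count)]
        return np.array(endo + neg)

    def target_class(self) -> np.ndarray:
        return np.array([ENDOGENOUS] * self.n_genes
                        + [NEGATIVE_PROBE] * self.negprobe_count)

    def base_means(self) -> np.ndarray:
        """Per-gene baseline NB means, a fixed draw per config seed."""
        rng = np.random.default_rng([self.seed, 0xBA5E])
        return rng.lognormal(self.base_mean_log_mu, self.base_mean_log_sd,
                             self.n_genes)

    def signatures(self) -> dict[str, tuple[np.ndarray, float]]:
        """Marker gene indices and log2 effect per cell type."""
        if self.signature_spec is not None:
            names = list(self.gene_names())
            out = {}
            for t, (genes, lfc) in self.signature_spec.items():
                idx = np.array([names.index(g) for g in genes])
                out[t] = (idx, float(lfc))
            return out
        m = self.n_markers_per_type
        if m * len(self.cell_types) > self.n_genes:
            raise ConfigurationError("not enough genes for the marker blocks")
        return {
            t: (np.arange(i * m, (i + 1) * m), self.marker_log2fc)
            for i, t in enumerate(self.cell_types)
        }


def _artery_rng(config: TissueConfig, slide_id: str, severity: str):
    tag = zlib.crc32(f"{slide_id}|{severity}".encode())
    return np.random.default_rng([config.seed, tag])


def _sample_types(rng, mix: Mapping[str, float], types: Sequence[str],
                  n: int) -> np.ndarray:
    p = np.array([mix.get(t, 0.0) for t in types])
    p = p / p.sum()
    return rng.choice(len(types), size=n, p=p)


def generate_artery(
    config: TissueConfig, severity: str, slide_id: str = "slide1",
) -> tuple[pd.DataFrame, ExpressionMatrix, GroundTruth]:
    """Generate one artery cross-section.

    Returns the cell table (with ``niche`` ground-truth labels), the
    cell x target count matrix, and the planted-failure ledger.
    """
    if severity not in SEVERITY_LEVELS:
        raise ConfigurationError(
            f"unknown severity {severity!r}; expected one of {SEVERITY_LEVELS}")
    if severity not in config.type_mixture:
        raise ConfigurationError(f"no mixture configured for severity {severity!r}")
    rng = _artery_rng(config, slide_id, severity)
    types = config.cell_types
    section_id = f"{slide_id}:{severity}"

    # ---- placement: uniform in each annulus ---------------------------
    radii_in = (config.lumen_radius, *config.layer_boundaries[:-1])
    radii_out = config.layer_boundaries
    xs, ys, layer_lab, type_idx = [], [], [], []
    for layer, r0, r1 in zip(LAYERS, radii_in, radii_out):
        n = int(config.cells_per_layer.get(layer, 0))
        if n == 0:
            continue
        r = np.sqrt(rng.uniform(r0 ** 2, r1 ** 2, n))
        theta = rng.uniform(0.0, 2.0 * np.pi, n)
        xs.append(r * np.cos(theta))
        ys.append(r * np.sin(theta))
        layer_lab.extend([layer] * n)
        type_idx.append(_sample_types(rng, config.type_mixture[severity][layer],
                                      types, n))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    layer_lab = np.array(layer_lab)
    type_idx = np.concatenate(type_idx)
    niche = layer_lab.copy()

    # ---- optional mixing noise (blurs niche identity) -----------------
    if config.mixing > 0:
        avg = {t: np.mean([config.type_mixture[severity][l].get(t, 0.0)
                           for l in LAYERS]) for t in types}
        blur = rng.random(len(x)) < config.mixing
        if blur.any():
            type_idx[blur] = _sample_types(rng, avg, types, int(blur.sum()))

    # ---- ATLO aggregate ----------------------------------------------
    atlo = config.atlo
    atlo_disc = None
    if atlo is not None and severity in atlo.severities:
        ang = rng.uniform(0.0, 2.0 * np.pi)
        cx, cy = (atlo.center_radius * np.cos(ang),
                  atlo.center_radius * np.sin(ang))
        if atlo.extra_cells:
            rr = atlo.radius * np.sqrt(rng.uniform(0, 1, atlo.extra_cells))
            tt = rng.uniform(0, 2 * np.pi, atlo.extra_cells)
            ex, ey = cx + rr * np.cos(tt), cy + rr * np.sin(tt)
            er = np.hypot(ex, ey)
            bounds = np.array((config.lumen_radius, *config.layer_boundaries))
            elayer = np.array(LAYERS)[
                np.clip(np.searchsorted(bounds, er, side="right") - 1, 0,
                        len(LAYERS) - 1)]
            x = np.concatenate([x, ex])
            y = np.concatenate([y, ey])
            layer_lab = np.concatenate([layer_lab, elayer])
            niche = np.concatenate([niche, np.full(atlo.extra_cells, "atlo")])
            type_idx = np.concatenate(
                [type_idx, np.zeros(atlo.extra_cells, dtype=type_idx.dtype)])
        inside = np.hypot(x - cx, y - cy) <= atlo.radius
        niche[inside] = "atlo"
        type_idx[inside] = _sample_types(rng, atlo.mixture, types,
                                         int(inside.sum()))
        atlo_disc = (section_id, float(cx), float(cy), float(atlo.radius))

    n_cells = len(x)
    order = rng.permutation(n_cells)  # break layer-block ordering
    x, y, layer_lab, niche, type_idx = (
        x[order], y[order], layer_lab[order], niche[order], type_idx[order])
    cell_ids = np.array([f"{section_id}:c{i:05d}" for i in range(n_cells)])
    true_type = np.array(types)[type_idx]

    # ---- FOV grid, clipped to tissue extent ---------------------------
    extent = config.layer_boundaries[-1]
    edge = config.fov_grid
    n_tiles = int(np.ceil(2 * extent / edge))
    origin = -n_tiles * edge / 2.0
    ix = np.clip(((x - origin) // edge).astype(int), 0, n_tiles - 1)
    iy = np.clip(((y - origin) // edge).astype(int), 0, n_tiles - 1)
    fov_id = np.array([f"{section_id}:F{a}{b}" for a, b in zip(ix, iy)])

    # ---- areas ---------------------------------------------------------
    area = rng.lognormal(config.area_log_mean, config.area_log_sd, n_cells)

    # ---- counts: NB endogenous + Poisson negative probes ---------------
    base = config.base_means()
    mu = np.tile(base, (n_cells, 1))
    for t, (idx, lfc) in config.signatures().items():
        sel = true_type == t
        if sel.any():
            mu[np.ix_(sel, idx)] *= 2.0 ** lfc
    r = config.nb_dispersion
    lam = rng.gamma(r, mu / r)
    endo = rng.poisson(lam)
    neg = rng.poisson(config.negprobe_rate,
                      size=(n_cells, config.negprobe_count))

    # ---- planted failures ----------------------------------------------
    truth = GroundTruth()
    if atlo_disc is not None:
        truth.atlo_discs.append(atlo_disc)
    pf = config.planted_failures
    fovs = np.unique(fov_id)
    if pf.dead_fovs > len(fovs):
        raise ConfigurationError("more dead FOVs requested than FOVs present")
    dead = rng.choice(fovs, size=pf.dead_fovs, replace=False)
    truth.dead_fovs.extend(dead.tolist())
    in_dead = np.isin(fov_id, dead)
    # dead FOVs: per-cell totals ~25-60, FOV mean safely below the 35
    # threshold, but each cell still above the 20-count floor
    for i in np.flatnonzero(in_dead):
        tot = 25 + rng.poisson(7)
        endo[i] = rng.multinomial(tot, mu[i] / mu[i].sum())

    n_plant = pf.low_count_cells + pf.high_negprobe_cells + pf.area_outliers
    candidates = np.flatnonzero(~in_dead)
    if n_plant > len(candidates):
        raise ConfigurationError("more planted failures than available cells")
    chosen = rng.choice(candidates, size=n_plant, replace=False)
    lo = chosen[:pf.low_count_cells]
    hi = chosen[pf.low_count_cells:pf.low_count_cells + pf.high_negprobe_cells]
    ao = chosen[pf.low_count_cells + pf.high_negprobe_cells:]
    for i in lo:
        tot = int(rng.integers(0, 16))  # strictly below the 20-count floor
        endo[i] = rng.multinomial(tot, mu[i] / mu[i].sum())
        neg[i] = 0
    truth.low_count_cells.extend(cell_ids[lo].tolist())
    for i in hi:
        neg[i] = rng.poisson(5.0, config.negprobe_count) + 1
        # make the negative-probe proportion unambiguously above 0.1
        while neg[i].sum() <= 0.12 * (endo[i].sum() + neg[i].sum()):
            neg[i] *= 2
    truth.high_negprobe_cells.extend(cell_ids[hi].tolist())
    area[ao] *= 15.0  # ~9 SD in log-area: certain Grubbs detection
    truth.area_outlier_cells.extend(cell_ids[ao].tolist())

    counts = sparse.csr_matrix(np.hstack([endo, neg]))
    expr = ExpressionMatrix(counts=counts, cell_ids=cell_ids,
                            targets=config.gene_names(),
                            target_class=config.target_class())
    cells = pd.DataFrame({
        "cell_id": cell_ids, "x": x, "y": y, "fov_id": fov_id, "area": area,
        "slide_id": slide_id, "severity": severity, "layer": layer_lab,
        "true_type": true_type, "niche": niche, "section_id": section_id,
    })
    return cells, expr, truth


def generate_cohort(
    config: TissueConfig,
    design: Sequence[tuple[str, str]] | None = None,
    batch_log2fc: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, ExpressionMatrix, GroundTruth]:
    """Concatenate one artery per (slide, severity) design cell.

    ``batch_log2fc`` optionally injects a slide-level mean count shift
    (log2 scale) to emulate batch structure.
    """
    if design is None:
        design = [("slide1", s) for s in SEVERITY_LEVELS]
    if len(design) == 0:
        raise ConfigurationError("empty cohort design")
    all_cells, all_expr, truth = [], [], GroundTruth()
    for slide_id, severity in design:
        cells, expr, t = generate_artery(config, severity, slide_id)
        if batch_log2fc and batch_log2fc.get(slide_id, 0.0) != 0.0:
            shift = 2.0 ** batch_log2fc[slide_id]
            rng = np.random.default_rng(
                [config.seed, zlib.crc32(f"batch|{slide_id}|{severity}".encode())])
            dense = expr.counts.toarray()
            # binomial thinning (shift<1) or Poisson topping-up (shift>1)
            if shift < 1:
                dense = rng.binomial(dense, shift)
            else:
                dense = dense + rng.poisson(dense * (shift - 1.0))
            expr = ExpressionMatrix(sparse.csr_matrix(dense), expr.cell_ids,
                                    expr.targets, expr.target_class)
        all_cells.append(cells)
        all_expr.append(expr)
        truth = truth.merged_with(t)
    cells = pd.concat(all_cells, ignore_index=True)
    expr = ExpressionMatrix(
        counts=sparse.vstack([e.counts for e in all_expr], format="csr"),
        cell_ids=np.concatenate([e.cell_ids for e in all_expr]),
        targets=all_expr[0].targets,
        target_class=all_expr[0].target_class,
    )
    return cells, expr, truth


@dataclass
class ROISpec:
    """A circular region of interest with an optional cell-type mask."""

    segment_id: str
    center: tuple[float, float]
    radius: float
    types: Sequence[str] | None = None  # None = all cells
    section_id: str | None = None
    location: str = "adventitia"
    marker_segment: str = "CD45+CD4-"


def pseudobulk_segments(
    cells: pd.DataFrame, expr: ExpressionMatrix, roi_spec: Iterable[ROISpec],
) -> SegmentTable:
    """Sum cell counts inside each ROI disc matching its type mask.

    Emulates segment collection: each segment's profile is the sum over
    member cells, ``nuclei_count`` the number of cells summed and
    ``surface_area`` the disc area. An ROI matching zero cells yields an
    all-zero segment with ``nuclei_count`` 0 (flagged, not an error).
    """
    label = cells["assigned_type"] if "assigned_type" in cells \
        else cells["true_type"]
    label = label.to_numpy()
    pos = np.column_stack([cells["x"].to_numpy(), cells["y"].to_numpy()])
    profiles, meta_rows = {}, []
    for roi in roi_spec:
        sel = np.hypot(pos[:, 0] - roi.center[0],
                       pos[:, 1] - roi.center[1]) <= roi.radius
        if roi.section_id is not None and "section_id" in cells:
            sel &= (cells["section_id"] == roi.section_id).to_numpy()
        if roi.types is not None:
            sel &= np.isin(label, list(roi.types))
        idx = np.flatnonzero(sel)
        prof = np.asarray(expr.counts[idx].sum(axis=0)).ravel()
        profiles[roi.segment_id] = prof
        member = cells.iloc[idx]
        meta_rows.append({
            "segment_id": roi.segment_id,
            "slide_id": member["slide_id"].iloc[0] if len(idx) else "",
            "severity": member["severity"].iloc[0] if len(idx) else "",
            "location": roi.location,
            "marker_segment": roi.marker_segment,
            "nuclei_count": int(len(idx)),
            "surface_area": float(np.pi * roi.radius ** 2),
        })
    counts = pd.DataFrame(profiles, index=expr.targets)
    meta = pd.DataFrame(meta_rows).set_index("segment_id")
    meta["empty"] = meta["nuclei_count"] == 0
    return SegmentTable(
        counts=counts, meta=meta,
        target_class=pd.Series(expr.target_class, index=expr.targets),
        normalized=False,
    )
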