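"""Cellular neighbourhood analysis.

Each cell is described by the cell-type composition of its spatial
neighbourhood — the frequency vector of annotated types among cells
within a fixed radius (20 µm by default) in the same tissue section.
k-means on these vectors defines recurring neighbourhood clusters
("niches"); summaries report niche frequency by lesion severity and a
type-by-niche enrichment z-score matrix. Per-FOV immune cell densities
are compared across severity with a Kruskal–Wallis test followed by
Dunn's pairwise test (Holm-adjusted).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .errors import DataError, ParameterError


@dataclass
class NeighbourhoodParams:
    radius: float = 20.0  # µm
    k: int = 10
    include_self: bool = True
    n_init: int = 10
    max_iter: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ParameterError("radius must be positive")
        if self.k < 2:
            raise ParameterError("k must be at least 2")
        if self.n_init < 1:
            raise ParameterError("n_init must be at least 1")


@dataclass
class NeighbourhoodModel:
    composition: np.ndarray  # cells x types frequency vectors
    types: np.ndarray  # the global type alphabet (column order)
    assignments: np.ndarray  # per-cell cluster in 1..k; 0 = excluded
    centroids: np.ndarray  # k x types
    inertia: float  # within-cluster sum of squares
    enrichment_z: pd.DataFrame  # types x clusters
    params: NeighbourhoodParams
    empty_clusters: list = field(default_factory=list)


def radius_neighbors(
    cells: pd.DataFrame, radius: float, include_self: bool = False,
) -> list[np.ndarray]:
    """Indices of all cells within ``radius`` µm (inclusive) of each cell.

    Neighbours are restricted to the same tissue section (``section_id``
    column if present, else ``slide_id``): cells on different physical
    sections are never neighbours.
    """
    if radius < 0:
        raise ParameterError("radius must be non-negative")
    group_col = "section_id" if "section_id" in cells.columns else "slide_id"
    xy = cells[["x", "y"]].to_numpy(dtype=float)
    out: list[np.ndarray] = [None] * len(cells)
    for _, idx in cells.groupby(group_col, sort=False).indices.items():
        idx = np.asarray(idx)
        tree = cKDTree(xy[idx])
        for local, hits in enumerate(tree.query_ball_point(xy[idx], r=radius)):
            nb = idx[np.asarray(hits, dtype=int)]
            if not include_self:
                nb = nb[nb != idx[local]]
            out[idx[local]] = np.sort(nb)
    return out


def composition_vectors(
    neighbors: list[np.ndarray],
    labels: np.ndarray,
    types: np.ndarray | None = None,
    include_self: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Neighbourhood type-frequency vector per cell.

    Returns ``(vectors, types, valid)``. With ``include_self=False`` an
    isolated cell has no defined composition: its vector is zero and its
    ``valid`` flag False (it must be excluded from clustering).

    ``neighbors`` must come from ``radius_neighbors(..., include_self=
    False)``; the self count is added here when requested.
    """
    labels = np.asarray(labels)
    if types is None:
        types = np.array(sorted(pd.unique(labels)))
    tindex = {t: j for j, t in enumerate(types)}
    codes = np.array([tindex[l] for l in labels])
    n, m = len(neighbors), len(types)
    vec = np.zeros((n, m))
    for i, nb in enumerate(neighbors):
        if len(nb):
            vec[i] = np.bincount(codes[nb], minlength=m)
        if include_self:
            vec[i, codes[i]] += 1
    sums = vec.sum(axis=1)
    valid = sums > 0
    vec[valid] /= sums[valid, None]
    if not valid.all():
        warnings.warn(f"{int((~valid).sum())} isolated cells have no "
                      "neighbourhood composition; excluded from clustering")
    return vec, types, valid


def _enrichment_z(centroid_comp: np.ndarray, types: np.ndarray) -> pd.DataFrame:
    """Per-type z across clusters of the mean member composition."""
    m = centroid_comp.T  # types x clusters
    mu = m.mean(axis=1, keepdims=True)
    sd = m.std(axis=1, ddof=0, keepdims=True)
    z = np.where(sd > 0, (m - mu) / np.where(sd == 0, 1.0, sd), 0.0)
    return pd.DataFrame(z, index=types,
                        columns=[f"N{c + 1}" for c in range(m.shape[1])])


def kmeans_neighbourhoods(
    vectors: np.ndarray,
    params: NeighbourhoodParams,
    types: np.ndarray | None = None,
    valid: np.ndarray | None = None,
) -> NeighbourhoodModel:
    """Cluster composition vectors with seeded k-means (k-means++ init).

    Clusters are numbered 1..k; excluded cells get assignment 0.
    """
    vectors = np.asarray(vectors, dtype=float)
    if types is None:
        types = np.array([f"type{j}" for j in range(vectors.shape[1])])
    if valid is None:
        valid = np.ones(len(vectors), dtype=bool)
    X = vectors[valid]
    n_distinct = len(np.unique(X, axis=0))
    if n_distinct < params.k:
        raise DataError(
            f"only {n_distinct} distinct composition vectors for k="
            f"{params.k}; choose a smaller k")
    km = KMeans(n_clusters=params.k, init="k-means++", n_init=params.n_init,
                max_iter=params.max_iter, random_state=params.seed)
    lab = km.fit_predict(X)
    assignments = np.zeros(len(vectors), dtype=int)
    assignments[valid] = lab + 1
    # mean member composition per cluster (equals the fitted centroid)
    comp = np.vstack([
        vectors[assignments == c + 1].mean(axis=0)
        if (assignments == c + 1).any() else np.zeros(vectors.shape[1])
        for c in range(params.k)
    ])
    empty = [c + 1 for c in range(params.k) if not (assignments == c + 1).any()]
    if empty:
        warnings.warn(f"empty clusters: {empty}")
    return NeighbourhoodModel(
        composition=vectors, types=np.asarray(types), assignments=assignments,
        centroids=km.cluster_centers_, inertia=float(km.inertia_),
        enrichment_z=_enrichment_z(comp, np.asarray(types)), params=params,
        empty_clusters=empty,
    )


def neighbourhood_summaries(
    model: NeighbourhoodModel, cells: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Niche frequency per severity (columns sum to 1) and the z matrix."""
    if len(model.assignments) != len(cells):
        raise ParameterError("model assignments are not aligned to cells")
    k = model.params.k
    freq = {}
    for sev, idx in cells.groupby("severity", sort=False,
                                  observed=True).indices.items():
        a = model.assignments[np.asarray(idx)]
        a = a[a > 0]
        if len(a) == 0:
            warnings.warn(f"severity {sev!r} has no clustered cells; omitted")
            continue
        freq[sev] = np.bincount(a, minlength=k + 1)[1:] / len(a)
    table = pd.DataFrame(freq, index=[f"N{c + 1}" for c in range(k)])
    return table, model.enrichment_z


def immune_density_tests(
    cells: pd.DataFrame,
    types_of_interest: list[str],
    label_col: str = "assigned_type",
    group_col: str = "severity",
) -> dict[str, pd.DataFrame]:
    """Per-FOV type percentages compared across severity groups.

    For each type: percentage = 100 * (cells of the type in the FOV) /
    (cells in the FOV); groups of FOV percentages compared with a
    tie-corrected Kruskal–Wallis test, and pairwise with Dunn's z test,
    Holm-adjusted across the pairs of each type.

    Returns ``{"percentages": ..., "kruskal": ..., "dunn": ...}``.
    """
    if label_col not in cells.columns:
        label_col = "true_type"
    lab = cells[label_col]
    per_fov = cells.groupby("fov_id", sort=False).agg(
        n=("cell_id", "size"), **{group_col: (group_col, "first")})
    pct = pd.DataFrame(index=per_fov.index)
    for t in types_of_interest:
        counts = cells[lab == t].groupby("fov_id", sort=False).size()
        pct[t] = 100.0 * counts.reindex(per_fov.index).fillna(0) / per_fov["n"]
    pct[group_col] = per_fov[group_col]

    groups = [g for g, _ in pct.groupby(group_col, sort=False, observed=True)]
    if len(groups) < 2:
        raise DataError("need at least two severity groups with FOVs")
    kw_rows, dunn_rows = [], []
    for t in types_of_interest:
        samples = [pct.loc[pct[group_col] == g, t].to_numpy() for g in groups]
        flat = np.concatenate(samples)
        if np.allclose(flat, flat[0]):
            h, p = 0.0, 1.0
        else:
            h, p = stats.kruskal(*samples)
        kw_rows.append({"type": t, "H": h, "p": p, "n_groups": len(groups)})
        dunn_rows.extend(_dunn(samples, groups, t))
    dunn = pd.DataFrame(dunn_rows)
    if len(dunn):
        for t in types_of_interest:  # Holm within each cell type
            sel = dunn["type"] == t
            if sel.any():
                dunn.loc[sel, "p_adj"] = multipletests(
                    dunn.loc[sel, "p"], method="holm")[1]
    return {"percentages": pct, "kruskal": pd.DataFrame(kw_rows), "dunn": dunn}


def _dunn(samples: list[np.ndarray], names: list, type_name: str) -> list[dict]:
    """Dunn's pairwise z statistics with tie correction."""
    ns = np.array([len(s) for s in samples])
    if (ns < 2).any():
        warnings.warn(f"{type_name}: a group has a single FOV; Dunn "
                      "comparisons are low-power")
    flat = np.concatenate(samples)
    N = len(flat)
    ranks = stats.rankdata(flat)
    mean_ranks = []
    start = 0
    for n in ns:
        mean_ranks.append(ranks[start:start + n].mean() if n else np.nan)
        start += n
    _, tie_counts = np.unique(flat, return_counts=True)
    tie_term = ((tie_counts ** 3 - tie_counts).sum() / (12.0 * (N - 1))
                if N > 1 else 0.0)
    var_base = N * (N + 1) / 12.0 - tie_term
    rows = []
    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            if ns[i] == 0 or ns[j] == 0:
                continue
            se = np.sqrt(var_base * (1.0 / ns[i] + 1.0 / ns[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
            p = 2.0 * stats.norm.sf(abs(z))
            rows.append({"type": type_name, "pair": f"{names[i]} vs {names[j]}",
                         "z": z, "p": p, "p_adj": np.nan})
    return rows
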