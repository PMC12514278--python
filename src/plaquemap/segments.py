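"""Segment-level (ROI) profiling pipeline.

Mirrors the whole-transcriptome workflow on user-drawn tissue segments:

1. technical QC on segment metadata (nuclei, surface area, raw reads);
2. background filtering against a per-segment limit of quantification
   (LOQ), the geometric mean of the negative probes times a power of
   their geometric SD;
3. Q3 normalization — each segment scaled by its third-quartile count
   relative to the cohort geometric mean of third quartiles;
4. unsupervised hierarchical clustering on Pearson distance;
5. per-target differential expression with a random-intercept linear
   mixed model (slide as the grouping factor, REML via 1-D profile
   optimization) and Benjamini–Hochberg correction;
6. preranked gene set enrichment (weighted running-sum ES, gene-label
   permutation null) and the compact pathway z-score
   (up − down) / sqrt(total).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from .datatypes import SegmentTable
from .errors import ConfigurationError, DataError, ParameterError

# --------------------------------------------------------------------------
# segment QC
# --------------------------------------------------------------------------


@dataclass
class SegmentQCParams:
    min_nuclei: int = 20
    min_area: float = 1600.0  # µm²
    min_raw_reads: float = 1000.0
    loq_n_sd: float = 2.0  # LOQ = geomean(neg) * geoSD(neg)**loq_n_sd
    loq_min_segment_fraction: float = 0.1
    min_targets_above_loq_per_segment: float = 0.05

    def __post_init__(self) -> None:
        if min(self.min_nuclei, self.min_area, self.min_raw_reads,
               self.loq_n_sd) < 0:
            raise ParameterError("thresholds must be non-negative")
        for f in (self.loq_min_segment_fraction,
                  self.min_targets_above_loq_per_segment):
            if not 0.0 <= f <= 1.0:
                raise ParameterError("fractions must be in [0, 1]")


def segment_qc(
    segments: SegmentTable, params: SegmentQCParams | None = None,
) -> pd.DataFrame:
    """Pass/fail per segment with enumerated failure reasons."""
    params = params or SegmentQCParams()
    for col in ("nuclei_count", "surface_area"):
        if col not in segments.meta.columns:
            raise ConfigurationError(f"segment metadata is missing {col!r}")
    raw_reads = segments.counts.sum(axis=0)
    rows = []
    for seg in segments.segments:
        reasons = []
        if segments.meta.loc[seg, "nuclei_count"] < params.min_nuclei:
            reasons.append("nuclei")
        if segments.meta.loc[seg, "surface_area"] < params.min_area:
            reasons.append("area")
        if raw_reads[seg] < params.min_raw_reads:
            reasons.append("raw_reads")
        rows.append({"segment_id": seg, "pass": not reasons,
                     "reasons": ";".join(reasons)})
    return pd.DataFrame(rows).set_index("segment_id")


# --------------------------------------------------------------------------
# LOQ filtering and Q3 normalization
# --------------------------------------------------------------------------


def _geomean(x: np.ndarray) -> float:
    return float(np.exp(np.mean(np.log(x))))


def _geosd(x: np.ndarray) -> float:
    if len(x) < 2:
        return 1.0
    return float(np.exp(np.std(np.log(x), ddof=1)))


def loq_target_filter(
    segments: SegmentTable, params: SegmentQCParams | None = None,
) -> tuple[SegmentTable, pd.Series]:
    """Remove targets and segments low in signal relative to background.

    The per-segment LOQ is geomean(negative probes) * geoSD ** loq_n_sd,
    with a 0.5 floor on zero probe counts before the geometric mean. A
    target is kept iff its counts exceed the LOQ in at least
    ``loq_min_segment_fraction`` of segments; a segment is kept iff at
    least ``min_targets_above_loq_per_segment`` of (endogenous) targets
    exceed its LOQ. Negative probes are dropped from the filtered table —
    they have served their purpose.
    """
    params = params or SegmentQCParams()
    neg = segments.counts.loc[segments.negprobe_mask]
    if neg.empty:
        raise DataError("no negative-probe targets; cannot compute LOQ")
    negv = np.maximum(neg.to_numpy(dtype=float), 0.5)
    loq = pd.Series(
        [_geomean(negv[:, j]) * _geosd(negv[:, j]) ** params.loq_n_sd
         for j in range(negv.shape[1])],
        index=segments.segments, name="loq")

    endo = segments.counts.loc[segments.endogenous_mask]
    above = endo.gt(loq, axis=1)  # strict: counts must exceed background
    keep_targets = above.mean(axis=1) >= params.loq_min_segment_fraction
    keep_segments = above.mean(axis=0) >= params.min_targets_above_loq_per_segment
    dropped_t = int((~keep_targets).sum())
    dropped_s = int((~keep_segments).sum())
    if dropped_t or dropped_s:
        warnings.warn(f"LOQ filter removed {dropped_t} targets and "
                      f"{dropped_s} segments low in signal vs background")
    filtered = SegmentTable(
        counts=endo.loc[keep_targets, keep_segments],
        meta=segments.meta.loc[keep_segments.to_numpy()],
        target_class=segments.target_class.loc[segments.endogenous_mask.to_numpy()]
        .loc[keep_targets.to_numpy()],
        normalized=segments.normalized,
    )
    return filtered, loq


def q3_normalize(segments: SegmentTable) -> SegmentTable:
    """Scale each segment by Q3 / geomean-of-Q3s.

    After normalization every segment's third quartile equals the cohort
    geometric mean of raw third quartiles; within-segment rank order is
    unchanged. Segments with Q3 = 0 cannot be normalized and are dropped
    with a warning.
    """
    endo = segments.counts.loc[segments.endogenous_mask]
    if endo.shape[0] < 4:
        raise DataError("need at least 4 endogenous targets for Q3")
    q3 = endo.quantile(0.75, axis=0)
    bad = q3 == 0
    if bad.any():
        warnings.warn(f"segments unnormalizable (Q3=0): "
                      f"{list(q3.index[bad])}; dropped")
        segments = SegmentTable(
            counts=segments.counts.loc[:, ~bad.to_numpy()],
            meta=segments.meta.loc[~bad.to_numpy()],
            target_class=segments.target_class,
            normalized=segments.normalized)
        q3 = q3[~bad]
    factors = q3 / _geomean(q3.to_numpy(dtype=float))
    counts = segments.counts.div(factors, axis=1)
    return SegmentTable(counts=counts, meta=segments.meta.copy(),
                        target_class=segments.target_class,
                        normalized=True)


# --------------------------------------------------------------------------
# hierarchical clustering on Pearson distance
# --------------------------------------------------------------------------


@dataclass
class HclustResult:
    linkage: np.ndarray
    labels: list[str]
    leaf_order: list[str]

    def to_newick(self) -> str:
        """Serialize the dendrogram as a Newick string with branch lengths."""
        tree = hierarchy.to_tree(self.linkage)

        def rec(node, parent_dist) -> str:
            if node.is_leaf():
                return f"{self.labels[node.id]}:{parent_dist - node.dist:.6g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{parent_dist - node.dist:.6g}"

        return f"({rec(tree.left, tree.dist)},{rec(tree.right, tree.dist)});"


def pearson_hclust(
    values: pd.DataFrame, orientation: str = "segments",
    method: str = "average",
) -> HclustResult:
    """Agglomerative clustering with distance 1 − Pearson correlation.

    ``values`` is a targets x segments table; ``orientation`` picks
    whether segments (columns) or targets (rows) are clustered. Leaf
    order follows scipy's deterministic dendrogram convention.
    """
    if orientation not in ("segments", "targets"):
        raise ParameterError("orientation must be 'segments' or 'targets'")
    X = values.T if orientation == "segments" else values
    labels = list(X.index.astype(str))
    if len(labels) < 2:
        raise DataError("need at least 2 items to cluster")
    arr = X.to_numpy(dtype=float)
    sd = arr.std(axis=1)
    if (sd == 0).any():
        bad = [labels[i] for i in np.flatnonzero(sd == 0)]
        raise DataError(f"constant items cannot be correlated: {bad}")
    dist = pdist(arr, metric="correlation")  # 1 - r
    dist = np.clip(dist, 0.0, None)  # guard tiny negative rounding
    Z = hierarchy.linkage(dist, method=method)
    order = hierarchy.leaves_list(Z)
    return HclustResult(linkage=Z, labels=labels,
                        leaf_order=[labels[i] for i in order])


# --------------------------------------------------------------------------
# mixed-model differential expression
# --------------------------------------------------------------------------


@dataclass
class DEResult:
    table: pd.DataFrame  # log2fc, se, t, df, p, fdr, var_ratio, converged
    contrast: str
    random_group: str


def _reml_profile(y, Xs, d, n, p):
    """Profile REML over the variance ratio for pre-rotated data.

    ``Xs``/``y`` are in the eigenbasis of ZZ' with eigenvalues ``d``;
    returns (var_ratio, beta, cov_beta_over_sigma2, sigma2).
    """

    def crit(lam):
        w = 1.0 / (1.0 + lam * d)
        XtWX = Xs.T @ (w[:, None] * Xs)
        XtWy = Xs.T @ (w * y)
        beta = np.linalg.solve(XtWX, XtWy)
        resid = y - Xs @ beta
        rss = float(np.sum(w * resid ** 2))
        sign, logdet = np.linalg.slogdet(XtWX)
        return (-np.sum(np.log(w)) + logdet + (n - p) * np.log(max(rss, 1e-300)))

    res = optimize.minimize_scalar(crit, bounds=(0.0, 1e5), method="bounded",
                                   options={"xatol": 1e-8})
    lam = float(res.x)
    if crit(0.0) <= res.fun:  # boundary check: OLS limit
        lam = 0.0
    w = 1.0 / (1.0 + lam * d)
    XtWX = Xs.T @ (w[:, None] * Xs)
    beta = np.linalg.solve(XtWX, Xs.T @ (w * y))
    resid = y - Xs @ beta
    sigma2 = float(np.sum(w * resid ** 2)) / (n - p)
    cov = np.linalg.inv(XtWX)
    return lam, beta, cov, sigma2


def lmm_differential_expression(
    segments: SegmentTable,
    group_col: str,
    groups: tuple[str, str],
    random_col: str = "slide_id",
    pseudocount: float = 1.0,
    force_var_ratio: float | None = None,
) -> DEResult:
    """Per-target two-group contrast with a random intercept per slide.

    Values are log2(normalized count + pseudocount). The model per target
    is ``y = b0 + b1*group + u_slide + e`` with ``u ~ N(0, s_u^2)``; the
    variance ratio ``s_u^2 / s_e^2`` is estimated by REML via a
    one-dimensional profile optimization (shared eigendecomposition of
    the grouping structure across targets). ``b1`` is the log2 fold
    change of ``groups[1]`` over ``groups[0]``; Wald t with residual df
    ``n - rank([X Z])``; Benjamini–Hochberg across converged targets.

    With a single random-effect level the model reduces exactly to OLS
    (a notice is logged). ``force_var_ratio`` pins the variance ratio
    (0 gives the OLS limit), mainly for validation.
    """
    meta = segments.meta
    for col in (group_col, random_col):
        if col not in meta.columns:
            raise ConfigurationError(f"segment metadata is missing {col!r}")
    sel = meta[group_col].isin(groups)
    if sel.sum() < 4:
        raise DataError("need at least 2 segments per group")
    meta = meta.loc[sel]
    for g in groups:
        if (meta[group_col] == g).sum() < 2:
            raise DataError(f"group {g!r} has fewer than 2 segments")
    Y = np.log2(segments.counts.loc[segments.endogenous_mask, sel.to_numpy()]
                .to_numpy(dtype=float) + pseudocount)
    targets = segments.targets[segments.endogenous_mask.to_numpy()]
    g = (meta[group_col] == groups[1]).to_numpy(dtype=float)
    n = len(g)
    X = np.column_stack([np.ones(n), g])
    slides = meta[random_col].astype(str).to_numpy()
    levels = np.unique(slides)
    single_level = len(levels) < 2
    if single_level:
        warnings.warn("single random-effect level; model reduces to OLS")
    Z = (slides[:, None] == levels[None, :]).astype(float)
    df = n - np.linalg.matrix_rank(np.column_stack([X, Z]))
    if df <= 0:
        raise DataError("no residual degrees of freedom for the contrast")
    # shared rotation: ZZ' = Q diag(d) Q'
    d, Q = np.linalg.eigh(Z @ Z.T)
    d = np.clip(d, 0.0, None)
    Xs = Q.T @ X

    rows = []
    for i, target in enumerate(targets):
        y = Q.T @ Y[i]
        try:
            if single_level or force_var_ratio is not None:
                lam = 0.0 if single_level else float(force_var_ratio)
                w = 1.0 / (1.0 + lam * d)
                XtWX = Xs.T @ (w[:, None] * Xs)
                beta = np.linalg.solve(XtWX, Xs.T @ (w * y))
                resid = y - Xs @ beta
                sigma2 = float(np.sum(w * resid ** 2)) / (n - 2)
                cov = np.linalg.inv(XtWX)
            else:
                lam, beta, cov, sigma2 = _reml_profile(y, Xs, d, n, 2)
            se = float(np.sqrt(sigma2 * cov[1, 1]))
            t = float(beta[1] / se) if se > 0 else np.nan
            ok = np.isfinite(t)
            rows.append({"target": target, "log2fc": float(beta[1]), "se": se,
                         "t": t, "df": df,
                         "p": 2.0 * stats.t.sf(abs(t), df) if ok else np.nan,
                         "var_ratio": lam, "converged": ok})
        except np.linalg.LinAlgError:
            rows.append({"target": target, "log2fc": np.nan, "se": np.nan,
                         "t": np.nan, "df": df, "p": np.nan,
                         "var_ratio": np.nan, "converged": False})
    table = pd.DataFrame(rows).set_index("target")
    bad = ~table["converged"]
    if bad.any():
        warnings.warn(f"{int(bad.sum())} targets did not converge; "
                      "excluded from FDR")
    table["fdr"] = np.nan
    ok = table["converged"]
    if ok.any():
        table.loc[ok, "fdr"] = bh_adjust(table.loc[ok, "p"].to_numpy())
    return DEResult(table=table,
                    contrast=f"{group_col}: {groups[1]} vs {groups[0]}",
                    random_group=random_col)


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ParameterError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# --------------------------------------------------------------------------
# preranked GSEA and the pathway z-score
# --------------------------------------------------------------------------


@dataclass
class GseaParams:
    min_set_size: int = 15
    max_set_size: int = 500
    min_coverage: float = 0.2
    n_perm: int = 10_000
    weight: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.min_set_size <= self.max_set_size:
            raise ParameterError("need 0 < min_set_size <= max_set_size")
        if not 0.0 < self.min_coverage <= 1.0:
            raise ParameterError("min_coverage must be in (0, 1]")


def _enrichment_score(pos: np.ndarray, absw: np.ndarray, N: int) -> float:
    """Weighted KS running-sum extremum for member positions ``pos``.

    ``pos`` must be sorted ranks (0-based) in the descending ranking.
    """
    m = len(pos)
    if m == 0 or m == N:
        raise DataError("gene set must be a proper subset of the ranking")
    hit_w = absw[pos]
    denom = hit_w.sum()
    miss_step = 1.0 / (N - m)
    miss_before = (pos - np.arange(m)) * miss_step
    if denom == 0:  # all member stats exactly zero
        cum_hit = np.arange(1, m + 1) / m
    else:
        cum_hit = np.cumsum(hit_w) / denom
    pos_dev = cum_hit - miss_before
    neg_dev = np.concatenate([[0.0], cum_hit[:-1]]) - miss_before
    hi, lo = float(pos_dev.max()), float(neg_dev.min())
    return hi if hi >= -lo else lo


def preranked_gsea(
    ranked: pd.Series, sets: dict[str, list[str]],
    params: GseaParams | None = None,
) -> pd.DataFrame:
    """Preranked gene set enrichment analysis.

    ``ranked`` maps gene name -> ranking statistic (e.g. the DE t
    statistic); sets are intersected with the ranking, then filtered to
    ``min_set_size <= size <= max_set_size`` and to sets with at least
    ``min_coverage`` of their genes covered by the ranking. The null
    distribution permutes gene labels (random sets of the same size,
    shared across sets of equal size); NES = ES / mean(|null ES| of the
    same sign) and the empirical p-value carries a +1 correction, so its
    floor is 1/(n_perm + 1). FDR is Benjamini–Hochberg across sets.
    """
    params = params or GseaParams()
    if ranked.index.duplicated().any():
        raise DataError("ranking contains duplicate gene names")
    if len(ranked) == 0:
        raise DataError("empty ranking")
    order = np.argsort(-ranked.to_numpy(), kind="stable")
    genes = ranked.index.to_numpy()[order]
    stat = ranked.to_numpy()[order]
    N = len(genes)
    rank_of = {g: i for i, g in enumerate(genes)}
    absw = np.abs(stat) ** params.weight

    kept: dict[str, np.ndarray] = {}
    for name, members in sets.items():
        members = set(members)
        inter = sorted(rank_of[g] for g in members if g in rank_of)
        if len(inter) == N:
            raise DataError(f"set {name!r} covers every ranked gene "
                            "(empty complement)")
        coverage = len(inter) / max(len(members), 1)
        if coverage < params.min_coverage:
            warnings.warn(f"set {name!r} skipped: coverage "
                          f"{coverage:.2f} < {params.min_coverage}")
            continue
        if not params.min_set_size <= len(inter) <= params.max_set_size:
            warnings.warn(f"set {name!r} skipped: size {len(inter)} outside "
                          f"[{params.min_set_size}, {params.max_set_size}]")
            continue
        kept[name] = np.asarray(inter)

    rng = np.random.default_rng(params.seed)
    null_cache: dict[int, np.ndarray] = {}

    def null_for(m: int) -> np.ndarray:
        if m not in null_cache:
            es = np.empty(params.n_perm)
            for b in range(params.n_perm):
                pos = np.sort(rng.choice(N, size=m, replace=False))
                es[b] = _enrichment_score(pos, absw, N)
            null_cache[m] = es
        return null_cache[m]

    rows = []
    for name, pos in kept.items():
        es = _enrichment_score(pos, absw, N)
        null = null_for(len(pos))
        # two-sided permutation p on |ES| over all permutations: floor is
        # 1/(n_perm+1) and the null distribution of p is uniform
        p = (1.0 + np.sum(np.abs(null) >= abs(es))) / (params.n_perm + 1.0)
        same = null[null > 0] if es >= 0 else null[null < 0]
        nes = es / np.abs(same).mean() if len(same) else np.nan
        rows.append({"set": name, "size": len(pos), "ES": es, "NES": nes,
                     "p": p})
    result = pd.DataFrame(rows)
    if len(result):
        result["fdr"] = bh_adjust(result["p"].to_numpy())
        result = result.set_index("set")
    return result


def pathway_zscore(
    set_members: list[str], de_table: pd.DataFrame, alpha: float = 0.05,
) -> float:
    """Compact pathway direction score: (n_up − n_down) / sqrt(n_total).

    ``n_up``/``n_down`` count set members significant at ``alpha`` (on
    the FDR column when present, else raw p) with positive/negative
    log2 fold change; ``n_total`` is the number of set members tested.
    Empty intersection with the tested targets -> NaN (reported missing).
    """
    sub = de_table.loc[de_table.index.intersection(set_members)]
    if sub.empty:
        warnings.warn("pathway has no tested members; z-score undefined")
        return float("nan")
    crit = sub["fdr"] if "fdr" in sub.columns else sub["p"]
    sig = crit <= alpha
    n_up = int((sig & (sub["log2fc"] > 0)).sum())
    n_down = int((sig & (sub["log2fc"] < 0)).sum())
    return (n_up - n_down) / np.sqrt(len(sub))
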