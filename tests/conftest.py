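import numpy as np
import pandas as pd
import pytest

import plaquemap as pm


def tiny_config(seed: int = 0, **overrides) -> pm.TissueConfig:
    """Small artery for fast unit tests (full defaults are heavier)."""
    kw = dict(
        seed=seed,
        cells_per_layer={"plaque": 300, "media": 250, "adventitia": 250,
                         "perivascular": 200},
        atlo=pm.AtloSpec(extra_cells=60),
    )
    kw.update(overrides)
    return pm.TissueConfig(**kw)


def simulate_segment_matrix(n_genes, n_per_group, n_slides, tau, sigma,
                            lfc=0.0, n_alt=0, seed=0):
    """Two-group segment study with slide random intercepts (log2-scale).

    Counts are 2**y so that log2(counts) recovers y exactly; the first
    ``n_alt`` genes carry a planted log2 fold change of ``lfc``.
    """
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    slides = np.array([f"s{i % n_slides}" for i in range(n)])
    group = np.array(["A", "B"] * n_per_group)
    u = {s: rng.normal(0, tau) for s in np.unique(slides)}
    beta = np.zeros(n_genes)
    beta[:n_alt] = lfc
    Y = np.empty((n_genes, n))
    for j in range(n):
        Y[:, j] = (8.0 + beta * (group[j] == "B") + u[slides[j]]
                   + rng.normal(0, sigma, n_genes))
    counts = pd.DataFrame(2.0 ** Y, index=[f"g{i}" for i in range(n_genes)],
                          columns=[f"seg{j}" for j in range(n)])
    meta = pd.DataFrame(
        {"slide_id": slides, "severity": "mild", "location": "adventitia",
         "marker_segment": "CD45+CD4-", "nuclei_count": 100,
         "surface_area": 1e4, "group": group}, index=counts.columns)
    tclass = pd.Series("endogenous", index=counts.index)
    return pm.SegmentTable(counts=counts, meta=meta, target_class=tclass,
                           normalized=True)


@pytest.fixture(scope="session")
def qc_cohort():
    """~20k-cell, 16-FOV cohort with planted QC failures (seeded)."""
    half = {k: v // 2 for k, v in pm.TissueConfig().cells_per_layer.items()}
    cfg = pm.TissueConfig(seed=11, cells_per_layer=half, fov_grid=650.0,
                          planted_failures=pm.PlantedFailures(
                              low_count_cells=25, high_negprobe_cells=10,
                              area_outliers=3, dead_fovs=1))
    cells, expr, truth = pm.generate_cohort(cfg)
    return cells, expr, truth


@pytest.fixture(scope="session")
def filtered_cohort(qc_cohort):
    cells, expr, truth = qc_cohort
    fexpr, fcells, report = pm.apply_qc(expr, cells)
    return fexpr, fcells, report


@pytest.fixture(scope="session")
def severe_artery():
    """One default-size severe artery (ATLO planted)."""
    return pm.generate_artery(pm.TissueConfig(seed=2), "severe")


@pytest.fixture(scope="session")
def niche_model(severe_artery):
    cells, _, _ = severe_artery
    nb = pm.radius_neighbors(cells, 20.0)
    vec, types, valid = pm.composition_vectors(nb, cells["true_type"].to_numpy())
    model = pm.kmeans_neighbourhoods(
        vec, pm.NeighbourhoodParams(k=5, seed=0), types, valid)
    return nb, vec, types, valid, model
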