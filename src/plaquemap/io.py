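"""Flat-file interchange: Matrix Market + TSV, GMT gene sets, YAML config.

Layout conventions follow the common single-cell flat export: a sparse
``matrix.mtx`` (cells x targets) with side-car ``targets.tsv`` (name and
endogenous/negative-probe class) and a ``cells.tsv`` metadata table.
Segment tables are a targets-by-segments TSV plus a segment metadata
TSV. Everything is plain text.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import io as spio
from scipy import sparse

from .datatypes import (ExpressionMatrix, ReferenceMatrix, SegmentTable,
                        validate_cell_table)
from .synthetic import AtloSpec, PlantedFailures, TissueConfig


# -- single-cell matrices ---------------------------------------------------

def write_expression(expr: ExpressionMatrix, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(outdir / "matrix.mtx", sparse.coo_matrix(expr.counts))
    pd.DataFrame({"target": expr.targets, "target_class": expr.target_class}
                 ).to_csv(outdir / "targets.tsv", sep="\t", index=False)
    pd.DataFrame({"cell_id": expr.cell_ids}).to_csv(
        outdir / "barcodes.tsv", sep="\t", index=False)


def read_expression(indir: str | Path) -> ExpressionMatrix:
    indir = Path(indir)
    counts = sparse.csr_matrix(spio.mmread(indir / "matrix.mtx"))
    targets = pd.read_csv(indir / "targets.tsv", sep="\t")
    cells = pd.read_csv(indir / "barcodes.tsv", sep="\t")
    return ExpressionMatrix(
        counts=counts, cell_ids=cells["cell_id"].to_numpy(),
        targets=targets["target"].to_numpy(),
        target_class=targets["target_class"].to_numpy())


def write_cell_table(cells: pd.DataFrame, path: str | Path) -> None:
    validate_cell_table(cells).to_csv(path, sep="\t", index=False)


def read_cell_table(path: str | Path) -> pd.DataFrame:
    return validate_cell_table(pd.read_csv(path, sep="\t"))


# -- segment tables ---------------------------------------------------------

def write_segment_table(seg: SegmentTable, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts = seg.counts.copy()
    counts.insert(0, "target_class", seg.target_class)
    counts.to_csv(outdir / "segments.tsv", sep="\t",
                  index_label="target")
    meta = seg.meta.copy()
    meta["normalized"] = seg.normalized
    meta.to_csv(outdir / "segment_meta.tsv", sep="\t", index_label="segment_id")


def read_segment_table(indir: str | Path) -> SegmentTable:
    indir = Path(indir)
    counts = pd.read_csv(indir / "segments.tsv", sep="\t", index_col="target")
    counts.index.name = None
    target_class = counts.pop("target_class")
    meta = pd.read_csv(indir / "segment_meta.tsv", sep="\t",
                       index_col="segment_id")
    normalized = bool(meta.pop("normalized").iloc[0]) if "normalized" in meta \
        else False
    meta.index = meta.index.astype(str)
    counts.columns = counts.columns.astype(str)
    return SegmentTable(counts=counts, meta=meta, target_class=target_class,
                        normalized=normalized)


# -- reference matrices -----------------------------------------------------

def write_reference(ref: ReferenceMatrix, path: str | Path) -> None:
    out = ref.profiles.copy()
    out.insert(0, "n_cells", ref.n_cells)
    out.insert(0, "scale", ref.scale)
    out.to_csv(path, sep="\t", index_label="cell_type")


def read_reference(path: str | Path) -> ReferenceMatrix:
    df = pd.read_csv(path, sep="\t", index_col="cell_type")
    scale = str(df.pop("scale").iloc[0])
    n_cells = df.pop("n_cells")
    return ReferenceMatrix(profiles=df, n_cells=n_cells, scale=scale)


# -- gene sets (GMT) --------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT: one set per line, tab-separated: name, description, genes..."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path,
              description: str = "na") -> None:
    lines = [f"{name}\t{description}\t" + "\t".join(genes)
             for name, genes in sets.items()]
    Path(path).write_text("\n".join(lines) + "\n")


# -- tissue config (YAML) ---------------------------------------------------

def _plainify(obj):
    """Recursively convert tuples/numpy scalars for YAML serialization."""
    if isinstance(obj, dict):
        return {k: _plainify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plainify(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def write_config(config: TissueConfig, path: str | Path) -> None:
    d = _plainify(dataclasses.asdict(config))
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def read_config(path: str | Path) -> TissueConfig:
    d = yaml.safe_load(Path(path).read_text())
    if d.get("atlo") is not None:
        a = d["atlo"]
        if "severities" in a:
            a["severities"] = tuple(a["severities"])
        d["atlo"] = AtloSpec(**a)
    if d.get("planted_failures") is not None:
        d["planted_failures"] = PlantedFailures(**d["planted_failures"])
    for k in ("layer_boundaries", "cell_types"):
        if k in d and d[k] is not None:
            d[k] = tuple(d[k])
    fields = {f.name for f in dataclasses.fields(TissueConfig)}
    return TissueConfig(**{k: v for k, v in d.items() if k in fields})
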