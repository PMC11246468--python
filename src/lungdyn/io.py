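"""File I/O: MatrixMarket counts, TSV/CSV tables, YAML configs, manifests.

Counts travel as ``matrix.mtx`` (cells x genes) with ``genes.tsv`` and
``cells.tsv`` sidecars; spatial maps and weight tables as CSV. Writers are
deterministic (fixed column order, ``%.10g`` float formatting) so repeated
runs are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import io as spio
from scipy import sparse

from .datatypes import CountMatrix
from .synthetic import SpatialMap, SpotWeights

FLOAT_FMT = "%.10g"


def write_counts(counts: CountMatrix, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(outdir / "matrix.mtx", sparse.csr_matrix(counts.counts))
    pd.Series(counts.gene_ids).to_csv(outdir / "genes.tsv", sep="\t",
                                      index=False, header=["gene_id"])
    counts.cell_meta.to_csv(outdir / "cells.tsv", sep="\t",
                            float_format=FLOAT_FMT)
    return outdir


def read_counts(indir: str | Path, mito_prefix: str = "MT-",
                require_gw: bool = False) -> CountMatrix:
    indir = Path(indir)
    mat = spio.mmread(indir / "matrix.mtx")
    counts = np.asarray(sparse.csr_matrix(mat).todense())
    genes = pd.read_csv(indir / "genes.tsv", sep="\t")["gene_id"]
    cells = pd.read_csv(indir / "cells.tsv", sep="\t", index_col="cell_id")
    if "sample_id" not in cells.columns:
        raise ValueError("cells.tsv must contain a 'sample_id' column")
    if require_gw and "gestational_week" not in cells.columns:
        raise ValueError("cells.tsv must contain a 'gestational_week' column")
    return CountMatrix(counts.astype(np.int64), cells, pd.Index(genes),
                       mito_prefix)


def write_spatial(smap: SpatialMap, path: str | Path) -> Path:
    path = Path(path)
    smap.table.to_csv(path, index=False, float_format=FLOAT_FMT)
    return path


def read_spatial(path: str | Path) -> SpatialMap:
    df = pd.read_csv(path)
    need = {"cell_id", "x", "y", "type"}
    if not need.issubset(df.columns):
        raise ValueError(f"spatial CSV must have columns {sorted(need)}")
    return SpatialMap(df)


def write_spot_weights(weights: SpotWeights, path: str | Path) -> Path:
    path = Path(path)
    out = weights.coords.join(weights.weights)
    out.to_csv(path, float_format=FLOAT_FMT)
    return path


def read_spot_weights(path: str | Path) -> SpotWeights:
    df = pd.read_csv(path, index_col="spot_id")
    coords = df[["x", "y"]]
    return SpotWeights(df.drop(columns=["x", "y"]), coords)


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=index, float_format=FLOAT_FMT)
    return path


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def write_manifest(manifest: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return path
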