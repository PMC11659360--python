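"""On-disk formats: MatrixMarket counts and tab-delimited tables.

Counts are stored genes x cells (MatrixMarket, the convention of public count
matrices); the in-memory container is cells x genes, so read/write transpose.
All metadata tables are tab-delimited with a header row.
"""

from __future__ import annotations

from dataclasses import fields
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .positivity import make_expression_dataset
from .simulate import SimulatedStudy, SimulationConfig


def write_expression(adata: ad.AnnData, outdir: str | Path) -> None:
    """Write counts (genes x cells .mtx), gene ids and cell metadata."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(outdir / "counts.mtx", sparse.csr_matrix(adata.X).T)
    pd.Series(adata.var_names, name="gene_id").to_csv(
        outdir / "genes.tsv", sep="\t", index=False
    )
    adata.obs.rename_axis("cell_id").to_csv(outdir / "cells.tsv", sep="\t")


def read_expression(indir: str | Path) -> ad.AnnData:
    """Read a dataset written by :func:`write_expression`."""
    indir = Path(indir)
    counts = sparse.csr_matrix(spio.mmread(indir / "counts.mtx")).T
    genes = pd.read_csv(indir / "genes.tsv", sep="\t")["gene_id"].tolist()
    obs = pd.read_csv(indir / "cells.tsv", sep="\t", index_col="cell_id")
    return make_expression_dataset(counts, genes, obs)


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def read_table(path: str | Path, index_col: str | None = None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_config(config: SimulationConfig, path: str | Path) -> None:
    """Flat key/value dump of the scalar simulation parameters."""
    lines = []
    for f in fields(config):
        value = getattr(config, f.name)
        if isinstance(value, (int, float, str, bool)) or value is None:
            lines.append(f"{f.name}\t{value}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text("\n".join(lines) + "\n")


def write_study(study: SimulatedStudy, outdir: str | Path) -> None:
    """Write every artifact of one simulation run under ``outdir``."""
    outdir = Path(outdir)
    write_expression(study.deep, outdir / "deep")
    write_table(study.taxonomy, outdir / "taxonomy.tsv")
    write_table(study.spatial_cells, outdir / "spatial_cells.tsv", index=False)
    write_table(study.structures, outdir / "structures.tsv")
    write_table(study.references, outdir / "references.tsv", index=False)
    if study.truth.cluster_rates is not None:
        write_table(study.truth.cluster_rates, outdir / "truth_cluster_rates.tsv")
    if study.truth.structure_truth is not None:
        write_table(study.truth.structure_truth, outdir / "truth_structures.tsv")
    write_config(study.config, outdir / "config.tsv")
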