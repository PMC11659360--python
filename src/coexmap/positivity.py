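"""CPM normalization and per-cell positivity calling.

Two rules are supported, matching the two conventions used for deep atlas
data versus smaller scRNA-seq sets:

* ``log2cpm``: a cell is positive for a gene when log2(CPM) exceeds a
  threshold (default 3), i.e. CPM strictly greater than ``2**threshold``.
  Zero counts are negative without evaluating a log of zero.
* ``count``: a cell is positive when the raw count reaches ``min_count``
  (default 1), with no normalization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

REQUIRED_OBS = ("cluster_id", "class_label", "neurotransmitter")


@dataclass(frozen=True)
class PositivityRule:
    mode: Literal["log2cpm", "count"]
    threshold: float = 3.0
    min_count: int = 1

    @classmethod
    def log2cpm(cls, threshold: float = 3.0) -> "PositivityRule":
        return cls(mode="log2cpm", threshold=threshold)

    @classmethod
    def count(cls, min_count: int = 1) -> "PositivityRule":
        return cls(mode="count", min_count=min_count)

    @property
    def cpm_cutoff(self) -> float:
        """CPM value above which a cell is positive (log2cpm mode)."""
        return float(2.0 ** self.threshold)


def min_positive_count(rule: PositivityRule, library_size: np.ndarray) -> np.ndarray:
    """Smallest integer count that makes a cell positive under ``rule``.

    For the log2cpm rule, CPM > 2**threshold <=> count > lib * 2**threshold / 1e6,
    so the minimum positive count is floor(...) + 1.
    """
    library_size = np.asarray(library_size)
    if rule.mode == "count":
        return np.full(library_size.shape, rule.min_count, dtype=np.int64)
    return np.floor(library_size * rule.cpm_cutoff / 1e6).astype(np.int64) + 1


def make_expression_dataset(
    counts: sparse.spmatrix | np.ndarray,
    gene_ids: list[str],
    obs: pd.DataFrame,
) -> ad.AnnData:
    """Assemble and validate an expression dataset (cells x genes AnnData).

    ``obs`` must be indexed by cell_id and carry cluster_id, class_label and
    neurotransmitter; library_size and structure_id are optional. Validates
    that no gene count exceeds its cell's library size.
    """
    X = sparse.csr_matrix(counts)
    if X.shape[0] != len(obs):
        raise ValueError("counts and obs disagree on the number of cells")
    if X.shape[1] != len(gene_ids):
        raise ValueError("counts and gene_ids disagree on the number of genes")
    missing = [c for c in REQUIRED_OBS if c not in obs.columns]
    if missing:
        raise ValueError(f"obs is missing required columns: {missing}")
    adata = ad.AnnData(
        X=X,
        obs=obs.copy(),
        var=pd.DataFrame(index=pd.Index(gene_ids, name="gene_id")),
    )
    lib = get_library_size(adata)
    per_gene_max = np.asarray(X.max(axis=1).todense()).ravel() if sparse.issparse(X) else X.max(axis=1)
    bad = per_gene_max > lib
    if bad.any():
        cell = adata.obs_names[np.flatnonzero(bad)[0]]
        raise ValueError(f"cell {cell}: gene count exceeds library size")
    return adata


def get_library_size(adata: ad.AnnData) -> np.ndarray:
    """Per-cell library size: the obs column if present, else row totals.

    The metadata column takes precedence because a matrix restricted to the
    genes of interest cannot supply transcriptome totals implicitly.
    """
    if "library_size" in adata.obs.columns:
        return adata.obs["library_size"].to_numpy(dtype=np.int64)
    return np.asarray(adata.X.sum(axis=1)).ravel().astype(np.int64)


def _gene_counts(adata: ad.AnnData, gene: str) -> np.ndarray:
    if gene not in adata.var_names:
        raise KeyError(f"gene {gene!r} is absent from the dataset")
    col = adata[:, gene].X
    return np.asarray(col.todense() if sparse.issparse(col) else col).ravel()


def compute_cpm(adata: ad.AnnData, gene: str) -> np.ndarray:
    """Counts per million of library size for one gene, per cell."""
    counts = _gene_counts(adata, gene)
    lib = get_library_size(adata)
    zero = lib == 0
    if zero.any():
        cell = adata.obs_names[np.flatnonzero(zero)[0]]
        raise ValueError(f"cell {cell}: library size is zero, CPM undefined")
    return counts / lib * 1e6


def call_positivity(
    adata: ad.AnnData,
    rule: PositivityRule,
    gene_a: str = "Ghsr",
    gene_b: str = "Cnr1",
) -> pd.DataFrame:
    """Per-cell boolean positivity calls for two genes and their conjunction.

    Returns a frame indexed like ``adata.obs`` with columns
    ``pos_a``, ``pos_b``, ``pos_ab`` (``pos_ab = pos_a & pos_b``).
    """

    def one_gene(gene: str) -> np.ndarray:
        if rule.mode == "count":
            return _gene_counts(adata, gene) >= rule.min_count
        cpm = compute_cpm(adata, gene)
        return cpm > rule.cpm_cutoff  # strict: "higher than" the threshold

    pos_a = one_gene(gene_a)
    pos_b = one_gene(gene_b)
    return pd.DataFrame(
        {"pos_a": pos_a, "pos_b": pos_b, "pos_ab": pos_a & pos_b},
        index=adata.obs_names.rename("cell_id"),
    )
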