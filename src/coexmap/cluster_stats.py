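"""Per-cluster positive fractions and phenotype composition.

The per-cluster fractions computed here are the quantity transferred from the
deep dataset onto the spatial dataset: for each cluster, the exact proportion
of cells called positive for gene A, gene B and both.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd

from .simulate import NEUROTRANSMITTERS, NO_NEUROTRANSMITTER

NT_CATEGORIES: tuple[str, ...] = NEUROTRANSMITTERS + (NO_NEUROTRANSMITTER,)


def cluster_fractions(calls: pd.DataFrame, adata: ad.AnnData) -> pd.DataFrame:
    """Exact positive fractions per cluster.

    Returns a frame indexed by cluster_id with n_cells, p_a, p_b, p_ab and the
    cluster's class/neurotransmitter labels. Clusters with zero cells do not
    appear. Every cell must carry a cluster label.
    """
    obs = adata.obs
    missing = obs["cluster_id"].isna() | (obs["cluster_id"].astype(str) == "")
    if missing.any():
        cell = obs.index[np.flatnonzero(missing)[0]]
        raise ValueError(f"cell {cell}: cluster label is missing")
    df = pd.DataFrame(
        {
            "cluster_id": obs["cluster_id"].to_numpy(),
            "class_label": obs["class_label"].to_numpy(),
            "neurotransmitter": obs["neurotransmitter"].to_numpy(),
            "pos_a": calls["pos_a"].to_numpy(),
            "pos_b": calls["pos_b"].to_numpy(),
            "pos_ab": calls["pos_ab"].to_numpy(),
        }
    )
    out = df.groupby("cluster_id", sort=True).agg(
        n_cells=("pos_a", "size"),
        p_a=("pos_a", "mean"),
        p_b=("pos_b", "mean"),
        p_ab=("pos_ab", "mean"),
        class_label=("class_label", "first"),
        neurotransmitter=("neurotransmitter", "first"),
    )
    return out


def phenotype_composition(
    calls: pd.DataFrame,
    adata: ad.AnnData,
    group_by: str = "cluster_id",
) -> pd.DataFrame:
    """Neurotransmitter composition of double-positive cells per group.

    ``group_by`` is an obs column (cluster_id, or structure_id when present).
    Returns one row per group that contains at least one double-positive cell:
    raw per-category counts (``n_<cat>``) summing exactly to the group's
    double-positive count, and percentages (``pct_<cat>``). Groups without
    double-positives are omitted (their composition is undefined).
    """
    if group_by not in adata.obs.columns:
        raise KeyError(f"obs has no column {group_by!r}")
    obs = adata.obs
    dp = calls["pos_ab"].to_numpy()
    df = pd.DataFrame(
        {
            "group": obs[group_by].to_numpy()[dp],
            "nt": obs["neurotransmitter"].to_numpy()[dp],
        }
    )
    if df.empty:
        return pd.DataFrame(
            columns=[f"n_{c}" for c in NT_CATEGORIES]
            + [f"pct_{c}" for c in NT_CATEGORIES]
        )
    tab = (
        df.groupby(["group", "nt"], sort=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=list(NT_CATEGORIES), fill_value=0)
    )
    total = tab.sum(axis=1)
    out = tab.add_prefix("n_")
    for c in NT_CATEGORIES:
        out[f"pct_{c}"] = 100.0 * tab[c] / total
    out.index.name = group_by
    return out


@dataclass(frozen=True)
class DatasetSummary:
    """Whole-dataset positive-cell tallies and shares."""

    n_pos_a: int
    n_pos_b: int
    n_pos_ab: int
    pct_ab_vs_a: float | None  # 100 * AB / A, None when A = 0
    pct_ab_vs_b: float | None
    pct_ab_neurons: float | None  # share of double-positives that are neurons


def dataset_level_summary(calls: pd.DataFrame, adata: ad.AnnData) -> DatasetSummary:
    """Overall positive counts and double-positive shares for one dataset."""
    n_a = int(calls["pos_a"].sum())
    n_b = int(calls["pos_b"].sum())
    n_ab = int(calls["pos_ab"].sum())
    dp = calls["pos_ab"].to_numpy()
    neurons = None
    if n_ab > 0:
        is_neuron = adata.obs["class_label"].to_numpy()[dp] == "neuron"
        neurons = 100.0 * float(is_neuron.mean())
    return DatasetSummary(
        n_pos_a=n_a,
        n_pos_b=n_b,
        n_pos_ab=n_ab,
        pct_ab_vs_a=100.0 * n_ab / n_a if n_a else None,
        pct_ab_vs_b=100.0 * n_ab / n_b if n_b else None,
        pct_ab_neurons=neurons,
    )
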