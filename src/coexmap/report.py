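"""Region summary tables: counts, percentages, composition, selection.

Produces the summary-table shape of the quantitative analysis: per structure,
estimated Ghsr+/Cnr1+/double+ counts, double-positive percentages relative to
each single-positive count (one decimal), integer neurotransmitter
percentages, density, and the selection flag (more than ``min_cells``
double-positive cells AND a density of more than ``min_density`` per mm^3,
both strict); plus per-region roll-ups of listed (selected) versus total
double-positive cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cluster_stats import NT_CATEGORIES
from .spatial import MARKER_COLS, StructureComposition, round_half_away

DEFAULT_MIN_CELLS = 350
DEFAULT_MIN_DENSITY = 50.0


def structure_phenotypes(
    contributions: pd.DataFrame, taxonomy: pd.DataFrame
) -> pd.DataFrame:
    """Integer neurotransmitter percentages of apportioned double-positives.

    ``contributions`` is the long (structure, cluster) frame from
    ``apportion_contributions``; each cluster's floored double-positive
    contribution carries its cluster's neurotransmitter label. Structures with
    zero apportioned double-positives are omitted (composition undefined).
    """
    df = contributions.merge(
        taxonomy["neurotransmitter"], left_on="cluster_id", right_index=True, how="left"
    )
    if df["neurotransmitter"].isna().any():
        bad = df.loc[df["neurotransmitter"].isna(), "cluster_id"].iloc[0]
        raise ValueError(f"cluster {bad} is absent from the taxonomy")
    tab = (
        df.groupby(["structure_id", "neurotransmitter"], sort=True)["est_ab"]
        .sum()
        .unstack(fill_value=0)
        .reindex(columns=list(NT_CATEGORIES), fill_value=0)
    )
    total = tab.sum(axis=1)
    tab = tab[total > 0]
    total = total[total > 0]
    pct = tab.div(total, axis=0) * 100.0
    out = pd.DataFrame(
        round_half_away(pct.to_numpy()).astype(np.int64),
        index=pct.index,
        columns=[f"pct_{c}" for c in pct.columns],
    )
    return out


def build_summary(
    estimates: pd.DataFrame,
    composition: StructureComposition,
    phenotypes: pd.DataFrame | None = None,
    min_cells: int = DEFAULT_MIN_CELLS,
    min_density: float = DEFAULT_MIN_DENSITY,
) -> pd.DataFrame:
    """Assemble the per-structure summary table.

    ``estimates`` holds integer est_a/est_b/est_ab per structure (calibrated
    or not — the arithmetic is the same). Percentages relative to a zero
    single-positive count are reported as missing (NaN), distinguishing "no
    single-positive cells" from "no overlap"; est_a = 0 with est_ab > 0 is an
    inconsistency error.
    """
    est = estimates[list(MARKER_COLS)]
    structs = composition.structures
    bad = (est["est_a"] == 0) & (est["est_ab"] > 0)
    if bad.any():
        raise ValueError(
            f"structure {est.index[bad][0]}: double-positive count exceeds "
            "zero Ghsr+ count"
        )
    out = est.copy()
    out.insert(0, "region_id", structs["region_id"].reindex(est.index))
    out["pct_vs_a"] = _pct(est["est_ab"], est["est_a"])
    out["pct_vs_b"] = _pct(est["est_ab"], est["est_b"])
    if phenotypes is not None:
        out = out.join(phenotypes, how="left")
        pct_cols = [c for c in phenotypes.columns]
        # structures with no double-positives keep an empty composition
        out.loc[est["est_ab"] == 0, pct_cols] = np.nan
    out["density_per_mm3"] = est["est_ab"] / structs["volume_mm3"].reindex(est.index)
    out["selected"] = select_structures(out, min_cells, min_density)
    return out


def _pct(num: pd.Series, den: pd.Series) -> pd.Series:
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(den > 0, 100.0 * num / den, np.nan)
    return pd.Series(round_half_away(pct, 1), index=num.index)


def select_structures(
    table: pd.DataFrame,
    min_cells: int = DEFAULT_MIN_CELLS,
    min_density: float = DEFAULT_MIN_DENSITY,
) -> pd.Series:
    """Strict double-count and density cut-offs ("more than" on both)."""
    return (table["est_ab"] > min_cells) & (table["density_per_mm3"] > min_density)


def region_rollup(table: pd.DataFrame) -> pd.DataFrame:
    """Per-region [listed/total] double-positive sums.

    listed sums est_ab over selected structures; total over all structures in
    the region. Every structure must carry a region."""
    if table["region_id"].isna().any():
        bad = table.index[table["region_id"].isna()][0]
        raise ValueError(f"structure {bad} has no region assignment")
    listed = (
        table.loc[table["selected"]]
        .groupby("region_id")["est_ab"]
        .sum()
    )
    total = table.groupby("region_id")["est_ab"].sum()
    out = pd.DataFrame({"listed_double": listed, "total_double": total}).fillna(0)
    return out.astype({"listed_double": np.int64, "total_double": np.int64})


@dataclass(frozen=True)
class HeadlineShares:
    """Whole-dataset double-positive shares, one decimal."""

    pct_vs_a: float | None
    pct_vs_b: float | None


def headline_shares(n_a: int, n_b: int, n_ab: int) -> HeadlineShares:
    """Double-positive count as one-decimal percentages of each gene's total."""
    return HeadlineShares(
        pct_vs_a=float(round_half_away(100.0 * n_ab / n_a, 1)) if n_a else None,
        pct_vs_b=float(round_half_away(100.0 * n_ab / n_b, 1)) if n_b else None,
    )
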