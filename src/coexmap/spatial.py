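"""Label transfer onto structures, partial-volume correction, calibration.

Per-cluster positive fractions estimated in the deep dataset are apportioned
over each structure's cluster composition observed in the spatial dataset.
Each (cluster, structure) contribution is floored to its integer part before
summing; the per-structure sums are then divided by the covered-volume
fraction (partial-volume correction) and scaled to the whole brain by a
single proportionality factor fitted by least squares through the origin
against literature-reported reference populations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MARKER_COLS = ("est_a", "est_b", "est_ab")


@dataclass
class StructureComposition:
    """Per-structure cluster cell counts plus the structure table.

    ``counts`` is a structures x clusters integer frame (zero-count structures
    retained); ``structures`` is indexed by structure_id with region_id,
    volume_mm3 and covered_fraction.
    """

    counts: pd.DataFrame
    structures: pd.DataFrame

    @property
    def total_cells(self) -> pd.Series:
        return self.counts.sum(axis=1)


def structure_cluster_counts(
    spatial_cells: pd.DataFrame,
    structures: pd.DataFrame,
    taxonomy: pd.DataFrame | None = None,
) -> StructureComposition:
    """Exact cross-tabulation of spatial cells by (structure, cluster).

    Cells whose cluster is absent from ``taxonomy`` (when given) are excluded
    with a logged count. Structures with no cells keep a zero row.
    """
    cells = spatial_cells
    if taxonomy is not None:
        known = cells["cluster_id"].isin(taxonomy.index)
        n_bad = int((~known).sum())
        if n_bad:
            logger.warning(
                "excluding %d spatial cells with clusters absent from the taxonomy",
                n_bad,
            )
            cells = cells[known]
    tab = (
        cells.groupby(["structure_id", "cluster_id"], sort=True)
        .size()
        .unstack(fill_value=0)
    )
    tab = tab.reindex(index=structures.index, fill_value=0)
    return StructureComposition(counts=tab, structures=structures)


def apportion_contributions(
    composition: StructureComposition, stats: pd.DataFrame
) -> pd.DataFrame:
    """Floored per-(structure, cluster) positive-cell contributions.

    For structure s, cluster c and marker X: floor(n(c, s) * p_X(c)). Clusters
    present spatially but absent from the deep statistics contribute zero and
    are logged (no fraction is estimable for them).
    Returns a long frame: structure_id, cluster_id, n_cells, est_a/b/ab.
    """
    for col in ("p_a", "p_b", "p_ab"):
        if (stats[col] < 0).any() or (stats[col] > 1).any():
            raise ValueError(f"{col} must lie in [0, 1]")
    if (composition.counts.to_numpy() < 0).any():
        raise ValueError("cluster counts must be non-negative")

    clusters = composition.counts.columns
    unknown = [c for c in clusters if c not in stats.index]
    if unknown:
        logger.warning(
            "%d spatial clusters have no deep statistics and contribute zero: %s",
            len(unknown),
            unknown[:10],
        )
    p = stats.reindex(clusters)[["p_a", "p_b", "p_ab"]].fillna(0.0)
    long = (
        composition.counts.stack()
        .rename("n_cells")
        .reset_index()
        .rename(columns={"level_1": "cluster_id"})
    )
    long = long[long["n_cells"] > 0]
    rates = p.loc[long["cluster_id"]].to_numpy()
    n = long["n_cells"].to_numpy()[:, None]
    floored = np.floor(n * rates).astype(np.int64)
    long[["est_a", "est_b", "est_ab"]] = floored
    return long.reset_index(drop=True)


def apportion(
    composition: StructureComposition,
    stats: pd.DataFrame,
    floor_per_cluster: bool = True,
) -> pd.DataFrame:
    """Per-structure apportioned positive counts (integers, pre-calibration).

    Default floors each (cluster, structure) contribution before summing; with
    ``floor_per_cluster=False`` the exact contributions are summed per
    structure and floored once.
    """
    if floor_per_cluster:
        long = apportion_contributions(composition, stats)
        out = (
            long.groupby("structure_id")[list(MARKER_COLS)]
            .sum()
            .reindex(composition.counts.index, fill_value=0)
        )
    else:
        p = stats.reindex(composition.counts.columns)[["p_a", "p_b", "p_ab"]].fillna(0.0)
        exact = composition.counts.to_numpy() @ p.to_numpy()
        out = pd.DataFrame(
            np.floor(exact).astype(np.int64),
            index=composition.counts.index,
            columns=list(MARKER_COLS),
        )
    return out.astype(np.int64)


def partial_volume_correct(
    counts: pd.DataFrame, composition: StructureComposition
) -> pd.DataFrame:
    """Divide each structure's estimates by its covered-volume fraction."""
    frac = composition.structures["covered_fraction"].reindex(counts.index)
    if (frac <= 0).any() or frac.isna().any():
        bad = counts.index[(frac <= 0) | frac.isna()][0]
        raise ValueError(f"structure {bad}: covered_fraction must be in (0, 1]")
    return counts[list(MARKER_COLS)].div(frac, axis=0)


@dataclass(frozen=True)
class CalibrationModel:
    """Single proportionality factor mapping sample estimates to brain counts."""

    k: float
    references: pd.DataFrame

    def apply(self, corrected: pd.DataFrame) -> pd.DataFrame:
        return corrected * self.k


def calibrate(references: pd.DataFrame) -> CalibrationModel:
    """Least squares through the origin: literature ~ k * estimated.

    k = sum(lit_i * est_i) / sum(est_i^2), the closed-form minimizer of the
    residual sum of squares for a single proportionality factor.
    """
    est = references["estimated_count"].to_numpy(dtype=float)
    lit = references["literature_count"].to_numpy(dtype=float)
    if len(est) == 0:
        raise ValueError("at least one reference population is required")
    if (est < 0).any() or (lit < 0).any():
        raise ValueError("reference counts must be non-negative")
    denom = float(est @ est)
    if denom == 0.0:
        raise ValueError("all estimated reference counts are zero; cannot calibrate")
    k = float(lit @ est) / denom
    return CalibrationModel(k=k, references=references.copy())


def round_half_away(x, decimals: int = 0):
    """Round half away from zero (numpy rounds half to even)."""
    x = np.asarray(x, dtype=float)
    factor = 10.0 ** decimals
    return np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor


def whole_brain_estimate(
    corrected: pd.DataFrame, model: CalibrationModel
) -> pd.DataFrame:
    """Calibrated whole-brain counts: round-half-away(k * corrected) as ints."""
    scaled = model.apply(corrected[list(MARKER_COLS)])
    return pd.DataFrame(
        round_half_away(scaled.to_numpy()).astype(np.int64),
        index=scaled.index,
        columns=scaled.columns,
    ).clip(lower=0)
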