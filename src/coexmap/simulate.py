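"""Synthetic paired deep/spatial datasets with a shared cluster taxonomy.

The generator emulates the structure of a whole-brain cell-type atlas at desk
scale: a deep droplet-style scRNA-seq dataset carrying full counts for the two
genes of interest, and a spatially resolved dataset sharing the same cluster
taxonomy in which each cell carries an anatomical structure assignment instead
of counts. Structures have volumes and a covered-volume fraction standing in
for sections missing from the 10 um / 200 um sectioning scheme. Ground truth
(per-cluster positive rates, whole-brain per-structure counts, and the
sample-to-brain proportionality factor) is retained for recovery tests.

Only the two genes of interest are simulated, at the scale the positivity rule
operates on: a latent per-cell positivity indicator drawn from a 2x2 joint
with configured margins and odds multiplier, plus a count magnitude
conditional on positivity that is guaranteed to respect the active rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

from .positivity import PositivityRule, min_positive_count

logger = logging.getLogger(__name__)

NEUROTRANSMITTERS: tuple[str, ...] = (
    "GABA", "GABA-Glyc", "Glut-GABA", "Glut", "Chol", "Dopa",
)
NO_NEUROTRANSMITTER = "none"

# Classic hypothalamic calibration populations: marker, structure slot index,
# plausible literature-scale whole-brain cell count.
_DEFAULT_REFERENCES: tuple[tuple[str, int, float], ...] = (
    ("Agrp", 0, 10000.0),
    ("Pomc", 0, 9000.0),
    ("Npy", 0, 12000.0),
    ("Gfap", 0, 30000.0),
    ("Oxt", 1, 8000.0),
    ("Avp", 1, 9000.0),
    ("Crh", 1, 6000.0),
)

# rng substream tags, fixed so each generator op is deterministic on its own
_STREAM_TAXONOMY = 0
_STREAM_RATES = 1
_STREAM_DEEP = 2
_STREAM_SPATIAL = 3
_STREAM_REFS = 4


@dataclass(frozen=True)
class StructureSpec:
    """One anatomical structure of the synthetic brain."""

    structure_id: str
    region_id: str
    volume_mm3: float
    covered_fraction: float = 1.0
    # cluster_id -> mixture weight; non-negative, summing to 1
    mixture: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.volume_mm3 <= 0:
            raise ValueError(f"structure {self.structure_id}: volume must be > 0")
        if not (0 < self.covered_fraction <= 1):
            raise ValueError(
                f"structure {self.structure_id}: covered_fraction must be in (0, 1]"
            )
        if self.mixture:
            w = np.array(list(self.mixture.values()), dtype=float)
            if (w < 0).any() or not np.isclose(w.sum(), 1.0):
                raise ValueError(
                    f"structure {self.structure_id}: mixture weights must be "
                    "non-negative and sum to 1"
                )


@dataclass(frozen=True)
class ReferencePopulation:
    """A calibration population with a configured true whole-brain count."""

    name: str
    marker: str
    structure_id: str
    true_count: float


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the paired synthetic datasets.

    Defaults reproduce the desk-scale study: 50 clusters, ~10^4 deep cells,
    20 structures over five parent regions, a rare gene A (Ghsr-like) roughly
    100-fold less prevalent than the common gene B (Cnr1-like), mild
    co-expression enrichment, full section coverage and noise-free
    calibration references.
    """

    n_clusters: int = 50
    mean_cells_per_cluster: float = 200.0
    gene_a: str = "Ghsr"
    gene_b: str = "Cnr1"
    # explicit (n_clusters, 2) marginal positivity rates; drawn from the
    # prevalence model below when None
    gene_rates: np.ndarray | None = None
    odds_multiplier: float = 2.0
    # prevalence model for gene A: a minority of clusters express it
    frac_expressing_a: float = 0.15
    rate_a_range: tuple[float, float] = (0.01, 0.06)
    background_a_max: float = 0.002
    rate_b_range: tuple[float, float] = (0.2, 0.9)
    frac_neuron_clusters: float = 0.8
    library_size_meanlog: float = float(np.log(1e4))
    library_size_sdlog: float = 0.4
    positivity_rule: PositivityRule = field(default_factory=PositivityRule.log2cpm)
    # spatial side
    n_structures: int = 20
    region_ids: tuple[str, ...] = ("HY", "MB", "HPF", "MY", "CTXsp")
    structure_volume_range: tuple[float, float] = (0.2, 1.0)
    covered_fraction: float = 1.0
    clusters_per_structure: int = 10
    cells_per_mm3: float = 40000.0
    section_thickness_um: float = 10.0
    section_interval_um: float = 200.0
    structures: tuple[StructureSpec, ...] | None = None
    reference_populations: tuple[ReferencePopulation, ...] | None = None
    reference_noise_sigma: float = 0.0
    seed: int = 0

    @property
    def sampling_rate(self) -> float:
        """Fraction of a fully covered structure's cells seen by the sections."""
        return self.section_thickness_um / self.section_interval_um

    @property
    def k_true(self) -> float:
        """True sample-to-whole-brain proportionality factor."""
        return 1.0 / self.sampling_rate


@dataclass
class SyntheticTruth:
    """Ground truth retained by the generators for recovery tests.

    ``cluster_rates`` has the configured marginal/joint positivity rates per
    cluster; ``realized_fractions`` the fractions actually realized in the deep
    draw. ``structure_truth`` has, per structure, the expected fully covered
    spatial cell count and the true whole-brain positive counts. ``k_true`` is
    the proportionality factor between a fully covered spatial sample and the
    whole brain.
    """

    cluster_rates: pd.DataFrame | None = None
    realized_fractions: pd.DataFrame | None = None
    structure_truth: pd.DataFrame | None = None
    k_true: float | None = None

    def merged(self, other: "SyntheticTruth") -> "SyntheticTruth":
        return SyntheticTruth(
            cluster_rates=self.cluster_rates if self.cluster_rates is not None else other.cluster_rates,
            realized_fractions=self.realized_fractions if self.realized_fractions is not None else other.realized_fractions,
            structure_truth=self.structure_truth if self.structure_truth is not None else other.structure_truth,
            k_true=self.k_true if self.k_true is not None else other.k_true,
        )


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


def generate_taxonomy(config: SimulationConfig) -> pd.DataFrame:
    """Assign class and neurotransmitter labels to ``n_clusters`` clusters.

    Returns a frame indexed by ``cluster_id`` with ``class_label`` in
    {neuron, non-neuron} and ``neurotransmitter`` one of the six categories
    for neurons, ``none`` for non-neurons.
    """
    if config.n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    rng = _rng(config, _STREAM_TAXONOMY)
    n = config.n_clusters
    cluster_ids = [f"c{i:03d}" for i in range(n)]
    is_neuron = rng.random(n) < config.frac_neuron_clusters
    if not is_neuron.any():  # keep at least one neuron cluster
        is_neuron[0] = True
    # glutamatergic and GABAergic dominate, as in the atlas taxonomy
    nt_weights = np.array([0.30, 0.05, 0.05, 0.45, 0.05, 0.10])
    nts = rng.choice(NEUROTRANSMITTERS, size=n, p=nt_weights)
    taxonomy = pd.DataFrame(
        {
            "class_label": np.where(is_neuron, "neuron", "non-neuron"),
            "neurotransmitter": np.where(is_neuron, nts, NO_NEUROTRANSMITTER),
        },
        index=pd.Index(cluster_ids, name="cluster_id"),
    )
    return taxonomy


def joint_positive_probability(
    p_a: np.ndarray, p_b: np.ndarray, odds: float
) -> np.ndarray:
    """P(A+ and B+) for given margins and a 2x2 odds multiplier.

    ``odds = 1`` gives independence (p_ab = p_a * p_b); larger values enrich
    co-expression. Solves the Plackett quadratic and clips to the Frechet
    bounds.
    """
    p_a = np.asarray(p_a, dtype=float)
    p_b = np.asarray(p_b, dtype=float)
    if odds < 0:
        raise ValueError("odds multiplier must be >= 0")
    if odds == 1.0:
        p11 = p_a * p_b
    else:
        s = 1.0 + (p_a + p_b) * (odds - 1.0)
        disc = s * s - 4.0 * odds * (odds - 1.0) * p_a * p_b
        p11 = (s - np.sqrt(np.maximum(disc, 0.0))) / (2.0 * (odds - 1.0))
    lower = np.maximum(0.0, p_a + p_b - 1.0)
    upper = np.minimum(p_a, p_b)
    return np.clip(p11, lower, upper)


def cluster_rates(config: SimulationConfig) -> pd.DataFrame:
    """Per-cluster marginal and joint positivity rates (the ground truth).

    Gene A is expressed appreciably in a minority of clusters (background
    elsewhere); gene B is broadly expressed, which reproduces the ~100-fold
    prevalence imbalance between the two receptors.
    """
    if config.gene_rates is not None:
        rates = np.asarray(config.gene_rates, dtype=float)
        if rates.shape != (config.n_clusters, 2):
            raise ValueError("gene_rates must have shape (n_clusters, 2)")
        if (rates < 0).any() or (rates > 1).any():
            raise ValueError("gene rates must lie in [0, 1]")
        p_a, p_b = rates[:, 0], rates[:, 1]
    else:
        rng = _rng(config, _STREAM_RATES)
        n = config.n_clusters
        expressing = rng.random(n) < config.frac_expressing_a
        p_a = np.where(
            expressing,
            rng.uniform(*config.rate_a_range, size=n),
            rng.uniform(0.0, config.background_a_max, size=n),
        )
        p_b = rng.uniform(*config.rate_b_range, size=n)
    p_ab = joint_positive_probability(p_a, p_b, config.odds_multiplier)
    taxonomy = generate_taxonomy(config)
    return pd.DataFrame(
        {"p_a": p_a, "p_b": p_b, "p_ab": p_ab}, index=taxonomy.index
    )


def _counts_from_flags(
    positive: np.ndarray,
    library_size: np.ndarray,
    rule: PositivityRule,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw integer counts consistent with the positivity flags under ``rule``."""
    m = min_positive_count(rule, library_size)
    counts = np.zeros(positive.shape, dtype=np.int64)
    n_pos = int(positive.sum())
    if n_pos:
        counts[positive] = m[positive] + rng.poisson(2.0, size=n_pos)
    neg = ~positive
    # negatives sit anywhere strictly below the positive minimum
    headroom = m[neg] - 1
    if headroom.size:
        counts[neg] = rng.integers(0, headroom + 1)
    return np.minimum(counts, library_size)


def generate_deep_dataset(
    config: SimulationConfig, taxonomy: pd.DataFrame | None = None
) -> tuple[ad.AnnData, SyntheticTruth]:
    """Simulate the deep scRNA-seq dataset for the two genes of interest.

    Returns an AnnData (cells x 2 genes, sparse counts) whose obs carries
    cluster, class, neurotransmitter and library size, plus the ground truth
    (configured and realized per-cluster positive fractions).
    """
    if taxonomy is None:
        taxonomy = generate_taxonomy(config)
    rates = cluster_rates(config)
    rng = _rng(config, _STREAM_DEEP)

    n_cells_per_cluster = rng.poisson(
        config.mean_cells_per_cluster, size=config.n_clusters
    )
    n_cells_per_cluster = np.maximum(n_cells_per_cluster, 1)
    cluster_of_cell = np.repeat(np.arange(config.n_clusters), n_cells_per_cluster)
    n_total = cluster_of_cell.size

    p_a = rates["p_a"].to_numpy()[cluster_of_cell]
    p_b = rates["p_b"].to_numpy()[cluster_of_cell]
    p_ab = rates["p_ab"].to_numpy()[cluster_of_cell]

    u = rng.random(n_total)
    # draw jointly from the 2x2 table: (AB, A only, B only, neither)
    pos_a = np.empty(n_total, dtype=bool)
    pos_b = np.empty(n_total, dtype=bool)
    both = u < p_ab
    a_only = (~both) & (u < p_ab + (p_a - p_ab))
    b_only = (~both) & (~a_only) & (u < p_a + (p_b - p_ab))
    pos_a = both | a_only
    pos_b = both | b_only

    library_size = np.maximum(
        rng.lognormal(config.library_size_meanlog, config.library_size_sdlog, n_total)
        .round()
        .astype(np.int64),
        100,
    )
    rule = config.positivity_rule
    counts_a = _counts_from_flags(pos_a, library_size, rule, rng)
    counts_b = _counts_from_flags(pos_b, library_size, rule, rng)

    cluster_ids = taxonomy.index.to_numpy()[cluster_of_cell]
    obs = pd.DataFrame(
        {
            "cluster_id": cluster_ids,
            "class_label": taxonomy["class_label"].to_numpy()[cluster_of_cell],
            "neurotransmitter": taxonomy["neurotransmitter"].to_numpy()[cluster_of_cell],
            "library_size": library_size,
        },
        index=pd.Index([f"deep_{i:06d}" for i in range(n_total)], name="cell_id"),
    )
    X = sparse.csr_matrix(
        np.column_stack([counts_a, counts_b]).astype(np.int64)
    )
    adata = ad.AnnData(
        X=X, obs=obs, var=pd.DataFrame(index=pd.Index([config.gene_a, config.gene_b], name="gene_id"))
    )

    realized = (
        pd.DataFrame({"cluster_id": cluster_ids, "a": pos_a, "b": pos_b, "ab": pos_a & pos_b})
        .groupby("cluster_id", sort=True)
        .agg(n_cells=("a", "size"), p_a=("a", "mean"), p_b=("b", "mean"), p_ab=("ab", "mean"))
    )
    truth = SyntheticTruth(cluster_rates=rates, realized_fractions=realized)
    return adata, truth


def default_structures(
    config: SimulationConfig, taxonomy: pd.DataFrame
) -> tuple[StructureSpec, ...]:
    """Draw the default structure panel: volumes, regions, cluster mixtures."""
    rng = _rng(config, _STREAM_SPATIAL)
    structures = []
    cluster_ids = taxonomy.index.to_numpy()
    for i in range(config.n_structures):
        region = config.region_ids[i % len(config.region_ids)]
        volume = rng.uniform(*config.structure_volume_range)
        k = min(config.clusters_per_structure, len(cluster_ids))
        members = rng.choice(cluster_ids, size=k, replace=False)
        weights = rng.dirichlet(np.ones(k))
        structures.append(
            StructureSpec(
                structure_id=f"s{i:02d}",
                region_id=region,
                volume_mm3=float(volume),
                covered_fraction=config.covered_fraction,
                mixture={c: float(w) for c, w in zip(members, weights)},
            )
        )
    return tuple(structures)


def generate_spatial_dataset(
    config: SimulationConfig, taxonomy: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Simulate the spatially resolved dataset sharing the cluster taxonomy.

    Returns ``(cells, structures, truth)``: per-cell metadata
    (cell_id, cluster_id, structure_id), the structure table
    (structure_id, region_id, volume_mm3, covered_fraction), and ground truth
    with expected fully covered spatial counts and true whole-brain positive
    counts per structure.
    """
    if taxonomy is None:
        taxonomy = generate_taxonomy(config)
    structures = config.structures
    if structures is None:
        structures = default_structures(config, taxonomy)
    if len(structures) == 0:
        raise ValueError("structure list is empty")
    rates = cluster_rates(config)
    rng = _rng(config, _STREAM_SPATIAL + 10)

    cell_rows = []
    truth_rows = []
    for spec in structures:
        whole_brain_n = config.cells_per_mm3 * spec.volume_mm3
        full_sample_n = whole_brain_n * config.sampling_rate
        observed_n = int(rng.poisson(full_sample_n * spec.covered_fraction))
        members = list(spec.mixture.keys())
        weights = np.array([spec.mixture[c] for c in members])
        if observed_n:
            draws = rng.choice(len(members), size=observed_n, p=weights)
            for j, d in enumerate(draws):
                cell_rows.append((spec.structure_id, members[d]))
        # true whole-brain positives under the configured per-cluster rates
        p = rates.reindex(members).fillna(0.0)
        truth_rows.append(
            {
                "structure_id": spec.structure_id,
                "region_id": spec.region_id,
                "expected_full_sample_cells": full_sample_n,
                "true_brain_a": whole_brain_n * float(weights @ p["p_a"].to_numpy()),
                "true_brain_b": whole_brain_n * float(weights @ p["p_b"].to_numpy()),
                "true_brain_ab": whole_brain_n * float(weights @ p["p_ab"].to_numpy()),
            }
        )

    cells = pd.DataFrame(cell_rows, columns=["structure_id", "cluster_id"])
    cells.insert(0, "cell_id", [f"sp_{i:06d}" for i in range(len(cells))])
    structure_table = pd.DataFrame(
        {
            "structure_id": [s.structure_id for s in structures],
            "region_id": [s.region_id for s in structures],
            "volume_mm3": [s.volume_mm3 for s in structures],
            "covered_fraction": [s.covered_fraction for s in structures],
        }
    ).set_index("structure_id")
    truth = SyntheticTruth(
        cluster_rates=rates,
        structure_truth=pd.DataFrame(truth_rows).set_index("structure_id"),
        k_true=config.k_true,
    )
    return cells, structure_table, truth


def generate_reference_populations(
    config: SimulationConfig, truth: SyntheticTruth | None = None
) -> pd.DataFrame:
    """Build the calibration table of reference populations.

    Each population carries an ``estimated_count`` on the spatial-sample scale
    (its true whole-brain count divided by the true proportionality factor,
    i.e. what a fully covered, noise-free spatial estimate would be) and a
    ``literature_count`` equal to the true count times multiplicative
    lognormal noise (sigma 0 reproduces the true count exactly).
    """
    refs = config.reference_populations
    taxonomy = generate_taxonomy(config)
    structures = config.structures
    if structures is None:
        structures = default_structures(config, taxonomy)
    structure_ids = [s.structure_id for s in structures]
    if refs is None:
        refs = tuple(
            ReferencePopulation(
                name=f"{marker}+",
                marker=marker,
                structure_id=structure_ids[slot % len(structure_ids)],
                true_count=count,
            )
            for marker, slot, count in _DEFAULT_REFERENCES
        )
    known = set(structure_ids)
    for r in refs:
        if r.structure_id not in known:
            raise ValueError(
                f"reference population {r.name}: structure {r.structure_id} "
                "is not in the structure list"
            )
    rng = _rng(config, _STREAM_REFS)
    noise = (
        rng.lognormal(0.0, config.reference_noise_sigma, size=len(refs))
        if config.reference_noise_sigma > 0
        else np.ones(len(refs))
    )
    return pd.DataFrame(
        {
            "population": [r.name for r in refs],
            "marker": [r.marker for r in refs],
            "structure_id": [r.structure_id for r in refs],
            "true_count": [r.true_count for r in refs],
            "estimated_count": [r.true_count / config.k_true for r in refs],
            "literature_count": [r.true_count * f for r, f in zip(refs, noise)],
        }
    )


@dataclass
class SimulatedStudy:
    """Everything one simulation run produces, plus merged ground truth."""

    config: SimulationConfig
    taxonomy: pd.DataFrame
    deep: ad.AnnData
    spatial_cells: pd.DataFrame
    structures: pd.DataFrame
    references: pd.DataFrame
    truth: SyntheticTruth


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Run all generators under one config/seed and merge the truth."""
    taxonomy = generate_taxonomy(config)
    deep, deep_truth = generate_deep_dataset(config, taxonomy)
    spatial_cells, structures, spatial_truth = generate_spatial_dataset(config, taxonomy)
    references = generate_reference_populations(config, spatial_truth)
    return SimulatedStudy(
        config=config,
        taxonomy=taxonomy,
        deep=deep,
        spatial_cells=spatial_cells,
        structures=structures,
        references=references,
        truth=deep_truth.merged(spatial_truth),
    )
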