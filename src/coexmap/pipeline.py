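"""End-to-end synthetic pipeline: simulate -> call -> transfer -> summarize."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import report
from .cluster_stats import DatasetSummary, cluster_fractions, dataset_level_summary
from .positivity import call_positivity
from .simulate import SimulatedStudy, SimulationConfig, simulate_study
from .spatial import (
    CalibrationModel,
    StructureComposition,
    apportion,
    apportion_contributions,
    calibrate,
    partial_volume_correct,
    structure_cluster_counts,
    whole_brain_estimate,
)


@dataclass
class PipelineResult:
    study: SimulatedStudy
    calls: pd.DataFrame
    stats: pd.DataFrame
    summary_counts: DatasetSummary
    composition: StructureComposition
    apportioned: pd.DataFrame
    corrected: pd.DataFrame
    model: CalibrationModel
    calibrated: pd.DataFrame
    summary: pd.DataFrame
    rollup: pd.DataFrame


def run_pipeline(
    config: SimulationConfig | None = None,
    min_cells: int = report.DEFAULT_MIN_CELLS,
    min_density: float = report.DEFAULT_MIN_DENSITY,
) -> PipelineResult:
    """Run the whole analysis on one simulated study."""
    if config is None:
        config = SimulationConfig()
    study = simulate_study(config)
    calls = call_positivity(
        study.deep, config.positivity_rule, config.gene_a, config.gene_b
    )
    stats = cluster_fractions(calls, study.deep)
    totals = dataset_level_summary(calls, study.deep)
    composition = structure_cluster_counts(
        study.spatial_cells, study.structures, study.taxonomy
    )
    apportioned = apportion(composition, stats)
    contributions = apportion_contributions(composition, stats)
    corrected = partial_volume_correct(apportioned, composition)
    model = calibrate(study.references)
    calibrated = whole_brain_estimate(corrected, model)
    phenotypes = report.structure_phenotypes(contributions, study.taxonomy)
    summary = report.build_summary(
        calibrated, composition, phenotypes, min_cells=min_cells, min_density=min_density
    )
    rollup = report.region_rollup(summary)
    return PipelineResult(
        study=study,
        calls=calls,
        stats=stats,
        summary_counts=totals,
        composition=composition,
        apportioned=apportioned,
        corrected=corrected,
        model=model,
        calibrated=calibrated,
        summary=summary,
        rollup=rollup,
    )
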