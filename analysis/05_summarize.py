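"""Build the per-structure summary table and per-region roll-ups."""

import argparse
from pathlib import Path

from coexmap import (
    apportion_contributions,
    build_summary,
    region_rollup,
    structure_cluster_counts,
    structure_phenotypes,
)
from coexmap.io import read_table, write_table

parser = argparse.ArgumentParser()
parser.add_argument("--dir", type=Path, default=Path("results/simulation"))
parser.add_argument("--min-cells", type=int, default=350)
parser.add_argument("--min-density", type=float, default=50.0)
args = parser.parse_args()

cells = read_table(args.dir / "spatial_cells.tsv")
structures = read_table(args.dir / "structures.tsv", index_col="structure_id")
taxonomy = read_table(args.dir / "taxonomy.tsv", index_col="cluster_id")
stats = read_table(args.dir / "cluster_stats.tsv", index_col="cluster_id")
estimates = read_table(args.dir / "estimates.tsv", index_col="structure_id")

composition = structure_cluster_counts(cells, structures, taxonomy)
contributions = apportion_contributions(composition, stats)
phenotypes = structure_phenotypes(contributions, taxonomy)
summary = build_summary(estimates, composition, phenotypes,
                        min_cells=args.min_cells, min_density=args.min_density)
rollup = region_rollup(summary)
write_table(summary, args.dir / "summary.tsv")
write_table(rollup, args.dir / "region_rollup.tsv")

n_sel = int(summary["selected"].sum())
print(f"{n_sel} of {len(summary)} structures pass the selection filter "
      f"(> {args.min_cells} double+ cells and > {args.min_density}/mm^3)")
print(rollup)
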