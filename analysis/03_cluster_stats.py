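"""Per-cluster positive fractions — the statistic transferred across datasets."""

import argparse
from pathlib import Path

from coexmap import cluster_fractions
from coexmap.io import read_expression, read_table, write_table

parser = argparse.ArgumentParser()
parser.add_argument("--dir", type=Path, default=Path("results/simulation"))
args = parser.parse_args()

adata = read_expression(args.dir / "deep")
calls = read_table(args.dir / "calls.tsv", index_col="cell_id")
stats = cluster_fractions(calls, adata)
write_table(stats, args.dir / "cluster_stats.tsv")

expressing = stats[stats["p_ab"] > 0]
print(f"{len(stats)} clusters; {len(expressing)} carry double-positive cells")
print("top clusters by double-positive fraction:")
print(expressing.sort_values("p_ab", ascending=False).head(5)
      [["n_cells", "p_a", "p_b", "p_ab", "neurotransmitter"]])
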