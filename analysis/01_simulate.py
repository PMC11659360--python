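"""Simulate the paired deep/spatial study and write it under results/.

Generates the default desk-scale study: 50 clusters, ~10^4 deep cells with
counts for Ghsr and Cnr1, ~2x10^4 spatial cells over 20 structures sharing
the cluster taxonomy, and 7 noise-free calibration reference populations.
"""

import argparse
from pathlib import Path

from coexmap import SimulationConfig, simulate_study
from coexmap.io import write_study

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--out", type=Path, default=Path("results/simulation"))
args = parser.parse_args()

study = simulate_study(SimulationConfig(seed=args.seed))
write_study(study, args.out)

print(f"deep dataset: {study.deep.n_obs} cells x {study.deep.n_vars} genes")
print(f"spatial dataset: {len(study.spatial_cells)} cells, "
      f"{len(study.structures)} structures")
print(f"references: {len(study.references)} populations "
      f"(true proportionality factor {study.config.k_true:g})")
print(f"written to {args.out}/")
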