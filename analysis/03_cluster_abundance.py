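#!/usr/bin/env python
"""Partition each species-week abundance surface into regional clusters.

Runs CLARA (k = 3) independently on every species-week of the study cube
and reports medoid locations and per-cluster abundance shares — the
stratification used by the clustered prioritization scenarios.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from fullcycle.workflows import study_inputs

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

grid, cube, clusters, _ = study_inputs(args.seed)

rows = []
for (species, week), asg in clusters.items():
    for j in range(asg.k):
        rows.append(
            {
                "species_id": species,
                "week": week,
                "cluster": j + 1,
                "medoid_cell": int(asg.medoid_cell_ids[j]),
                "n_cells": int((asg.labels == j + 1).sum()),
                "abundance_share": asg.abundance_share[j],
            }
        )
table = pd.DataFrame(rows)
table.to_csv(args.out / "cluster_assignments.csv", index=False)

shares = table["abundance_share"]
print(f"{len(clusters)} species-week surfaces clustered into k=3 regions each")
print(
    "abundance share per cluster: "
    f"mean {shares.mean():.3f}, min {shares.min():.3f}, max {shares.max():.3f} "
    "(equal shares would be 0.333)"
)
print(
    "geography dominates the partition (abundance weighted 1/3), so shares "
    "track regional population sizes rather than being forced equal"
)
print(f"tables written to {args.out}/")
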