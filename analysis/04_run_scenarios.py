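#!/usr/bin/env python
"""Solve the eight planning scenarios and compare their area demands.

Crosses weekly/yearly optimization, single/clustered population targets
and uniform/footprint costs on the study landscape; writes per-scenario
areas, objectives and attainment plus the scenario-agreement histogram.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from fullcycle.workflows import scenario_suite

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

suite = scenario_suite(args.seed)

rows = []
for name, res in suite["results"].items():
    rows.append(
        {
            "scenario": name,
            "summed_area_km2": res.summed_area_km2,
            "union_area_km2": res.union_area_km2,
            "objective": res.objective,
            "status": res.status,
            "n_features": sum(len(rep.feature_names) for rep in res.attainments),
            "max_shortfall": max(float(rep.shortfall.max()) for rep in res.attainments),
        }
    )
table = pd.DataFrame(rows)
table.to_csv(args.out / "scenario_areas.csv", index=False)

agreement = suite["agreement"]
hist = pd.DataFrame(
    {"n_scenarios_agreeing": np.arange(9), "n_cells": np.bincount(agreement, minlength=9)}
)
hist.to_csv(args.out / "scenario_agreement_histogram.csv", index=False)
np.savetxt(args.out / "agreement_map.csv", agreement.reshape(suite["grid"].n_rows, -1), fmt="%d", delimiter=",")

print(table.to_string(index=False))
print(
    f"\nyearly planning needs {suite['mean_yearly_vs_weekly_reduction_pct']:.1f}% less summed "
    "area than weekly planning (mean over the four scenario pairs)"
)
print(
    f"stratifying targets over abundance clusters costs "
    f"{suite['clustered_vs_single_increase_pct']:.1f}% more area (shared-use, yearly)"
)
print(f"every feature target met: max shortfall {suite['max_shortfall']:.2e}")
print(f"cells selected by all 8 scenarios: {int((agreement == 8).sum())}")
print(f"tables written to {args.out}/")
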