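"""The eight planning scenarios and their map/area products.

Scenarios are the cross of three binary axes:

* approach — ``weekly`` (one optimization per week, the 52 solutions
  summed into a 0–52 selection-frequency map) vs. ``yearly`` (every
  species-week is a feature of a single optimization; binary map);
* population — ``single`` (one range-wide target per feature) vs.
  ``clustered`` (targets stratified over k regional abundance clusters);
* cost — ``shared_use`` (uniform cost 1) vs. ``intact_habitat``
  (human-footprint-style cost).

Each scenario reports its selection map, the summed area (weekly: sum of
per-week solution areas; yearly: the solution area), the union area, and
a per-solve feature-attainment report.  An agreement map counts, per
cell, how many of the eight scenarios selected it.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from fullcycle.abundance_clustering import ClusterAssignment
from fullcycle.prioritization_core import (
    AttainmentReport,
    build_features,
    build_problem,
    solve_exact,
    verify_solution,
)
from fullcycle.synthetic_landscape import AbundanceCube, CostSurface, PlanningGrid

logger = logging.getLogger(__name__)

__all__ = [
    "ScenarioConfig",
    "ScenarioResult",
    "all_scenarios",
    "run_scenario",
    "agreement_map",
    "compare_area",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """One of the eight scenario combinations."""

    approach: str  # weekly | yearly
    population: str  # single | clustered
    cost_mode: str  # shared_use | intact_habitat
    target_proportion: float = 0.30
    k: int = 5

    def __post_init__(self):
        if self.approach not in ("weekly", "yearly"):
            raise ValueError(f"unknown approach {self.approach!r}")
        if self.population not in ("single", "clustered"):
            raise ValueError(f"unknown population mode {self.population!r}")
        if self.cost_mode not in ("shared_use", "intact_habitat"):
            raise ValueError(f"unknown cost mode {self.cost_mode!r}")

    @property
    def name(self) -> str:
        return f"{self.approach}_{self.population}_{self.cost_mode}"


def all_scenarios(target_proportion: float = 0.30, k: int = 5) -> list[ScenarioConfig]:
    """The eight configurations from the three binary axes."""
    return [
        ScenarioConfig(approach=a, population=p, cost_mode=c, target_proportion=target_proportion, k=k)
        for a, p, c in itertools.product(
            ("weekly", "yearly"), ("single", "clustered"), ("shared_use", "intact_habitat")
        )
    ]


@dataclass
class ScenarioResult:
    """Solution maps, areas and attainment of one scenario."""

    config: ScenarioConfig
    selection_map: np.ndarray  # 0/1 yearly; 0..n_weeks counts weekly
    summed_area_km2: float
    union_area_km2: float
    objective: float
    status: str
    attainments: list[AttainmentReport] = field(default_factory=list)

    def binary_map(self, min_weeks: int = 1) -> np.ndarray:
        """Selected-anywhere map; weekly scenarios binarize at
        ``selected in >= min_weeks`` weeks."""
        if self.config.approach == "yearly":
            return (self.selection_map > 0).astype(int)
        return (self.selection_map >= min_weeks).astype(int)


def run_scenario(
    config: ScenarioConfig,
    cube: AbundanceCube,
    grid: PlanningGrid,
    costs: Mapping[str, CostSurface],
    clusters: Mapping[tuple[str, int], ClusterAssignment] | None = None,
    weeks: Sequence[int] | None = None,
    gap_tolerance: float = 0.0,
    time_limit: float | None = None,
) -> ScenarioResult:
    """Build and solve the scenario's optimization problem(s).

    ``costs`` maps cost modes to surfaces (``shared_use`` must be uniform).
    ``weeks`` restricts the annual cycle (default: all weeks in the cube).
    Weekly scenarios solve one independent problem per week and stack the
    solutions into a selection-frequency map.
    """
    week_list = [int(w) for w in (weeks if weeks is not None else cube.weeks)]
    cost = costs[config.cost_mode]
    cluster_arg = None
    if config.population == "clustered":
        if clusters is None:
            raise ValueError("clustered scenario requires cluster assignments")
        cluster_arg = clusters

    cell_area = grid.cell_area_km2
    if config.approach == "weekly":
        counts = np.zeros(grid.n_cells, dtype=int)
        summed_area = 0.0
        objective = 0.0
        attainments = []
        for w in week_list:
            feats = build_features(
                cube, "weekly", config.target_proportion, week=w, clusters=cluster_arg
            )
            problem = build_problem(feats, cost, n_units=grid.n_cells)
            sol = solve_exact(problem, gap_tolerance=gap_tolerance, time_limit=time_limit)
            if sol.x is None:
                raise RuntimeError(f"scenario {config.name}: week {w} infeasible")
            counts += sol.x
            summed_area += float(sol.x.sum()) * cell_area
            objective += sol.objective
            attainments.append(verify_solution(problem, sol))
        union_area = float((counts > 0).sum()) * cell_area
        status = "optimal" if all(a.ok for a in attainments) else "feasible_gap"
        return ScenarioResult(
            config=config,
            selection_map=counts,
            summed_area_km2=summed_area,
            union_area_km2=union_area,
            objective=objective,
            status=status,
            attainments=attainments,
        )

    feats = build_features(cube, "yearly", config.target_proportion, weeks=week_list, clusters=cluster_arg)
    problem = build_problem(feats, cost, n_units=grid.n_cells)
    sol = solve_exact(problem, gap_tolerance=gap_tolerance, time_limit=time_limit)
    if sol.x is None:
        raise RuntimeError(f"scenario {config.name}: yearly problem infeasible")
    area = float(sol.x.sum()) * cell_area
    report = verify_solution(problem, sol)
    return ScenarioResult(
        config=config,
        selection_map=sol.x.astype(int),
        summed_area_km2=area,
        union_area_km2=area,
        objective=sol.objective,
        status=sol.status,
        attainments=[report],
    )


def agreement_map(results: Sequence[ScenarioResult], min_weeks: int = 1) -> np.ndarray:
    """Per-cell count (0–8) of scenarios whose solution includes the cell.

    Weekly scenarios are binarized as selected-in-``>= min_weeks`` weeks.
    """
    if len(results) != 8:
        raise ValueError(f"expected exactly 8 scenario results, got {len(results)}")
    shapes = {r.selection_map.shape for r in results}
    if len(shapes) != 1:
        raise ValueError("scenario results are on different grids")
    return np.sum([r.binary_map(min_weeks) for r in results], axis=0)


def compare_area(result_a: ScenarioResult, result_b: ScenarioResult, metric: str = "summed") -> float:
    """Percent area difference, 100 × (area_b − area_a) / area_b.

    With ``result_a`` the smaller-area scenario this reads as "a requires
    X% less area than b".  ``metric`` selects summed or union areas.
    """
    if result_a.selection_map.shape != result_b.selection_map.shape:
        raise ValueError("results are on different grids")
    if metric == "summed":
        a, b = result_a.summed_area_km2, result_b.summed_area_km2
    elif metric == "union":
        a, b = result_a.union_area_km2, result_b.union_area_km2
    else:
        raise ValueError(f"unknown metric {metric!r}")
    if b == 0:
        raise ValueError("zero reference area")
    return 100.0 * (b - a) / b
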