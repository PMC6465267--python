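"""Minimum-set-cover reserve selection: minimize c·x subject to Ax ≥ b.

The decision variable x_j ∈ {0, 1} says whether planning unit j is
selected; c_j is its cost (1 under shared-use, mean human-footprint under
intact-habitat); A_ij = r_ij is the representation level (relative
abundance) of conservation feature i in unit j; and b_i is the feature's
target — a fixed proportion (default 30%) of its total abundance.
Features are species (one weekly problem), species-weeks (the yearly
problem), or species-(cluster)-weeks when regional abundance clusters
stratify the targets.

``solve_exact`` solves the integer program with the HiGHS branch-and-cut
solver; ``solve_bruteforce`` is an exhaustive oracle for instances of at
most 20 units, used to validate the exact solver on small problems.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from fullcycle.abundance_clustering import ClusterAssignment
from fullcycle.synthetic_landscape import AbundanceCube, CostSurface

logger = logging.getLogger(__name__)

__all__ = [
    "Feature",
    "ProblemInstance",
    "Solution",
    "AttainmentReport",
    "build_features",
    "build_problem",
    "solve_exact",
    "solve_bruteforce",
    "verify_solution",
]

BRUTEFORCE_MAX_UNITS = 20


@dataclass(frozen=True)
class Feature:
    """One conservation feature and its representation across units."""

    species_id: str
    week: int | None
    cluster: int | None
    cells: np.ndarray
    amounts: np.ndarray
    total_abundance: float
    target_level: float

    @property
    def name(self) -> str:
        parts = [self.species_id]
        if self.week is not None:
            parts.append(f"w{self.week:02d}")
        if self.cluster is not None:
            parts.append(f"c{self.cluster}")
        return "_".join(parts)


@dataclass
class ProblemInstance:
    """Sparse minimum-set-cover instance (c, A, b with sense ≥)."""

    costs: np.ndarray
    A: sparse.csr_matrix
    targets: np.ndarray
    features: list[Feature]

    @property
    def n_units(self) -> int:
        return len(self.costs)

    @property
    def n_features(self) -> int:
        return len(self.targets)


@dataclass
class Solution:
    """Binary selection with its objective and solver status."""

    x: np.ndarray | None
    objective: float
    status: str  # optimal | feasible_gap | infeasible
    gap: float = 0.0

    @property
    def selected(self) -> np.ndarray:
        if self.x is None:
            raise ValueError(f"no selection available (status={self.status})")
        return np.nonzero(self.x > 0.5)[0]


@dataclass
class AttainmentReport:
    """Independent check of a solution against every feature target."""

    attained: np.ndarray
    shortfall: np.ndarray
    objective: float
    ok: bool
    feature_names: list[str]


def build_features(
    cube: AbundanceCube,
    approach: str,
    target_proportion: float = 0.30,
    week: int | None = None,
    weeks: Sequence[int] | None = None,
    clusters: Mapping[tuple[str, int], ClusterAssignment] | None = None,
) -> list[Feature]:
    """Assemble conservation features from an abundance cube.

    ``approach='weekly'`` with ``week=w``: one feature per species (or per
    species-cluster) for that week.  ``approach='yearly'``: one feature
    per species-week (or species-cluster-week) over ``weeks`` (default:
    all weeks in the cube).  Feature totals are over rendered (non-missing)
    estimates; zero-total features are dropped with a log line.
    """
    if cube.values.size == 0:
        raise ValueError("empty abundance cube")
    if approach == "weekly":
        if week is None:
            raise ValueError("weekly approach requires a week")
        week_list = [week]
    elif approach == "yearly":
        week_list = list(weeks) if weeks is not None else [int(w) for w in cube.weeks]
    else:
        raise ValueError(f"unknown approach {approach!r}")

    vals = cube.filled()
    features: list[Feature] = []
    for s_idx, sp in enumerate(cube.species):
        for w in week_list:
            surf = vals[s_idx, cube.week_index(w)]
            if clusters is None:
                groups = [(None, np.nonzero(surf > 0)[0])]
            else:
                asg = clusters[(sp, int(w))]
                groups = [
                    (int(c), asg.cell_id[asg.labels == c]) for c in range(1, asg.k + 1)
                ]
            for cluster_label, cells in groups:
                amounts = surf[cells]
                total = float(amounts.sum())
                if total <= 0:
                    logger.info("dropping zero-abundance feature %s week %s cluster %s", sp, w, cluster_label)
                    continue
                features.append(
                    Feature(
                        species_id=sp,
                        week=int(w),
                        cluster=cluster_label,
                        cells=np.asarray(cells, dtype=int),
                        amounts=np.asarray(amounts, dtype=float),
                        total_abundance=total,
                        target_level=target_proportion * total,
                    )
                )
    return features


def build_problem(
    features: Sequence[Feature],
    cost: CostSurface | np.ndarray,
    n_units: int | None = None,
    zero_cost_floor: float = 1e-6,
) -> ProblemInstance:
    """Assemble the sparse c/A/b instance from features and a cost surface.

    Costs are floored at ``zero_cost_floor`` so zero-cost units cannot
    bloat solutions invisibly.  Any feature whose attainable maximum falls
    short of its target makes the build fail, naming the feature.
    """
    if not features:
        raise ValueError("no features")
    c = np.asarray(cost.cost if isinstance(cost, CostSurface) else cost, dtype=float)
    if n_units is None:
        n_units = len(c)
    if len(c) != n_units:
        raise ValueError("cost vector length != number of units")
    c = np.maximum(c, zero_cost_floor)

    bad = [f.name for f in features if f.amounts.sum() < f.target_level - 1e-9]
    if bad:
        raise ValueError(f"infeasible at build time: targets exceed attainable representation for {bad}")

    rows, cols, data = [], [], []
    for i, f in enumerate(features):
        rows.extend([i] * len(f.cells))
        cols.extend(f.cells.tolist())
        data.extend(f.amounts.tolist())
    A = sparse.csr_matrix((data, (rows, cols)), shape=(len(features), n_units))
    b = np.array([f.target_level for f in features])
    return ProblemInstance(costs=c, A=A, targets=b, features=list(features))


def solve_exact(problem: ProblemInstance, gap_tolerance: float = 0.0, time_limit: float | None = None) -> Solution:
    """Solve the integer program exactly with HiGHS branch-and-cut.

    ``gap_tolerance`` is the relative MIP gap (0 proves optimality).
    """
    n = problem.n_units
    # row-scale constraints to A_ij / b_i >= 1: mathematically identical,
    # much better conditioned when representation levels span wide ranges
    b = problem.targets
    scale = np.where(b > 0, b, 1.0)
    A_scaled = sparse.diags(1.0 / scale) @ problem.A
    constraints = LinearConstraint(A_scaled, lb=np.where(b > 0, 1.0, 0.0), ub=np.inf)
    options: dict = {"mip_rel_gap": gap_tolerance}
    if time_limit is not None:
        options["time_limit"] = time_limit
    res = milp(
        c=problem.costs,
        constraints=constraints,
        integrality=np.ones(n),
        bounds=Bounds(0, 1),
        options=options,
    )
    if res.status == 2:  # proven infeasible
        return Solution(x=None, objective=np.inf, status="infeasible")
    if res.x is None:  # hit a limit before finding any incumbent
        raise RuntimeError(f"solver stopped without a feasible incumbent (status {res.status}: {res.message})")
    x = np.round(res.x).astype(int)
    objective = float(problem.costs @ x)
    gap = float(res.mip_gap) if res.mip_gap is not None else 0.0
    status = "optimal" if res.status == 0 and gap <= max(gap_tolerance, 1e-9) else "feasible_gap"
    return Solution(x=x, objective=objective, status=status, gap=gap)


def solve_bruteforce(problem: ProblemInstance) -> Solution:
    """Exhaustive oracle: enumerate all unit subsets (n ≤ 20).

    Returns the minimum-cost feasible subset; ties are broken by the
    lexicographically smallest sorted selection.
    """
    n = problem.n_units
    if n > BRUTEFORCE_MAX_UNITS:
        raise ValueError(f"brute force limited to {BRUTEFORCE_MAX_UNITS} units, got {n}")
    A = problem.A.toarray()
    b = problem.targets
    c = problem.costs
    masks = np.arange(2**n, dtype=np.uint32)
    bits = ((masks[:, None] >> np.arange(n)) & 1).astype(float)
    feasible = np.all(bits @ A.T >= b - 1e-9, axis=1)
    if not feasible.any():
        return Solution(x=None, objective=np.inf, status="infeasible")
    costs = bits @ c
    costs[~feasible] = np.inf
    best_cost = costs.min()
    candidates = np.nonzero(costs <= best_cost + 1e-12)[0]
    best = min(candidates, key=lambda m: tuple(np.nonzero(bits[m])[0]))
    x = bits[best].astype(int)
    return Solution(x=x, objective=float(c @ x), status="optimal")


def verify_solution(problem: ProblemInstance, solution: Solution, tol: float = 1e-6) -> AttainmentReport:
    """Re-derive attainment and objective independently of the solver."""
    if solution.x is None:
        attained = np.zeros(problem.n_features)
    else:
        x = np.asarray(solution.x, dtype=float)
        if x.shape != (problem.n_units,):
            raise ValueError("solution/problem dimension mismatch")
        attained = problem.A @ x
    shortfall = np.maximum(0.0, problem.targets - attained)
    objective = float(problem.costs @ solution.x) if solution.x is not None else np.inf
    return AttainmentReport(
        attained=np.asarray(attained),
        shortfall=shortfall,
        objective=objective,
        ok=bool((shortfall <= tol * np.maximum(1.0, problem.targets)).all()),
        feature_names=[f.name for f in problem.features],
    )
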