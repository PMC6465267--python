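"""Regional clustering of weekly abundance surfaces (k-medoids / CLARA).

Each species-week surface is partitioned into k regional clusters so that
downstream prioritization can stratify its representation target across a
species' range.  Points are occupied planning cells described by
(lat, lon, abundance); each coordinate is min-max scaled to [0, 1], the
abundance axis is down-weighted (default 1/3) so geography dominates the
partition, and dissimilarity is Euclidean distance in the scaled space.

PAM (partitioning around medoids) is implemented directly — BUILD
initialization followed by steepest-descent SWAP — and CLARA extends it to
larger point sets by running PAM on random subsamples, assigning all
points to the nearest candidate medoids, and keeping the medoid set with
the smallest total dissimilarity.  Clusters are re-drawn independently in
each week; no cross-week cluster identity is implied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform

from fullcycle.synthetic_landscape import AbundanceCube, PlanningGrid

logger = logging.getLogger(__name__)

__all__ = [
    "ClusteringConfig",
    "ClusterPoints",
    "ClusterAssignment",
    "scale_points",
    "build_dissimilarity",
    "pam",
    "clara",
    "cluster_weekly",
    "points_from_surface",
]


@dataclass(frozen=True)
class ClusteringConfig:
    """k, abundance weight and CLARA sampling parameters.

    Defaults: 5 clusters, abundance down-weighted to 1/3 of the geographic
    axes, 5 subsamples of size min(n, 40 + 2k) — the classical CLARA
    sampling rule.
    """

    k: int = 5
    abundance_weight: float = 1.0 / 3.0
    n_samples: int = 5
    sample_size: int | None = None  # default min(n, 40 + 2k)
    seed: int = 0
    rebalance: bool = False

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.abundance_weight < 0:
            raise ValueError("abundance_weight must be >= 0")

    def effective_sample_size(self, n: int) -> int:
        size = self.sample_size if self.sample_size is not None else 40 + 2 * self.k
        return min(n, size)


@dataclass(frozen=True)
class ClusterPoints:
    """Occupied cells of one species-week surface."""

    cell_id: np.ndarray
    lat: np.ndarray
    lon: np.ndarray
    abundance: np.ndarray

    def __post_init__(self):
        for name in ("cell_id", "lat", "lon", "abundance"):
            object.__setattr__(self, name, np.asarray(getattr(self, name)))
        if not (len(self.cell_id) == len(self.lat) == len(self.lon) == len(self.abundance)):
            raise ValueError("point arrays must align")
        if (self.abundance <= 0).any():
            raise ValueError("only occupied cells (abundance > 0) are clustered")

    def __len__(self) -> int:
        return len(self.cell_id)


@dataclass
class ClusterAssignment:
    """Partition of one species-week's occupied cells into clusters 1..k."""

    cell_id: np.ndarray
    labels: np.ndarray  # 1..k per point
    medoid_cell_ids: np.ndarray
    total_dissimilarity: float
    abundance_share: np.ndarray  # fraction of the week's abundance per cluster

    @property
    def k(self) -> int:
        return len(self.medoid_cell_ids)


def scale_points(points: ClusterPoints, abundance_weight: float) -> np.ndarray:
    """Min-max scale (lat, lon, abundance) to [0, 1] and weight abundance.

    A degenerate axis (all values equal) contributes zero, not an error.
    """
    X = np.column_stack([points.lat, points.lon, points.abundance]).astype(float)
    lo, hi = X.min(axis=0), X.max(axis=0)
    span = hi - lo
    span[span == 0] = 1.0  # degenerate axis -> all zeros after shift
    X = (X - lo) / span
    X[:, 2] *= abundance_weight
    return X


def build_dissimilarity(points: ClusterPoints, abundance_weight: float = 1.0 / 3.0) -> np.ndarray:
    """Symmetric Euclidean dissimilarity on the scaled (lat, lon, w·abund)."""
    if len(points) < 1:
        raise ValueError("need at least one point")
    X = scale_points(points, abundance_weight)
    return squareform(pdist(X)) if len(points) > 1 else np.zeros((1, 1))


def _assign(D: np.ndarray, medoids: np.ndarray) -> tuple[np.ndarray, float]:
    """Nearest-medoid assignment; ties go to the lowest medoid index."""
    sub = D[:, medoids]
    idx = np.argmin(sub, axis=1)
    return idx, float(sub[np.arange(D.shape[0]), idx].sum())


def _build_init(D: np.ndarray, k: int) -> np.ndarray:
    """BUILD: start from the 1-medoid optimum, then greedily add the point
    with the largest reduction in total dissimilarity."""
    medoids = [int(np.argmin(D.sum(axis=1)))]
    dist_near = D[:, medoids[0]].copy()
    while len(medoids) < k:
        gain = np.maximum(dist_near[None, :] - D, 0.0).sum(axis=1)
        gain[medoids] = -np.inf
        new = int(np.argmax(gain))
        medoids.append(new)
        dist_near = np.minimum(dist_near, D[:, new])
    return np.array(sorted(medoids))


def _swap_descent(D: np.ndarray, medoids: np.ndarray) -> tuple[np.ndarray, float]:
    """Steepest-descent SWAP over all (medoid, non-medoid) exchanges."""
    n = D.shape[0]
    _, best_cost = _assign(D, medoids)
    while True:
        best_swap = None
        non_medoids = np.setdiff1d(np.arange(n), medoids)
        if non_medoids.size == 0:  # k = n: every point is a medoid
            return medoids, best_cost
        for mi in range(len(medoids)):
            others = np.delete(medoids, mi)
            if others.size:
                d_others = D[:, others].min(axis=1)
            else:
                d_others = np.full(n, np.inf)
            # cost of swapping medoid mi for each candidate h, vectorized
            costs = np.minimum(d_others[:, None], D[:, non_medoids]).sum(axis=0)
            j = int(np.argmin(costs))
            if costs[j] < best_cost - 1e-12:
                best_cost = float(costs[j])
                best_swap = (mi, non_medoids[j])
        if best_swap is None:
            return medoids, best_cost
        mi, h = best_swap
        medoids = np.array(sorted(np.concatenate([np.delete(medoids, mi), [h]])))


def pam(
    D: np.ndarray, k: int, seed: int = 0, n_restarts: int = 8
) -> tuple[np.ndarray, np.ndarray, float]:
    """k-medoids: BUILD + steepest-descent SWAP, with seeded random restarts.

    SWAP descent from the greedy BUILD start can stall in a local optimum;
    ``n_restarts`` additional descents from random medoid sets (drawn from
    ``seed``) are run and the best local optimum kept.  Returns (medoid
    indices sorted ascending, labels 0..k-1 per point, total
    dissimilarity).  Deterministic given ``seed`` (default 0).
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n):
        raise ValueError("D must be square")
    if k > n:
        raise ValueError(f"k={k} exceeds number of points n={n}")

    best_medoids, best_cost = _swap_descent(D, _build_init(D, k))
    rng = np.random.default_rng(seed)
    for _ in range(n_restarts):
        init = np.sort(rng.choice(n, size=k, replace=False))
        medoids, cost = _swap_descent(D, init)
        if cost < best_cost - 1e-12:
            best_medoids, best_cost = medoids, cost
    labels, total = _assign(D, best_medoids)
    return best_medoids, labels, total


def clara(points: ClusterPoints, config: ClusteringConfig) -> ClusterAssignment:
    """CLARA: best-of-subsamples PAM, all points assigned to the winner.

    Scaling of the three axes uses the *full* point set, so subsample
    dissimilarities are consistent with the final whole-set assignment.
    When the subsample is the whole set this reduces exactly to PAM.
    """
    n = len(points)
    if n < config.k:
        raise ValueError(f"need at least k={config.k} points, got {n}")
    size = config.effective_sample_size(n)
    if size < config.k:
        raise ValueError(f"sample_size={size} smaller than k={config.k}")
    X = scale_points(points, config.abundance_weight)
    rng = np.random.default_rng(config.seed)

    best = None
    n_draws = 1 if size >= n else config.n_samples
    for _ in range(n_draws):
        sub = np.sort(rng.choice(n, size=size, replace=False)) if size < n else np.arange(n)
        D_sub = squareform(pdist(X[sub])) if size > 1 else np.zeros((1, 1))
        med_local, _, _ = pam(D_sub, config.k, seed=config.seed)
        medoids = sub[med_local]
        d_all = cdist(X, X[medoids])
        lab = np.argmin(d_all, axis=1)
        total = float(d_all[np.arange(n), lab].sum())
        if best is None or total < best[2] - 1e-12:
            best = (medoids, lab, total)
    medoids, lab, total = best

    # relabel clusters 1..k in medoid order (sorted by cell id for stability)
    order = np.argsort(points.cell_id[medoids], kind="stable")
    medoids = medoids[order]
    remap = np.empty(len(order), dtype=int)
    remap[order] = np.arange(len(order))
    labels = remap[lab] + 1

    if config.rebalance:
        labels = _rebalance(X, points.abundance, labels, medoids)

    share = np.array([points.abundance[labels == j + 1].sum() for j in range(len(medoids))])
    share = share / points.abundance.sum()
    return ClusterAssignment(
        cell_id=points.cell_id.copy(),
        labels=labels,
        medoid_cell_ids=points.cell_id[medoids],
        total_dissimilarity=total,
        abundance_share=share,
    )


def _rebalance(X: np.ndarray, abundance: np.ndarray, labels: np.ndarray, medoids: np.ndarray, max_moves: int | None = None) -> np.ndarray:
    """Greedy optional pass nudging per-cluster abundance shares toward 1/k.

    Repeatedly moves the point, among those whose second-nearest medoid
    belongs to a lighter cluster, with the smallest dissimilarity penalty.
    Off by default; a k-medoids partition cannot guarantee equal shares.
    """
    k = len(medoids)
    labels = labels.copy()
    total = abundance.sum()
    d = cdist(X, X[medoids])
    max_moves = max_moves or len(labels)
    for _ in range(max_moves):
        shares = np.array([abundance[labels == j + 1].sum() for j in range(k)]) / total
        heavy = int(np.argmax(shares))
        light = int(np.argmin(shares))
        if shares[heavy] - shares[light] <= 1.0 / k * 0.1:
            break
        cand = np.nonzero(labels == heavy + 1)[0]
        if cand.size <= 1:
            break
        penalty = d[cand, light] - d[cand, heavy]
        move = cand[int(np.argmin(penalty))]
        labels[move] = light + 1
    return labels


def points_from_surface(surface: np.ndarray, grid: PlanningGrid) -> ClusterPoints:
    """Occupied-cell points (abundance > 0, non-missing) of one weekly map."""
    vals = np.nan_to_num(np.asarray(surface, dtype=float), nan=0.0)
    occ = np.nonzero(vals > 0)[0]
    lat, lon = grid.cell_centers_latlon()
    return ClusterPoints(cell_id=occ, lat=lat[occ], lon=lon[occ], abundance=vals[occ])


def cluster_weekly(
    cube: AbundanceCube,
    grid: PlanningGrid,
    config: ClusteringConfig | None = None,
) -> dict[tuple[str, int], ClusterAssignment]:
    """Cluster every species-week surface independently.

    Weeks with fewer occupied cells than k fall back to a single cluster
    (with a logged warning).  Returns {(species_id, week): assignment}.
    """
    cfg = config or ClusteringConfig()
    out: dict[tuple[str, int], ClusterAssignment] = {}
    for s_idx, sp in enumerate(cube.species):
        for w_idx, week in enumerate(cube.weeks):
            points = points_from_surface(cube.values[s_idx, w_idx], grid)
            if len(points) == 0:
                logger.warning("no occupied cells for %s week %d; skipping", sp, week)
                continue
            if len(points) < cfg.k:
                logger.warning(
                    "%s week %d has %d occupied cells < k=%d; using one cluster", sp, week, len(points), cfg.k
                )
                out[(sp, int(week))] = ClusterAssignment(
                    cell_id=points.cell_id.copy(),
                    labels=np.ones(len(points), dtype=int),
                    medoid_cell_ids=points.cell_id[:1].copy(),
                    total_dissimilarity=0.0,
                    abundance_share=np.array([1.0]),
                )
                continue
            out[(sp, int(week))] = clara(points, cfg)
    return out
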