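"""Synthetic landscapes, migratory abundance cubes and checklist observations.

Everything downstream of this module (estimation, clustering, optimization,
land-cover accounting) operates on a regular planning grid of square cells.
The generators here produce inputs with the statistical structure the
analysis assumes:

* weekly relative-abundance surfaces for migratory species — an isotropic
  Gaussian kernel that tracks a 52-week route, rescaled so the weekly total
  equals the species' population size (constant through the year);
* checklist-style observations — a zero-inflated count process whose mean
  increases with search effort, emulating semi-structured citizen-science
  protocols;
* a bounded [0, 50] spatially autocorrelated cost surface in the style of a
  human-footprint index, or a uniform cost of 1;
* a categorical land-cover raster at a finer resolution than the planning
  grid, with controllable class proportions and spatial autocorrelation.

All generators are pure functions of their parameters and a seed.

The grid is treated as locally flat: cell geometry is defined by kilometre
offsets from the grid origin and converted to degrees with a constant
111.32 km/degree on both axes.  Latitude only matters downstream, for the
latitude-dependent block-size rule of the estimation ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit
from scipy.stats import rankdata

KM_PER_DEG = 111.32

__all__ = [
    "KM_PER_DEG",
    "PlanningGrid",
    "SpeciesParams",
    "AbundanceCube",
    "EffortModel",
    "CostSurface",
    "LandCoverRaster",
    "make_planning_grid",
    "make_migratory_route",
    "default_species_pool",
    "simulate_species",
    "build_cube",
    "simulate_checklists",
    "expected_count",
    "make_cost_surface",
    "make_landcover",
    "make_elevation",
    "elevation_at",
]


# ---------------------------------------------------------------------------
# Planning grid
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlanningGrid:
    """Regular grid of square planning units.

    Cell ids are 0-based and row-major (id = row * n_cols + col).  Row 0 is
    the southernmost row; the grid origin is the south-west corner.  Cell
    extents are half-open: a point on a shared edge belongs to the cell to
    its north-east.
    """

    n_rows: int
    n_cols: int
    cell_size_km: float
    origin_lat: float
    origin_lon: float

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def cell_area_km2(self) -> float:
        return self.cell_size_km**2

    @property
    def cell_size_deg(self) -> float:
        return self.cell_size_km / KM_PER_DEG

    def cell_centers_km(self) -> tuple[np.ndarray, np.ndarray]:
        """(east_km, north_km) offsets of cell centers from the origin."""
        rows, cols = np.divmod(np.arange(self.n_cells), self.n_cols)
        x = (cols + 0.5) * self.cell_size_km
        y = (rows + 0.5) * self.cell_size_km
        return x, y

    def cell_centers_latlon(self) -> tuple[np.ndarray, np.ndarray]:
        x, y = self.cell_centers_km()
        return self.origin_lat + y / KM_PER_DEG, self.origin_lon + x / KM_PER_DEG

    @property
    def lat_extent(self) -> tuple[float, float]:
        return self.origin_lat, self.origin_lat + self.n_rows * self.cell_size_deg

    @property
    def lon_extent(self) -> tuple[float, float]:
        return self.origin_lon, self.origin_lon + self.n_cols * self.cell_size_deg

    def cell_of(self, lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
        """Map coordinates to cell ids; coordinates must lie on the grid."""
        row = np.floor((np.asarray(lat) - self.origin_lat) / self.cell_size_deg)
        col = np.floor((np.asarray(lon) - self.origin_lon) / self.cell_size_deg)
        row = np.clip(row, 0, self.n_rows - 1).astype(int)
        col = np.clip(col, 0, self.n_cols - 1).astype(int)
        return row * self.n_cols + col


def make_planning_grid(
    n_rows: int,
    n_cols: int,
    cell_size_km: float,
    origin: tuple[float, float] = (30.0, -100.0),
) -> PlanningGrid:
    """Create a planning grid of ``n_rows`` x ``n_cols`` square cells.

    ``origin`` is the (lat, lon) of the south-west corner.
    """
    if n_rows < 1 or n_cols < 1:
        raise ValueError(f"grid dimensions must be >= 1, got {n_rows}x{n_cols}")
    if cell_size_km <= 0:
        raise ValueError(f"cell_size_km must be > 0, got {cell_size_km}")
    return PlanningGrid(int(n_rows), int(n_cols), float(cell_size_km), float(origin[0]), float(origin[1]))


# ---------------------------------------------------------------------------
# Species and abundance cubes
# ---------------------------------------------------------------------------

N_WEEKS = 52


@dataclass(frozen=True)
class SpeciesParams:
    """Parameters of one synthetic migratory species.

    ``route`` gives the kernel center (lat, lon) for each of the 52 weeks;
    ``spread_km`` the isotropic dispersion of the abundance kernel;
    ``total_abundance`` the constant weekly population total.
    ``stationary_weeks`` records the breeding / non-breeding phases used to
    build the route (informational; the route itself is authoritative).
    """

    species_id: str
    total_abundance: float
    route: np.ndarray  # (52, 2) of (lat, lon)
    spread_km: float
    stationary_weeks: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        route = np.asarray(self.route, dtype=float)
        if route.shape != (N_WEEKS, 2):
            raise ValueError(f"route must have one (lat, lon) per week, shape (52, 2); got {route.shape}")
        if self.total_abundance <= 0:
            raise ValueError("total_abundance must be > 0")
        if self.spread_km <= 0:
            raise ValueError("spread_km must be > 0")
        object.__setattr__(self, "route", route)


@dataclass
class AbundanceCube:
    """Species x week x cell nonnegative relative abundance.

    ``values`` has shape (n_species, n_weeks, n_cells).  For estimated
    cubes, ``support`` carries the number of contributing base models per
    (species, week, cell) and ``values`` is NaN wherever the support
    requirement was not met.  True cubes have ``support=None``.
    """

    values: np.ndarray
    species: list[str]
    weeks: np.ndarray
    support: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.weeks = np.asarray(self.weeks, dtype=int)
        if self.values.ndim != 3:
            raise ValueError("values must be (species, week, cell)")
        if self.values.shape[0] != len(self.species) or self.values.shape[1] != len(self.weeks):
            raise ValueError("values shape inconsistent with species/weeks")

    @property
    def n_cells(self) -> int:
        return self.values.shape[2]

    def week_index(self, week: int) -> int:
        idx = np.nonzero(self.weeks == week)[0]
        if idx.size == 0:
            raise KeyError(f"week {week} not in cube")
        return int(idx[0])

    def filled(self) -> np.ndarray:
        """Values with missing (NaN) entries replaced by 0."""
        return np.nan_to_num(self.values, nan=0.0)


def make_migratory_route(
    grid: PlanningGrid,
    breeding: tuple[float, float],
    nonbreeding: tuple[float, float],
    breeding_weeks: tuple[int, int] = (22, 35),
    nonbreeding_weeks: tuple[int, int] = (48, 9),
) -> tuple[np.ndarray, tuple[tuple[int, int], ...]]:
    """Build a 52-week route with two stationary phases and smooth transits.

    ``breeding`` / ``nonbreeding`` are fractional (row, col) positions in
    [0, 1] within the grid.  Week ranges are inclusive and 1-based;
    ``nonbreeding_weeks`` may wrap the year end.
    """

    def frac_to_latlon(frac):
        lat = grid.origin_lat + frac[0] * grid.n_rows * grid.cell_size_deg
        lon = grid.origin_lon + frac[1] * grid.n_cols * grid.cell_size_deg
        return np.array([lat, lon])

    b = frac_to_latlon(breeding)
    nb = frac_to_latlon(nonbreeding)

    def in_range(w, rng):
        lo, hi = rng
        return lo <= w <= hi if lo <= hi else (w >= lo or w <= hi)

    route = np.zeros((N_WEEKS, 2))
    # position parameter: 0 at nonbreeding, 1 at breeding, cosine-smoothed transit
    nb_end = nonbreeding_weeks[1]
    b_start, b_end = breeding_weeks
    nb_start = nonbreeding_weeks[0]
    for i in range(N_WEEKS):
        w = i + 1
        if in_range(w, breeding_weeks):
            t = 1.0
        elif in_range(w, nonbreeding_weeks):
            t = 0.0
        elif nb_end < w < b_start:  # spring migration
            t = (w - nb_end) / (b_start - nb_end)
        else:  # autumn migration (b_end < w < nb_start)
            t = 1.0 - (w - b_end) / (nb_start - b_end)
        t = 0.5 - 0.5 * np.cos(np.pi * t)  # ease-in/ease-out
        route[i] = nb + t * (b - nb)
    return route, (breeding_weeks, nonbreeding_weeks)


def default_species_pool(grid: PlanningGrid, n_species: int, seed: int) -> list[SpeciesParams]:
    """A pool of migratory species with varied routes, spreads and totals.

    Routes run roughly south-to-north (non-breeding in the southern part of
    the grid, breeding in the north), with per-species jitter in position,
    phenology, kernel spread and population size.
    """
    rng = np.random.default_rng(seed)
    pool = []
    for s in range(n_species):
        breeding = (rng.uniform(0.65, 0.95), rng.uniform(0.1, 0.9))
        nonbreeding = (rng.uniform(0.05, 0.35), rng.uniform(0.1, 0.9))
        b0 = int(rng.integers(20, 25))
        route, phases = make_migratory_route(
            grid,
            breeding,
            nonbreeding,
            breeding_weeks=(b0, b0 + int(rng.integers(10, 15))),
            nonbreeding_weeks=(int(rng.integers(46, 51)), int(rng.integers(6, 11))),
        )
        extent_km = min(grid.n_rows, grid.n_cols) * grid.cell_size_km
        pool.append(
            SpeciesParams(
                species_id=f"sp{s:02d}",
                total_abundance=float(rng.uniform(5e3, 2e4)),
                route=route,
                spread_km=float(rng.uniform(0.08, 0.2) * extent_km),
                stationary_weeks=phases,
            )
        )
    return pool


def simulate_species(
    params: SpeciesParams, grid: PlanningGrid, seed: int = 0, presence_threshold: float = 1e-4
) -> np.ndarray:
    """Weekly abundance surfaces for one species, shape (52, n_cells).

    Each week's surface is an isotropic Gaussian kernel (in km-space)
    centered on that week's route position.  Kernel values below
    ``presence_threshold`` times the weekly maximum are set to exactly
    zero — the species is absent, not astronomically rare, outside its
    weekly range — and the surface is rescaled so the weekly sum equals
    ``total_abundance``.  The construction is deterministic; the seed is
    part of the generator contract but unused here.
    """
    x, y = grid.cell_centers_km()
    vals = np.zeros((N_WEEKS, grid.n_cells))
    for i in range(N_WEEKS):
        clat, clon = params.route[i]
        cx = (clon - grid.origin_lon) * KM_PER_DEG
        cy = (clat - grid.origin_lat) * KM_PER_DEG
        d2 = (x - cx) ** 2 + (y - cy) ** 2
        g = np.exp(-d2 / (2.0 * params.spread_km**2))
        g[g < presence_threshold * g.max()] = 0.0
        total = g.sum()
        if total <= 0:  # kernel entirely off-grid at double precision
            g = np.full(grid.n_cells, 1.0 / grid.n_cells)
            total = 1.0
        vals[i] = g * (params.total_abundance / total)
    return vals


def build_cube(species: Sequence[SpeciesParams], grid: PlanningGrid, seed: int = 0) -> AbundanceCube:
    """Stack per-species weekly surfaces into a true abundance cube."""
    values = np.stack([simulate_species(p, grid, seed) for p in species])
    return AbundanceCube(values=values, species=[p.species_id for p in species], weeks=np.arange(1, N_WEEKS + 1))


# ---------------------------------------------------------------------------
# Checklist observation process
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EffortModel:
    """Parameters of the zero-inflated checklist observation process.

    The expected count of a species on a checklist at a cell with local
    true abundance ``a`` (birds per cell) under effort (duration ``t`` h,
    distance ``d`` km, party size ``p``) is::

        E[count] = P(detected) * detection_scale * a * t * sqrt(1 + d)
        P(detected) = expit(occ_intercept + occ_slope * log(a)
                            + party_effect * log(p))      (0 if a = 0)

    Counts are Bernoulli(P) x Poisson(mean), i.e. zero-inflated Poisson
    with a logistic occupancy model in log abundance; party size enters
    detection only.  ``detection_certain=True`` forces P = 1 wherever
    abundance is positive (used for closed-form checks).
    """

    occ_intercept: float = 1.0
    occ_slope: float = 1.0
    party_effect: float = 0.5
    detection_certain: bool = False
    duration_range_h: tuple[float, float] = (0.25, 3.0)
    distance_range_km: tuple[float, float] = (0.0, 5.0)
    start_time_range_h: tuple[float, float] = (5.0, 12.0)
    mean_extra_party: float = 0.7
    years: tuple[int, int] = (2004, 2016)


def _abundance_density_scale(grid: PlanningGrid) -> float:
    """Convert cell abundance to a per-km2-ish density so detection rates
    are comparable across grid resolutions."""
    return 1.0 / grid.cell_area_km2


def occupancy_probability(abundance: np.ndarray, party_size: np.ndarray, effort: EffortModel) -> np.ndarray:
    a = np.asarray(abundance, dtype=float)
    p = np.zeros_like(a)
    pos = a > 0
    if effort.detection_certain:
        p[pos] = 1.0
        return p
    party = np.broadcast_to(np.asarray(party_size, dtype=float), a.shape)
    p[pos] = expit(effort.occ_intercept + effort.occ_slope * np.log(a[pos]) + effort.party_effect * np.log(party[pos]))
    return p


def expected_count(
    abundance: np.ndarray,
    duration_h: np.ndarray,
    distance_km: np.ndarray,
    party_size: np.ndarray,
    effort: EffortModel,
    detection_scale: float,
) -> np.ndarray:
    """Closed-form mean of the simulated count process."""
    lam = detection_scale * np.asarray(abundance, dtype=float) * np.asarray(duration_h) * np.sqrt(
        1.0 + np.asarray(distance_km)
    )
    return occupancy_probability(abundance, party_size, effort) * lam


def simulate_checklists(
    cube: AbundanceCube,
    grid: PlanningGrid,
    n_checklists: int,
    effort_model: EffortModel | None = None,
    detection_scale: float = 1.0,
    seed: int = 0,
    effort_density: np.ndarray | None = None,
) -> pd.DataFrame:
    """Simulate checklist events with per-species zero-inflated counts.

    Returns a long table with one row per (checklist, species):
    ``checklist_id, lat, lon, day_of_year, year, start_time, duration_h,
    distance_km, party_size, species_id, count``.  ``effort_density``, if
    given, weights checklist placement per planning cell (it is normalized
    internally); by default effort is spatially uniform.
    """
    if n_checklists < 1:
        raise ValueError("n_checklists must be >= 1")
    if detection_scale <= 0:
        raise ValueError("detection_scale must be > 0")
    if cube.values.size == 0:
        raise ValueError("empty abundance cube")
    effort = effort_model or EffortModel()
    rng = np.random.default_rng(seed)

    if effort_density is None:
        cells = rng.integers(0, grid.n_cells, size=n_checklists)
    else:
        w = np.asarray(effort_density, dtype=float)
        if w.shape != (grid.n_cells,) or (w < 0).any() or w.sum() <= 0:
            raise ValueError("effort_density must be a nonnegative vector over cells with positive sum")
        cells = rng.choice(grid.n_cells, size=n_checklists, p=w / w.sum())
    rows, cols = np.divmod(cells, grid.n_cols)
    lat = grid.origin_lat + (rows + rng.uniform(0, 1, n_checklists)) * grid.cell_size_deg
    lon = grid.origin_lon + (cols + rng.uniform(0, 1, n_checklists)) * grid.cell_size_deg

    day = rng.integers(1, N_WEEKS * 7 + 1, size=n_checklists)  # days 1..364 -> weeks 1..52
    week = (day - 1) // 7 + 1
    year = rng.integers(effort.years[0], effort.years[1] + 1, size=n_checklists)
    start_time = rng.uniform(*effort.start_time_range_h, size=n_checklists)
    duration = rng.uniform(*effort.duration_range_h, size=n_checklists)
    distance = rng.uniform(*effort.distance_range_km, size=n_checklists)
    party = 1 + rng.poisson(effort.mean_extra_party, size=n_checklists)

    dens_scale = _abundance_density_scale(grid)
    week_idx = np.searchsorted(cube.weeks, week)
    frames = []
    for s_idx, sp in enumerate(cube.species):
        a = cube.filled()[s_idx][week_idx, cells] * dens_scale
        lam = detection_scale * a * duration * np.sqrt(1.0 + distance)
        p = occupancy_probability(a, party, effort)
        count = rng.binomial(1, p) * rng.poisson(lam)
        frames.append(
            pd.DataFrame(
                {
                    "checklist_id": np.arange(n_checklists),
                    "lat": lat,
                    "lon": lon,
                    "day_of_year": day,
                    "year": year,
                    "start_time": start_time,
                    "duration_h": duration,
                    "distance_km": distance,
                    "party_size": party,
                    "species_id": sp,
                    "count": count,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Cost surface and land cover
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CostSurface:
    """Per-cell planning cost: uniform 1 (shared-use) or a bounded [0, 50]
    footprint-style index (intact-habitat)."""

    cost: np.ndarray
    mode: str

    def __post_init__(self):
        object.__setattr__(self, "cost", np.asarray(self.cost, dtype=float))


def make_cost_surface(
    grid: PlanningGrid,
    mode: str = "uniform",
    seed: int = 0,
    correlation_cells: float = 3.0,
    mean: float = 20.0,
    sd: float = 12.0,
) -> CostSurface:
    """Uniform cost of 1, or a spatially autocorrelated footprint-style
    surface clipped to [0, 50]."""
    if mode == "uniform":
        return CostSurface(cost=np.ones(grid.n_cells), mode=mode)
    if mode == "footprint":
        rng = np.random.default_rng(seed)
        z = rng.standard_normal((grid.n_rows, grid.n_cols))
        z = gaussian_filter(z, sigma=correlation_cells, mode="reflect")
        sd_z = z.std()
        if sd_z > 0:
            z = (z - z.mean()) / sd_z
        # logistic squash into (0, 50): a *mean* footprint over a coarse cell
        # is rarely exactly 0 or 50, and the open bounds avoid plateaus of
        # tied costs
        cost = 50.0 * expit((mean - 25.0) / 10.0 + (sd / 10.0) * z)
        return CostSurface(cost=np.clip(cost, 0.0, 50.0).ravel(), mode=mode)
    raise ValueError(f"unknown cost mode {mode!r}; expected 'uniform' or 'footprint'")


@dataclass(frozen=True)
class LandCoverRaster:
    """Categorical land cover on a fine grid nested in the planning grid.

    ``class_id`` is (n_rows*fine_factor, n_cols*fine_factor) with 1-based
    class labels; row 0 is the southernmost fine row.
    """

    class_id: np.ndarray
    fine_cell_size_km: float
    fine_factor: int
    origin_lat: float
    origin_lon: float
    class_names: dict[int, str] = field(default_factory=dict)

    @property
    def fine_cell_area_km2(self) -> float:
        return self.fine_cell_size_km**2

    @property
    def fine_cell_size_deg(self) -> float:
        return self.fine_cell_size_km / KM_PER_DEG

    def fine_index_of(self, lat: np.ndarray, lon: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        r = np.floor((np.asarray(lat) - self.origin_lat) / self.fine_cell_size_deg)
        c = np.floor((np.asarray(lon) - self.origin_lon) / self.fine_cell_size_deg)
        r = np.clip(r, 0, self.class_id.shape[0] - 1).astype(int)
        c = np.clip(c, 0, self.class_id.shape[1] - 1).astype(int)
        return r, c


def make_landcover(
    grid: PlanningGrid,
    n_classes: int,
    fine_factor: int,
    seed: int = 0,
    proportions: Sequence[float] | None = None,
    correlation_fine_cells: float = 4.0,
    class_names: dict[int, str] | None = None,
) -> LandCoverRaster:
    """Spatially autocorrelated categorical raster with given class mix.

    A smoothed Gaussian field is rank-transformed to uniform and cut at the
    cumulative ``proportions`` (equal shares by default), so the realized
    class histogram matches the target mix up to rounding while classes
    remain spatially clumped.
    """
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    if fine_factor < 1:
        raise ValueError("fine_factor must be >= 1")
    if proportions is None:
        props = np.full(n_classes, 1.0 / n_classes)
    else:
        props = np.asarray(proportions, dtype=float)
        if props.shape != (n_classes,) or (props < 0).any():
            raise ValueError("proportions must be nonnegative with one entry per class")
        props = props / props.sum()
    rng = np.random.default_rng(seed)
    shape = (grid.n_rows * fine_factor, grid.n_cols * fine_factor)
    z = gaussian_filter(rng.standard_normal(shape), sigma=correlation_fine_cells, mode="reflect")
    u = (rankdata(z.ravel(), method="ordinal") - 0.5) / z.size
    classes = (np.searchsorted(np.cumsum(props)[:-1], u, side="right") + 1).reshape(shape)
    return LandCoverRaster(
        class_id=classes.astype(np.int32),
        fine_cell_size_km=grid.cell_size_km / fine_factor,
        fine_factor=int(fine_factor),
        origin_lat=grid.origin_lat,
        origin_lon=grid.origin_lon,
        class_names=class_names or {i + 1: f"class_{i + 1}" for i in range(n_classes)},
    )


def make_elevation(grid: PlanningGrid, seed: int = 0, relief_m: float = 1500.0, correlation_cells: float = 4.0) -> np.ndarray:
    """Smooth synthetic elevation surface (metres) per planning cell."""
    rng = np.random.default_rng(seed)
    z = gaussian_filter(rng.standard_normal((grid.n_rows, grid.n_cols)), sigma=correlation_cells, mode="reflect")
    sd = z.std()
    if sd > 0:
        z = (z - z.min()) / (z.max() - z.min())
    return (z * relief_m).ravel()


def elevation_at(grid: PlanningGrid, elevation: np.ndarray, lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    """Sample a per-cell elevation surface at point locations."""
    return np.asarray(elevation)[grid.cell_of(lat, lon)]
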