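"""Ensemble estimation of weekly relative abundance from checklists.

The estimator is a spatiotemporal ensemble model: the study extent x year
is partitioned many times into randomly offset spatiotemporal blocks, one
local two-step model (occupancy classifier x conditional-abundance
regressor) is fitted per block with enough data, and the estimate at a
(location, date) is the average of ``P(occupied) * E[count | occupied]``
over all base models whose block contains it, evaluated at a standardized
search effort.  Averaging over many partially overlapping local models
controls inter-model variability and adapts to non-stationary
predictor-response relationships; estimates with too few contributing
models are withheld.

Blocks are squares in degrees crossed with 30 continuous days.  North of a
latitude split the blocks are smaller (denser data), south of it larger.
A 366-day year is not a multiple of 30, so each partition owns the year
through 13 day-bins (twelve 30-day bins and the 6-day wrap remainder): the
bins give every (location, day) exactly one block per partition, while
each block is *trained* on the full 30 continuous (wrapping) days starting
at its bin.

Landscape composition/configuration covariates (PLAND, LPI, PD, ED) are
computed from a categorical land-cover raster in a square neighborhood
around each location, with 4-connected patches.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.base import clone
from sklearn.ensemble import GradientBoostingClassifier, GradientBoostingRegressor
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from fullcycle.synthetic_landscape import AbundanceCube, LandCoverRaster, PlanningGrid

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 366
N_DAY_BINS = 13  # twelve 30-day bins + the 6-day wrap remainder

__all__ = [
    "StemConfig",
    "EnsembleDesign",
    "BaseModel",
    "StemModel",
    "design_ensemble",
    "block_extent",
    "assign_day_bins",
    "compute_landscape_metrics",
    "fit_stem",
    "predict_abundance",
    "week_midday",
    "fast_tree_learners",
    "boosted_tree_learners",
]


@dataclass(frozen=True)
class StemConfig:
    """Tuning parameters of the ensemble estimator.

    Defaults follow the standard configuration for boosted-tree base
    learners (bag fraction 0.80, shrinkage 0.05, 1000 trees, depth 5 for
    occupancy / 10 for abundance), a minimum of 50 checklists with 10
    detections per base model, an ensemble support requirement of 50
    models per estimate, and a 10% validation holdout.  Predictions are
    made for a standardized search: 1 km travelled in 1 h starting 07:00,
    single observer.
    """

    bag_fraction: float = 0.80
    shrinkage: float = 0.05
    n_trees: int = 1000
    depth_occupancy: int = 5
    depth_abundance: int = 10
    min_checklists: int = 50
    min_detections: int = 10
    min_support: int = 50
    holdout_fraction: float = 0.10
    n_partitions: int = 100
    north_block_deg: float = 10.0
    south_block_deg: float = 20.0
    latitude_split_deg: float = 12.0
    day_window: int = 30
    std_start_time: float = 7.0
    std_duration_h: float = 1.0
    std_distance_km: float = 1.0
    std_party_size: int = 1

    def __post_init__(self):
        if not (0 < self.holdout_fraction < 1):
            raise ValueError("holdout_fraction must be in (0, 1)")
        for name in ("bag_fraction", "shrinkage", "n_trees", "min_checklists", "min_detections", "min_support"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class EnsembleDesign:
    """Randomly offset spatiotemporal block tilings of the study extent.

    One tiling ("partition") per Monte-Carlo replicate; each partition
    tiles the extent with no gaps or overlaps.  Block size depends on the
    latitude band of the block center relative to ``latitude_split_deg``.
    """

    lat_extent: tuple[float, float]
    lon_extent: tuple[float, float]
    n_partitions: int
    north_block_deg: float
    south_block_deg: float
    latitude_split_deg: float
    # per-partition offsets, all in [0, block)/[0, 30)
    lat_offsets: np.ndarray = field(repr=False)  # (n_partitions, 2): north, south bands
    lon_offsets: np.ndarray = field(repr=False)
    day_offsets: np.ndarray = field(repr=False)  # (n_partitions,)

    def band_of(self, lat: np.ndarray) -> np.ndarray:
        """0 = northern band (small blocks), 1 = southern band."""
        return (np.asarray(lat) < self.latitude_split_deg).astype(int)

    def block_size_deg(self, band: np.ndarray) -> np.ndarray:
        return np.where(np.asarray(band) == 0, self.north_block_deg, self.south_block_deg)

    def block_keys(self, partition: int, lat: np.ndarray, lon: np.ndarray, day: np.ndarray) -> np.ndarray:
        """Integer-coded block key per point: (band, i_lat, i_lon, i_day).

        Every (lat, lon, day) maps to exactly one key per partition.
        """
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        band = self.band_of(lat)
        size = self.block_size_deg(band)
        off_lat = self.lat_offsets[partition][band]
        off_lon = self.lon_offsets[partition][band]
        i_lat = np.floor((lat - (self.lat_extent[0] - off_lat)) / size).astype(int)
        i_lon = np.floor((lon - (self.lon_extent[0] - off_lon)) / size).astype(int)
        i_day = assign_day_bins(day, self.day_offsets[partition])
        return np.stack([band, i_lat, i_lon, i_day], axis=-1)


def assign_day_bins(day: np.ndarray, day_offset: float) -> np.ndarray:
    """Bin days 1..366 into 13 ownership bins of a partition (bin 12 is the
    6-day wrap remainder)."""
    rel = np.mod(np.asarray(day) - 1 - day_offset, DAYS_PER_YEAR)
    return np.minimum(rel // 30, N_DAY_BINS - 1).astype(int)


def design_ensemble(
    extent: tuple[tuple[float, float], tuple[float, float]],
    n_partitions: int,
    config: StemConfig | None = None,
    seed: int = 0,
) -> EnsembleDesign:
    """Draw ``n_partitions`` randomly offset block tilings of ``extent``.

    ``extent`` is ((lat_min, lat_max), (lon_min, lon_max)).  Offsets are
    uniform per partition in both space (per latitude band) and
    day-of-year, so block boundaries fall uniformly over the extent.
    """
    cfg = config or StemConfig()
    (lat_min, lat_max), (lon_min, lon_max) = extent
    if lat_max <= lat_min or lon_max <= lon_min:
        raise ValueError("extent must be non-empty")
    if n_partitions < 1:
        raise ValueError("n_partitions must be >= 1")
    rng = np.random.default_rng(seed)
    sizes = np.array([cfg.north_block_deg, cfg.south_block_deg])
    return EnsembleDesign(
        lat_extent=(lat_min, lat_max),
        lon_extent=(lon_min, lon_max),
        n_partitions=int(n_partitions),
        north_block_deg=cfg.north_block_deg,
        south_block_deg=cfg.south_block_deg,
        latitude_split_deg=cfg.latitude_split_deg,
        lat_offsets=rng.uniform(0, 1, size=(n_partitions, 2)) * sizes,
        lon_offsets=rng.uniform(0, 1, size=(n_partitions, 2)) * sizes,
        day_offsets=rng.uniform(0, cfg.day_window, size=n_partitions),
    )


def block_extent(design: EnsembleDesign, partition: int, key: tuple[int, int, int, int]) -> dict:
    """Lat/lon box and 30-day training window of one block key."""
    band, i_lat, i_lon, i_day = key
    size = float(design.block_size_deg(np.array([band]))[0])
    lat0 = design.lat_extent[0] - design.lat_offsets[partition][band] + i_lat * size
    lon0 = design.lon_extent[0] - design.lon_offsets[partition][band] + i_lon * size
    day_start = (design.day_offsets[partition] + i_day * 30) % DAYS_PER_YEAR
    return {
        "lat_range": (lat0, lat0 + size),
        "lon_range": (lon0, lon0 + size),
        "train_day_start": day_start,  # 30 continuous days from here, wrapping
    }


# ---------------------------------------------------------------------------
# Landscape composition/configuration metrics
# ---------------------------------------------------------------------------


def compute_landscape_metrics(
    landcover: LandCoverRaster,
    lat: np.ndarray,
    lon: np.ndarray,
    window_km: float = 2.8,
    classes: Sequence[int] | None = None,
) -> pd.DataFrame:
    """PLAND/LPI/PD/ED per land-cover class in a square neighborhood.

    For each location, a ``window_km`` x ``window_km`` window of fine cells
    centered on the containing fine cell is extracted (clipped at raster
    edges) and per class:

    * PLAND — percent of the window covered by the class;
    * LPI — percent covered by its largest 4-connected patch;
    * PD — number of 4-connected patches in the window;
    * ED — edge length (km) per km² of window, counting class/non-class
      boundaries and the window border along class cells.

    Returns a wide DataFrame, one row per location, columns
    ``pland_<c>, lpi_<c>, pd_<c>, ed_<c>`` for each class.
    """
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    half_cells = max(1, int(round(window_km / landcover.fine_cell_size_km / 2)))
    arr = landcover.class_id
    if classes is None:
        classes = sorted(np.unique(arr).tolist())
    rows_i, cols_i = landcover.fine_index_of(lat, lon)
    cell_km = landcover.fine_cell_size_km
    out = np.zeros((lat.size, 4 * len(classes)))
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])  # 4-connectivity
    for i, (r, c) in enumerate(zip(rows_i, cols_i)):
        r0, r1 = max(0, r - half_cells), min(arr.shape[0], r + half_cells + 1)
        c0, c1 = max(0, c - half_cells), min(arr.shape[1], c + half_cells + 1)
        win = arr[r0:r1, c0:c1]
        if win.size == 0:
            raise ValueError("empty landscape window")
        area = win.size * cell_km**2
        for j, cls in enumerate(classes):
            mask = win == cls
            n = int(mask.sum())
            if n == 0:
                continue
            labels, n_patches = ndimage.label(mask, structure=structure)
            largest = np.bincount(labels.ravel())[1:].max()
            # internal edges: horizontal + vertical neighbors straddling the class
            h_edges = int((mask[:, 1:] != mask[:, :-1]).sum())
            v_edges = int((mask[1:, :] != mask[:-1, :]).sum())
            # window-border edges along class cells
            border = int(mask[0, :].sum() + mask[-1, :].sum() + mask[:, 0].sum() + mask[:, -1].sum())
            edge_km = (h_edges + v_edges + border) * cell_km
            out[i, 4 * j + 0] = 100.0 * n / win.size
            out[i, 4 * j + 1] = 100.0 * largest / win.size
            out[i, 4 * j + 2] = n_patches
            out[i, 4 * j + 3] = edge_km / area
    columns = []
    for cls in classes:
        columns += [f"pland_{cls}", f"lpi_{cls}", f"pd_{cls}", f"ed_{cls}"]
    return pd.DataFrame(out, columns=columns)


# ---------------------------------------------------------------------------
# Base models and the fitted ensemble
# ---------------------------------------------------------------------------


class _ConstantClassifier:
    """Degenerate occupancy model for single-class training blocks."""

    def __init__(self, p: float):
        self.p = float(p)

    def predict_proba(self, X):
        n = np.asarray(X).shape[0]
        return np.column_stack([np.full(n, 1 - self.p), np.full(n, self.p)])


@dataclass
class BaseModel:
    """One local two-step model: occupancy x conditional abundance."""

    partition: int
    key: tuple[int, int, int, int]
    lat_range: tuple[float, float]
    lon_range: tuple[float, float]
    train_day_start: float
    occupancy_submodel: object
    abundance_submodel: object
    n_train: int
    n_detections: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        p = self.occupancy_submodel.predict_proba(X)[:, 1]
        mu = self.abundance_submodel.predict(X)
        return p * np.maximum(mu, 0.0)


@dataclass
class StemModel:
    """Fitted ensemble: base models plus everything needed to predict."""

    species: str
    base_models: list[BaseModel]
    design: EnsembleDesign
    config: StemConfig
    feature_names: list[str]
    holdout: pd.DataFrame | None = None

    @property
    def n_base_models(self) -> int:
        return len(self.base_models)


def boosted_tree_learners(config: StemConfig, seed: int) -> tuple:
    """Default two-step learners: gradient-boosted trees with the standard
    hyperparameters (bag 0.80, shrinkage 0.05, 1000 trees, depths 5/10)."""
    clf = GradientBoostingClassifier(
        n_estimators=config.n_trees,
        learning_rate=config.shrinkage,
        subsample=config.bag_fraction,
        max_depth=config.depth_occupancy,
        random_state=seed,
    )
    reg = GradientBoostingRegressor(
        n_estimators=config.n_trees,
        learning_rate=config.shrinkage,
        subsample=config.bag_fraction,
        max_depth=config.depth_abundance,
        random_state=seed,
    )
    return clf, reg


def fast_tree_learners(config: StemConfig, seed: int) -> tuple:
    """Fast deterministic learners (single CART pair) for tests and
    desk-scale experiments; depths follow the occupancy/abundance split."""
    return (
        DecisionTreeClassifier(max_depth=config.depth_occupancy, min_samples_leaf=5, random_state=seed),
        DecisionTreeRegressor(max_depth=config.depth_abundance, min_samples_leaf=5, random_state=seed),
    )


SPATIAL_FEATURES = ["lat", "lon"]
TEMPORAL_FEATURES = ["day_of_year", "year", "start_time"]
EFFORT_FEATURES = ["duration_h", "distance_km", "party_size"]


def _in_training_window(day: np.ndarray, day_start: float, window: int = 30) -> np.ndarray:
    rel = np.mod(np.asarray(day) - 1 - day_start, DAYS_PER_YEAR)
    return rel < window


def fit_stem(
    checklists: pd.DataFrame,
    design: EnsembleDesign,
    species: str,
    config: StemConfig | None = None,
    seed: int = 0,
    covariates: pd.DataFrame | None = None,
    learner_factory: Callable[[StemConfig, int], tuple] | None = None,
) -> StemModel:
    """Fit the block-local two-step ensemble for one species.

    ``checklists`` is the long table from the observation process (one row
    per checklist x species); ``covariates``, if given, adds per-checklist
    spatial predictor columns (landscape metrics, elevation) aligned
    row-wise with the species' checklist rows.  A 10% holdout is split off
    first and used only for reporting validation metrics.  Blocks with
    fewer than ``min_checklists`` checklists or ``min_detections``
    detections contribute no base model.
    """
    cfg = config or StemConfig()
    rng = np.random.default_rng(seed)
    df = checklists.loc[checklists["species_id"] == species].reset_index(drop=True)
    if df.empty:
        raise ValueError(f"no checklists for species {species!r}")
    if covariates is not None:
        covariates = covariates.reset_index(drop=True)
        if len(covariates) != len(df):
            raise ValueError("covariates must align with the species' checklist rows")
        extra = [c for c in covariates.columns]
        df = pd.concat([df, covariates], axis=1)
    else:
        extra = []
    feature_names = SPATIAL_FEATURES + extra + TEMPORAL_FEATURES + EFFORT_FEATURES

    n = len(df)
    perm = rng.permutation(n)
    n_hold = int(round(cfg.holdout_fraction * n))
    hold_idx, train_idx = perm[:n_hold], perm[n_hold:]
    holdout = df.iloc[hold_idx].reset_index(drop=True)
    train = df.iloc[train_idx].reset_index(drop=True)

    X_all = train[feature_names].to_numpy(dtype=float)
    y_all = train["count"].to_numpy(dtype=float)
    lat = train["lat"].to_numpy()
    lon = train["lon"].to_numpy()
    day = train["day_of_year"].to_numpy()

    factory = learner_factory or boosted_tree_learners
    base_models: list[BaseModel] = []
    for p in range(design.n_partitions):
        keys = design.block_keys(p, lat, lon, day)
        # group rows by block key
        order = np.lexsort(keys.T[::-1])
        sorted_keys = keys[order]
        boundaries = np.nonzero(np.any(np.diff(sorted_keys, axis=0) != 0, axis=1))[0] + 1
        groups = np.split(order, boundaries)
        for g in groups:
            key = tuple(int(v) for v in keys[g[0]])
            ext = block_extent(design, p, key)
            # train on the block's full 30-day window (ownership bins for the
            # wrap remainder are shorter, but training context is 30 days)
            in_box = (
                (lat >= ext["lat_range"][0])
                & (lat < ext["lat_range"][1])
                & (lon >= ext["lon_range"][0])
                & (lon < ext["lon_range"][1])
                & _in_training_window(day, ext["train_day_start"])
            )
            rows = np.nonzero(in_box)[0]
            y = y_all[rows]
            n_det = int((y > 0).sum())
            if rows.size < cfg.min_checklists or n_det < cfg.min_detections:
                continue
            X = X_all[rows]
            detected = (y > 0).astype(int)
            sub_seed = int(rng.integers(0, 2**31 - 1))
            clf_proto, reg_proto = factory(cfg, sub_seed)
            if detected.min() == detected.max():
                clf = _ConstantClassifier(float(detected[0]))
            else:
                clf = clone(clf_proto).fit(X, detected)
            reg = clone(reg_proto).fit(X[y > 0], y[y > 0])
            base_models.append(
                BaseModel(
                    partition=p,
                    key=key,
                    lat_range=ext["lat_range"],
                    lon_range=ext["lon_range"],
                    train_day_start=ext["train_day_start"],
                    occupancy_submodel=clf,
                    abundance_submodel=reg,
                    n_train=int(rows.size),
                    n_detections=n_det,
                )
            )
    if not base_models:
        warnings.warn(f"no spatiotemporal block met the data requirements for {species!r}; empty ensemble")
    logger.info("fit %d base models for %s over %d partitions", len(base_models), species, design.n_partitions)
    return StemModel(
        species=species,
        base_models=base_models,
        design=design,
        config=cfg,
        feature_names=feature_names,
        holdout=holdout,
    )


def week_midday(week: np.ndarray) -> np.ndarray:
    """Representative day-of-year of a week (1..52 -> 4, 11, ..., 361)."""
    return (np.asarray(week) - 1) * 7 + 4


def predict_abundance(
    model: StemModel,
    grid: PlanningGrid,
    weeks: Sequence[int] | None = None,
    config: StemConfig | None = None,
    cell_covariates: pd.DataFrame | None = None,
    year: int = 2016,
) -> AbundanceCube:
    """Ensemble relative-abundance estimates on the planning grid.

    For each (week, cell), every base model whose block contains the cell
    center and owns the week's representative day contributes
    ``P(occupied) * E[count | occupied]`` at the standardized effort; the
    estimate is the mean over contributors, withheld (NaN) where fewer
    than ``min_support`` models contribute.
    """
    cfg = config or model.config
    weeks = np.arange(1, 53) if weeks is None else np.asarray(list(weeks), dtype=int)
    days = week_midday(weeks)
    lat_c, lon_c = grid.cell_centers_latlon()
    n_cells = grid.n_cells

    if cell_covariates is not None and len(cell_covariates) != n_cells:
        raise ValueError("cell_covariates must have one row per planning cell")

    # assemble the standardized-effort feature matrix template
    base_cols = {}
    for name in model.feature_names:
        if name == "lat":
            base_cols[name] = lat_c
        elif name == "lon":
            base_cols[name] = lon_c
        elif name == "day_of_year":
            base_cols[name] = np.zeros(n_cells)  # filled per week
        elif name == "year":
            base_cols[name] = np.full(n_cells, float(year))
        elif name == "start_time":
            base_cols[name] = np.full(n_cells, cfg.std_start_time)
        elif name == "duration_h":
            base_cols[name] = np.full(n_cells, cfg.std_duration_h)
        elif name == "distance_km":
            base_cols[name] = np.full(n_cells, cfg.std_distance_km)
        elif name == "party_size":
            base_cols[name] = np.full(n_cells, float(cfg.std_party_size))
        elif cell_covariates is not None and name in cell_covariates.columns:
            base_cols[name] = cell_covariates[name].to_numpy(dtype=float)
        else:
            raise ValueError(f"no cell-level value for predictor {name!r}")
    X_template = np.column_stack([base_cols[name] for name in model.feature_names])
    day_col = model.feature_names.index("day_of_year")

    total = np.zeros((len(weeks), n_cells))
    support = np.zeros((len(weeks), n_cells), dtype=int)
    design = model.design
    # precompute, per partition, the day-bin of each requested week
    week_bins = np.stack([assign_day_bins(days, design.day_offsets[p]) for p in range(design.n_partitions)])

    for bm in model.base_models:
        cells = np.nonzero(
            (lat_c >= bm.lat_range[0])
            & (lat_c < bm.lat_range[1])
            & (lon_c >= bm.lon_range[0])
            & (lon_c < bm.lon_range[1])
        )[0]
        if cells.size == 0:
            continue
        owned = np.nonzero(week_bins[bm.partition] == bm.key[3])[0]
        for wi in owned:
            X = X_template[cells]
            X[:, day_col] = days[wi]
            total[wi, cells] += bm.predict(X)
            support[wi, cells] += 1

    with np.errstate(invalid="ignore", divide="ignore"):
        values = total / support
    values = np.where(support >= cfg.min_support, np.maximum(values, 0.0), np.nan)
    return AbundanceCube(
        values=values[None, :, :],
        species=[model.species],
        weeks=weeks,
        support=support[None, :, :],
    )
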