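"""Land-cover accounting of prioritization solutions.

Selected planning cells are warped onto the fine land-cover grid by pure
containment (every fine cell inherits the state of its containing planning
cell — the planning grid is an exact multiple of the fine grid), the
selected area per land-cover class is tabulated, and fine classes are
aggregated into broader groups.  "Available" area is the land cover within
cells where at least a configurable number of species is present at any
point in the year.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from fullcycle.synthetic_landscape import AbundanceCube, LandCoverRaster, PlanningGrid

__all__ = [
    "ClassAggregationMap",
    "warp_selection",
    "availability_mask",
    "tabulate_landcover",
]


@dataclass(frozen=True)
class ClassAggregationMap:
    """fine class id -> broad class label; unmapped classes become 'other'."""

    mapping: dict[int, str] = field(default_factory=dict)
    other_label: str = "other"

    def broad(self, class_id: int) -> str:
        return self.mapping.get(int(class_id), self.other_label)


def warp_selection(selection: np.ndarray, grid: PlanningGrid, landcover: LandCoverRaster) -> np.ndarray:
    """Binary planning-cell selection -> binary mask on the fine grid."""
    sel = np.asarray(selection)
    if sel.shape != (grid.n_cells,):
        raise ValueError("selection must have one value per planning cell")
    f = landcover.fine_factor
    if landcover.class_id.shape != (grid.n_rows * f, grid.n_cols * f):
        raise ValueError("land-cover raster does not nest within the planning grid")
    coarse = (sel > 0).astype(np.int8).reshape(grid.n_rows, grid.n_cols)
    return np.repeat(np.repeat(coarse, f, axis=0), f, axis=1)


def availability_mask(cube: AbundanceCube, min_species: int = 1) -> np.ndarray:
    """Planning cells where >= ``min_species`` species are present (nonzero
    abundance) in at least one week of the year."""
    present = (cube.filled() > 0).any(axis=1)  # (species, cells)
    return (present.sum(axis=0) >= min_species).astype(int)


def tabulate_landcover(
    mask: np.ndarray,
    landcover: LandCoverRaster,
    aggregation: ClassAggregationMap | None = None,
    availability: np.ndarray | None = None,
    grid: PlanningGrid | None = None,
) -> pd.DataFrame:
    """Selected (and available) area in km² per broad land-cover class.

    ``mask`` is a fine-grid binary selection (from :func:`warp_selection`);
    ``availability`` is an optional planning-cell presence mask (warped
    internally; requires ``grid``).  Returns one row per broad class with
    ``area_selected_km2`` and, if availability was given,
    ``area_available_km2``.
    """
    mask = np.asarray(mask)
    if mask.shape != landcover.class_id.shape:
        raise ValueError("mask and land-cover raster are not congruent")
    agg = aggregation or ClassAggregationMap()
    area = landcover.fine_cell_area_km2

    classes = landcover.class_id.ravel()
    sel = mask.ravel() > 0
    df = pd.DataFrame({"class_id": classes[sel]})
    df["broad"] = df["class_id"].map(agg.broad)
    selected = df.groupby("broad").size() * area

    out = pd.DataFrame({"area_selected_km2": selected})
    if availability is not None:
        if grid is None:
            raise ValueError("availability tabulation requires the planning grid")
        avail_fine = warp_selection(availability, grid, landcover).ravel() > 0
        da = pd.DataFrame({"class_id": classes[avail_fine]})
        da["broad"] = da["class_id"].map(agg.broad)
        out["area_available_km2"] = da.groupby("broad").size() * area
    out = out.fillna(0.0).sort_index()
    out.index.name = "land_cover"
    return out.reset_index()
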