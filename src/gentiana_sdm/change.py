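"""Habitat-change detection between binary suitability maps, and
protected-area intersection reports.

Change categories compare the baseline and future presence/absence maps
cell-wise: *loss* (suitable now, unsuitable later), *stable* (suitable in
both), *gain* (unsuitable now, suitable later), *never* (unsuitable in
both).  Percentages are reported on two bases: ``total`` (share of all
cells) and ``dynamic`` (share of loss+stable+gain cells only, the
convention under which the three categories sum to ~100%).

Protected-area membership uses the cell-centre-in-polygon rule, which
gives exact, testable counts on the toy grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.ops import unary_union

from .areas import ProtectedArea
from .grid import GridSpec

logger = logging.getLogger(__name__)

CHANGE_LABELS = ("loss", "stable", "gain", "never")
#: Integer codes used when a change map is written as a raster.
CHANGE_CODES = {"loss": 0, "stable": 1, "gain": 2, "never": 3}


@dataclass
class ChangeMap:
    codes: np.ndarray   # values in CHANGE_CODES
    grid: GridSpec
    period_hist: str = "historical"
    period_future: str = "future"

    def label_grid(self) -> np.ndarray:
        lut = np.array(CHANGE_LABELS, dtype=object)
        return lut[self.codes]

    def count(self, label: str) -> int:
        return int((self.codes == CHANGE_CODES[label]).sum())


def change_map(
    binary_hist: np.ndarray,
    binary_future: np.ndarray,
    grid: GridSpec,
    period_hist: str = "historical",
    period_future: str = "future",
) -> ChangeMap:
    """Cell-wise change category from two binary suitability maps."""
    h = np.asarray(binary_hist)
    f = np.asarray(binary_future)
    if h.shape != f.shape or h.shape != grid.shape:
        raise ValueError("binary maps and grid must share one shape")
    codes = np.empty(h.shape, dtype=int)
    codes[(h == 1) & (f == 0)] = CHANGE_CODES["loss"]
    codes[(h == 1) & (f == 1)] = CHANGE_CODES["stable"]
    codes[(h == 0) & (f == 1)] = CHANGE_CODES["gain"]
    codes[(h == 0) & (f == 0)] = CHANGE_CODES["never"]
    return ChangeMap(codes=codes, grid=grid, period_hist=period_hist,
                     period_future=period_future)


def change_percentages(cmap: ChangeMap, basis: str = "dynamic") -> pd.Series:
    """Label shares in percent on the requested basis."""
    counts = pd.Series(
        {lab: cmap.count(lab) for lab in CHANGE_LABELS}, dtype=float
    )
    if basis == "total":
        return 100.0 * counts / counts.sum()
    if basis == "dynamic":
        dynamic = counts[["loss", "stable", "gain"]]
        if dynamic.sum() == 0:
            raise ValueError("no loss/stable/gain cells; dynamic basis "
                             "undefined")
        out = 100.0 * dynamic / dynamic.sum()
        return out
    raise ValueError(f"unknown basis {basis!r}")


def _cells_in_polygon(geometry, grid: GridSpec) -> np.ndarray:
    """Boolean mask of grid cells whose centre lies in the polygon."""
    xx, yy = grid.center_mesh()
    return shapely.contains_xy(geometry, xx.ravel(),
                               yy.ravel()).reshape(grid.shape)


def protected_area_report(
    layer,
    areas: list[ProtectedArea],
    grid: GridSpec | None = None,
) -> pd.DataFrame:
    """Per-designation composition of a binary grid or a ChangeMap.

    For a binary grid the report gives the percent of each designation's
    cells that are suitable; for a ChangeMap, the percent in each change
    class.  Designations with no covered cells are reported empty with a
    warning.
    """
    if isinstance(layer, ChangeMap):
        grid = layer.grid
        values = layer.label_grid()
        categories = list(CHANGE_LABELS)
    else:
        if grid is None:
            raise ValueError("grid is required for a plain binary layer")
        arr = np.asarray(layer)
        values = np.where(arr == 1, "suitable", "unsuitable").astype(object)
        categories = ["suitable", "unsuitable"]

    rows = []
    designations = sorted({a.designation for a in areas})
    for designation in designations:
        geom = unary_union([a.geometry for a in areas
                            if a.designation == designation])
        mask = _cells_in_polygon(geom, grid)
        n_cells = int(mask.sum())
        if n_cells == 0:
            logger.warning("designation %r covers no grid cells",
                           designation)
            for cat in categories:
                rows.append({"designation": designation, "category": cat,
                             "percent": np.nan, "n_cells": 0})
            continue
        inside = values[mask]
        for cat in categories:
            rows.append(
                {
                    "designation": designation,
                    "category": cat,
                    "percent": 100.0 * float((inside == cat).sum())
                    / n_cells,
                    "n_cells": n_cells,
                }
            )
    return pd.DataFrame(rows)
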