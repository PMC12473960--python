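"""Raster and table I/O on plain formats.

Grids are written as TIFF (via :mod:`tifffile`) with the local-frame grid
geometry stored as JSON in the ImageDescription tag; the toy study uses a
local equal-area Cartesian frame, so no CRS machinery is needed.
"""

from __future__ import annotations

import json

import numpy as np
import tifffile

from .grid import GridSpec


def write_raster(path, values: np.ndarray, grid: GridSpec) -> None:
    if values.shape != grid.shape:
        raise ValueError("raster shape does not match grid")
    meta = {
        "nx": grid.nx, "ny": grid.ny, "cell_size": grid.cell_size,
        "x0": grid.x0, "y0": grid.y0,
    }
    tifffile.imwrite(path, np.asarray(values, dtype=np.float32),
                     description=json.dumps(meta))


def read_raster(path) -> tuple[np.ndarray, GridSpec]:
    with tifffile.TiffFile(path) as tif:
        values = tif.asarray()
        meta = json.loads(tif.pages[0].description)
    grid = GridSpec(nx=meta["nx"], ny=meta["ny"],
                    cell_size=meta["cell_size"],
                    x0=meta["x0"], y0=meta["y0"])
    return values.astype(float), grid


def write_stack(directory, stack) -> None:
    """One TIFF per indicator plus a JSON manifest."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in stack.names:
        write_raster(directory / f"{name}.tif", stack[name], stack.grid)
    manifest = {
        "indicators": list(stack.names),
        "period": stack.period,
        "scenario": stack.scenario,
        "members": list(stack.members),
    }
    with open(directory / "stack.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def read_stack(directory):
    from pathlib import Path

    from .bioclim import IndicatorStack

    directory = Path(directory)
    with open(directory / "stack.json") as fh:
        manifest = json.load(fh)
    data = {}
    grid = None
    for name in manifest["indicators"]:
        data[name], grid = read_raster(directory / f"{name}.tif")
    return IndicatorStack(data=data, grid=grid,
                          period=manifest["period"],
                          scenario=manifest["scenario"],
                          members=tuple(manifest["members"]))
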