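"""Readers and writers for the package's standard artifacts.

Grid stacks go out as NetCDF cubes (via xarray's scipy backend) and per-year
TIFF rasters with the geotransform and nodata sentinel recorded in a JSON
sidecar; masks and classification layers as single-band TIFF plus the integer
code table; tables as CSV and truth sidecars as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import xarray as xr

#: Integer codes used in trend-classification rasters.
TREND_CODES = {"nodata": 0, "no_trend": 1, "linear_increase": 2,
               "linear_decrease": 3, "abrupt": 4}
PATTERN_CODES = {"nodata": 0, "none": 1, "I_D": 2, "D_I": 3}


def write_cube_netcdf(cube: xr.Dataset, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cube.to_netcdf(path, engine="scipy")  # NETCDF3 container
    return path


def read_cube_netcdf(path: str | Path) -> xr.Dataset:
    return xr.open_dataset(path, engine="scipy").load()


def write_raster(
    array: np.ndarray,
    path: str | Path,
    transform: tuple[float, float, float, float] = (0.0, 1.0, 0.0, -1.0),
    nodata: float | int | None = None,
    code_table: dict | None = None,
) -> Path:
    """Single- or multi-band TIFF with a JSON geospatial sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(array))
    meta = {"transform_x0_dx_y0_dy": list(transform), "nodata": nodata}
    if code_table:
        meta["code_table"] = code_table
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    return path


def read_raster(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path))


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def write_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, default=_jsonable))
    return path


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, np.ndarray):
        return v.tolist()
    if isinstance(v, pd.Series):
        return v.to_dict()
    raise TypeError(f"not JSON serializable: {type(v)}")
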