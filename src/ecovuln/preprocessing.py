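"""Raw inputs to analysis-ready aligned cubes and masks.

Covers maximum-value compositing of sub-monthly NDVI, nearest-neighbor
(categorical-safe) resampling, stable-pixel ecosystem masking, and the
per-window deseasonalize-then-z-score standardization that precedes the
window regressions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .synthetic import CLASS_CODES, CODE_CLASSES

#: Code for pixels whose class changed during the record.
UNSTABLE_CODE = 255


@dataclass(frozen=True)
class EcosystemMask:
    """Per-pixel stable ecosystem labels.

    ``labels`` holds the class code where the pixel kept a single vegetated
    class through every input year, ``0`` where the class was nodata in all
    years, and ``UNSTABLE_CODE`` (255) where the class changed.
    """

    labels: np.ndarray

    def stable(self, class_name: str) -> np.ndarray:
        return self.labels == CLASS_CODES[class_name]

    @property
    def any_stable(self) -> np.ndarray:
        return (self.labels != CLASS_CODES["nodata"]) & (self.labels != UNSTABLE_CODE)

    @property
    def unstable(self) -> np.ndarray:
        return self.labels == UNSTABLE_CODE

    def class_name(self, code: int) -> str:
        return "unstable" if code == UNSTABLE_CODE else CODE_CLASSES[code]


def max_value_composite(biweekly: xr.DataArray) -> xr.DataArray:
    """Aggregate sub-monthly NDVI layers to monthly maxima.

    Per pixel and calendar month the output is the maximum over that month's
    layers, skipping NaN (nodata); a pixel-month whose layers are all NaN
    stays NaN.  A calendar month inside the record with zero layers is a hard
    error.
    """
    if "time" not in biweekly.dims:
        raise ValueError("expected a 'time' dimension")
    time = pd.DatetimeIndex(biweekly["time"].values)
    months = time.to_period("M")
    expected = pd.period_range(months.min(), months.max(), freq="M")
    counts = pd.Series(1, index=months).groupby(level=0).sum()
    missing = expected.difference(counts.index)
    if len(missing) > 0:
        raise ValueError(f"months with zero layers: {list(missing.astype(str))}")

    monthly = biweekly.resample(time="1MS").max(skipna=True)
    return monthly


def resample_nearest(
    grid: np.ndarray,
    src_transform: tuple[float, float, float, float],
    target_cell: float,
) -> tuple[np.ndarray, tuple[float, float, float, float]]:
    """Resample a single 2-D grid to a new cell size, nearest-neighbor.

    ``src_transform`` is ``(x0, dx, y0, dy)`` in the north-up convention:
    ``x0, y0`` are the coordinates of the top-left corner, ``dx > 0`` and
    ``dy < 0`` the cell sizes.  Each target cell takes the value of the
    source cell *containing* the target cell's center, so values are never
    interpolated and categorical grids survive intact.
    """
    grid = np.asarray(grid)
    if grid.ndim != 2 or grid.size == 0:
        raise ValueError("expected a non-empty 2-D grid")
    x0, dx, y0, dy = src_transform
    if dx <= 0 or dy >= 0:
        raise ValueError("north-up convention requires dx > 0 and dy < 0")
    if target_cell <= 0:
        raise ValueError("target_cell must be positive")

    height = grid.shape[0] * abs(dy)
    width = grid.shape[1] * dx
    n_rows = int(np.floor(height / target_cell))
    n_cols = int(np.floor(width / target_cell))
    if n_rows == 0 or n_cols == 0:
        raise ValueError("empty overlap between source and target grids")

    # Target cell centers.
    cx = x0 + target_cell * (np.arange(n_cols) + 0.5)
    cy = y0 - target_cell * (np.arange(n_rows) + 0.5)
    col = np.floor((cx - x0) / dx).astype(int)
    row = np.floor((cy - y0) / dy).astype(int)
    col = np.clip(col, 0, grid.shape[1] - 1)
    row = np.clip(row, 0, grid.shape[0] - 1)

    out = grid[np.ix_(row, col)]
    return out, (x0, target_cell, y0, -target_cell)


def stable_pixel_mask(class_stack: np.ndarray) -> EcosystemMask:
    """Label pixels whose land-cover class is identical in every input year.

    Conversions are labeled unstable; all-nodata pixels keep the nodata code.
    """
    stack = np.asarray(class_stack)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("need a (years, rows, cols) stack with >= 2 years")

    first = stack[0]
    constant = np.all(stack == first[None, :, :], axis=0)
    labels = np.where(constant, first, UNSTABLE_CODE).astype(np.uint8)
    return EcosystemMask(labels=labels)


def standardize_window(
    cube_slice: np.ndarray,
    month_of_year: np.ndarray,
    eps: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray]:
    """Deseasonalize and z-score one variable over one window.

    ``cube_slice`` has shape ``(n_months, ...)`` (typically 60 months by
    pixels); ``month_of_year`` gives each layer's calendar month 1-12.  Per
    pixel: subtract the month-of-year mean computed within the window, then
    scale the residual to zero mean and unit (population) standard deviation
    over the window.  Pixels with zero residual variance or any non-finite
    month are flagged invalid (returned mask False) rather than raising.
    """
    arr = np.asarray(cube_slice, dtype=float)
    month_of_year = np.asarray(month_of_year)
    if arr.shape[0] != month_of_year.shape[0]:
        raise ValueError("slice length and month_of_year length differ")

    deseason = np.empty_like(arr)
    for m in np.unique(month_of_year):
        sel = month_of_year == m
        deseason[sel] = arr[sel] - arr[sel].mean(axis=0)

    mean = deseason.mean(axis=0)
    sd = deseason.std(axis=0)  # population sd: output sd exactly 1
    valid = np.isfinite(arr).all(axis=0) & (sd > eps)

    safe_sd = np.where(valid, sd, 1.0)
    z = (deseason - mean) / safe_sd
    z = np.where(valid, z, np.nan)
    return z, valid
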