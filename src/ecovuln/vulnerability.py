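"""Sliding-window exposure-sensitivity-resilience vulnerability index.

For each five-year window the monthly NDVI, temperature, and precipitation
series are standardized per pixel, the NDVI anomaly is regressed on the
contemporaneous climate anomalies and its own one-month lag,

    NDVI_t = alpha * Temp_t + beta * Pre_t + gamma * NDVI_{t-1} + eps_t,

and the coefficients are min-max normalized across pixels within the window.
The component indices are then

    EI = alpha_n + beta_n                      (exposure)
    SI = alpha_n * T_norm + beta_n * P_norm    (sensitivity)
    RI = 1 - gamma_n                           (resilience)
    VI = EI * SI / (1 + RI)                    (vulnerability)

with T_norm / P_norm the min-max-normalized window means of raw temperature
and precipitation.  One VI value is recorded per pixel at each window's
center year.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .preprocessing import standardize_window

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Window:
    window_id: int
    start_year: int
    end_year: int
    center_year: int


def enumerate_windows(
    first_year: int, last_year: int, length: int = 5, step: int = 1
) -> list[Window]:
    """Contiguous sliding windows ``[y, y+length-1]`` with the given step.

    A 1983-2022 span at the default length/step yields 36 windows with center
    years 1985-2020.
    """
    span = last_year - first_year + 1
    if span < length:
        raise ValueError(f"span {span} shorter than window length {length}")
    windows = []
    for i, y in enumerate(range(first_year, last_year - length + 2, step)):
        windows.append(
            Window(window_id=i, start_year=y, end_year=y + length - 1,
                   center_year=y + length // 2)
        )
    return windows


def fit_ndvi_recursion(
    ndvi: np.ndarray,
    temp: np.ndarray,
    pre: np.ndarray,
    intercept: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """OLS of NDVI_t on (Temp_t, Pre_t, NDVI_{t-1}) over t = 2..n.

    Accepts 1-D series or ``(n_months, n_pixels)`` stacks.  Returns
    ``(alpha, beta, gamma, residual_sd, valid)`` per pixel; rank-deficient or
    non-finite fits are marked invalid rather than raising.
    """
    ndvi = np.atleast_2d(np.asarray(ndvi, dtype=float).T).T
    temp = np.atleast_2d(np.asarray(temp, dtype=float).T).T
    pre = np.atleast_2d(np.asarray(pre, dtype=float).T).T
    n, npx = ndvi.shape

    y = ndvi[1:]
    regressors = [temp[1:], pre[1:], ndvi[:-1]]
    if intercept:
        regressors.insert(0, np.ones_like(y))
    k = len(regressors)

    alpha = np.full(npx, np.nan)
    beta = np.full(npx, np.nan)
    gamma = np.full(npx, np.nan)
    resid_sd = np.full(npx, np.nan)
    valid = np.zeros(npx, dtype=bool)

    off = 1 if intercept else 0
    for j in range(npx):
        X = np.column_stack([r[:, j] for r in regressors])
        yj = y[:, j]
        if not (np.isfinite(X).all() and np.isfinite(yj).all()):
            continue
        coef, _, rank, _ = np.linalg.lstsq(X, yj, rcond=None)
        if rank < k:
            continue
        resid = yj - X @ coef
        dof = max(len(yj) - k, 1)
        alpha[j], beta[j], gamma[j] = coef[off], coef[off + 1], coef[off + 2]
        resid_sd[j] = np.sqrt(resid @ resid / dof)
        valid[j] = True

    return alpha, beta, gamma, resid_sd, valid


def minmax_normalize(
    values: np.ndarray, valid: np.ndarray | None = None, eps: float = 1e-12
) -> np.ndarray:
    """Min-max scale ``values`` to [0, 1] across the valid entries.

    A degenerate range (max == min, including a single valid value) maps every
    valid entry to 0.5 and logs a warning.  Invalid entries come back NaN.
    """
    values = np.asarray(values, dtype=float)
    if valid is None:
        valid = np.isfinite(values)
    out = np.full(values.shape, np.nan)
    if not valid.any():
        return out
    vmin = values[valid].min()
    vmax = values[valid].max()
    if vmax - vmin <= eps:
        logger.warning("degenerate min-max range (min == max); mapping to 0.5")
        out[valid] = 0.5
    else:
        out[valid] = (values[valid] - vmin) / (vmax - vmin)
    return out


def normalize_coefficients(
    alpha: np.ndarray,
    beta: np.ndarray,
    gamma: np.ndarray,
    valid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Min-max normalize each coefficient channel across the pixels of one
    window (degenerate channels map to 0.5 with a logged warning)."""
    return (
        minmax_normalize(alpha, valid),
        minmax_normalize(beta, valid),
        minmax_normalize(gamma, valid),
    )


def compute_hydrothermal_norms(
    temp_window: np.ndarray, pre_window: np.ndarray, valid: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Window means of raw temperature / precipitation, min-max normalized
    across pixels within the window."""
    t_mean = np.asarray(temp_window, dtype=float).mean(axis=0)
    p_mean = np.asarray(pre_window, dtype=float).mean(axis=0)
    return minmax_normalize(t_mean, valid), minmax_normalize(p_mean, valid)


def compute_indices(
    alpha_n: np.ndarray,
    beta_n: np.ndarray,
    gamma_n: np.ndarray,
    t_norm: np.ndarray,
    p_norm: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Exposure, sensitivity, resilience and vulnerability from normalized
    coefficients and hydrothermal state (all inputs in [0, 1])."""
    ei = alpha_n + beta_n
    si = alpha_n * t_norm + beta_n * p_norm
    ri = 1.0 - gamma_n
    vi = ei * si / (1.0 + ri)
    return ei, si, ri, vi


def build_vi_series(
    cube: xr.Dataset,
    window_length: int = 5,
    window_step: int = 1,
    normalization_scope: str = "window",
    deseasonalize: bool = True,
    intercept: bool = True,
) -> xr.Dataset:
    """Run the full window pipeline over a monthly cube.

    ``normalization_scope`` controls the min-max scope for the coefficients
    and hydrothermal means: ``"window"`` (across pixels within each window,
    the default) or ``"pooled"`` (across all pixel-windows jointly).
    Returns an annual dataset with variables EI/SI/RI/VI and the raw window
    coefficients, dims ``(year, y, x)``; invalid pixel-windows are NaN.
    """
    if normalization_scope not in ("window", "pooled"):
        raise ValueError("normalization_scope must be 'window' or 'pooled'")
    time = pd.DatetimeIndex(cube["time"].values)
    years = time.year
    first_year, last_year = int(years.min()), int(years.max())
    windows = enumerate_windows(first_year, last_year, window_length, window_step)

    ny, nx = cube.sizes["y"], cube.sizes["x"]
    npx = ny * nx
    nw = len(windows)

    raw = {name: np.full((nw, npx), np.nan) for name in
           ("alpha", "beta", "gamma", "t_mean", "p_mean")}
    valid_all = np.zeros((nw, npx), dtype=bool)

    ndvi = cube["ndvi"].values.reshape(len(time), npx)
    temp = cube["temperature"].values.reshape(len(time), npx)
    pre = cube["precipitation"].values.reshape(len(time), npx)
    month_of_year = time.month.values

    for w in windows:
        sel = (years >= w.start_year) & (years <= w.end_year)
        moy = month_of_year[sel]
        if deseasonalize:
            zn, vn = standardize_window(ndvi[sel], moy)
            zt, vt = standardize_window(temp[sel], moy)
            zp, vp = standardize_window(pre[sel], moy)
        else:
            zn, vn = _plain_zscore(ndvi[sel])
            zt, vt = _plain_zscore(temp[sel])
            zp, vp = _plain_zscore(pre[sel])
        upstream_valid = vn & vt & vp
        a, b, g, _, vfit = fit_ndvi_recursion(zn, zt, zp, intercept=intercept)
        v = upstream_valid & vfit
        raw["alpha"][w.window_id] = np.where(v, a, np.nan)
        raw["beta"][w.window_id] = np.where(v, b, np.nan)
        raw["gamma"][w.window_id] = np.where(v, g, np.nan)
        raw["t_mean"][w.window_id] = temp[sel].mean(axis=0)
        raw["p_mean"][w.window_id] = pre[sel].mean(axis=0)
        valid_all[w.window_id] = v

    norm = {}
    if normalization_scope == "window":
        for key in ("alpha", "beta", "gamma", "t_mean", "p_mean"):
            norm[key] = np.vstack([
                minmax_normalize(raw[key][i], valid_all[i]) for i in range(nw)
            ])
    else:  # pooled across all windows and pixels
        for key in ("alpha", "beta", "gamma", "t_mean", "p_mean"):
            norm[key] = minmax_normalize(
                raw[key].ravel(), valid_all.ravel()
            ).reshape(nw, npx)

    ei, si, ri, vi = compute_indices(
        norm["alpha"], norm["beta"], norm["gamma"], norm["t_mean"], norm["p_mean"]
    )

    center_years = [w.center_year for w in windows]
    shape = (nw, ny, nx)
    data_vars = {
        "EI": ei, "SI": si, "RI": ri, "VI": vi,
        "alpha": raw["alpha"], "beta": raw["beta"], "gamma": raw["gamma"],
    }
    return xr.Dataset(
        {k: (("year", "y", "x"), np.asarray(v).reshape(shape))
         for k, v in data_vars.items()},
        coords={"year": center_years,
                "y": cube["y"].values, "x": cube["x"].values},
    )


def _plain_zscore(arr: np.ndarray, eps: float = 1e-12):
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0)
    valid = np.isfinite(arr).all(axis=0) & (sd > eps)
    z = (arr - mean) / np.where(valid, sd, 1.0)
    return np.where(valid, z, np.nan), valid


def vi_series_to_frame(vi_ds: xr.Dataset) -> pd.DataFrame:
    """Tidy (pixel_id, year, EI, SI, RI, VI) table from the annual dataset."""
    ny, nx = vi_ds.sizes["y"], vi_ds.sizes["x"]
    df = vi_ds[["EI", "SI", "RI", "VI"]].to_dataframe().reset_index()
    df["pixel_id"] = (
        df["y"].astype(int) * nx + df["x"].astype(int)
    )
    return df[["pixel_id", "year", "EI", "SI", "RI", "VI"]]
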