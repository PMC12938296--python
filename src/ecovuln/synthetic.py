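"""Synthetic landscapes, climate-vegetation cubes, and driver tables with known truth.

Every generator in this module returns its ground truth alongside the data,
so each downstream stage (standardization, window regression, trend
classification, driver attribution) can be validated against planted signal.
All randomness flows through an explicit seed; there is no global state.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import xarray as xr

#: Integer codes used in land-cover rasters. 0 is reserved for nodata.
CLASS_CODES: dict[str, int] = {
    "nodata": 0,
    "cropland": 1,
    "forest": 2,
    "shrubland": 3,
    "grassland": 4,
    "wetland": 5,
}
CODE_CLASSES = {v: k for k, v in CLASS_CODES.items()}
VEGETATED_CLASSES = ("cropland", "forest", "shrubland", "grassland", "wetland")

#: The 13 candidate drivers of interannual vulnerability variation.
DRIVER_NAMES = (
    "PRE", "PET", "AET", "AI", "VPD", "RHU", "SM",
    "TEM", "TMX", "TMN", "SR", "GI", "NTL",
)

#: Realistic sampling ranges (uniform) for each driver, in its native unit:
#: mm for water fluxes and soil moisture, degC for temperatures, kPa for VPD,
#: % for relative humidity, kWh/m2 for solar radiation, SU/ha for grazing
#: intensity, dimensionless DN for nighttime light and the aridity index.
DRIVER_RANGES: dict[str, tuple[float, float]] = {
    "PRE": (475.0, 1080.0),
    "PET": (600.0, 1100.0),
    "AET": (300.0, 700.0),
    "AI": (0.4, 1.6),
    "VPD": (0.25, 0.50),
    "RHU": (50.0, 80.0),
    "SM": (50.0, 110.0),
    "TEM": (-6.0, 12.0),
    "TMX": (2.0, 18.0),
    "TMN": (-18.0, -8.0),
    "SR": (2800.0, 4200.0),
    "GI": (0.0, 3.0),
    "NTL": (0.0, 10.0),
}


@dataclass(frozen=True)
class LandscapeSpec:
    """Geometry, composition, and land-cover dynamics of a synthetic landscape."""

    n_rows: int = 20
    n_cols: int = 20
    #: Fraction of pixels per class; grassland-dominated mosaic by default,
    #: echoing a high-plateau landscape where grassland and forest dominate.
    class_fractions: Mapping[str, float] = field(
        default_factory=lambda: {
            "grassland": 0.58,
            "forest": 0.29,
            "shrubland": 0.04,
            "cropland": 0.02,
            "wetland": 0.02,
            "nodata": 0.05,
        }
    )
    conversion_fraction: float = 0.0
    years: tuple[int, ...] = tuple(range(1983, 2023))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("landscape must have positive area")
        total = float(sum(self.class_fractions.values()))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_fractions must sum to 1, got {total}")
        unknown = set(self.class_fractions) - set(CLASS_CODES)
        if unknown:
            raise ValueError(f"unknown classes: {sorted(unknown)}")
        if not (0.0 <= self.conversion_fraction < 1.0):
            raise ValueError("conversion_fraction must lie in [0, 1)")
        if len(self.years) < 2:
            raise ValueError("need at least two annual maps")

    @property
    def n_pixels(self) -> int:
        return self.n_rows * self.n_cols


@dataclass(frozen=True)
class ProcessParams:
    """Coefficients of the generating NDVI-anomaly recursion.

    The monthly NDVI anomaly evolves as

        N_t = alpha * T_t + beta * P_t + gamma * N_{t-1} + eps_t

    with T_t, P_t unit-variance white-noise temperature / precipitation
    anomalies and eps_t ~ N(0, noise_sd^2).  The coefficients may be scalars
    or per-pixel arrays.  ``trend_spec`` optionally drifts the
    climate-coupling coefficients (alpha, beta) over calendar years so that
    downstream vulnerability series carry a planted trend: ``("none",)``,
    ``("linear", slope_per_year)`` or
    ``("piecewise", break_year, slope1, slope2)``.  The drift is applied to a
    random ``trend_pixel_fraction`` of pixels; the untouched remainder anchor
    the cross-pixel min-max normalization downstream (a drift shared by every
    pixel would cancel under min-max scaling and plant no relative trend).

    Because each window is z-scored before the regression, a bare coefficient
    drift would be invisible: shrinking (alpha, beta) shrinks the NDVI
    anomaly variance in proportion, leaving the standardized coefficients
    almost unchanged.  The drift is therefore planted as a change in the
    *share* of anomaly variance explained by climate: while the coupling
    coefficients are scaled by the drift factor, the residual variance is
    compensated so the total anomaly variance stays fixed.  The standardized
    window regression then recovers coefficients proportional to the drift
    factor, and the planted trend maps monotonically onto exposure and
    sensitivity.
    """

    alpha_true: float | np.ndarray = 0.4
    beta_true: float | np.ndarray = 0.3
    gamma_true: float | np.ndarray = 0.2
    noise_sd: float = 0.1
    trend_pixel_fraction: float = 0.6
    #: Range of a per-pixel multiplicative coupling scale (also variance
    #: compensated).  (1, 1) leaves every pixel at the stated coefficients;
    #: a spread such as (0.5, 1) gives the landscape a stable cross-pixel
    #: coupling gradient, which keeps the per-window min-max frame anchored
    #: when a drift is planted.
    coupling_heterogeneity: tuple[float, float] = (1.0, 1.0)
    #: (offset, amplitude) of the fixed 12-month sinusoidal climatology for
    #: NDVI (unitless), temperature (degC), precipitation (mm/month).
    seasonal_amplitudes: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "ndvi": (0.35, 0.20),
            "temperature": (2.0, 10.0),
            "precipitation": (55.0, 45.0),
        }
    )
    #: Half-range of a fixed spatial gradient added to the climatology offset
    #: (temperature rises along rows, precipitation along columns), mimicking
    #: the stable latitudinal / orographic structure of a real landscape.
    #: This is what keeps each pixel's window-mean hydrothermal state, and
    #: hence T_norm / P_norm, persistent over time.
    spatial_gradient: Mapping[str, float] = field(
        default_factory=lambda: {"temperature": 6.0, "precipitation": 20.0}
    )
    trend_spec: tuple = ("none",)
    #: Scale applied to the unit-free NDVI anomaly before adding it to the
    #: NDVI climatology (keeps NDVI inside [-1, 1]).
    ndvi_anomaly_scale: float = 0.05

    def __post_init__(self) -> None:
        if np.any(np.abs(self.gamma_true) >= 1.0):
            raise ValueError("|gamma_true| must be < 1 (stationary AR(1))")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not (0.0 <= self.trend_pixel_fraction <= 1.0):
            raise ValueError("trend_pixel_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class DriverSpec:
    """Design of a synthetic driver table with planted effects.

    ``response_shape`` maps feature name -> planted effect on the target:
      ("flat",)                        no effect
      ("linear", slope)                slope * (x - midrange)
      ("step", threshold, low, high)   low below threshold, high above
      ("v_shape", vertex, slope)       slope * |x - vertex|
      ("plateau", threshold, slope)    slope * (x - threshold) below the
                                       threshold, constant 0 above it

    ``collinear_pairs`` are (driver_a, driver_b, r): driver_b is regenerated
    as an r-correlated copy of driver_a (same marginal mean/sd).

    ``derived`` gives multi-parent collinearity: feature -> ((parent, loading),
    ...); the feature is rebuilt on the standardized scale as the loaded sum of
    its parents plus residual noise (sum of squared loadings must stay < 1).
    This is how physically derived quantities (mean temperature from the
    extremes, PET from temperature/radiation/VPD, ...) are emulated, and it
    makes the derived member of a collinear group the one with the highest
    VIF, as it is in real driver sets.
    """

    feature_names: tuple[str, ...] = DRIVER_NAMES
    collinear_pairs: tuple[tuple[str, str, float], ...] = ()
    derived: Mapping[str, tuple[tuple[str, float], ...]] = field(default_factory=dict)
    response_shape: Mapping[str, tuple] = field(default_factory=dict)
    noise_sd: float = 0.1

    def __post_init__(self) -> None:
        for a, b, r in self.collinear_pairs:
            if not (-1.0 < r < 1.0):
                raise ValueError(f"correlation for ({a}, {b}) must be in (-1, 1)")
        for name, parents in self.derived.items():
            ss = sum(r * r for _, r in parents)
            if ss >= 1.0:
                raise ValueError(f"derived {name!r}: sum of squared loadings >= 1")
        for name in self.response_shape:
            if name not in self.feature_names:
                raise ValueError(f"response_shape for unknown feature {name!r}")


#: Physically motivated collinearity: mean temperature is built from the
#: daily extremes, potential evapotranspiration from temperature/radiation/
#: atmospheric demand, the aridity index from precipitation and PET, relative
#: humidity mirrors VPD and precipitation, and nighttime light co-locates
#: with grazing pressure in the warmer valleys.
PHYSICAL_DERIVED: dict[str, tuple[tuple[str, float], ...]] = {
    "TEM": (("TMX", 0.70), ("TMN", 0.70)),
    "PET": (("TMX", 0.68), ("SR", 0.60), ("VPD", 0.38)),
    "AI": (("PRE", 0.45), ("PET", -0.85)),
    "RHU": (("VPD", -0.93), ("PRE", 0.30)),
    "NTL": (("GI", 0.90), ("TMX", 0.35)),
}


def default_driver_spec() -> DriverSpec:
    """Driver table emulating the study conditions: strong planted effects of
    grazing intensity, soil moisture and vapor pressure deficit (plateau /
    step responses at their published-style thresholds), a weaker linear
    precipitation effect, and physically motivated collinearity."""
    return DriverSpec(
        derived=PHYSICAL_DERIVED,
        response_shape={
            "GI": ("plateau", 0.90, -1.0),
            "SM": ("step", 79.0, 1.0, 0.0),
            "VPD": ("step", 0.39, 0.6, 0.0),
            "PRE": ("linear", -0.001),
        },
        noise_sd=0.1,
    )


# ---------------------------------------------------------------------------
# land cover


def generate_landcover(spec: LandscapeSpec) -> tuple[np.ndarray, dict]:
    """Generate an annual stack of land-cover class maps.

    Returns ``(stack, truth)`` where ``stack`` has shape
    ``(n_years, n_rows, n_cols)`` of integer class codes and ``truth`` records
    the base class map, the boolean converted-pixel mask and each converted
    pixel's conversion year.  Exactly
    ``round(conversion_fraction * n_vegetated)`` vegetated pixels switch class
    once, at a uniformly drawn interior year; all other pixels are constant.
    """
    rng = np.random.default_rng(spec.seed)
    names = list(spec.class_fractions)
    probs = np.array([spec.class_fractions[n] for n in names], dtype=float)
    codes = np.array([CLASS_CODES[n] for n in names])
    base = rng.choice(codes, size=spec.n_pixels, p=probs / probs.sum())
    base = base.reshape(spec.n_rows, spec.n_cols)

    n_years = len(spec.years)
    stack = np.broadcast_to(base, (n_years, spec.n_rows, spec.n_cols)).copy()

    veg_rows, veg_cols = np.nonzero(base != CLASS_CODES["nodata"])
    n_veg = veg_rows.size
    n_convert = int(round(spec.conversion_fraction * n_veg))
    converted = np.zeros((spec.n_rows, spec.n_cols), dtype=bool)
    conversion_year = np.full((spec.n_rows, spec.n_cols), -1, dtype=int)

    if n_convert > 0:
        pick = rng.choice(n_veg, size=n_convert, replace=False)
        veg_codes = np.array([CLASS_CODES[c] for c in VEGETATED_CLASSES])
        for idx in pick:
            r, c = veg_rows[idx], veg_cols[idx]
            old = base[r, c]
            new = rng.choice(veg_codes[veg_codes != old])
            yr_idx = rng.integers(1, n_years)  # change takes effect at yr_idx
            stack[yr_idx:, r, c] = new
            converted[r, c] = True
            conversion_year[r, c] = spec.years[yr_idx]

    truth = {
        "base_class": base,
        "converted": converted,
        "conversion_year": conversion_year,
        "n_converted": n_convert,
    }
    return stack, truth


# ---------------------------------------------------------------------------
# climate-vegetation cube


def _climatology(offset: float, amplitude: float, month_of_year: np.ndarray) -> np.ndarray:
    # Peak in July (month 7), trough in January: northern-hemisphere cycle.
    return offset + amplitude * np.cos(2 * np.pi * (month_of_year - 7) / 12.0)


def _coefficient_drift(trend_spec: tuple, years_of_month: np.ndarray) -> np.ndarray:
    """Multiplicative factor applied to (alpha, beta) at each month."""
    kind = trend_spec[0]
    y = years_of_month.astype(float)
    y0 = y.min()
    if kind == "none":
        return np.ones_like(y)
    if kind == "linear":
        (slope,) = trend_spec[1:]
        return 1.0 + slope * (y - y0)
    if kind == "piecewise":
        break_year, s1, s2 = trend_spec[1:]
        f = 1.0 + s1 * (y - y0)
        f_at_break = 1.0 + s1 * (break_year - y0)
        after = y > break_year
        f[after] = f_at_break + s2 * (y[after] - break_year)
        return f
    raise ValueError(f"unknown trend_spec kind {kind!r}")


def generate_climate_veg(
    spec: LandscapeSpec, params: ProcessParams
) -> tuple[xr.Dataset, dict]:
    """Generate a monthly NDVI / temperature / precipitation cube.

    Temperature and precipitation are a fixed sinusoidal climatology plus
    unit-variance white-noise anomalies; the NDVI anomaly is evolved by the
    AR(1)-coupled recursion with ``params``' coefficients and added (scaled)
    to the NDVI climatology.  Returns the cube as an ``xarray.Dataset`` with
    dims ``(time, y, x)`` and a truth dict holding the per-pixel generating
    coefficients and the raw anomaly fields.
    """
    n_months = 12 * len(spec.years)
    if n_months < 60:
        raise ValueError("need at least 60 months (five years)")
    rng = np.random.default_rng(spec.seed + 1)

    months = np.arange(n_months)
    month_of_year = months % 12 + 1
    year_of_month = np.repeat(np.asarray(spec.years), 12)
    npx = spec.n_pixels

    t_anom = rng.standard_normal((n_months, npx))
    p_anom = rng.standard_normal((n_months, npx))
    eps = rng.normal(0.0, params.noise_sd, (n_months, npx))

    alpha_px = np.broadcast_to(np.asarray(params.alpha_true, dtype=float), (npx,))
    beta_px = np.broadcast_to(np.asarray(params.beta_true, dtype=float), (npx,))
    gamma_px = np.broadcast_to(np.asarray(params.gamma_true, dtype=float), (npx,))

    drift = _coefficient_drift(params.trend_spec, year_of_month)
    if np.any(drift <= 0):
        raise ValueError("trend_spec drives the coupling factor non-positive")
    lo, hi = params.coupling_heterogeneity
    base_scale = rng.uniform(lo, hi, npx)
    trended = np.zeros(npx, dtype=bool)
    if params.trend_spec[0] != "none" and params.trend_pixel_fraction > 0:
        n_trend = int(round(params.trend_pixel_fraction * npx))
        trended[rng.choice(npx, size=n_trend, replace=False)] = True
    # Total coupling factor per month and pixel: the per-pixel baseline scale
    # times the drift (drifting pixels only).
    factor = base_scale[None, :] * np.where(trended[None, :], drift[:, None], 1.0)
    alpha_t = alpha_px[None, :] * factor
    beta_t = beta_px[None, :] * factor

    # Variance compensation: the residual sd is inflated so the total anomaly
    # variance is the same at every coupling level (see the class docstring).
    signal_var = alpha_px**2 + beta_px**2
    c2 = float(np.max(factor) ** 2)
    eps_sd = np.sqrt(params.noise_sd**2 + (c2 - factor**2) * signal_var[None, :])
    eps = eps * (eps_sd / params.noise_sd)

    n_anom = np.zeros((n_months, npx))
    n_anom[0] = eps[0]
    for t in range(1, n_months):
        n_anom[t] = (
            alpha_t[t] * t_anom[t] + beta_t[t] * p_anom[t]
            + gamma_px * n_anom[t - 1] + eps[t]
        )

    amps = params.seasonal_amplitudes
    # Fixed spatial climate structure: temperature graded along rows,
    # precipitation along columns (broadcast over the flattened pixel axis).
    rows = np.repeat(np.linspace(-1.0, 1.0, spec.n_rows), spec.n_cols)
    cols = np.tile(np.linspace(-1.0, 1.0, spec.n_cols), spec.n_rows)
    t_offset = params.spatial_gradient.get("temperature", 0.0) * rows
    p_offset = params.spatial_gradient.get("precipitation", 0.0) * cols

    ndvi = _climatology(*amps["ndvi"], month_of_year)[:, None] + (
        params.ndvi_anomaly_scale * n_anom
    )
    temp = (
        _climatology(*amps["temperature"], month_of_year)[:, None]
        + t_offset[None, :] + t_anom
    )
    # Precipitation anomalies scaled to a realistic monthly spread, floored
    # at zero (physical constraint; clipping is rare at these settings).
    pre = (
        _climatology(*amps["precipitation"], month_of_year)[:, None]
        + p_offset[None, :] + 8.0 * p_anom
    )
    pre = np.clip(pre, 0.0, None)

    shape = (n_months, spec.n_rows, spec.n_cols)
    time = pd.period_range(
        start=f"{spec.years[0]}-01", periods=n_months, freq="M"
    ).to_timestamp()
    coords = {
        "time": time,
        "y": np.arange(spec.n_rows),
        "x": np.arange(spec.n_cols),
    }
    cube = xr.Dataset(
        {
            "ndvi": (("time", "y", "x"), ndvi.reshape(shape)),
            "temperature": (("time", "y", "x"), temp.reshape(shape)),
            "precipitation": (("time", "y", "x"), pre.reshape(shape)),
        },
        coords=coords,
    )
    truth = {
        "alpha_true": params.alpha_true,
        "beta_true": params.beta_true,
        "gamma_true": params.gamma_true,
        "coefficient_drift": drift,
        "trended_pixels": trended.reshape(spec.n_rows, spec.n_cols),
        "coupling_scale": base_scale.reshape(spec.n_rows, spec.n_cols),
        "ndvi_anomaly": n_anom,
        "temperature_anomaly": t_anom,
        "precipitation_anomaly": p_anom,
        "trend_spec": params.trend_spec,
    }
    return cube, truth


# ---------------------------------------------------------------------------
# annual vulnerability series


def generate_vi_series(
    pattern: tuple,
    n_years: int,
    noise_sd: float,
    seed: int,
    start_year: int = 1985,
    base_level: float = 1.0,
    min_segment: int = 2,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Generate an annual vulnerability series with a planted trend.

    ``pattern`` is ``("none",)``, ``("linear", slope)`` or
    ``("piecewise", break_index, slope1, slope2)`` with the break given as a
    0-based year index.  A planted break leaving fewer than ``min_segment``
    points on either side is rejected (2 points is the bare minimum needed to
    define a segment slope; near-boundary breaks are legitimate fixtures for
    the boundary re-evaluation rule).  Returns ``(years, values, truth)``.
    """
    if n_years < 11:
        raise ValueError("need n_years >= 11 (two 5-year segments plus break)")
    rng = np.random.default_rng(seed)
    t = np.arange(n_years, dtype=float)
    years = start_year + np.arange(n_years)

    kind = pattern[0]
    if kind == "none":
        signal = np.zeros(n_years)
        truth = {"type": "none", "break_index": None, "slopes": (0.0,)}
    elif kind == "linear":
        (slope,) = pattern[1:]
        signal = slope * t
        truth = {"type": "linear", "break_index": None, "slopes": (slope,)}
    elif kind == "piecewise":
        break_index, s1, s2 = pattern[1:]
        if not (min_segment - 1 <= break_index <= n_years - min_segment):
            raise ValueError("break too close to a series end")
        signal = np.where(
            t <= break_index,
            s1 * t,
            s1 * break_index + s2 * (t - break_index),
        )
        truth = {
            "type": "piecewise",
            "break_index": int(break_index),
            "break_year": int(years[break_index]),
            "slopes": (s1, s2),
        }
    else:
        raise ValueError(f"unknown pattern kind {kind!r}")

    values = base_level + signal + rng.normal(0.0, noise_sd, n_years)
    return years, values, truth


# ---------------------------------------------------------------------------
# driver tables


def _planted_effect(x: np.ndarray, shape: tuple, lo: float, hi: float) -> np.ndarray:
    kind = shape[0]
    if kind == "flat":
        return np.zeros_like(x)
    if kind == "linear":
        (slope,) = shape[1:]
        return slope * (x - 0.5 * (lo + hi))
    if kind == "step":
        threshold, low, high = shape[1:]
        _check_inside(threshold, lo, hi)
        return np.where(x < threshold, low, high)
    if kind == "v_shape":
        vertex, slope = shape[1:]
        _check_inside(vertex, lo, hi)
        return slope * np.abs(x - vertex)
    if kind == "plateau":
        threshold, slope = shape[1:]
        _check_inside(threshold, lo, hi)
        return np.where(x < threshold, slope * (x - threshold), 0.0)
    raise ValueError(f"unknown response shape {kind!r}")


def _check_inside(value: float, lo: float, hi: float) -> None:
    if not (lo < value < hi):
        raise ValueError(f"planted threshold {value} outside feature range ({lo}, {hi})")


def generate_driver_table(
    spec: DriverSpec, n_samples: int, seed: int
) -> tuple[pd.DataFrame, np.ndarray, dict]:
    """Generate a driver feature table and target with planted effects.

    Features are sampled uniformly on their realistic ranges; collinear pairs
    are enforced by regenerating the second member as an r-correlated copy of
    the first (matching marginal mean and sd); the target is the sum of the
    planted per-feature effects plus Gaussian noise.  Returns
    ``(features, target, truth)``.
    """
    if n_samples < 500:
        raise ValueError("need n_samples >= 500")
    rng = np.random.default_rng(seed)

    cols: dict[str, np.ndarray] = {}
    for name in spec.feature_names:
        lo, hi = DRIVER_RANGES[name]
        cols[name] = rng.uniform(lo, hi, n_samples)

    def _z(v: np.ndarray) -> np.ndarray:
        return (v - v.mean()) / v.std()

    # Multi-parent derived features, in declaration order so chains
    # (e.g. AI built on PET built on TMX) resolve.
    for name, parents in spec.derived.items():
        lo, hi = DRIVER_RANGES[name]
        mean, sd = 0.5 * (lo + hi), (hi - lo) / np.sqrt(12.0)
        ss = sum(r * r for _, r in parents)
        z = sum(r * _z(cols[p]) for p, r in parents)
        z = z + np.sqrt(1.0 - ss) * rng.standard_normal(n_samples)
        cols[name] = mean + sd * z

    for a, b, r in spec.collinear_pairs:
        lo, hi = DRIVER_RANGES[b]
        mean_b = 0.5 * (lo + hi)
        sd_b = (hi - lo) / np.sqrt(12.0)
        za = (cols[a] - cols[a].mean()) / cols[a].std()
        cols[b] = mean_b + sd_b * (r * za + np.sqrt(1 - r * r) * rng.standard_normal(n_samples))

    features = pd.DataFrame(cols, columns=list(spec.feature_names))

    target = np.zeros(n_samples)
    effects: dict[str, tuple] = {}
    for name in spec.feature_names:
        shape = spec.response_shape.get(name, ("flat",))
        lo, hi = DRIVER_RANGES[name]
        target += _planted_effect(features[name].to_numpy(), shape, lo, hi)
        effects[name] = shape
    target = target + rng.normal(0.0, spec.noise_sd, n_samples)

    truth = {
        "effects": effects,
        "thresholds": {
            name: shape[1]
            for name, shape in effects.items()
            if shape[0] in ("step", "v_shape", "plateau")
        },
        "collinear_pairs": spec.collinear_pairs,
        "noise_sd": spec.noise_sd,
    }
    return features, target, truth


def truth_to_json(truth: Mapping) -> dict:
    """Machine-readable sidecar form of a truth dict (numpy -> lists)."""
    out = {}
    for k, v in truth.items():
        if isinstance(v, np.ndarray):
            out[k] = v.tolist()
        elif isinstance(v, Mapping):
            out[k] = truth_to_json(v)
        elif isinstance(v, tuple):
            out[k] = list(v)
        else:
            out[k] = v
    return out
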