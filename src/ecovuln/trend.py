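"""Per-pixel classification of annual vulnerability series into regimes.

Three candidate descriptions of each series are fit — a simple linear trend,
a continuous two-segment piecewise-linear trend, and a Pettitt change point
(scored through a two-mean step model) — and the classification cascade
picks among them by significance and AIC, with a boundary rule that demotes
turning points found within five years of either series end.

Trend taxonomy: no_trend, linear_increase, linear_decrease, abrupt; abrupt
pixels carry a turning year and a turning pattern (I_D = significant
increase then significant decrease, D_I = the reverse).
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

NO_TREND = "no_trend"
LINEAR_INCREASE = "linear_increase"
LINEAR_DECREASE = "linear_decrease"
ABRUPT = "abrupt"

PATTERN_ID = "I_D"
PATTERN_DI = "D_I"
PATTERN_NONE = "none"

#: Default 5-year turning-year bins (left-closed; the last bin is closed).
DEFAULT_TURNING_EDGES = (1990, 1995, 2000, 2005, 2010, 2015)


@dataclass
class TrendClassification:
    pixel_id: int | None
    cv_percent: float
    cv_bin: str
    trend_type: str
    turning_pattern: str = PATTERN_NONE
    turning_year: int | None = None
    model_chosen: str = "none"
    slopes: tuple = ()
    p_values: dict = field(default_factory=dict)
    aic: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# per-series statistics


def coefficient_of_variation(series: np.ndarray, eps: float = 1e-12) -> tuple[float, str]:
    """CV in percent (sample sd over mean) and its bin: <20, 20-30, >30.

    A series with mean at or below ``eps`` is flagged with bin ``"invalid"``.
    """
    x = np.asarray(series, dtype=float)
    mean = x.mean()
    if not np.isfinite(mean) or mean <= eps:
        return np.nan, "invalid"
    cv = 100.0 * x.std(ddof=1) / mean
    if cv < 20.0:
        return cv, "<20"
    if cv <= 30.0:
        return cv, "20-30"
    return cv, ">30"


def _aic_from_rss(rss: float, n: int, k: int, eps: float = 1e-300) -> float:
    return n * np.log(max(rss, eps) / n) + 2 * k


def fit_linear(series: np.ndarray, years: np.ndarray | None = None) -> dict:
    """OLS trend of the series on year: slope, t-test p-value, and AIC
    (Gaussian likelihood, k = 3 for intercept, slope, variance)."""
    y = np.asarray(series, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 points")
    x = np.arange(n, dtype=float) if years is None else np.asarray(years, dtype=float)
    if np.ptp(y) == 0.0:
        return {"slope": 0.0, "p_value": 1.0,
                "aic": _aic_from_rss(0.0, n, 3), "rss": 0.0}
    res = stats.linregress(x, y)
    resid = y - (res.intercept + res.slope * x)
    rss = float(resid @ resid)
    return {"slope": float(res.slope), "p_value": float(res.pvalue),
            "aic": _aic_from_rss(rss, n, 3), "rss": rss}


def fit_piecewise(
    series: np.ndarray,
    years: np.ndarray | None = None,
    min_segment: int = 5,
) -> dict:
    """Continuous two-segment linear fit by exhaustive break search.

    Candidate breaks are the interior years giving each segment at least
    ``min_segment`` points (the knot year belongs to both segments); the
    break minimizing RSS wins.  Per-segment slope p-values come from separate
    OLS t-tests on each segment; AIC uses k = 5 (two slopes, intercept,
    break, variance).  Too-short series come back ``{"available": False}``.
    """
    y = np.asarray(series, dtype=float)
    n = len(y)
    if n < 2 * min_segment + 1:
        return {"available": False}
    x = np.arange(n, dtype=float) if years is None else np.asarray(years, dtype=float)

    best = None
    for k_idx in range(min_segment - 1, n - min_segment):
        hinge = np.maximum(x - x[k_idx], 0.0)
        X = np.column_stack([np.ones(n), x, hinge])
        coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        if rank < 3:
            continue
        resid = y - X @ coef
        rss = float(resid @ resid)
        if best is None or rss < best["rss"]:
            best = {"rss": rss, "k_idx": k_idx, "coef": coef}
    if best is None:
        return {"available": False}

    k_idx = best["k_idx"]
    slope1 = float(best["coef"][1])
    slope2 = float(best["coef"][1] + best["coef"][2])
    p1 = _segment_slope_p(x[: k_idx + 1], y[: k_idx + 1])
    p2 = _segment_slope_p(x[k_idx:], y[k_idx:])
    return {
        "available": True,
        "break_index": k_idx,
        "break_x": float(x[k_idx]),
        "slopes": (slope1, slope2),
        "p_values": (p1, p2),
        "rss": best["rss"],
        "aic": _aic_from_rss(best["rss"], n, 5),
    }


def _segment_slope_p(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 3 or np.ptp(y) == 0.0:
        return 1.0
    return float(stats.linregress(x, y).pvalue)


@functools.lru_cache(maxsize=16)
def _pettitt_null_table(n: int, n_sim: int = 4000) -> np.ndarray:
    """Sorted Monte Carlo null distribution of the Pettitt K statistic.

    K is a rank statistic, so its null distribution is distribution-free;
    simulating random permutations of ranks gives an (arbitrarily accurate)
    exact reference.  Seeded by the series length, so results are
    deterministic and the table is computed once per length.
    """
    rng = np.random.default_rng(97 + n)
    ks = np.empty(n_sim)
    for s in range(n_sim):
        x = rng.permutation(n).astype(float)
        sign = np.sign(np.subtract.outer(x, x))
        u = np.array([np.sum(sign[t + 1 :, : t + 1]) for t in range(n - 1)])
        ks[s] = np.max(np.abs(u))
    ks.sort()
    return ks


def pettitt_test(series: np.ndarray, p_method: str = "auto") -> dict:
    """Pettitt rank-based change-point test.

    U_t = sum_{i<=t} sum_{j>t} sign(x_j - x_i); the statistic K = max|U_t|
    locates the change point.  ``p_method`` selects the significance
    computation: ``"exact"`` uses a seeded Monte Carlo table of the
    distribution-free null (calibrated at any n), ``"asymptotic"`` the
    classical approximation p ~ 2 exp(-6 K^2 / (n^3 + n^2)) (conservative for
    short series), and ``"auto"`` (default) the exact table for n <= 100 and
    the approximation beyond.  For AIC comparability a two-mean step model
    split at the change point is scored with k = 4.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 8:
        raise ValueError("need at least 8 points")
    sign = np.sign(np.subtract.outer(x, x))  # sign[i, j] = sign(x_i - x_j)
    u = np.empty(n - 1)
    for t in range(n - 1):
        u[t] = np.sum(sign[t + 1 :, : t + 1])  # sum sign(x_j - x_i), i<=t<j
    k_stat = float(np.max(np.abs(u)))
    change_index = int(np.argmax(np.abs(u)))  # last index of the first segment

    if p_method == "auto":
        p_method = "exact" if n <= 100 else "asymptotic"
    if p_method == "exact":
        table = _pettitt_null_table(n)
        # Upper-tail probability with the add-one permutation correction.
        exceed = len(table) - np.searchsorted(table, k_stat, side="left")
        p = (1.0 + exceed) / (1.0 + len(table))
    elif p_method == "asymptotic":
        p = min(1.0, 2.0 * np.exp(-6.0 * k_stat**2 / (n**3 + n**2)))
    else:
        raise ValueError("p_method must be 'auto', 'exact' or 'asymptotic'")

    left = x[: change_index + 1]
    right = x[change_index + 1 :]
    rss = float(np.sum((left - left.mean()) ** 2) + np.sum((right - right.mean()) ** 2))
    return {
        "k_statistic": k_stat,
        "change_index": change_index,
        "u": u,
        "p_value": p,
        "rss": rss,
        "aic": _aic_from_rss(rss, n, 4),
    }


# ---------------------------------------------------------------------------
# classification cascade

#: Tie-break order: the simpler model wins at equal AIC.
_SIMPLICITY = {"linear": 0, "piecewise": 1, "pettitt": 2}


def classify_trend(
    series: np.ndarray,
    first_year: int,
    last_year: int,
    alpha: float = 0.05,
    min_segment: int = 5,
    boundary_years: int = 5,
    pixel_id: int | None = None,
) -> TrendClassification:
    """Classify one annual series into the regime taxonomy.

    Cascade: fit all three candidates; none significant -> no_trend; exactly
    one significant -> that model; several -> lowest AIC (ties to the simpler
    model).  An abrupt winner whose turning year falls within
    ``boundary_years`` of either series end (inclusive) is re-evaluated with
    a simple linear fit (significant -> linear by slope sign, else no_trend).
    Abrupt patterns are labeled I_D / D_I from significant opposite-signed
    segment slopes; significant same-signed segments fall back to the linear
    re-fit label.
    """
    y = np.asarray(series, dtype=float)
    n = len(y)
    years = np.arange(first_year, first_year + n)
    if last_year != first_year + n - 1:
        raise ValueError("series length inconsistent with year span")
    cv, cv_bin = coefficient_of_variation(y)
    if not np.isfinite(y).all():
        return TrendClassification(pixel_id, np.nan, "invalid", "nodata")

    lin = fit_linear(y, years)
    pw = fit_piecewise(y, years, min_segment=min_segment)
    pt = pettitt_test(y)

    p_values = {"linear": lin["p_value"], "pettitt": pt["p_value"]}
    aics = {"linear": lin["aic"], "pettitt": pt["aic"]}
    significant = {"linear": lin["p_value"] < alpha, "pettitt": pt["p_value"] < alpha}
    if pw.get("available"):
        p_values["piecewise"] = max(pw["p_values"])
        aics["piecewise"] = pw["aic"]
        significant["piecewise"] = all(p < alpha for p in pw["p_values"])

    winners = [m for m, sig in significant.items() if sig]
    common = dict(pixel_id=pixel_id, cv_percent=cv, cv_bin=cv_bin,
                  p_values=p_values, aic=aics)

    if not winners:
        return TrendClassification(trend_type=NO_TREND, **common)

    winners.sort(key=lambda m: (aics[m], _SIMPLICITY[m]))
    model = winners[0]

    if model == "linear":
        return _linear_label(lin, common, model_chosen="linear")

    if model == "piecewise":
        turning_year = int(pw["break_x"])
        seg_slopes = pw["slopes"]
        seg_ps = pw["p_values"]
    else:  # pettitt: side slopes from per-segment OLS at the change point
        ci = pt["change_index"]
        turning_year = int(years[ci])
        s1 = stats.linregress(years[: ci + 1], y[: ci + 1]) if ci >= 2 else None
        s2 = stats.linregress(years[ci:], y[ci:]) if n - ci >= 3 else None
        seg_slopes = (
            s1.slope if s1 else 0.0,
            s2.slope if s2 else 0.0,
        )
        seg_ps = (s1.pvalue if s1 else 1.0, s2.pvalue if s2 else 1.0)

    near_start = turning_year <= first_year + boundary_years
    near_end = turning_year >= last_year - boundary_years
    if near_start or near_end:
        if lin["p_value"] < alpha:
            return _linear_label(lin, common, model_chosen="linear")
        return TrendClassification(trend_type=NO_TREND, model_chosen="none", **common)

    both_sig = all(p < alpha for p in seg_ps)
    opposite = seg_slopes[0] * seg_slopes[1] < 0
    if both_sig and opposite:
        pattern = PATTERN_ID if seg_slopes[0] > 0 else PATTERN_DI
        return TrendClassification(
            trend_type=ABRUPT, turning_pattern=pattern, turning_year=turning_year,
            model_chosen=model, slopes=seg_slopes, **common,
        )
    # An abrupt regime is defined by two significant opposite-signed trends;
    # anything weaker (same-sign segments, or a mean shift without
    # significant side trends) is re-evaluated with the simple linear fit.
    if lin["p_value"] < alpha:
        return _linear_label(lin, common, model_chosen="linear")
    return TrendClassification(trend_type=NO_TREND, model_chosen="none", **common)


def _linear_label(lin: dict, common: dict, model_chosen: str) -> TrendClassification:
    trend = LINEAR_INCREASE if lin["slope"] > 0 else LINEAR_DECREASE
    return TrendClassification(
        trend_type=trend, model_chosen=model_chosen, slopes=(lin["slope"],), **common
    )


def bin_turning_years(
    classifications: list[TrendClassification],
    edges: tuple[int, ...] = DEFAULT_TURNING_EDGES,
) -> pd.DataFrame:
    """Histogram of abrupt pixels' turning years in 5-year intervals.

    Bins are left-closed; the final bin includes its right edge
    ([1990, 1995), ..., [2010, 2015] by default).  Returns a table with the
    bin label, count, and percent of abrupt pixels.
    """
    years = [c.turning_year for c in classifications
             if c.trend_type == ABRUPT and c.turning_year is not None]
    labels = [f"{edges[i]}-{edges[i + 1]}" for i in range(len(edges) - 1)]
    counts = dict.fromkeys(labels, 0)
    for yr in years:
        for i in range(len(edges) - 1):
            last = i == len(edges) - 2
            if edges[i] <= yr < edges[i + 1] or (last and yr == edges[i + 1]):
                counts[labels[i]] += 1
                break
    total = max(len(years), 1)
    return pd.DataFrame({
        "bin": labels,
        "count": [counts[lb] for lb in labels],
        "percent_of_abrupt": [100.0 * counts[lb] / total for lb in labels],
    })
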