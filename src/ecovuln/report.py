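"""End-to-end pipeline orchestration and area-percentage summary tables.

``run_pipeline`` drives synthetic generation -> preprocessing -> window
vulnerability -> trend classification -> ecosystem stratification -> driver
analysis and writes every artifact plus a reproducibility manifest.
``summarize_areas`` emits the breakdown tables (by CV bin, trend type,
turning pattern, turning period; overall and per stable ecosystem class);
each breakdown sums to 100% of its denominator, and fractions of the total
valid area are emitted alongside.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as eio
from .drivers import DEFAULT_GRID, SMALL_GRID, per_ecosystem_analysis, run_driver_analysis
from .preprocessing import EcosystemMask, stable_pixel_mask
from .synthetic import (
    CODE_CLASSES,
    DriverSpec,
    LandscapeSpec,
    ProcessParams,
    default_driver_spec,
    generate_climate_veg,
    generate_driver_table,
    generate_landcover,
    truth_to_json,
)
from .trend import ABRUPT, DEFAULT_TURNING_EDGES, TrendClassification, bin_turning_years, classify_trend
from .vulnerability import build_vi_series, vi_series_to_frame

logger = logging.getLogger(__name__)

TREND_CATEGORIES = ("no_trend", "linear_increase", "linear_decrease", "abrupt")
CV_CATEGORIES = ("<20", "20-30", ">30", "invalid")
PATTERN_CATEGORIES = ("I_D", "D_I")


@dataclass
class PipelineConfig:
    """Configuration of a full synthetic-landscape run."""

    n_rows: int = 20
    n_cols: int = 20
    first_year: int = 1983
    last_year: int = 2022
    conversion_fraction: float = 0.1
    seed: int = 0
    window_length: int = 5
    window_step: int = 1
    normalization_scope: str = "window"
    significance_level: float = 0.05
    min_segment: int = 5
    boundary_years: int = 5
    turning_edges: tuple[int, ...] = DEFAULT_TURNING_EDGES
    #: Drift of the climate-coupling coefficients over calendar years; this is
    #: what plants a vulnerability trend (see ProcessParams.trend_spec).
    trend_spec: tuple = ("none",)
    trend_pixel_fraction: float = 0.6
    #: Per-pixel baseline coupling spread: the landscape carries a stable
    #: cross-pixel gradient in how strongly NDVI tracks climate, which keeps
    #: the per-window min-max frame anchored.
    coupling_heterogeneity: tuple[float, float] = (0.5, 1.0)
    driver_grid: str = "small"  # "small" or "default"
    vif_cutoff: float = 10.0
    split_fraction: float = 0.8
    pdp_mode: str = "at_means"
    driver_samples_per_pixel_year: bool = True
    min_class_samples: int = 500
    output_dir: str = "ecovuln_run"

    def __post_init__(self) -> None:
        if not (0.0 < self.significance_level < 1.0):
            raise ValueError("significance level must be in (0, 1)")
        if list(self.turning_edges) != sorted(set(self.turning_edges)):
            raise ValueError("bin edges must be strictly increasing")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        if "trend_spec" in data:
            data["trend_spec"] = tuple(data["trend_spec"])
        if "turning_edges" in data:
            data["turning_edges"] = tuple(data["turning_edges"])
        if "coupling_heterogeneity" in data:
            data["coupling_heterogeneity"] = tuple(data["coupling_heterogeneity"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["trend_spec"] = list(self.trend_spec)
        d["turning_edges"] = list(self.turning_edges)
        d["coupling_heterogeneity"] = list(self.coupling_heterogeneity)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _percent_table(
    labels: np.ndarray, categories: tuple[str, ...], denominator: int, total: int
) -> pd.DataFrame:
    counts = pd.Series(labels).value_counts()
    rows = []
    for cat in categories:
        c = int(counts.get(cat, 0))
        rows.append({
            "category": cat,
            "count": c,
            "percent": 100.0 * c / denominator if denominator else 0.0,
            "percent_of_total": 100.0 * c / total if total else 0.0,
        })
    return pd.DataFrame(rows)


def summarize_areas(
    classifications: list[TrendClassification],
    mask: EcosystemMask,
    turning_edges: tuple[int, ...] = DEFAULT_TURNING_EDGES,
) -> dict[str, pd.DataFrame]:
    """Area-percentage breakdowns of the classified landscape.

    ``classifications`` must carry pixel_ids indexing the flattened mask.
    Returned tables: ``trend_type`` and ``cv_bin`` over all classified pixels,
    ``turning_pattern`` and ``turning_bin`` over abrupt pixels, and
    ``by_ecosystem`` (trend types per stable class, with percent of the total
    classified area alongside percent of the class's own area).
    ``percent`` always sums to 100 over its denominator.
    """
    if not classifications:
        raise ValueError("no classifications given")
    flat = mask.labels.ravel()
    for c in classifications:
        if c.pixel_id is None or not (0 <= c.pixel_id < flat.size):
            raise ValueError("classification pixel_ids do not match mask geometry")

    trend_labels = np.array([c.trend_type for c in classifications])
    cv_labels = np.array([c.cv_bin for c in classifications])
    total = len(classifications)

    tables: dict[str, pd.DataFrame] = {}
    tables["trend_type"] = _percent_table(trend_labels, TREND_CATEGORIES, total, total)
    tables["cv_bin"] = _percent_table(cv_labels, CV_CATEGORIES, total, total)

    abrupt = [c for c in classifications if c.trend_type == ABRUPT]
    n_abrupt = len(abrupt)
    pattern_labels = np.array([c.turning_pattern for c in abrupt])
    tables["turning_pattern"] = _percent_table(
        pattern_labels, PATTERN_CATEGORIES, max(n_abrupt, 1), total
    )
    tbin = bin_turning_years(abrupt, edges=turning_edges)
    tbin["percent_of_total"] = 100.0 * tbin["count"] / total
    tables["turning_bin"] = tbin

    rows = []
    for c in classifications:
        cls = mask.class_name(int(flat[c.pixel_id]))
        rows.append({"class": cls, "trend_type": c.trend_type})
    eco = pd.DataFrame(rows)
    out = []
    for cls, grp in eco.groupby("class"):
        n_cls = len(grp)
        counts = grp["trend_type"].value_counts()
        for cat in TREND_CATEGORIES:
            c = int(counts.get(cat, 0))
            out.append({
                "class": cls, "category": cat, "count": c,
                "percent": 100.0 * c / n_cls,
                "percent_of_total": 100.0 * c / total,
            })
    tables["by_ecosystem"] = pd.DataFrame(out)
    return tables


def run_pipeline(config: PipelineConfig, write_outputs: bool = True) -> dict:
    """Execute the full pipeline on a synthetic landscape.

    Returns a result bundle with the land-cover stack, stable-pixel mask,
    annual vulnerability dataset, per-pixel trend classifications, summary
    tables, driver analyses (pooled and per ecosystem), and the run manifest.
    Rerunning with an identical config is bit-identical for the deterministic
    stages.
    """
    years = tuple(range(config.first_year, config.last_year + 1))
    spec = LandscapeSpec(
        n_rows=config.n_rows, n_cols=config.n_cols,
        conversion_fraction=config.conversion_fraction,
        years=years, seed=config.seed,
    )
    params = ProcessParams(
        trend_spec=config.trend_spec,
        trend_pixel_fraction=config.trend_pixel_fraction,
        coupling_heterogeneity=config.coupling_heterogeneity,
    )

    logger.info("stage simulate: %d x %d pixels, %d years", spec.n_rows, spec.n_cols, len(years))
    landcover, lc_truth = generate_landcover(spec)
    cube, cube_truth = generate_climate_veg(spec, params)

    logger.info("stage preprocess: stable-pixel mask")
    mask = stable_pixel_mask(landcover)

    logger.info("stage vulnerability: %d monthly layers", cube.sizes["time"])
    vi_ds = build_vi_series(
        cube,
        window_length=config.window_length,
        window_step=config.window_step,
        normalization_scope=config.normalization_scope,
    )
    vi_years = vi_ds["year"].values
    vi = vi_ds["VI"].values.reshape(len(vi_years), -1)

    logger.info("stage trend: classifying stable pixels")
    stable_flat = mask.any_stable.ravel()
    classifications: list[TrendClassification] = []
    for pid in np.nonzero(stable_flat)[0]:
        series = vi[:, pid]
        if not np.isfinite(series).all():
            continue
        classifications.append(
            classify_trend(
                series, int(vi_years[0]), int(vi_years[-1]),
                alpha=config.significance_level,
                min_segment=config.min_segment,
                boundary_years=config.boundary_years,
                pixel_id=int(pid),
            )
        )
    if not classifications:
        raise RuntimeError("stage trend: no valid classified pixels")

    tables = summarize_areas(classifications, mask, config.turning_edges)

    logger.info("stage drivers: pooled and per-ecosystem analysis")
    grid = SMALL_GRID if config.driver_grid == "small" else DEFAULT_GRID
    n_years_annual = len(vi_years)
    stable_ids = np.array([c.pixel_id for c in classifications])
    n_samples = max(500, len(stable_ids) * n_years_annual)
    driver_spec = default_driver_spec()
    features, target, driver_truth = generate_driver_table(
        driver_spec, n_samples=n_samples, seed=config.seed + 7
    )
    pooled = run_driver_analysis(
        features, target,
        vif_cutoff=config.vif_cutoff, split_fraction=config.split_fraction,
        grid=grid, seed=config.seed, pdp_mode=config.pdp_mode,
    )

    flat_labels = mask.labels.ravel()
    sample_pixel = stable_ids[np.arange(len(features)) % len(stable_ids)]
    sample_class = np.array([CODE_CLASSES[int(flat_labels[p])] for p in sample_pixel])
    class_tables = {
        cls: (features[sample_class == cls], target[sample_class == cls])
        for cls in np.unique(sample_class)
    }
    per_class = per_ecosystem_analysis(
        class_tables, min_samples=config.min_class_samples,
        vif_cutoff=config.vif_cutoff, split_fraction=config.split_fraction,
        grid=grid, seed=config.seed, pdp_mode=config.pdp_mode,
    )

    manifest = _manifest(config)
    bundle = {
        "landcover": landcover,
        "landcover_truth": lc_truth,
        "cube_truth": cube_truth,
        "mask": mask,
        "vi_dataset": vi_ds,
        "classifications": classifications,
        "tables": tables,
        "driver_analysis": pooled,
        "driver_truth": driver_truth,
        "per_ecosystem": per_class,
        "manifest": manifest,
    }
    if write_outputs:
        _write_bundle(bundle, config)
    return bundle


def _manifest(config: PipelineConfig) -> dict:
    import sklearn
    import xgboost

    return {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "xgboost": xgboost.__version__,
            "scikit-learn": sklearn.__version__,
        },
    }


def _write_bundle(bundle: dict, config: PipelineConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    eio.write_raster(bundle["landcover"], out / "landcover.tif",
                     code_table={v: k for k, v in CODE_CLASSES.items()})
    eio.write_raster(bundle["mask"].labels, out / "stable_mask.tif",
                     code_table={str(k): v for k, v in CODE_CLASSES.items()} | {"255": "unstable"})
    eio.write_cube_netcdf(bundle["vi_dataset"][["EI", "SI", "RI", "VI"]].rename(
        {"year": "time"}), out / "vi_series.nc")
    eio.write_table(vi_series_to_frame(bundle["vi_dataset"]), out / "vi_series.csv")

    cls_rows = []
    for c in bundle["classifications"]:
        cls_rows.append({
            "pixel_id": c.pixel_id, "cv_percent": c.cv_percent, "cv_bin": c.cv_bin,
            "trend_type": c.trend_type, "turning_pattern": c.turning_pattern,
            "turning_year": c.turning_year, "model_chosen": c.model_chosen,
        })
    eio.write_table(pd.DataFrame(cls_rows), out / "trend_classification.csv")

    trend_map = np.zeros(bundle["mask"].labels.size, dtype=np.uint8)
    for c in bundle["classifications"]:
        trend_map[c.pixel_id] = eio.TREND_CODES[c.trend_type]
    eio.write_raster(trend_map.reshape(bundle["mask"].labels.shape),
                     out / "trend_type.tif", code_table=eio.TREND_CODES)

    for name, table in bundle["tables"].items():
        eio.write_table(table, out / f"summary_{name}.csv")

    da = bundle["driver_analysis"]
    eio.write_json({"metrics": da.model_metrics,
                    "retained_features": da.retained_features,
                    "base_value": da.base_value}, out / "driver_metrics.json")
    eio.write_table(
        da.importance_percent.rename_axis("feature").reset_index(name="importance_percent"),
        out / "driver_importance.csv")
    pdp_rows = []
    for feat, (gx, gy) in da.pdp_curves.items():
        for xv, yv in zip(gx, gy):
            pdp_rows.append({"feature": feat, "grid": xv, "response": yv})
    eio.write_table(pd.DataFrame(pdp_rows), out / "driver_pdp.csv")
    eio.write_json({k: v for k, v in da.thresholds.items()}, out / "driver_thresholds.json")
    eio.write_json(truth_to_json(bundle["driver_truth"]), out / "driver_truth.json")
    eio.write_json(bundle["manifest"], out / "manifest.json")
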