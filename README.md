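# ecovuln

Sliding-window ecosystem vulnerability analysis for gridded vegetation and
climate records: a per-pixel exposure–sensitivity–resilience vulnerability
index, interannual regime-shift classification, and driver-threshold
attribution — with a synthetic-data module that plants known ground truth so
every stage is testable without external downloads.

## The problem

Terrestrial ecosystems rarely degrade or recover along straight lines.
Long NDVI records over climatically stressed regions show abrupt reversals —
decades of improvement that tip into renewed decline — and the drivers
(grazing pressure, soil moisture, atmospheric water demand) act through
thresholds rather than linear dose–response. `ecovuln` implements an
analysis chain for this problem, aimed at researchers working with monthly
NDVI / temperature / precipitation cubes and annual driver covariates.

## The model

Within each five-year window (one-year step; a 1983–2022 record gives 36
windows with center years 1985–2020), monthly series are deseasonalized and
z-scored per pixel, and the standardized NDVI anomaly is regressed on the
climate anomalies and its own lag:

    NDVI_t = α·Temp_t + β·Pre_t + γ·NDVI_{t−1} + ε_t

The coefficients are min-max normalized across pixels within the window and
combined into

    EI = α + β                 (exposure)
    SI = α·T_norm + β·P_norm   (sensitivity; T_norm, P_norm are normalized
                                window-mean temperature and precipitation)
    RI = 1 − γ                 (resilience)
    VI = EI·SI / (1 + RI)      (vulnerability)

Each pixel's annual VI series is then classified into **no trend / linear /
abrupt** regimes by a cascade of a linear fit, a continuous two-segment
piecewise fit, and the Pettitt change-point test, screened by significance
and AIC, with turning points within five years of either series end demoted
by a linear re-fit. Abrupt pixels are labeled I–D (significant increase then
significant decrease) or D–I (the reverse).

Finally, interannual VI variation is attributed to 13 candidate drivers
(PRE, PET, AET, AI, VPD, RHU, SM, TEM, TMX, TMN, SR, GI, NTL): iterative
VIF screening (cutoff 10), a grid-searched XGBoost regression on an 80/20
split, exact TreeSHAP importance, and partial-dependence curves whose
regime changes are read off as thresholds by BIC-selected piecewise-linear
fits.

## Worked example

Recover planted driver thresholds end to end:

```bash
python examples/04_driver_thresholds.py
```

```
retained after VIF screening (9 of 13): PRE, AET, AI, VPD, SM, TMX, TMN, SR, GI
held-out fit: R2=0.976 RMSE=0.103 MAE=0.080

top importances (% of total attribution):
  SM    43.28%
  VPD   25.13%
  GI    17.03%
  PRE   13.06%

detected thresholds (planted: SM 79 mm, GI 0.90 SU/ha, VPD 0.39 kPa):
  SM   [79.364, 78.162]
  VPD  [0.387, 0.392]
  GI   [0.929, 0.147]
```

The screening removed the physically derived, collinear candidates (mean
temperature, PET, humidity, nighttime light); the planted soil-moisture step
at 79 mm is recovered at 79.4 mm, the VPD step at 0.39 kPa at 0.387, and the
grazing plateau at 0.90 SU/ha at 0.93. The importance ranking mirrors the
planted effect sizes.

The other examples cover landscape simulation (`01`), the vulnerability
index (`02`), regime classification (`03`), and the full pipeline with a
planted decrease-then-increase reversal (`05`), which prints the
area-percentage tables:

```
turning patterns among abrupt pixels:
category  count   percent
     I_D     33 23.741007
     D_I    106 76.258993
```

A thin CLI wraps the same pipeline: `ecovuln all config.json` (subcommands
`simulate`, `preprocess`, `vi`, `trends`, `drivers`, `report`, `all`; config
keys mirror `PipelineConfig`).

## Layout

- `src/ecovuln/synthetic.py` — truth-bearing generators (landscape, cube, VI series, driver tables)
- `src/ecovuln/preprocessing.py` — compositing, resampling, stable-pixel masks, window standardization
- `src/ecovuln/vulnerability.py` — window regression and the EI/SI/RI/VI indices
- `src/ecovuln/trend.py` — CV, trend models, Pettitt test, classification cascade
- `src/ecovuln/drivers.py` — VIF, XGBoost, TreeSHAP, PDP, threshold detection
- `src/ecovuln/report.py`, `cli.py`, `io.py` — orchestration, summaries, CLI, readers/writers
- `docs/methods.md` — modeling choices, defaults, and limitations
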