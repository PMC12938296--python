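"""Generate a synthetic landscape: annual land-cover maps and a monthly
climate-vegetation cube with known generating coefficients.

The land-cover stack emulates a grassland-dominated mosaic in which a chosen
fraction of pixels converts class mid-record; the cube couples monthly NDVI
anomalies to temperature and precipitation anomalies through a lag-1
autoregressive recursion whose coefficients are returned as ground truth.
"""

import numpy as np

from ecovuln import LandscapeSpec, ProcessParams, generate_climate_veg, generate_landcover
from ecovuln.preprocessing import stable_pixel_mask

spec = LandscapeSpec(n_rows=20, n_cols=20, conversion_fraction=0.1,
                     years=tuple(range(1983, 2023)), seed=1)
stack, lc_truth = generate_landcover(spec)
mask = stable_pixel_mask(stack)
print(f"land-cover stack: {stack.shape[0]} annual maps of {stack.shape[1]}x{stack.shape[2]} pixels")
print(f"stable vegetated pixels: {int(mask.any_stable.sum())}, "
      f"converted (unstable): {int(mask.unstable.sum())}")

cube, truth = generate_climate_veg(spec, ProcessParams())
print(f"cube: {cube.sizes['time']} monthly layers of NDVI/temperature/precipitation")
print(f"generating coefficients: alpha={truth['alpha_true']}, "
      f"beta={truth['beta_true']}, gamma={truth['gamma_true']}")
print(f"NDVI range: [{float(cube['ndvi'].min()):.2f}, {float(cube['ndvi'].max()):.2f}] "
      "(climatology plus AR(1)-coupled anomaly)")
# The unstable count is the planted 10% of vegetated pixels; the coefficients
# are what the window regression downstream is expected to recover.
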