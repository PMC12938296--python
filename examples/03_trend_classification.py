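"""Classify annual vulnerability series into regimes.

Three planted series — pure noise, a steady linear rise, and a V-shaped
reversal — are pushed through the decision cascade (linear fit, continuous
piecewise fit, Pettitt change-point test; significance screening, AIC
selection, boundary re-evaluation).
"""

from ecovuln import generate_vi_series
from ecovuln.trend import classify_trend

cases = {
    "pure noise": ("none",),
    "linear rise (slope 0.02/yr)": ("linear", 0.02),
    "reversal in 2005 (down then up)": ("piecewise", 20, -0.02, 0.02),
}
for label, pattern in cases.items():
    years, values, truth = generate_vi_series(pattern, 36, 0.04, seed=8)
    c = classify_trend(values, 1985, 2020)
    extra = ""
    if c.trend_type == "abrupt":
        extra = f", pattern {c.turning_pattern}, turning year {c.turning_year}"
    print(f"{label:34s} -> {c.trend_type}{extra} "
          f"(CV {c.cv_percent:.1f}%, model {c.model_chosen})")
# The V-shaped series comes back abrupt/D_I with the turning year at the
# planted break; noise stays no_trend; the ramp is linear_increase.
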