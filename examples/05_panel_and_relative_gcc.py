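"""Reference-panel stability and cross-camera rescaling.

A grey reflectance panel in the field of view should keep a constant
colour balance; the SD of its Gcc bounds the per-image uncertainty of
the index.  Relative Gcc linearly rescales a year of data so the
dormant-season mean is 0 and the peak-summer mean is 1, putting
different cameras on a common scale.
"""

import numpy as np
import pandas as pd

from greencam import SyntheticSiteSpec, panel_stability, relative_gcc

rng = np.random.default_rng(7)

# a year of half-hourly panel records with realistic Gcc scatter
n = 5000
panel = pd.DataFrame({
    "gcc": rng.normal(1 / 3, 0.004, n),
    "solar_elev": rng.uniform(-10, 65, n),
    "r_mean": rng.uniform(50, 160, n),
    "g_mean": rng.uniform(50, 160, n),
    "b_mean": rng.uniform(50, 160, n),
})
sd, used, half = panel_stability(panel)
print(f"panel records used: {used} of {n} (after elevation/brightness screening)")
print(f"panel Gcc SD: {sd:.4f}; conservative 99% half-width (2.5 sigma): {half:.4f}")

# rescale a deciduous year to the relative 0-1 scale
doy = np.arange(1, 366)
spec = SyntheticSiteSpec(seed=1)
gcc = spec.trajectory(doy.astype(float)) + rng.laplace(0, 0.002, doy.size)
rel = relative_gcc(doy, gcc)
summer = (doy > 150) & (doy < 180)
winter = (doy > 290) | (doy < 110)
print(f"relative Gcc: dormant mean {rel[winter].mean():+.3f}, "
      f"peak mean {rel[summer].mean():.3f}")
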