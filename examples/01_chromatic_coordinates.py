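"""Chromatic coordinates of a region of interest.

Builds a small image whose ROI pixels are mostly green, computes the
per-channel statistics over the masked region, and converts the channel
means to the green and red chromatic coordinates (Gcc, Rcc).
"""

import numpy as np

from greencam import BinaryMask, chromatic_coords, roi_channel_stats

# a 60x80 scene: grey background, a greenish canopy patch in the middle
img = np.full((60, 80, 3), 120, np.uint8)
img[20:50, 20:60] = (90, 135, 75)

mask = BinaryMask(np.zeros((60, 80), bool))
mask.include[20:50, 20:60] = True

stats = roi_channel_stats(img, mask)
gcc, rcc = chromatic_coords(stats["r_mean"], stats["g_mean"], stats["b_mean"])

print(f"ROI pixels: {mask.n_include}")
print(f"channel means (DN): r={stats['r_mean']:.1f} "
      f"g={stats['g_mean']:.1f} b={stats['b_mean']:.1f}")
print(f"Gcc = {gcc:.4f}   Rcc = {rcc:.4f}")
print(f"red-green pixel correlation: {stats['r_g_cor']}")
# Gcc = g/(r+g+b): 0.45 here means a green-dominated canopy; an
# achromatic scene (snow, bare branches) would sit near 1/3.
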