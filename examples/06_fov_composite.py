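"""Field-of-view shift inspection composite.

Day i's midday image contributes its centre pixel column to column i of
a year-long composite; a camera pointing change shows up as a vertical
discontinuity.  Here the synthetic site shifts its scene 12 pixels on
day 100, and the jump in adjacent-column differences pinpoints it.
"""

import tempfile
from pathlib import Path

import numpy as np
from PIL import Image

from greencam import SyntheticSiteSpec, build_composite, make_site_images
from greencam.solar import parse_image_filename

# keep the canopy patch away from the image centre so the composite's
# centre column samples the (shifting) landscape, not the ROI
spec = SyntheticSiteSpec(seed=5, step=1, fov_shift=(100, 12),
                         roi_box=(30, 10, 90, 60))
with tempfile.TemporaryDirectory() as tmp:
    site_dir, _ = make_site_images(spec, tmp)
    frames = {}
    for path in sorted((site_dir / "images").glob("*.jpg")):
        ts = parse_image_filename(path.name)
        frames[ts.date] = np.asarray(Image.open(path).convert("RGB"))

composite = build_composite(frames, spec.year)
below_sky = composite[composite.shape[0] // 6 :]  # skip the sky band,
# whose brightness varies with the day's illumination factor
diffs = np.sqrt(
    ((below_sky[:, 1:].astype(float) - below_sky[:, :-1].astype(float)) ** 2)
    .mean(axis=(0, 2))
)
jump_day = int(np.argmax(diffs)) + 2  # boundary between day i+1 and i+2
print(f"composite size: {composite.shape[1]} day-columns x "
      f"{composite.shape[0]} rows")
print(f"largest column-to-column jump at day {jump_day} "
      f"(shift was injected on day {spec.fov_shift[0]})")
out = Path(tempfile.gettempdir()) / "fov_composite.png"
Image.fromarray(composite).save(out)
print(f"composite image written to {out}")
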