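"""Classify a stained image and render the four-color overlay.

Strong positives are painted red, medium orange, weak yellow, negative
tissue blue, and excluded glass white.
"""

from pathlib import Path

import numpy as np

from dabquant import ImageSpec, PixelClass, classify_image, render_image, render_overlay
from dabquant.io import write_image

out = Path("example_output")
out.mkdir(exist_ok=True)

image, truth = render_image(ImageSpec(width=256, height=256, seed=11))
labels = classify_image(image)

for cls in (PixelClass.NEGATIVE, PixelClass.WEAK, PixelClass.MEDIUM,
            PixelClass.STRONG, PixelClass.EXCLUDED):
    n = int(np.count_nonzero(labels == int(cls)))
    print(f"{cls.name.lower():>9}: {n:6d} pixels")

write_image(out / "overlay.png", render_overlay(labels))
print(f"wrote {out/'overlay.png'}")
# Counts over non-excluded pixels feed the positivity fractions; excluded
# pixels (bare glass / outside any ROI) never enter the denominator.
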