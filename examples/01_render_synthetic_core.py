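"""Render one synthetic DAB + hematoxylin core with known ground truth.

Builds an image recipe with target positivity fractions, renders it via
Beer-Lambert stain mixing, and prints the realized class fractions and
the exact true H-score recorded in the ground truth.
"""

from pathlib import Path

from dabquant import ImageSpec, render_image
from dabquant.io import write_class_map, write_image

out = Path("example_output")
out.mkdir(exist_ok=True)

spec = ImageSpec(
    width=256,
    height=256,
    target_fractions=(0.20, 0.10, 0.05),  # weak, medium, strong
    tissue_fraction=0.75,
    noise_sd=2.0,
    seed=7,
)
image, truth = render_image(spec)

write_image(out / "core.png", image)
write_class_map(out / "core_truth.png", truth.class_map)

fw, fm, fs = truth.true_fractions
print(f"realized fractions: weak={fw:.4f} medium={fm:.4f} strong={fs:.4f}")
print(f"true H-score: {truth.true_h_score:.4f}  (= 1*{fw:.4f} + 2*{fm:.4f} + 3*{fs:.4f})")
print(f"wrote {out/'core.png'} and {out/'core_truth.png'}")
# The realized fractions match the targets to within a pixel of rounding,
# and the true H-score is their exact grade-weighted sum on the 0-3 scale.
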