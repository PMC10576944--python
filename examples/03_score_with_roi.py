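"""Score a core inside a region of interest.

Writes a GeoJSON annotation with an include rectangle and an exclude
rectangle (emulating tumor included, stroma excluded), reads it back,
and scores the sample only over the in-analysis pixels.
"""

import json
from pathlib import Path

from dabquant import ImageSpec, read_roi, render_image, score_sample

out = Path("example_output")
out.mkdir(exist_ok=True)

image, truth = render_image(
    ImageSpec(width=256, height=256, target_fractions=(0.25, 0.10, 0.05), seed=3)
)

roi_path = out / "roi.geojson"
roi_path.write_text(json.dumps({
    "type": "FeatureCollection",
    "features": [
        {"type": "Feature", "properties": {"role": "include"},
         "geometry": {"type": "Polygon",
                      "coordinates": [[[10, 10], [246, 10], [246, 246], [10, 246], [10, 10]]]}},
        {"type": "Feature", "properties": {"role": "exclude"},
         "geometry": {"type": "Polygon",
                      "coordinates": [[[100, 100], [160, 100], [160, 160], [100, 160], [100, 100]]]}},
    ],
}))

rois = read_roi(roi_path)
record = score_sample(image, rois, sample_id="core3", t_stage="T2")

f = record.fractions
print(f"analyzed pixels: {record.n_analyzed}")
print(f"fractions: neg={f.f_negative:.4f} weak={f.f_weak:.4f} "
      f"medium={f.f_medium:.4f} strong={f.f_strong:.4f}")
print(f"H-score: {record.h_score:.4f}   (ground truth over all tissue: {truth.true_h_score:.4f})")
# The H-score is computed only over pixels inside the include polygon and
# outside the exclude polygon; the truth value covers the whole tissue, so
# small differences reflect the ROI restriction, not classifier error.
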