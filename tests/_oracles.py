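"""Independent reference implementations used only to check the package.

The classifier reference re-states the gating rule table literally and
independently of the vectorized implementation (the HSI conversion is
shared, since distinct conversions disagree in the last bit exactly on
gate boundaries and are cross-checked against colorsys separately); the
point-in-polygon reference is a plain even-odd ray-casting test.
"""

from __future__ import annotations


def reference_classify(pixel, params) -> int:
    """Literal rule-table pixel classifier.

    Returns the integer class code (0 negative, 1 weak, 2 medium,
    3 strong, 255 excluded).
    """
    from dabquant import rgb_to_hsi

    hue, sat, intensity = rgb_to_hsi(pixel)

    if intensity >= params.background_intensity_min and sat < params.saturation_min:
        return 255
    dh = abs(hue - params.hue_center) % 1.0
    dh = min(dh, 1.0 - dh)
    if sat < params.saturation_min or dh > params.hue_width / 2.0:
        return 0
    if intensity <= params.i_strong_upper:
        return 3
    if intensity <= params.i_weak_lower:
        return 2
    if intensity <= params.i_weak_upper:
        return 1
    return 0


def point_in_polygon(x: float, y: float, vertices) -> bool:
    """Even-odd ray-casting containment test for a single polygon ring."""
    inside = False
    n = len(vertices)
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            x_cross = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < x_cross:
                inside = not inside
    return inside


def reference_mask(polygons, width: int, height: int):
    """Per-pixel include/exclude membership via the ray-casting test."""
    import numpy as np

    mask = np.zeros((height, width), dtype=bool)
    for yy in range(height):
        for xx in range(width):
            cx, cy = xx + 0.5, yy + 0.5
            inc = any(
                point_in_polygon(cx, cy, p.vertices)
                for p in polygons
                if p.role == "include"
            )
            exc = any(
                point_in_polygon(cx, cy, p.vertices)
                for p in polygons
                if p.role == "exclude"
            )
            mask[yy, xx] = inc and not exc
    return mask
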