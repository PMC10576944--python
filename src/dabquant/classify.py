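"""Positive-pixel classification of DAB-stained photomicrographs.

Pixels are gated by hue and saturation to find chromogen-positive
candidates, which are then binned into weak / medium / strong by mean
intensity; near-white low-saturation pixels (bare glass) are excluded
from analysis.  This mirrors the positive-pixel-counting approach used
by slide-analysis software for brightfield immunohistochemistry.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np


class PixelClass(IntEnum):
    """Per-pixel label.  Integer codes double as the class-map PNG codes."""

    NEGATIVE = 0
    WEAK = 1
    MEDIUM = 2
    STRONG = 3
    EXCLUDED = 255


#: Pseudocolor overlay palette: red / orange / yellow for strong / medium /
#: weak positivity, blue for negative tissue, white for excluded pixels.
OVERLAY_COLORS: dict[PixelClass, tuple[int, int, int]] = {
    PixelClass.STRONG: (255, 0, 0),
    PixelClass.MEDIUM: (255, 165, 0),
    PixelClass.WEAK: (255, 255, 0),
    PixelClass.NEGATIVE: (0, 0, 255),
    PixelClass.EXCLUDED: (255, 255, 255),
}


@dataclass(frozen=True)
class ClassifierParams:
    """Hue/saturation gate and intensity bins of the pixel classifier.

    Parameters
    ----------
    hue_center, hue_width
        Center and full width of the positive hue window, as fractions of
        the color wheel in [0, 1).  The default window is centered on the
        brown of the DAB chromogen.
    saturation_min
        Minimum saturation for a pixel to be a positive candidate; also the
        saturation below which a bright pixel counts as bare glass.
    i_weak_upper, i_weak_lower, i_strong_upper
        Intensity bin edges (mean of R, G, B on a 0-255 scale):
        weak = (i_weak_lower, i_weak_upper], medium = (i_strong_upper,
        i_weak_lower], strong = [0, i_strong_upper].  Candidates brighter
        than ``i_weak_upper`` are negative.
    background_intensity_min
        Intensity at or above which a low-saturation pixel is excluded as
        background glass rather than counted as negative tissue.

    Defaults follow the widely published defaults of the positive-pixel
    algorithm family; every value can be overridden from a config file.
    """

    hue_center: float = 0.1
    hue_width: float = 0.5
    saturation_min: float = 0.04
    i_weak_upper: float = 220.0
    i_weak_lower: float = 175.0
    i_strong_upper: float = 100.0
    background_intensity_min: float = 230.0

    def validate(self) -> None:
        """Raise ``ValueError`` if any invariant is violated."""
        if not 0.0 <= self.hue_center < 1.0:
            raise ValueError(f"hue_center must be in [0, 1): {self.hue_center}")
        if not 0.0 <= self.hue_width <= 1.0:
            raise ValueError(f"hue_width must be in [0, 1]: {self.hue_width}")
        if not 0.0 <= self.saturation_min <= 1.0:
            raise ValueError(
                f"saturation_min must be in [0, 1]: {self.saturation_min}"
            )
        if not (
            0.0
            <= self.i_strong_upper
            < self.i_weak_lower
            < self.i_weak_upper
            <= 255.0
        ):
            raise ValueError(
                "intensity bins must satisfy 0 <= i_strong_upper < "
                f"i_weak_lower < i_weak_upper <= 255, got "
                f"({self.i_strong_upper}, {self.i_weak_lower}, "
                f"{self.i_weak_upper})"
            )
        if not 0.0 <= self.background_intensity_min <= 255.0:
            raise ValueError(
                "background_intensity_min must be in [0, 255]: "
                f"{self.background_intensity_min}"
            )


def _check_rgb(pixel) -> np.ndarray:
    px = np.asarray(pixel, dtype=float)
    if px.shape != (3,):
        raise ValueError(f"expected an RGB triple, got shape {px.shape}")
    if np.any(px < 0) or np.any(px > 255):
        raise ValueError(f"channel values must lie in [0, 255]: {pixel}")
    return px


def rgb_to_hsi(pixel) -> tuple[float, float, float]:
    """Convert an RGB triple to (hue, saturation, intensity).

    Hue follows the standard hexagonal HSV formula scaled to [0, 1), with
    achromatic pixels assigned hue 0.  Saturation is (max - min) / max
    (0 for black).  Intensity is the unweighted channel mean (R + G + B) / 3
    as a real number on the 0-255 scale.
    """
    r, g, b = _check_rgb(pixel)
    cmax = max(r, g, b)
    cmin = min(r, g, b)
    delta = cmax - cmin
    intensity = (r + g + b) / 3.0
    if cmax == 0.0:
        return 0.0, 0.0, intensity
    saturation = delta / cmax
    if delta == 0.0:
        return 0.0, saturation, intensity
    if cmax == r:
        hue = ((g - b) / delta) % 6.0 / 6.0
    elif cmax == g:
        hue = (2.0 + (b - r) / delta) / 6.0
    else:
        hue = (4.0 + (r - g) / delta) / 6.0
    return hue % 1.0, saturation, intensity


def circular_hue_distance(h1: float, h2: float) -> float:
    """Shortest distance between two hues on the unit color wheel."""
    d = abs(h1 - h2) % 1.0
    return min(d, 1.0 - d)


def classify_pixel(pixel, params: ClassifierParams | None = None) -> PixelClass:
    """Classify one RGB pixel into the five-label scheme.

    Rule order: bright low-saturation pixels are excluded as glass; pixels
    inside the hue window with sufficient saturation are positive
    candidates, binned by intensity; everything else (and candidates
    brighter than the weak bin) is negative.
    """
    if params is None:
        params = ClassifierParams()
    params.validate()
    hue, sat, intensity = rgb_to_hsi(pixel)

    if intensity >= params.background_intensity_min and sat < params.saturation_min:
        return PixelClass.EXCLUDED
    candidate = (
        sat >= params.saturation_min
        and circular_hue_distance(hue, params.hue_center) <= params.hue_width / 2.0
    )
    if not candidate:
        return PixelClass.NEGATIVE
    if intensity <= params.i_strong_upper:
        return PixelClass.STRONG
    if intensity <= params.i_weak_lower:
        return PixelClass.MEDIUM
    if intensity <= params.i_weak_upper:
        return PixelClass.WEAK
    return PixelClass.NEGATIVE


def _check_image(image) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 RGB image, got shape {img.shape}")
    if img.shape[0] < 1 or img.shape[1] < 1:
        raise ValueError("image dimensions must be >= 1")
    if np.issubdtype(img.dtype, np.floating):
        if np.any(img < 0) or np.any(img > 255):
            raise ValueError("channel values must lie in [0, 255]")
    elif img.dtype != np.uint8:
        if np.any(img < 0) or np.any(img > 255):
            raise ValueError("channel values must lie in [0, 255]")
    return img.astype(float)


def classify_image(image, params: ClassifierParams | None = None) -> np.ndarray:
    """Vectorized per-pixel classification of a full image.

    Returns a uint8 label map with :class:`PixelClass` codes, identical to
    applying :func:`classify_pixel` independently at every pixel.
    """
    if params is None:
        params = ClassifierParams()
    params.validate()
    img = _check_image(image)
    r, g, b = img[..., 0], img[..., 1], img[..., 2]

    cmax = np.max(img, axis=-1)
    cmin = np.min(img, axis=-1)
    delta = cmax - cmin
    intensity = img.sum(axis=-1) / 3.0

    with np.errstate(divide="ignore", invalid="ignore"):
        sat = np.where(cmax > 0, delta / np.where(cmax > 0, cmax, 1.0), 0.0)
        safe_delta = np.where(delta > 0, delta, 1.0)
        hue = np.where(
            cmax == r,
            ((g - b) / safe_delta) % 6.0 / 6.0,
            np.where(
                cmax == g,
                (2.0 + (b - r) / safe_delta) / 6.0,
                (4.0 + (r - g) / safe_delta) / 6.0,
            ),
        )
    hue = np.where(delta > 0, hue % 1.0, 0.0)

    hue_dist = np.abs(hue - params.hue_center) % 1.0
    hue_dist = np.minimum(hue_dist, 1.0 - hue_dist)

    excluded = (intensity >= params.background_intensity_min) & (
        sat < params.saturation_min
    )
    candidate = (
        ~excluded
        & (sat >= params.saturation_min)
        & (hue_dist <= params.hue_width / 2.0)
    )

    labels = np.full(img.shape[:2], int(PixelClass.NEGATIVE), dtype=np.uint8)
    labels[excluded] = int(PixelClass.EXCLUDED)
    labels[candidate & (intensity <= params.i_weak_upper)] = int(PixelClass.WEAK)
    labels[candidate & (intensity <= params.i_weak_lower)] = int(PixelClass.MEDIUM)
    labels[candidate & (intensity <= params.i_strong_upper)] = int(PixelClass.STRONG)
    return labels


def render_overlay(class_map) -> np.ndarray:
    """Render the four-color pseudocolor overlay of a class map.

    Strong positives are painted red, medium orange, weak yellow, negative
    blue, and excluded pixels white, matching the conventional markup of
    positive-pixel analysis output.
    """
    cmap = np.asarray(class_map)
    valid = {int(c) for c in PixelClass}
    present = set(np.unique(cmap).tolist())
    if not present <= valid:
        raise ValueError(f"unknown class codes in map: {sorted(present - valid)}")
    lut = np.zeros((256, 3), dtype=np.uint8)
    for cls, color in OVERLAY_COLORS.items():
        lut[int(cls)] = color
    return lut[cmap]
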