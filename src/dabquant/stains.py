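"""Beer-Lambert stain mixing for hematoxylin + DAB brightfield rendering.

In brightfield microscopy, stain absorbance is additive in optical
density: a pixel carrying hematoxylin at concentration h and DAB at
concentration d transmits ``I_c = I_0 * 10 ** -(h * H_c + d * D_c)``
per RGB channel c, where H and D are the per-channel optical-density
signatures of the two stains.  This module renders pixels from
concentrations and calibrates DAB concentrations that land in the
middle of each positivity intensity bin of the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classify import ClassifierParams, PixelClass, classify_pixel


class CalibrationError(RuntimeError):
    """A requested positivity bin is unreachable under the given gates."""


@dataclass(frozen=True)
class StainVectors:
    """Per-channel optical-density signatures of the two stains.

    Defaults are the standard literature deconvolution vectors for
    hematoxylin (0.65, 0.70, 0.29) and DAB (0.27, 0.57, 0.78).
    """

    hematoxylin_od: tuple[float, float, float] = (0.65, 0.70, 0.29)
    dab_od: tuple[float, float, float] = (0.27, 0.57, 0.78)

    def validate(self) -> None:
        for name, vec in (
            ("hematoxylin_od", self.hematoxylin_od),
            ("dab_od", self.dab_od),
        ):
            arr = np.asarray(vec, dtype=float)
            if arr.shape != (3,):
                raise ValueError(f"{name} must have three components")
            if np.any(arr < 0):
                raise ValueError(f"{name} components must be >= 0: {vec}")
            if np.linalg.norm(arr) <= 0:
                raise ValueError(f"{name} must have positive norm")


def transmitted_rgb(
    hematoxylin_conc, dab_conc, vectors: StainVectors | None = None
) -> np.ndarray:
    """Continuous (unrounded) transmitted RGB for given stain concentrations.

    Accepts scalars or broadcastable arrays of concentrations; returns an
    array with a trailing axis of length 3.
    """
    if vectors is None:
        vectors = StainVectors()
    vectors.validate()
    h = np.asarray(hematoxylin_conc, dtype=float)
    d = np.asarray(dab_conc, dtype=float)
    if np.any(h < 0) or np.any(d < 0):
        raise ValueError("stain concentrations must be >= 0")
    hod = np.asarray(vectors.hematoxylin_od, dtype=float)
    dod = np.asarray(vectors.dab_od, dtype=float)
    od = h[..., None] * hod + d[..., None] * dod
    return 255.0 * 10.0 ** (-od)


def render_pixel(
    hematoxylin_conc: float, dab_conc: float, vectors: StainVectors | None = None
) -> tuple[int, int, int]:
    """Render one pixel: round(255 * 10**-OD) per channel, clipped to [0, 255].

    Zero concentrations give pure white; infinite concentration tends to
    black.  Increasing either concentration never brightens any channel.
    """
    rgb = transmitted_rgb(hematoxylin_conc, dab_conc, vectors)
    quantized = np.clip(np.rint(rgb), 0, 255).astype(int)
    return int(quantized[0]), int(quantized[1]), int(quantized[2])


def _bin_midpoint(target_class: PixelClass, params: ClassifierParams) -> float:
    if target_class == PixelClass.STRONG:
        return params.i_strong_upper / 2.0
    if target_class == PixelClass.MEDIUM:
        return (params.i_strong_upper + params.i_weak_lower) / 2.0
    if target_class == PixelClass.WEAK:
        return (params.i_weak_lower + params.i_weak_upper) / 2.0
    raise ValueError(f"no intensity bin for target class {target_class!r}")


def calibrate_dab_concentration(
    target_class: PixelClass | str,
    params: ClassifierParams | None = None,
    vectors: StainVectors | None = None,
    intensity_tol: float = 0.5,
) -> float:
    """Find the pure-DAB concentration whose pixel sits mid-bin.

    Bisects the (strictly decreasing) mean transmitted intensity as a
    function of DAB concentration until it is within ``intensity_tol`` of
    the midpoint of the target class's intensity bin, then verifies that
    the rendered pixel actually classifies into the target class.

    Raises
    ------
    CalibrationError
        If the gates make the bin unreachable (e.g. the saturation or hue
        gate rejects every pure-DAB pixel).
    ValueError
        If the params violate their invariants (e.g. inverted bin order).
    """
    if params is None:
        params = ClassifierParams()
    if vectors is None:
        vectors = StainVectors()
    params.validate()
    vectors.validate()
    if isinstance(target_class, str):
        target_class = PixelClass[target_class.upper()]
    target_intensity = _bin_midpoint(target_class, params)

    def mean_intensity(d: float) -> float:
        return float(transmitted_rgb(0.0, d, vectors).mean())

    lo, hi = 0.0, 1.0
    while mean_intensity(hi) > target_intensity:
        hi *= 2.0
        if hi > 1e6:  # pragma: no cover - requires a near-zero OD vector
            raise CalibrationError(
                f"cannot reach intensity {target_intensity} with DAB vector "
                f"{vectors.dab_od}"
            )
    conc = (lo + hi) / 2.0
    for _ in range(200):
        conc = (lo + hi) / 2.0
        intensity = mean_intensity(conc)
        if abs(intensity - target_intensity) <= intensity_tol:
            break
        if intensity > target_intensity:
            lo = conc
        else:
            hi = conc
    rendered = render_pixel(0.0, conc, vectors)
    realized = classify_pixel(rendered, params)
    if realized != target_class:
        raise CalibrationError(
            f"calibrated pure-DAB pixel {rendered} classifies as "
            f"{realized.name}, not {target_class.name}; the gates exclude "
            "this bin"
        )
    return conc
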