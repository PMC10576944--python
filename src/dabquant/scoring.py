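"""Class tallies, positivity fractions, and the H-score per tissue core.

The H-score weights the positive area fractions by staining grade:

    H = 1 * f_weak + 2 * f_medium + 3 * f_strong

with fractions on the [0, 1] scale, so H ranges from 0 (fully negative)
to 3 (uniformly strong).  Fractions are pixel-based — the positive-pixel
algorithm counts pixels, which proxy for cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classify import ClassifierParams, PixelClass, classify_image
from .roi import RoiPolygonSet, apply_mask, rasterize


class UnscorableSampleError(ValueError):
    """No analyzable (non-excluded) pixels remain in the sample."""


@dataclass(frozen=True)
class ClassCounts:
    """Pixel tallies over the analyzed (non-excluded) area."""

    n_negative: int
    n_weak: int
    n_medium: int
    n_strong: int

    @property
    def n_analyzed(self) -> int:
        return self.n_negative + self.n_weak + self.n_medium + self.n_strong


@dataclass(frozen=True)
class PositivityFractions:
    """Per-class area fractions of the analyzed area; they sum to 1."""

    f_negative: float
    f_weak: float
    f_medium: float
    f_strong: float


@dataclass(frozen=True)
class SampleRecord:
    """Scored tissue core: metadata, analyzed pixel count, fractions, H."""

    sample_id: str
    tissue_type: str
    t_stage: str
    n_stage: str
    m_stage: str
    n_analyzed: int
    fractions: PositivityFractions
    h_score: float


def count_classes(class_map) -> ClassCounts:
    """Tally negative/weak/medium/strong pixels, ignoring excluded ones.

    Raises :class:`UnscorableSampleError` if every pixel is excluded.
    """
    cmap = np.asarray(class_map)
    counts = ClassCounts(
        n_negative=int(np.count_nonzero(cmap == int(PixelClass.NEGATIVE))),
        n_weak=int(np.count_nonzero(cmap == int(PixelClass.WEAK))),
        n_medium=int(np.count_nonzero(cmap == int(PixelClass.MEDIUM))),
        n_strong=int(np.count_nonzero(cmap == int(PixelClass.STRONG))),
    )
    if counts.n_analyzed == 0:
        raise UnscorableSampleError(
            "no analyzable pixels: every pixel is excluded"
        )
    return counts


def positivity_fractions(counts: ClassCounts) -> PositivityFractions:
    """Convert class tallies to fractions of the analyzed area."""
    n = counts.n_analyzed
    if n <= 0:
        raise UnscorableSampleError("cannot form fractions with no analyzed pixels")
    return PositivityFractions(
        f_negative=counts.n_negative / n,
        f_weak=counts.n_weak / n,
        f_medium=counts.n_medium / n,
        f_strong=counts.n_strong / n,
    )


def h_score(fractions: PositivityFractions) -> float:
    """Weighted positivity index 1*f_weak + 2*f_medium + 3*f_strong in [0, 3]."""
    return (
        1.0 * fractions.f_weak
        + 2.0 * fractions.f_medium
        + 3.0 * fractions.f_strong
    )


def score_sample(
    image,
    rois: RoiPolygonSet | np.ndarray | None = None,
    params: ClassifierParams | None = None,
    *,
    sample_id: str = "sample",
    tissue_type: str = "melanoma",
    t_stage: str = "NA",
    n_stage: str = "NA",
    m_stage: str = "NA",
) -> SampleRecord:
    """Score one core: classify, mask to the ROI, tally, and compute H.

    ``rois`` may be a polygon set, a precomputed boolean mask, or None
    (whole image analyzed, background still excluded by the classifier).
    Raises :class:`UnscorableSampleError` if nothing analyzable remains.
    """
    class_map = classify_image(image, params)
    if rois is not None:
        if isinstance(rois, RoiPolygonSet):
            mask = rasterize(rois, class_map.shape[1], class_map.shape[0])
        else:
            mask = np.asarray(rois, dtype=bool)
        class_map = apply_mask(class_map, mask)
    counts = count_classes(class_map)
    fractions = positivity_fractions(counts)
    return SampleRecord(
        sample_id=sample_id,
        tissue_type=tissue_type,
        t_stage=t_stage,
        n_stage=n_stage,
        m_stage=m_stage,
        n_analyzed=counts.n_analyzed,
        fractions=fractions,
        h_score=h_score(fractions),
    )
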