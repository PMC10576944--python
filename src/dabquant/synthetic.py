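"""Synthetic DAB + hematoxylin photomicrographs with per-pixel ground truth.

The generator stands in for stained tissue-microarray cores: tissue is
laid down as random elliptical patches on a white glass background,
hematoxylin counterstain covers all tissue-negative pixels, and DAB
positivity at three calibrated intensity grades is carved out of the
tissue as smooth blobs whose areas match requested class fractions.
Gaussian camera noise is added after rendering; ground-truth labels are
assigned before noise, so recovery tests measure classifier robustness.

Whole cohorts with tumor/node/metastasis metadata can be simulated so
the complete scoring and statistics pipeline is exercisable without any
real slides.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import ellipse as draw_ellipse

from .classify import ClassifierParams, PixelClass
from .stains import StainVectors, calibrate_dab_concentration, transmitted_rgb

#: Class-map PNG code for non-tissue background.
BACKGROUND_CODE = int(PixelClass.EXCLUDED)


@dataclass(frozen=True)
class ImageSpec:
    """Recipe for one synthetic photomicrograph.

    ``target_fractions`` are the desired (weak, medium, strong) DAB area
    fractions among tissue pixels; ``tissue_fraction`` is the fraction of
    the frame covered by tissue; ``counterstain_density`` scales the
    hematoxylin optical density of tissue-negative pixels; ``noise_sd``
    is Gaussian per-channel camera noise in 8-bit RGB units.
    """

    width: int = 128
    height: int = 128
    target_fractions: tuple[float, float, float] = (0.2, 0.1, 0.05)
    tissue_fraction: float = 0.7
    counterstain_density: float = 0.6
    noise_sd: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("image dimensions must be >= 1")
        fw, fm, fs = self.target_fractions
        if min(fw, fm, fs) < 0 or max(fw, fm, fs) > 1:
            raise ValueError(f"class fractions must be in [0, 1]: {self.target_fractions}")
        if fw + fm + fs > 1.0 + 1e-12:
            raise ValueError(
                f"class fractions must sum to <= 1: {self.target_fractions}"
            )
        if not 0.0 < self.tissue_fraction <= 1.0:
            raise ValueError(f"tissue_fraction must be in (0, 1]: {self.tissue_fraction}")
        if self.counterstain_density < 0:
            raise ValueError("counterstain_density must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """True per-pixel labels and exact class fractions of a rendered image.

    ``class_map`` uses the same codes as the classifier output, with 255
    marking non-tissue background.  ``true_fractions`` are (weak, medium,
    strong) among tissue pixels and ``true_h_score`` is exactly
    ``1*f_weak + 2*f_medium + 3*f_strong``.
    """

    class_map: np.ndarray
    true_fractions: tuple[float, float, float]
    true_h_score: float


@dataclass(frozen=True)
class GroupSpec:
    """One cohort arm: sample count, mean class fractions, spread, staging."""

    label: str
    n_samples: int
    mean_target_fractions: tuple[float, float, float]
    between_sample_sd: float = 0.06
    tissue_type: str = "melanoma"
    t_stages: tuple[str, ...] | None = None
    n_stages: tuple[str, ...] = ("N0",)
    m_stages: tuple[str, ...] = ("M0",)


#: Default T-stage pools by group label, mirroring the thickness dichotomy
#: (T1-T2 at or below 2 mm Breslow depth, T3-T4 above).
_DEFAULT_T_STAGES = {
    "thin": ("T1", "T2"),
    "thick": ("T3", "T4"),
    "normal": ("NA",),
}


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a simulated cohort of stained cores with TNM metadata."""

    groups: tuple[GroupSpec, ...]
    template: ImageSpec = field(default_factory=ImageSpec)
    seed: int = 0

    def validate(self) -> None:
        if len(self.groups) == 0:
            raise ValueError("cohort must define at least one group")
        for g in self.groups:
            if g.n_samples < 1:
                raise ValueError(f"group {g.label!r} must have n_samples >= 1")
            if g.between_sample_sd < 0:
                raise ValueError("between_sample_sd must be >= 0")


@dataclass(frozen=True)
class SimulatedSample:
    """One rendered core together with its metadata and ground truth."""

    sample_id: str
    group: str
    tissue_type: str
    t_stage: str
    n_stage: str
    m_stage: str
    image: np.ndarray
    ground_truth: GroundTruth


def _tissue_mask(spec: ImageSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.height, spec.width
    if spec.tissue_fraction >= 1.0:
        return np.ones((h, w), dtype=bool)
    mask = np.zeros((h, w), dtype=bool)
    target = spec.tissue_fraction * h * w
    scale = min(h, w)
    # Union of random ellipses; overshoot is at most one ellipse's area.
    for _ in range(5000):
        if mask.sum() >= target:
            break
        cy = rng.uniform(0, h)
        cx = rng.uniform(0, w)
        ry = rng.uniform(0.08, 0.22) * scale
        rx = rng.uniform(0.08, 0.22) * scale
        theta = rng.uniform(0, np.pi)
        rr, cc = draw_ellipse(cy, cx, ry, rx, shape=(h, w), rotation=theta)
        mask[rr, cc] = True
    return mask


def _class_counts(fractions: tuple[float, float, float], n_tissue: int):
    n_w = int(round(fractions[0] * n_tissue))
    n_m = int(round(fractions[1] * n_tissue))
    n_s = int(round(fractions[2] * n_tissue))
    while n_w + n_m + n_s > n_tissue:  # rounding can overflow by a pixel
        if n_w >= max(n_m, n_s):
            n_w -= 1
        elif n_m >= n_s:
            n_m -= 1
        else:
            n_s -= 1
    return n_w, n_m, n_s


_CONC_CACHE: dict[tuple[ClassifierParams, StainVectors], dict[int, float]] = {}


def _calibrated_concentrations(
    params: ClassifierParams, vectors: StainVectors
) -> dict[int, float]:
    key = (params, vectors)
    if key not in _CONC_CACHE:
        _CONC_CACHE[key] = {
            int(PixelClass.WEAK): calibrate_dab_concentration("weak", params, vectors),
            int(PixelClass.MEDIUM): calibrate_dab_concentration(
                "medium", params, vectors
            ),
            int(PixelClass.STRONG): calibrate_dab_concentration(
                "strong", params, vectors
            ),
        }
    return _CONC_CACHE[key]


def render_image(
    spec: ImageSpec,
    params: ClassifierParams | None = None,
    vectors: StainVectors | None = None,
) -> tuple[np.ndarray, GroundTruth]:
    """Render one synthetic photomicrograph and its ground truth.

    Deterministic given ``spec.seed``.  DAB patch areas match the target
    fractions exactly up to single-pixel rounding; realized fractions and
    the exact true H-score are recorded in the returned ground truth.
    """
    spec.validate()
    if params is None:
        params = ClassifierParams()
    if vectors is None:
        vectors = StainVectors()
    rng = np.random.default_rng(spec.seed)

    tissue = _tissue_mask(spec, rng)
    n_tissue = int(tissue.sum())
    h, w = spec.height, spec.width

    class_map = np.full((h, w), BACKGROUND_CODE, dtype=np.uint8)
    class_map[tissue] = int(PixelClass.NEGATIVE)

    # Smooth random field ranks tissue pixels; the top-ranked pixels become
    # DAB blobs, giving contiguous patches with exact pixel counts.
    n_w, n_m, n_s = _class_counts(spec.target_fractions, n_tissue)
    if n_w + n_m + n_s > 0:
        field_ = gaussian_filter(
            rng.standard_normal((h, w)), sigma=max(2.0, min(h, w) / 12.0)
        )
        tissue_idx = np.flatnonzero(tissue.ravel())
        order = tissue_idx[np.argsort(-field_.ravel()[tissue_idx], kind="stable")]
        flat = class_map.ravel()
        flat[order[:n_s]] = int(PixelClass.STRONG)
        flat[order[n_s : n_s + n_m]] = int(PixelClass.MEDIUM)
        flat[order[n_s + n_m : n_s + n_m + n_w]] = int(PixelClass.WEAK)

    if n_tissue > 0:
        true_fractions = (n_w / n_tissue, n_m / n_tissue, n_s / n_tissue)
    else:
        true_fractions = (0.0, 0.0, 0.0)
    true_h = (
        1.0 * true_fractions[0] + 2.0 * true_fractions[1] + 3.0 * true_fractions[2]
    )

    # Pure DAB at the calibrated mid-bin concentration per grade; the
    # counterstain covers only tissue-negative pixels so that noise-free
    # classification recovers the labels exactly.
    conc = _calibrated_concentrations(params, vectors)
    h_conc = np.zeros((h, w))
    d_conc = np.zeros((h, w))
    h_conc[class_map == int(PixelClass.NEGATIVE)] = spec.counterstain_density
    for code, c in conc.items():
        d_conc[class_map == code] = c

    rgb = transmitted_rgb(h_conc, d_conc, vectors)
    if spec.noise_sd > 0:
        rgb = rgb + rng.normal(0.0, spec.noise_sd, size=rgb.shape)
    image = np.clip(np.rint(rgb), 0, 255).astype(np.uint8)

    return image, GroundTruth(
        class_map=class_map, true_fractions=true_fractions, true_h_score=true_h
    )


def _clip_to_simplex(fractions: np.ndarray) -> tuple[float, float, float]:
    f = np.clip(fractions, 0.0, 1.0)
    total = float(f.sum())
    if total > 1.0:
        f = f / total
    return float(f[0]), float(f[1]), float(f[2])


def simulate_cohort(
    cohort: CohortSpec,
    params: ClassifierParams | None = None,
    vectors: StainVectors | None = None,
) -> list[SimulatedSample]:
    """Simulate every core of a cohort: one image + ground truth per sample.

    Per-sample class fractions are drawn around each group's mean with the
    group's between-sample spread, clipped to the valid simplex; T/N/M
    stages are drawn from the group's stage pools.  Deterministic given
    ``cohort.seed``.
    """
    cohort.validate()
    rng = np.random.default_rng(cohort.seed)
    samples: list[SimulatedSample] = []
    counter = 0
    for group in cohort.groups:
        t_pool = group.t_stages or _DEFAULT_T_STAGES.get(group.label, ("NA",))
        for _ in range(group.n_samples):
            counter += 1
            mean = np.asarray(group.mean_target_fractions, dtype=float)
            jitter = rng.normal(0.0, group.between_sample_sd, size=3)
            fractions = _clip_to_simplex(mean + jitter)
            seed = int(rng.integers(0, 2**31 - 1))
            t_stage = str(rng.choice(list(t_pool)))
            n_stage = str(rng.choice(list(group.n_stages)))
            m_stage = str(rng.choice(list(group.m_stages)))
            spec = replace(cohort.template, target_fractions=fractions, seed=seed)
            image, truth = render_image(spec, params, vectors)
            samples.append(
                SimulatedSample(
                    sample_id=f"S{counter:04d}",
                    group=group.label,
                    tissue_type=group.tissue_type,
                    t_stage=t_stage,
                    n_stage=n_stage,
                    m_stage=m_stage,
                    image=image,
                    ground_truth=truth,
                )
            )
    return samples


#: Mean (weak, medium, strong) fractions whose H-scores hit the study's
#: reported group means: thin 1*0.35 + 2*0.15 + 3*0.10 = 0.95 and thick
#: 1*0.25 + 2*0.10 + 3*0.04 = 0.57.
THIN_GROUP_FRACTIONS: tuple[float, float, float] = (0.35, 0.15, 0.10)
THICK_GROUP_FRACTIONS: tuple[float, float, float] = (0.25, 0.10, 0.04)


def melanoma_study_cohort(
    seed: int = 0,
    template: ImageSpec | None = None,
    n_thin: int = 8,
    n_thick: int = 75,
    between_sample_sd: float = 0.06,
) -> CohortSpec:
    """Cohort spec emulating the study design under the thickness dichotomy.

    Eight thin (T1+T2, Breslow depth at or below 2.0 mm) and 75 thick
    (T3+T4) melanoma cores whose group mean H-scores target 0.95 and 0.57.
    The between-sample spread (sd per class fraction, about 0.22 on the H
    scale) is a free parameter of the emulation; see the methods note.
    """
    if template is None:
        template = ImageSpec()
    return CohortSpec(
        groups=(
            GroupSpec(
                label="thin",
                n_samples=n_thin,
                mean_target_fractions=THIN_GROUP_FRACTIONS,
                between_sample_sd=between_sample_sd,
            ),
            GroupSpec(
                label="thick",
                n_samples=n_thick,
                mean_target_fractions=THICK_GROUP_FRACTIONS,
                between_sample_sd=between_sample_sd,
            ),
        ),
        template=template,
        seed=seed,
    )


def normal_skin_spec(width: int = 128, height: int = 128, seed: int = 0) -> ImageSpec:
    """Preset emulating normal epidermis: faint, diffusely distributed
    positivity — a broad weak-grade area with little medium and no strong."""
    return ImageSpec(
        width=width,
        height=height,
        target_fractions=(0.55, 0.05, 0.0),
        tissue_fraction=0.7,
        counterstain_density=0.6,
        noise_sd=2.0,
        seed=seed,
    )


def _tissue_bbox_geojson(class_map: np.ndarray) -> dict:
    tissue = class_map != BACKGROUND_CODE
    rows = np.any(tissue, axis=1)
    cols = np.any(tissue, axis=0)
    if rows.any():
        y0, y1 = int(np.argmax(rows)), int(len(rows) - np.argmax(rows[::-1]))
        x0, x1 = int(np.argmax(cols)), int(len(cols) - np.argmax(cols[::-1]))
    else:  # no tissue: cover the whole frame
        y0, y1 = 0, class_map.shape[0]
        x0, x1 = 0, class_map.shape[1]
    ring = [[x0, y0], [x1, y0], [x1, y1], [x0, y1], [x0, y0]]
    return {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "properties": {"role": "include"},
                "geometry": {"type": "Polygon", "coordinates": [ring]},
            }
        ],
    }


def write_cohort(samples: list[SimulatedSample], out_dir: str | Path) -> Path:
    """Write a simulated cohort to disk in the pipeline's input layout.

    Produces ``<id>.png`` (RGB image), ``<id>_truth.png`` (class-map codes,
    255 = background), ``<id>_roi.geojson`` (include rectangle over the
    tissue bounding region) per sample, plus ``metadata.csv`` with columns
    sample_id, image, roi, tissue_type, t_stage, n_stage, m_stage, group.
    Returns the metadata path.
    """
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta_path = out / "metadata.csv"
    with open(meta_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            [
                "sample_id",
                "image",
                "roi",
                "tissue_type",
                "t_stage",
                "n_stage",
                "m_stage",
                "group",
            ]
        )
        for s in samples:
            img_name = f"{s.sample_id}.png"
            roi_name = f"{s.sample_id}_roi.geojson"
            iio.imwrite(out / img_name, s.image)
            iio.imwrite(out / f"{s.sample_id}_truth.png", s.ground_truth.class_map)
            with open(out / roi_name, "w") as rf:
                json.dump(_tissue_bbox_geojson(s.ground_truth.class_map), rf)
            writer.writerow(
                [
                    s.sample_id,
                    img_name,
                    roi_name,
                    s.tissue_type,
                    s.t_stage,
                    s.n_stage,
                    s.m_stage,
                    s.group,
                ]
            )
    return meta_path
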