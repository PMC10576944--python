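"""Synthetic image and cohort generator: determinism, ground truth, layout."""

import csv

import numpy as np
import pytest

from dabquant import (
    CohortSpec,
    GroupSpec,
    ImageSpec,
    PixelClass,
    melanoma_study_cohort,
    normal_skin_spec,
    read_roi,
    render_image,
    simulate_cohort,
    write_cohort,
)
from dabquant.synthetic import BACKGROUND_CODE


class TestRenderImage:
    def test_seeded_determinism_is_bitwise(self):
        spec = ImageSpec(width=64, height=64, seed=7)
        img1, truth1 = render_image(spec)
        img2, truth2 = render_image(spec)
        assert np.array_equal(img1, img2)
        assert np.array_equal(truth1.class_map, truth2.class_map)

    def test_different_seeds_differ(self):
        img1, _ = render_image(ImageSpec(width=64, height=64, seed=1))
        img2, _ = render_image(ImageSpec(width=64, height=64, seed=2))
        assert not np.array_equal(img1, img2)

    def test_all_negative_truth_has_zero_h(self):
        _, truth = render_image(
            ImageSpec(width=32, height=32, target_fractions=(0, 0, 0), seed=3)
        )
        assert truth.true_h_score == 0.0
        assert truth.true_fractions == (0.0, 0.0, 0.0)

    def test_all_strong_full_tissue_has_h_three(self):
        _, truth = render_image(
            ImageSpec(
                width=32,
                height=32,
                target_fractions=(0, 0, 1),
                tissue_fraction=1.0,
                seed=3,
            )
        )
        assert truth.true_h_score == 3.0

    def test_true_h_equals_weighted_fractions_exactly(self):
        for seed in range(5):
            _, truth = render_image(
                ImageSpec(width=48, height=48, target_fractions=(0.3, 0.2, 0.1), seed=seed)
            )
            fw, fm, fs = truth.true_fractions
            assert truth.true_h_score == 1.0 * fw + 2.0 * fm + 3.0 * fs

    def test_realized_fractions_match_targets(self):
        target = (0.25, 0.15, 0.05)
        _, truth = render_image(
            ImageSpec(width=96, height=96, target_fractions=target, seed=11)
        )
        for realized, wanted in zip(truth.true_fractions, target):
            assert realized == pytest.approx(wanted, abs=0.01)

    def test_overfull_fractions_rejected(self):
        with pytest.raises(ValueError):
            render_image(ImageSpec(target_fractions=(0.5, 0.4, 0.2)))

    def test_zero_tissue_fraction_rejected(self):
        with pytest.raises(ValueError):
            ImageSpec(tissue_fraction=0.0).validate()

    def test_background_is_near_white_and_tissue_stained(self):
        img, truth = render_image(ImageSpec(width=64, height=64, noise_sd=0, seed=5))
        background = truth.class_map == BACKGROUND_CODE
        assert np.all(img[background] == 255)
        negative = truth.class_map == int(PixelClass.NEGATIVE)
        assert img[negative].mean() < 230

    def test_normal_skin_preset_is_faint_and_diffuse(self):
        spec = normal_skin_spec(seed=9)
        _, truth = render_image(spec)
        fw, fm, fs = truth.true_fractions
        assert fs == 0.0
        assert fw > fm
        assert 0.0 < truth.true_h_score < 1.0


class TestSimulateCohort:
    def test_sample_and_metadata_counts(self):
        spec = CohortSpec(
            groups=(
                GroupSpec("thin", 3, (0.3, 0.1, 0.1)),
                GroupSpec("thick", 3, (0.2, 0.1, 0.0)),
            ),
            template=ImageSpec(width=32, height=32),
            seed=0,
        )
        samples = simulate_cohort(spec)
        assert len(samples) == 6
        assert sorted({s.group for s in samples}) == ["thick", "thin"]

    def test_zero_spread_shares_true_fractions(self):
        spec = CohortSpec(
            groups=(GroupSpec("thin", 4, (0.3, 0.1, 0.1), between_sample_sd=0.0),),
            template=ImageSpec(width=32, height=32),
            seed=1,
        )
        samples = simulate_cohort(spec)
        fractions = {s.ground_truth.true_fractions for s in samples}
        # identical targets; realized counts may differ by single-pixel rounding
        for f in fractions:
            for got, want in zip(f, (0.3, 0.1, 0.1)):
                assert got == pytest.approx(want, abs=0.01)

    def test_empty_group_list_rejected(self):
        with pytest.raises(ValueError):
            simulate_cohort(CohortSpec(groups=()))

    def test_t_stages_follow_group_pools(self):
        spec = melanoma_study_cohort(
            seed=2, template=ImageSpec(width=32, height=32), n_thin=4, n_thick=4
        )
        samples = simulate_cohort(spec)
        for s in samples:
            if s.group == "thin":
                assert s.t_stage in ("T1", "T2")
            else:
                assert s.t_stage in ("T3", "T4")

    def test_group_mean_true_h_obeys_law_of_large_numbers(self):
        """At n = 200 the realized mean true H-score of a group targeting
        0.95 sits within three standard errors of the target."""
        spec = CohortSpec(
            groups=(GroupSpec("thin", 200, (0.35, 0.15, 0.10)),),
            template=ImageSpec(width=32, height=32),
            seed=3,
        )
        samples = simulate_cohort(spec)
        h = np.array([s.ground_truth.true_h_score for s in samples])
        sem = h.std(ddof=1) / np.sqrt(len(h))
        assert abs(h.mean() - 0.95) <= 3.0 * sem

    def test_cohort_determinism(self):
        spec = melanoma_study_cohort(
            seed=4, template=ImageSpec(width=32, height=32), n_thin=2, n_thick=2
        )
        a = simulate_cohort(spec)
        b = simulate_cohort(spec)
        for sa, sb in zip(a, b):
            assert sa.t_stage == sb.t_stage
            assert np.array_equal(sa.image, sb.image)


class TestWriteCohort:
    def test_output_layout(self, tmp_path):
        spec = CohortSpec(
            groups=(GroupSpec("thin", 2, (0.3, 0.1, 0.1)),),
            template=ImageSpec(width=32, height=32),
            seed=5,
        )
        meta = write_cohort(simulate_cohort(spec), tmp_path)
        with open(meta) as fh:
            rows = list(csv.DictReader(fh))
        assert len(rows) == 2
        assert list(rows[0].keys()) == [
            "sample_id",
            "image",
            "roi",
            "tissue_type",
            "t_stage",
            "n_stage",
            "m_stage",
            "group",
        ]
        for row in rows:
            assert (tmp_path / row["image"]).exists()
            rois = read_roi(tmp_path / row["roi"])
            assert len(rois) == 1
            assert rois.polygons[0].role == "include"
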