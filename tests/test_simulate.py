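"""Generator tests: grading rules, determinism, rendering, cohort assembly."""

import dataclasses

import numpy as np
import pytest

import glaucoscreen as gs
from glaucoscreen.simulate import (
    EyeTruth,
    GONGrade,
    RimDefect,
    Wedge,
    grade_gon,
)


def plain_truth(**overrides) -> EyeTruth:
    """A hand-built eye with an ISNT-conforming rim and no lesions."""
    params = dict(
        disc_center=(256.0, 256.0),
        disc_radii=(90.0, 95.0),
        base_level=0.55,
        dip_superior=(0.08, 130.0),
        dip_inferior=(0.12, 130.0),
        boost_temporal=(0.05, 95.0),
    )
    params.update(overrides)
    return EyeTruth(**params)


class TestGradingRules:
    def test_high_vcdr_is_definite(self):
        truth = plain_truth(base_level=1.0, dip_superior=(0.08, 130.0), dip_inferior=(0.12, 130.0))
        assert truth.vcdr_true >= 0.85
        assert grade_gon(truth).category == "definite"

    def test_localized_notch_is_definite(self):
        truth = plain_truth(defects=(RimDefect(center_deg=190.0, width_deg=40.0, depth=0.2),))
        assert grade_gon(truth).category == "definite"

    def test_moderate_vcdr_is_probable(self):
        truth = plain_truth(base_level=0.85)  # vcdr = 0.85 - 0.10 = 0.75
        assert 0.7 <= truth.vcdr_true < 0.85
        assert grade_gon(truth).category == "probable"

    def test_low_vcdr_no_signs_is_unlikely(self):
        truth = plain_truth(base_level=0.5)
        assert truth.vcdr_true < 0.7
        assert grade_gon(truth).category == "unlikely"

    def test_any_wedge_makes_referable(self):
        truth = plain_truth(base_level=0.5, rnfld_wedges=(Wedge(120.0, 20.0),))
        grade = grade_gon(truth)
        assert grade.category == "probable"
        assert grade.referable

    def test_hemorrhage_is_probable(self):
        truth = plain_truth(base_level=0.5, hemorrhage=True)
        assert grade_gon(truth).category == "probable"

    def test_general_thinning_is_probable(self):
        truth = plain_truth(defects=(RimDefect(center_deg=90.0, width_deg=90.0, depth=0.12),))
        assert grade_gon(truth).category == "probable"

    def test_localized_thinning_outside_vertical_sectors_is_not_probable(self):
        truth = plain_truth(defects=(RimDefect(center_deg=90.0, width_deg=40.0, depth=0.12),))
        assert grade_gon(truth).category == "unlikely"

    def test_localized_thinning_in_vertical_sector_is_probable(self):
        truth = plain_truth(defects=(RimDefect(center_deg=350.0, width_deg=40.0, depth=0.12),))
        assert grade_gon(truth).category == "probable"

    def test_referable_iff_probable_or_definite(self):
        assert not GONGrade("unlikely").referable
        assert GONGrade("probable").referable
        assert GONGrade("definite").referable

    def test_grading_is_pure(self):
        truth = plain_truth(base_level=0.8)
        assert grade_gon(truth) == grade_gon(truth) == truth.grade

    def test_raising_vcdr_never_lowers_grade(self):
        order = {g: i for i, g in enumerate(gs.simulate.GRADE_CATEGORIES)}
        for seed in range(10):
            base = gs.sample_eye_truth("unlikely", seed)
            previous = order[base.grade.category]
            for level in np.linspace(base.base_level, base.base_level + 0.35, 8):
                try:
                    current = order[base.with_base_level(float(level)).grade.category]
                except ValueError:
                    continue
                assert current >= previous
                previous = current

    def test_vcdr_matches_profile_implied_vertical_ratio(self):
        for seed in range(20):
            truth = gs.sample_eye_truth("probable", seed)
            implied = (truth.rim_profile(0.0) + truth.rim_profile(180.0)) / 2.0
            assert truth.vcdr_true == pytest.approx(float(implied), abs=1e-6)


class TestSampling:
    @pytest.mark.parametrize("grade", ["unlikely", "probable", "definite"])
    def test_sampled_truth_has_requested_grade(self, grade):
        for seed in (0, 7, 99):
            truth = gs.sample_eye_truth(grade, seed)
            assert truth.grade.category == grade

    def test_same_seed_reproduces_truth(self):
        assert gs.sample_eye_truth("probable", 3) == gs.sample_eye_truth("probable", 3)

    def test_unlikely_truths_have_no_lesions(self):
        truth = gs.sample_eye_truth("unlikely", 7)
        assert truth.vcdr_true < 0.7
        assert truth.defects == () and truth.rnfld_wedges == ()
        assert not truth.hemorrhage

    def test_definite_truths_show_a_definite_sign(self):
        truth = gs.sample_eye_truth("definite", 7)
        notch = any(d.width_deg < 60 and d.depth >= 0.15 for d in truth.defects)
        assert truth.vcdr_true >= 0.85 or notch

    def test_mcdr_window_is_honoured(self):
        for seed in range(10):
            truth = gs.sample_eye_truth("unlikely", seed, mcdr_range=(0.5, 0.7))
            assert 0.5 <= float(truth.profile_360.mean()) <= 0.7

    def test_rim_profile_values_stay_in_unit_interval(self):
        for grade in gs.simulate.GRADE_CATEGORIES:
            profile = gs.sample_eye_truth(grade, 5).profile_360
            assert np.all(profile >= 0.0) and np.all(profile <= 1.0)

    def test_unknown_grade_rejected(self):
        with pytest.raises(ValueError):
            gs.sample_eye_truth("severe", 1)


class TestRendering:
    def test_masks_are_consistent_with_geometry(self):
        truth = gs.sample_eye_truth("definite", 13)
        image, masks = gs.render_eye(truth, gs.RenderConfig(canvas_size=256, seed=1))
        assert image.shape == (256, 256, 3) and image.dtype == np.uint8
        assert masks.cup.sum() <= masks.disc.sum()
        assert not np.any(masks.cup & ~masks.disc)

    def test_no_wedges_means_empty_rnfld_mask(self):
        truth = gs.sample_eye_truth("unlikely", 3)
        _, masks = gs.render_eye(truth, gs.RenderConfig(canvas_size=256, seed=1))
        assert not masks.rnfld.any()

    def test_rendering_is_deterministic(self):
        truth = gs.sample_eye_truth("probable", 5)
        cfg = gs.RenderConfig(canvas_size=256, seed=9)
        img1, m1 = gs.render_eye(truth, cfg)
        img2, m2 = gs.render_eye(truth, cfg)
        assert np.array_equal(img1, img2)
        assert np.array_equal(m1.disc, m2.disc)

    def test_circular_disc_and_cup_recover_constant_profile(self):
        truth = EyeTruth(
            disc_center=(256.0, 256.0), disc_radii=(100.0, 100.0), base_level=0.5,
            dip_superior=(0.0, 130.0), dip_inferior=(0.0, 130.0), boost_temporal=(0.0, 95.0),
        )
        _, masks = gs.render_eye(truth, gs.RenderConfig(seed=0))
        profile = gs.compute_cdr_profile(masks)
        assert np.all(np.abs(profile.values - 0.5) < 0.02)

    def test_rendered_masks_match_analytic_profile(self):
        truth = gs.sample_eye_truth("probable", 17)
        _, masks = gs.render_eye(truth, gs.RenderConfig(seed=2))
        recovered = gs.compute_cdr_profile(masks).values
        assert np.mean(np.abs(recovered - truth.profile_360)) < 0.02

    def test_oversized_geometry_rejected(self):
        with pytest.raises(ValueError):
            EyeTruth(
                disc_center=(256.0, 256.0), disc_radii=(260.0, 260.0), base_level=0.5,
                dip_superior=(0.0, 130.0), dip_inferior=(0.0, 130.0),
                boost_temporal=(0.0, 95.0),
            )

    def test_left_eye_image_is_mirror_of_right(self):
        truth = gs.sample_eye_truth("unlikely", 23)
        right = dataclasses.replace(truth, laterality="right")
        left = dataclasses.replace(truth, laterality="left")
        cfg = gs.RenderConfig(canvas_size=256, seed=4)
        img_r, masks_r = gs.render_eye(right, cfg)
        img_l, masks_l = gs.render_eye(left, cfg)
        assert np.array_equal(masks_l.disc, masks_r.disc[:, ::-1])
        # and both canonicalize to the same CDR profile
        p_r = gs.compute_cdr_profile(masks_r).values
        p_l = gs.compute_cdr_profile(masks_l).values
        assert np.max(np.abs(p_r - p_l)) < 0.02


class TestCohorts:
    def test_exact_class_mix(self):
        cohort = gs.generate_dataset(
            100, {"unlikely": 0.5, "probable": 0.25, "definite": 0.25}, 1,
            config=gs.RenderConfig(canvas_size=128, seed=1),
        )
        counts = cohort.manifest["grade"].value_counts().to_dict()
        assert counts == {"unlikely": 50, "probable": 25, "definite": 25}

    def test_single_grade_mix(self):
        cohort = gs.generate_dataset(
            10, {"unlikely": 1.0}, 2, config=gs.RenderConfig(canvas_size=128, seed=2)
        )
        assert (cohort.manifest["grade"] == "unlikely").all()

    def test_manifest_is_reproducible(self):
        cfg = gs.RenderConfig(canvas_size=128, seed=3)
        mix = {"unlikely": 0.6, "probable": 0.2, "definite": 0.2}
        m1 = gs.generate_dataset(15, mix, 3, config=cfg).manifest
        m2 = gs.generate_dataset(15, mix, 3, config=cfg).manifest
        assert m1.to_csv(index=False) == m2.to_csv(index=False)

    def test_invalid_mix_rejected(self):
        with pytest.raises(ValueError):
            gs.generate_dataset(10, {"unlikely": 0.5, "probable": 0.2}, 1)

    def test_manifest_schema(self, small_train_cohort):
        assert list(small_train_cohort.manifest.columns) == [
            "id", "laterality", "grade", "referable", "vcdr_true", "seed",
        ]
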