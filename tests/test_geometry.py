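"""Rim-geometry tests against closed-form polar oracles and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import glaucoscreen as gs
from glaucoscreen.geometry import BaselineVector, CDRProfile, MaskSet, standardize_profile

from conftest import circle_mask, ellipse_mask

N = 512
CENTER = (N / 2, N / 2)


def make_masks(disc, cup=None, rnfld=None, laterality="right"):
    zeros = np.zeros_like(disc, dtype=bool)
    return MaskSet(disc=disc, cup=zeros if cup is None else cup,
                   rnfld=zeros if rnfld is None else rnfld, laterality=laterality)


def ellipse_polar_radius(theta_deg, a, b):
    """Closed-form polar radius of an axis-aligned ellipse from its centre.

    theta follows the canonical frame: 0 = up (-row), clockwise, so the
    column component is sin(theta) (horizontal axis a) and the row
    component is cos(theta) (vertical axis b).
    """
    t = np.deg2rad(theta_deg)
    return 1.0 / np.sqrt((np.sin(t) / a) ** 2 + (np.cos(t) / b) ** 2)


class TestCDRProfile:
    def test_concentric_circles_give_constant_ratio(self):
        masks = make_masks(circle_mask(N, CENTER, 100), circle_mask(N, CENTER, 50))
        profile = gs.compute_cdr_profile(masks)
        assert np.all(np.abs(profile.values - 0.5) < 0.02)

    def test_empty_cup_gives_zero_profile(self):
        masks = make_masks(circle_mask(N, CENTER, 100))
        assert np.all(gs.compute_cdr_profile(masks).values == 0.0)

    def test_elliptical_cup_matches_polar_radius_formula(self):
        masks = make_masks(
            circle_mask(N, CENTER, 100), ellipse_mask(N, CENTER, a=60, b=40)
        )
        profile = gs.compute_cdr_profile(masks)
        expected = ellipse_polar_radius(np.arange(360.0), 60, 40) / 100.0
        assert np.mean(np.abs(profile.values - expected)) < 0.02

    def test_empty_disc_rejected(self):
        with pytest.raises(ValueError):
            gs.compute_cdr_profile(make_masks(np.zeros((64, 64), bool)))

    def test_rotation_by_90_degrees_permutes_profile(self):
        # an asymmetric cup: ellipse offset is avoided (centroid must stay
        # put), so use an axis-ratio cup whose profile is angle-dependent
        masks = make_masks(circle_mask(N, CENTER, 100), ellipse_mask(N, CENTER, 70, 40))
        profile = gs.compute_cdr_profile(masks).values
        rot = make_masks(
            np.rot90(masks.disc).copy(), np.rot90(masks.cup).copy()
        )
        profile_rot = gs.compute_cdr_profile(rot).values
        # np.rot90 is a 90-degree counter-clockwise image rotation, which
        # shifts the clockwise-indexed profile by +90 degrees
        assert np.max(np.abs(np.roll(profile, -90) - profile_rot)) < 0.02 + 1e-9

    def test_profile_scale_invariance(self):
        small = make_masks(circle_mask(256, (128, 128), 50), ellipse_mask(256, (128, 128), 30, 20))
        big = make_masks(circle_mask(N, CENTER, 100), ellipse_mask(N, CENTER, 60, 40))
        p_small = gs.compute_cdr_profile(small).values
        p_big = gs.compute_cdr_profile(big).values
        assert np.max(np.abs(p_small - p_big)) < 0.02

    def test_left_eye_profile_is_mirrored(self):
        disc = circle_mask(N, CENTER, 100)
        cup = ellipse_mask(N, CENTER, 60, 40) & circle_mask(N, (CENTER[0], CENTER[1] + 20), 70)
        right = gs.compute_cdr_profile(make_masks(disc, cup, laterality="right")).values
        left = gs.compute_cdr_profile(make_masks(disc, cup, laterality="left")).values
        mirrored = right[(360 - np.arange(360)) % 360]
        assert np.max(np.abs(left - mirrored)) < 0.02


class TestScalarFeatures:
    def test_mean_cdr_is_arithmetic_mean(self):
        profile = CDRProfile(values=np.full(360, 0.5))
        assert gs.mean_cdr(profile) == pytest.approx(0.5)
        two_level = CDRProfile(values=np.r_[np.full(180, 0.3), np.full(180, 0.7)])
        assert gs.mean_cdr(two_level) == pytest.approx(0.5)

    def test_mean_cdr_within_profile_range(self):
        rng = np.random.default_rng(0)
        values = rng.uniform(0, 1, 360)
        m = gs.mean_cdr(CDRProfile(values=values))
        assert values.min() <= m <= values.max()

    def test_vertical_cdr_concentric_circles(self):
        masks = make_masks(circle_mask(N, CENTER, 100), circle_mask(N, CENTER, 50))
        assert gs.vertical_cdr(masks) == pytest.approx(0.5, abs=0.02)

    def test_vertical_cdr_empty_cup_is_zero(self):
        assert gs.vertical_cdr(make_masks(circle_mask(N, CENTER, 100))) == 0.0

    def test_vertical_cdr_matches_generator_truth(self):
        truth = gs.sample_eye_truth("probable", 21)
        _, masks = gs.render_eye(truth)
        assert gs.vertical_cdr(masks) == pytest.approx(truth.vcdr_true, abs=0.02)


class TestStandardization:
    def test_constant_profile_degenerates_to_zero(self):
        z, degenerate = standardize_profile(CDRProfile(values=np.full(360, 0.4)))
        assert degenerate
        assert np.all(z == 0.0)

    def test_two_level_profile_standardizes_to_unit_values(self):
        values = np.r_[np.full(180, 0.2), np.full(180, 0.8)]
        z, degenerate = standardize_profile(CDRProfile(values=values))
        assert not degenerate
        assert np.allclose(np.abs(z), 1.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_output_is_always_mean_zero_unit_sd(self, seed):
        rng = np.random.default_rng(seed)
        z, degenerate = standardize_profile(rng.uniform(0, 1, 360))
        assert not degenerate
        assert abs(z.mean()) < 1e-9
        assert abs(z.std() - 1.0) < 1e-9


class TestBaselineAndISNT:
    def test_baseline_of_identical_profiles_is_their_standardization(self):
        rng = np.random.default_rng(3)
        values = rng.uniform(0.2, 0.8, 360)
        baseline = gs.build_baseline([CDRProfile(values=values)] * 5)
        z, _ = standardize_profile(values)
        assert np.allclose(baseline.values, z)
        assert baseline.n_source_eyes == 5

    def test_baseline_of_two_profiles_is_standardized_average(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(0.2, 0.8, 360)
        q = rng.uniform(0.2, 0.8, 360)
        baseline = gs.build_baseline([p, q])
        z, _ = standardize_profile((p + q) / 2.0)
        assert np.allclose(baseline.values, z)

    def test_empty_profile_list_rejected(self):
        with pytest.raises(ValueError):
            gs.build_baseline([])

    def test_normal_baseline_is_bimodal_with_nasal_temporal_peaks(self):
        """ISNT-conforming rims dip at the vertical poles, so the averaged
        normal profile has exactly two local maxima, on the nasal and
        temporal sides of the circle."""
        profiles = [
            gs.sample_eye_truth("unlikely", seed).profile_360 for seed in range(500)
        ]
        baseline = gs.build_baseline(profiles)
        v = baseline.values
        maxima = [
            i for i in range(360)
            if v[i] > v[(i - 1) % 360] and v[i] >= v[(i + 1) % 360]
        ]
        assert len(maxima) == 2
        for m in maxima:
            assert 45 <= m <= 135 or 225 <= m <= 315  # nasal / temporal quadrant

    def test_self_score_is_one_and_antiprofile_minus_one(self):
        rng = np.random.default_rng(5)
        values = rng.uniform(0.2, 0.8, 360)
        baseline = gs.build_baseline([values])
        assert gs.isnt_score(values, baseline) == pytest.approx(1.0, abs=1e-9)
        z, _ = standardize_profile(values)
        anti = BaselineVector(values=-z, n_source_eyes=1)
        assert gs.isnt_score(values, anti) == pytest.approx(-1.0, abs=1e-9)

    def test_constant_profile_scores_zero(self):
        baseline = gs.build_baseline([np.random.default_rng(6).uniform(0, 1, 360)])
        assert gs.isnt_score(np.full(360, 0.7), baseline) == 0.0

    @given(st.floats(0.05, 5.0), st.floats(-0.3, 0.3))
    @settings(max_examples=25, deadline=None)
    def test_affine_invariance_of_isnt_score(self, alpha, beta):
        rng = np.random.default_rng(7)
        values = rng.uniform(0.3, 0.6, 360)
        baseline = gs.build_baseline([rng.uniform(0.2, 0.8, 360)])
        mapped = np.clip(alpha * values + beta, 0.0, 1.0)
        # only meaningful while the affine map stays inside [0, 1]
        if np.any(mapped != alpha * values + beta):
            return
        assert gs.isnt_score(mapped, baseline) == pytest.approx(
            gs.isnt_score(values, baseline), abs=1e-9
        )

    def test_isnt_scores_bounded(self, small_baseline):
        for seed in range(20):
            truth = gs.sample_eye_truth("definite", seed)
            score = gs.isnt_score(truth.profile_360, small_baseline)
            assert -1.0 <= score <= 1.0


class TestMaskSet:
    def test_cup_is_intersected_with_disc(self):
        disc = circle_mask(128, (64, 64), 30)
        cup = circle_mask(128, (64, 94), 20)  # sticks out of the disc
        masks = make_masks(disc, cup)
        assert not np.any(masks.cup & ~masks.disc)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            MaskSet(disc=np.zeros((4, 4), bool), cup=np.zeros((5, 5), bool),
                    rnfld=np.zeros((4, 4), bool))
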