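"""Flicker-area estimation: STD chain, particle boxes, Bessel reconstruction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stripeflick import (
    FilterParams,
    TimeLapse,
    binarize_particles,
    collapse_std,
    enhance,
    extend_boxes,
    flicker_area,
    joint_rescale,
    reconstruction_length,
    std_timelapse,
)
from stripeflick.flicker import FlickerMap, StdLapse, bandpass, variance_filter


def lapse(frames):
    return StdLapse(np.asarray(frames, dtype=float), window=5, step=5)


class TestStdTimelapse:
    def test_constant_stack_gives_zeros(self):
        out = std_timelapse(TimeLapse(np.full((25, 8, 8), 3.0), 44.0), 5, 5)
        np.testing.assert_array_equal(out.frames, 0.0)
        assert out.frames.shape[0] == 5

    def test_alternating_pixel_matches_direct_formula(self):
        data = np.zeros((10, 4, 4))
        data[::2, 2, 2] = 2.0  # pixel alternates 2, 0
        out = std_timelapse(TimeLapse(data, 44.0), 4, 4)
        # independent oracle: sample STD of [2,0,2,0]
        expected = np.std([2.0, 0.0, 2.0, 0.0], ddof=1)
        np.testing.assert_allclose(out.frames[:, 2, 2], expected)
        assert np.all(out.frames[:, 0, 0] == 0.0)

    def test_window_count(self):
        out = std_timelapse(TimeLapse(np.zeros((25, 4, 4)), 44.0), 5, 5)
        assert out.frames.shape[0] == (25 - 5) // 5 + 1

    def test_window_exceeding_frames_rejected(self):
        with pytest.raises(ValueError):
            std_timelapse(TimeLapse(np.zeros((3, 4, 4)), 44.0), 5, 5)


class TestJointRescale:
    def test_identical_lapses_map_to_unit_range(self):
        a = lapse(np.random.default_rng(0).uniform(5, 9, (3, 6, 6)))
        a2, b2 = joint_rescale(a, lapse(a.frames.copy()))
        np.testing.assert_allclose(a2.frames, b2.frames)
        assert a2.frames.min() == 0.0 and a2.frames.max() == 1.0

    def test_halved_lapse_keeps_ratio(self):
        a = lapse(np.linspace(0, 10, 48).reshape(3, 4, 4))
        b = lapse(a.frames / 2)
        a2, b2 = joint_rescale(a, b)
        assert a2.frames.max() == 1.0
        assert b2.frames.max() == pytest.approx(0.5)

    def test_argmax_preserved(self):
        rng = np.random.default_rng(2)
        a, b = lapse(rng.uniform(0, 7, (2, 5, 5))), lapse(rng.uniform(0, 3, (2, 5, 5)))
        a2, b2 = joint_rescale(a, b)
        assert np.argmax(a2.frames) == np.argmax(a.frames)
        assert np.argmax(b2.frames) == np.argmax(b.frames)

    def test_degenerate_pair_warns_and_zeroes(self):
        a = lapse(np.full((2, 3, 3), 4.0))
        with pytest.warns(UserWarning):
            a2, b2 = joint_rescale(a, lapse(a.frames.copy()))
        np.testing.assert_array_equal(a2.frames, 0.0)


class TestEnhance:
    def test_gamma_fixed_points_at_endpoints(self):
        from stripeflick.flicker import apply_gamma

        v = np.array([0.0, 1.0])
        np.testing.assert_array_equal(apply_gamma(v, 1.1), v)

    def test_variance_filter_zero_on_constant_frame(self):
        assert variance_filter(np.full((10, 10), 3.3), 2).max() == pytest.approx(0.0, abs=1e-12)

    def test_bandpass_suppresses_tiny_blob_keeps_stripe(self):
        frame = np.zeros((80, 80))
        frame[40, 40] = 1.0  # ~1-2 px blob
        stripe = np.zeros((80, 80))
        stripe[30:40, :] = 1.0  # 10-px-tall stripe, mid-band structure
        bp_blob = bandpass(frame, 3, 40)
        bp_stripe = bandpass(stripe, 3, 40)
        assert bp_stripe.max() > 5 * bp_blob.max()
        # oracle: explicit difference of two Gaussian filters
        from scipy.ndimage import gaussian_filter

        expected = gaussian_filter(stripe, 1.5, mode="nearest") - gaussian_filter(
            stripe, 20.0, mode="nearest"
        )
        np.testing.assert_allclose(bp_stripe, expected, atol=1e-10)


class TestCollapseStd:
    def test_identical_frames_collapse_to_zero(self):
        out = collapse_std(lapse(np.ones((4, 5, 5))))
        np.testing.assert_array_equal(out, 0.0)

    def test_alternating_frames_match_direct_formula(self):
        frames = np.zeros((6, 3, 3))
        frames[::2] = 1.0
        out = collapse_std(lapse(frames))
        np.testing.assert_allclose(out, np.std([1.0, 0, 1, 0, 1, 0], ddof=1))

    def test_single_divergent_row(self):
        frames = np.zeros((3, 6, 6))
        frames[1, 2, :] = 5.0
        out = collapse_std(lapse(frames))
        assert np.all(out[2] > 0)
        out[2] = 0
        np.testing.assert_array_equal(out, 0.0)

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            collapse_std(lapse(np.zeros((1, 3, 3))))


class TestBinarizeParticles:
    def test_all_below_threshold_gives_no_particles(self):
        fm = binarize_particles(np.zeros((6, 6)), 0.2, np.ones((6, 6), bool))
        assert fm.particles == []

    def test_two_disjoint_squares(self):
        img = np.zeros((20, 20))
        img[2:5, 2:5] = 1.0
        img[10:13, 14:17] = 1.0
        fm = binarize_particles(img, 0.5, np.ones((20, 20), bool))
        assert sorted(fm.particles) == [(2, 2, 3, 3), (10, 14, 3, 3)]

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_boxes_match_brute_force_min_max(self, seed):
        rng = np.random.default_rng(seed)
        img = (rng.random((24, 24)) > 0.8).astype(float)
        fm = binarize_particles(img, 0.5, np.ones((24, 24), bool))
        # oracle: label independently and take min/max row/col per component
        from scipy import ndimage as ndi

        labels, n = ndi.label(img > 0.5, structure=np.ones((3, 3)))
        expected = set()
        for lab in range(1, n + 1):
            rr, cc = np.where(labels == lab)
            expected.add(
                (rr.min(), cc.min(), rr.max() - rr.min() + 1, cc.max() - cc.min() + 1)
            )
        assert set(fm.particles) == expected

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            binarize_particles(np.ones((4, 4)), 0.5, np.zeros((4, 4), bool))


class TestReconstructionLength:
    @pytest.mark.parametrize(
        "h,beta,form,expected",
        [
            (0, 0.3, "physical", 0),
            (0, 0.3, "literal", 0),
            (10, math.pi / 4, "physical", 5),
            (10, math.pi / 4, "literal", 5),
            (10, 0.1, "physical", 50),  # ceil(5 / tan(0.1)) = ceil(49.83) = 50
            (10, 0.1, "literal", 1),  # ceil(tan(0.1) * 5) = ceil(0.502) = 1
            (8, 0.12, "physical", 34),  # ceil(4 / 0.12058) = ceil(33.17)
            (7, 0.2, "literal", 1),  # ceil(0.2027 * 3.5) = ceil(0.7095)
        ],
    )
    def test_hand_computed_grid(self, h, beta, form, expected):
        assert reconstruction_length(h, beta, form) == expected

    def test_invalid_angle_rejected(self):
        for beta in (0.0, -0.1, math.pi / 2):
            with pytest.raises(ValueError):
                reconstruction_length(5, beta)

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 200), st.floats(0.01, 1.5))
    def test_matches_closed_form_ceiling(self, h, beta):
        x = reconstruction_length(h, beta, "physical")
        exact = 0.5 * h / math.tan(beta)
        assert x - 1 < exact <= x + 1e-6


class TestExtendBoxes:
    def test_no_particles_gives_zero_fraction(self):
        fm = FlickerMap(mask=np.zeros((10, 10), bool), particles=[])
        out = extend_boxes(fm, "gaussian", 0.12, np.ones((10, 10), bool))
        assert out.affected_fraction == 0.0

    def test_gaussian_box_covers_full_mask_width(self):
        mask = np.zeros((20, 30), bool)
        mask[:, 5:25] = True  # rectangular mask of width 20
        fm = FlickerMap(mask=np.zeros((20, 30), bool), particles=[(4, 10, 5, 3)])
        out = extend_boxes(fm, "gaussian", 0.12, mask)
        assert out.affected_fraction == pytest.approx(5 * 20 / mask.sum())

    def test_gaussian_fraction_dominates_bessel(self):
        mask = np.ones((40, 60), bool)
        fm = FlickerMap(mask=np.zeros((40, 60), bool), particles=[(10, 5, 6, 4)])
        g = extend_boxes(fm, "gaussian", 0.1, mask)
        b = extend_boxes(fm, "bessel", 0.1, mask)
        assert g.affected_fraction >= b.affected_fraction

    def test_extended_boxes_contain_particles(self):
        mask = np.ones((30, 30), bool)
        fm = FlickerMap(mask=np.zeros((30, 30), bool), particles=[(3, 4, 5, 6)])
        for modality in ("gaussian", "bessel"):
            out = extend_boxes(fm, modality, 0.12, mask)
            (t, l, h, w) = out.extended_boxes[0]
            assert t <= 3 and l <= 4 and t + h >= 3 + 5 and l + w >= 4 + 6


class TestFullChain:
    def test_static_scene_pair_yields_zero_fractions(self):
        rng = np.random.default_rng(0)
        frame = rng.uniform(100, 200, (32, 32))
        static = TimeLapse(np.repeat(frame[None], 30, axis=0), 44.0)
        fm_g, fm_b = flicker_area(static, static)
        assert fm_g.affected_fraction == 0.0
        assert fm_b.affected_fraction == 0.0

    def test_recovers_truth_fraction_on_absorber_scene(self, absorber_truth, absorber_pair):
        g, b = absorber_pair
        fm_g, fm_b = flicker_area(g, b, beta=absorber_truth.config.cone_angle_beta)
        truth_frac = absorber_truth.flicker_truth_masks["gaussian"].mean()
        assert fm_g.affected_fraction == pytest.approx(truth_frac, rel=0.20)
        assert fm_g.affected_fraction >= fm_b.affected_fraction

    def test_chain_invariant_to_shared_gain(self, absorber_pair):
        g, b = absorber_pair
        fm1 = flicker_area(g, b)
        g2 = TimeLapse(g.data * 3.0, g.frame_rate, g.modality)
        b2 = TimeLapse(b.data * 3.0, b.frame_rate, b.modality)
        fm2 = flicker_area(g2, b2)
        assert fm1[0].affected_fraction == pytest.approx(fm2[0].affected_fraction)
        assert fm1[1].affected_fraction == pytest.approx(fm2[1].affected_fraction)

    def test_fraction_monotone_in_threshold(self, absorber_pair):
        g, b = absorber_pair
        fracs = []
        for thr in (0.05, 0.2, 0.5, 0.8):
            fm_g, _ = flicker_area(g, b, FilterParams(threshold=thr))
            fracs.append(fm_g.affected_fraction)
        assert all(x >= y for x, y in zip(fracs, fracs[1:]))

    def test_row_support_matches_truth(self, absorber_truth, absorber_pair):
        """Jaccard of estimated vs true flicker row-support at default params."""
        g, b = absorber_pair
        fm_g, _ = flicker_area(g, b, beta=absorber_truth.config.cone_angle_beta)
        est_rows = fm_g.extended_mask.any(axis=1)
        true_rows = absorber_truth.flicker_truth_masks["gaussian"].any(axis=1)
        jaccard = (est_rows & true_rows).sum() / (est_rows | true_rows).sum()
        assert jaccard >= 0.8
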