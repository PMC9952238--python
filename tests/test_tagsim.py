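"""Bloch-simulated SPAMM tagging: profiles, grid pattern, fading, full transform."""

import numpy as np
import pytest

from cine2tag import (
    ConfigurationError,
    ImageFrame,
    SegMask,
    TagPrepConfig,
    apply_fading,
    contrast_transform,
    make_grid_pattern,
    measure_tag_period,
    simulate_spamm_profile,
    transform_cine_to_tagged,
)
from oracles import spamm_mz_matrix_oracle


class TestContrastTransform:
    def test_square_root_values(self):
        img = ImageFrame(np.array([[0.0, 0.25], [0.5, 1.0]]))
        out = contrast_transform(img)
        np.testing.assert_allclose(out.data, np.sqrt([[0.0, 0.25], [0.5, 1.0]]))

    def test_endpoints_fixed_and_monotone(self, rng):
        img = ImageFrame(rng.random((32, 32)))
        out = contrast_transform(img).data
        norm = (img.data - img.data.min()) / (img.data.max() - img.data.min())
        assert out.min() == 0.0 and out.max() == 1.0
        flat_in, flat_out = norm.ravel(), out.ravel()
        order = np.argsort(flat_in)
        assert (np.diff(flat_out[order]) >= 0).all()

    def test_preserves_spacing_metadata(self):
        img = ImageFrame(np.linspace(0, 1, 16).reshape(4, 4), spacing_mm=(1.5, 2.0))
        assert contrast_transform(img).spacing_mm == (1.5, 2.0)


class TestSpammProfile:
    def test_zero_flip_is_identity(self):
        psi = np.linspace(0, 2 * np.pi, 17)
        np.testing.assert_array_equal(simulate_spamm_profile(psi, 0.0), np.ones_like(psi))

    def test_coherent_phase_gives_cos_total_flip(self):
        """At psi=0 the sub-rotations add coherently: Mz = cos(total flip)."""
        for weights in [(1, 3, 3, 1), (1, 1), (2, 5, 2), (1,)]:
            mz = simulate_spamm_profile(np.array([0.0]), 70.0, weights)
            assert abs(mz[0] - np.cos(np.deg2rad(70))) < 1e-9

    def test_one_one_spamm_closed_form(self):
        """1-1 SPAMM at 90 degrees has the textbook profile (1 - cos psi)/2."""
        psi = np.linspace(0, 2 * np.pi, 101)
        mz = simulate_spamm_profile(psi, 90.0, (1.0, 1.0))
        np.testing.assert_allclose(mz, (1 - np.cos(psi)) / 2, atol=1e-9)

    def test_matches_rotation_matrix_oracle(self, rng):
        """100 random (psi, flip, weights) draws agree with explicit 3x3 composition."""
        for _ in range(100):
            psi = float(rng.uniform(0, 2 * np.pi))
            flip = float(rng.uniform(0, 180))
            weights = tuple(rng.uniform(0.1, 5.0, size=int(rng.integers(1, 6))))
            mine = simulate_spamm_profile(np.array([psi]), flip, weights)[0]
            assert abs(mine - spamm_mz_matrix_oracle(psi, flip, weights)) < 1e-9

    def test_magnetization_magnitude_bounded(self, rng):
        psi = rng.uniform(0, 2 * np.pi, size=1000)
        mz = simulate_spamm_profile(psi, 137.0, (1, 3, 3, 1))
        assert np.all(np.abs(mz) <= 1 + 1e-12)

    @pytest.mark.parametrize("weights", [(), (1.0, -1.0), (0.0, 1.0)])
    def test_bad_weights_rejected(self, weights):
        with pytest.raises(ConfigurationError):
            simulate_spamm_profile(np.array([0.0]), 70.0, weights)


class TestGridPattern:
    def test_zero_flip_all_ones(self):
        cfg = TagPrepConfig(total_flip_deg=0.0)
        np.testing.assert_array_equal(make_grid_pattern((32, 32), cfg), np.ones((32, 32)))

    def test_unrotated_grid_is_separable(self):
        """At rotation 0 the pattern is the outer product of the two 1D profiles."""
        cfg = TagPrepConfig(rotation_deg=0.0)
        pattern = make_grid_pattern((20, 30), cfg)
        k = 2 * np.pi / cfg.spacing_px
        prof_r = simulate_spamm_profile(k * np.arange(20), cfg.total_flip_deg, cfg.weights)
        prof_c = simulate_spamm_profile(k * np.arange(30), cfg.total_flip_deg, cfg.weights)
        np.testing.assert_allclose(pattern, np.outer(prof_r, prof_c), atol=1e-12)

    def test_periodicity_along_rotated_axes(self):
        """The pattern repeats with the tag spacing along each rotated axis.

        Checked exactly at rotation 0 where a spacing_px shift maps pixels to
        pixels.
        """
        cfg = TagPrepConfig(rotation_deg=0.0, spacing_px=5.0)
        pattern = make_grid_pattern((40, 40), cfg)
        np.testing.assert_allclose(pattern[5:, :], pattern[:-5, :], atol=1e-12)
        np.testing.assert_allclose(pattern[:, 5:], pattern[:, :-5], atol=1e-12)

    def test_origin_is_dark_line_crossing(self):
        cfg = TagPrepConfig()
        pattern = make_grid_pattern((16, 16), cfg)
        expected = np.cos(np.deg2rad(70.0)) ** 2
        assert abs(pattern[0, 0] - expected) < 1e-12
        assert abs(pattern[0, 0]) == np.abs(pattern).min()

    def test_spacing_below_nyquist_rejected(self):
        with pytest.raises(ConfigurationError):
            TagPrepConfig(spacing_px=1.5)


class TestFading:
    def _cfg(self, **kw):
        return TagPrepConfig(fade_enabled=True, t1_ms=850.0, frame_interval_ms=40.0, **kw)

    def test_frame_zero_identity(self):
        pattern = make_grid_pattern((16, 16), self._cfg())
        np.testing.assert_array_equal(apply_fading(pattern, 0, self._cfg()), pattern)

    def test_relaxation_law_at_t1(self):
        """After exactly one T1 the deviation from recovery shrinks by 1/e."""
        cfg = TagPrepConfig(fade_enabled=True, t1_ms=200.0, frame_interval_ms=200.0)
        pattern = make_grid_pattern((16, 16), cfg)
        faded = apply_fading(pattern, 1, cfg)
        np.testing.assert_allclose(faded, 1 + (pattern - 1) / np.e, atol=1e-12)

    def test_contrast_monotonically_fades(self):
        cfg = self._cfg()
        pattern = make_grid_pattern((32, 32), cfg)
        contrasts = [np.ptp(apply_fading(pattern, i, cfg)) for i in range(8)]
        assert all(a >= b for a, b in zip(contrasts, contrasts[1:]))

    def test_disabled_fading_is_passthrough(self):
        cfg = TagPrepConfig(fade_enabled=False)
        pattern = make_grid_pattern((16, 16), cfg)
        assert apply_fading(pattern, 7, cfg) is pattern


class TestFullTransform:
    def test_zero_flip_reduces_to_contrast_transform(self, rng):
        img = ImageFrame(rng.random((64, 64)))
        mask = SegMask((rng.random((64, 64)) < 0.2).astype(np.uint8))
        cfg = TagPrepConfig(total_flip_deg=0.0)
        tagged, out_mask = transform_cine_to_tagged(img, mask, config=cfg)
        np.testing.assert_array_equal(tagged.data, contrast_transform(img).data)
        np.testing.assert_array_equal(out_mask.data, mask.data)

    def test_mask_transferred_bit_identical(self, phantom_pair):
        img, mask = phantom_pair
        _, out_mask = transform_cine_to_tagged(img, mask)
        np.testing.assert_array_equal(out_mask.data, mask.data)
        assert out_mask.data.dtype == mask.data.dtype

    def test_tag_lines_static_across_frames(self, uniform_image, empty_mask_256):
        """Without fading, every frame of a static scene gets the same tags."""
        cfg = TagPrepConfig()
        first, _ = transform_cine_to_tagged(uniform_image, empty_mask_256, 0, cfg)
        later, _ = transform_cine_to_tagged(uniform_image, empty_mask_256, 10, cfg)
        np.testing.assert_array_equal(first.data, later.data)

    def test_default_tag_period_is_five_pixels(self, uniform_image, empty_mask_256):
        tagged, _ = transform_cine_to_tagged(uniform_image, empty_mask_256)
        period = measure_tag_period(tagged, rotation_deg=45.0)
        assert abs(period - 5.0) < 0.05

    def test_output_range_normalized(self, phantom_pair):
        img, mask = phantom_pair
        tagged, _ = transform_cine_to_tagged(img, mask)
        assert tagged.data.min() == 0.0 and tagged.data.max() == 1.0


def test_measured_period_tracks_spacing(uniform_image, empty_mask_256):
    for spacing, rot in [(4.0, 45.0), (7.0, 30.0), (5.0, 0.0)]:
        cfg = TagPrepConfig(spacing_px=spacing, rotation_deg=rot)
        tagged, _ = transform_cine_to_tagged(uniform_image, empty_mask_256, config=cfg)
        assert abs(measure_tag_period(tagged, rotation_deg=rot) - spacing) < 0.1
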