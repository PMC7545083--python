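"""Unit tests for the stimulus-synthesis chain."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pareidolia.stimuli import (
    DEFAULT_NOISE_LEVELS,
    FilterSpec,
    GeometryConfig,
    RMS_RANGE,
    angular_size,
    bandpass_filter,
    build_stimulus_set,
    compute_rms_contrast,
    filter_gain,
    generate_pink_noise,
    location_side,
    pixel_mix,
    place_signal,
    prepare_signal_image,
    scale_to_rms,
)
from pareidolia.signals import draw_face, draw_flower


def fitted_spectral_slope(pixels: np.ndarray) -> float:
    """Independent slope oracle: least-squares fit of radially averaged
    log-amplitude against log-frequency, DC excluded."""
    n = pixels.shape[0]
    amp = np.abs(np.fft.fft2(pixels - pixels.mean()))
    fy = np.fft.fftfreq(n)[:, None]
    fx = np.fft.fftfreq(n)[None, :]
    f = np.hypot(fy, fx)
    mask = f > 0
    bins = np.logspace(np.log10(1.0 / n), np.log10(0.5), 25)
    idx = np.digitize(f[mask], bins)
    lf, la = [], []
    for b in range(1, len(bins)):
        sel = idx == b
        if sel.sum() > 5:
            lf.append(np.log10(f[mask][sel].mean()))
            la.append(np.log10(amp[mask][sel].mean()))
    return float(np.polyfit(lf, la, 1)[0])


class TestPinkNoise:
    def test_spectral_slope_near_minus_one(self):
        field = generate_pink_noise(400, 400, 128.0, seed=1)
        assert -1.1 <= fitted_spectral_slope(field.pixels) <= -0.9

    def test_mean_level_and_determinism(self):
        a = generate_pink_noise(200, 200, 100.0, seed=7)
        b = generate_pink_noise(200, 200, 100.0, seed=7)
        c = generate_pink_noise(200, 200, 100.0, seed=8)
        assert a.pixels.mean() == pytest.approx(100.0, abs=1e-9)
        np.testing.assert_array_equal(a.pixels, b.pixels)
        assert not np.array_equal(a.pixels, c.pixels)

    def test_rejects_tiny_dimensions(self):
        with pytest.raises(ValueError):
            generate_pink_noise(4, 400, 128.0, seed=0)


class TestSignalPreparation:
    @pytest.mark.parametrize(
        "draw, width", [(draw_face, 110), (draw_flower, 120)]
    )
    def test_height_and_mean_matching(self, draw, width):
        sig = prepare_signal_image(draw(0), target_height=150, reference_mean=128.0)
        assert sig.pixels.shape[0] == 150
        assert sig.width_px == width
        assert sig.pixels.mean() == pytest.approx(128.0, abs=0.5)

    def test_mean_already_matched_unchanged(self):
        raw = np.full((150, 100), 90.0)
        out = prepare_signal_image(raw, 150, 90.0)
        np.testing.assert_allclose(out.pixels, raw)

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            prepare_signal_image(np.empty((0, 0)), 150, 128.0)


class TestPlacement:
    def test_eight_locations_split_by_hemifield(self):
        sides = [location_side(i) for i in range(8)]
        assert sides.count("left") == 4 and sides.count("right") == 4
        with pytest.raises(ValueError):
            location_side(8)

    @pytest.mark.parametrize("loc", range(8))
    def test_footprint_confined_to_its_half(self, loc):
        field = generate_pink_noise(400, 400, 128.0, seed=3)
        sig = prepare_signal_image(draw_face(0), 150, 128.0)
        grid = place_signal(sig, field, loc)
        changed = np.argwhere(grid != field.pixels)
        assert len(changed) > 0
        cols = changed[:, 1]
        if loc < 4:
            assert cols.max() < 200
        else:
            assert cols.min() >= 200

    def test_untouched_outside_footprint(self):
        field = generate_pink_noise(400, 400, 128.0, seed=3)
        sig = prepare_signal_image(draw_face(0), 150, 128.0)
        grid = place_signal(sig, field, 0)
        footprint = grid != field.pixels
        np.testing.assert_array_equal(grid[~footprint], field.pixels[~footprint])


class TestPixelMix:
    def test_exact_noise_pixel_count(self):
        a = np.zeros((400, 400))
        b = np.ones((400, 400))
        mixed = pixel_mix(a, b, 0.44, seed=1)
        assert int(mixed.sum()) == 70400  # round(0.44 * 160000)

    @pytest.mark.parametrize("frac, expect_src", [(0.0, "signal"), (1.0, "noise")])
    def test_degenerate_fractions(self, frac, expect_src):
        rng = np.random.default_rng(0)
        a, b = rng.random((50, 50)), rng.random((50, 50))
        mixed = pixel_mix(a, b, frac, seed=2)
        np.testing.assert_array_equal(mixed, a if expect_src == "signal" else b)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pixel_mix(np.zeros((10, 10)), np.zeros((9, 10)), 0.5)


class TestContrast:
    def test_constant_image_zero_contrast(self):
        assert compute_rms_contrast(np.full((20, 20), 77.0)) == 0.0

    def test_two_valued_image(self):
        img = np.concatenate([np.full(200, 96.0), np.full(200, 160.0)])
        assert compute_rms_contrast(img) == pytest.approx(0.25, abs=1e-12)

    @given(st.floats(min_value=0.1, max_value=10.0))
    @settings(derandomize=True, max_examples=25)
    def test_scale_invariance(self, k):
        rng = np.random.default_rng(9)
        img = rng.uniform(50, 200, size=(30, 30))
        assert compute_rms_contrast(img * k) == pytest.approx(
            compute_rms_contrast(img), rel=1e-9
        )

    def test_scale_to_rms_hits_target(self):
        field = generate_pink_noise(200, 200, 128.0, seed=11).pixels
        out = scale_to_rms(field, 0.25)
        assert compute_rms_contrast(out) == pytest.approx(0.25, abs=1e-9)
        assert out.mean() == pytest.approx(field.mean(), abs=1e-9)

    def test_constant_image_cannot_scale(self):
        with pytest.raises(ValueError):
            scale_to_rms(np.full((10, 10), 5.0), 0.3)


class TestBandpass:
    def test_octave_half_height_gains(self):
        spec = FilterSpec()
        assert filter_gain(1.5, spec) == pytest.approx(1.0, abs=1e-12)
        assert filter_gain(1.5 * 2**-0.5, spec) == pytest.approx(0.5, abs=1e-6)
        assert filter_gain(1.5 * 2**0.5, spec) == pytest.approx(0.5, abs=1e-6)
        lo, hi = spec.half_height_cpd
        assert hi / lo == pytest.approx(2.0, abs=1e-12)

    def test_cycles_per_image_at_defaults(self):
        geom, spec = GeometryConfig(), FilterSpec()
        assert spec.center_cpd * geom.image_deg == pytest.approx(6.3)

    def test_dc_preserved_by_recentering(self):
        img = np.full((64, 64), 120.0)
        out = bandpass_filter(
            img, FilterSpec(), GeometryConfig(image_px=64, signal_height_px=32)
        )
        np.testing.assert_allclose(out, img, atol=1e-9)

    def test_center_above_nyquist_rejected(self):
        geom = GeometryConfig(image_px=16, image_deg=4.2, signal_height_px=8)
        with pytest.raises(ValueError):
            bandpass_filter(np.zeros((16, 16)), FilterSpec(center_cpd=3.0), geom)

    def test_target_rms_enforced(self):
        field = generate_pink_noise(400, 400, 128.0, seed=2).pixels
        out = bandpass_filter(field, FilterSpec(), GeometryConfig(), target_rms=0.30)
        assert compute_rms_contrast(out) == pytest.approx(0.30, abs=1e-9)


class TestGeometry:
    @pytest.mark.parametrize(
        "px, expected", [(400, 4.2), (150, 1.575), (0, 0.0)]
    )
    def test_angular_size(self, px, expected):
        assert angular_size(px) == pytest.approx(expected, abs=1e-9)

    def test_signal_height_prints_as_157(self):
        assert round(angular_size(150), 2) == 1.57

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            GeometryConfig(image_px=100, signal_height_px=150)


class TestStimulusSet:
    def test_counts_and_levels(self, small_stimulus_set):
        faces = [c for c in small_stimulus_set.composites if c.category == "face"]
        flowers = [c for c in small_stimulus_set.composites if c.category == "flower"]
        # 2 identities x 4 levels x 2 images per cell
        assert len(faces) == len(flowers) == 16
        assert len(small_stimulus_set.noise_only) == 32
        assert sorted({c.noise_fraction for c in faces}) == [0.44, 0.46, 0.48, 0.50]
        assert sorted({c.noise_fraction for c in flowers}) == [0.38, 0.40, 0.42, 0.44]

    def test_rms_within_range_and_manifest_complete(self, small_stimulus_set):
        lo, hi = RMS_RANGE
        for rec in small_stimulus_set.manifest:
            assert lo <= rec["rms_contrast"] <= hi
            assert rec["image_id"]
        ids = [rec["image_id"] for rec in small_stimulus_set.manifest]
        assert len(ids) == len(set(ids))

    def test_determinism(self):
        from pareidolia.stimuli import GeometryConfig

        geom = GeometryConfig(image_px=96, image_deg=4.2, signal_height_px=36)
        a = build_stimulus_set(geometry=geom, seed=5, images_per_cell=1)
        b = build_stimulus_set(geometry=geom, seed=5, images_per_cell=1)
        assert a.manifest == b.manifest
        np.testing.assert_array_equal(a.composites[0].pixels, b.composites[0].pixels)

    def test_save_round_trip(self, tmp_path):
        from pareidolia.stimuli import GeometryConfig

        geom = GeometryConfig(image_px=96, image_deg=4.2, signal_height_px=36)
        sset = build_stimulus_set(geometry=geom, seed=5, images_per_cell=1)
        sset.save(tmp_path)
        assert (tmp_path / "manifest.jsonl").exists()
        pngs = list(tmp_path.glob("*.png"))
        assert len(pngs) == len(sset.manifest)
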