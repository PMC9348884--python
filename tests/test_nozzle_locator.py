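import numpy as np
import pytest
from skimage.feature import match_template as skimage_match

from _oracles import zncc_brute_force
from jetvision import (
    Frame,
    MatchResult,
    NozzleTemplate,
    PipelineConfig,
    crop,
    default_nozzle_template,
    derive_roi,
    match_template,
    zncc_map,
)
from jetvision.errors import DimensionError, LocationError
from jetvision.synthetic_jet import SceneParams, render_scene


def _paste_frame(template: np.ndarray, at=(5, 7), shape=(40, 40), bg=20000):
    img = np.full(shape, bg, dtype=np.uint16)
    r, c = at
    img[r : r + template.shape[0], c : c + template.shape[1]] = template
    return img


class TestZncc:
    def test_perfect_paste_scores_one_at_location(self, rng):
        tpl = rng.integers(0, 65536, size=(8, 8), dtype=np.uint16)
        frame = Frame(_paste_frame(tpl, (5, 7)))
        m = match_template(frame, NozzleTemplate(tpl, (0, 0)))
        assert m.top_left_rc == (5, 7)
        assert m.score == pytest.approx(1.0, abs=1e-9)

    def test_affine_intensity_invariance(self, rng):
        tpl = rng.integers(0, 3000, size=(8, 8), dtype=np.uint16)
        base = _paste_frame(tpl, (11, 3), bg=1000)
        rescaled = (base.astype(np.float64) * 2.5 + 400).astype(np.uint16)
        m1 = match_template(Frame(base), NozzleTemplate(tpl, (0, 0)))
        m2 = match_template(Frame(rescaled), NozzleTemplate(tpl, (0, 0)))
        assert m1.top_left_rc == m2.top_left_rc == (11, 3)

    @pytest.mark.parametrize("trial", range(10))
    def test_map_matches_brute_force_oracle(self, trial, rng):
        img = rng.integers(0, 65536, size=(20 + trial, 20), dtype=np.uint16)
        tpl = rng.integers(0, 65536, size=(8, 8), dtype=np.uint16)
        ours = zncc_map(img, tpl)
        oracle = zncc_brute_force(img, tpl)
        np.testing.assert_allclose(ours, oracle, atol=1e-8)

    def test_argmax_matches_brute_force_on_noiseless_paste(self, rng):
        tpl = rng.integers(0, 65536, size=(8, 8), dtype=np.uint16)
        img = _paste_frame(tpl, (3, 4), shape=(20, 20))
        ours = zncc_map(img, tpl)
        oracle = zncc_brute_force(img, tpl)
        assert np.unravel_index(np.argmax(ours), ours.shape) == np.unravel_index(
            np.argmax(oracle), oracle.shape
        ) == (3, 4)

    def test_agrees_with_skimage_cross_check(self, rng):
        """Independent library implementation of normalised correlation."""
        img = rng.integers(0, 65536, size=(48, 36), dtype=np.uint16)
        tpl = rng.integers(0, 65536, size=(9, 7), dtype=np.uint16)
        ours = zncc_map(img, tpl)
        theirs = skimage_match(img.astype(np.float64), tpl.astype(np.float64))
        np.testing.assert_allclose(ours, theirs, atol=1e-6)

    def test_constant_frame_scores_zero_everywhere(self):
        img = np.full((40, 40), 12345, dtype=np.uint16)
        tpl = np.arange(64, dtype=np.uint16).reshape(8, 8)
        assert np.abs(zncc_map(img, tpl)).max() == 0.0

    def test_tie_break_first_row_major(self):
        # Two identical paste sites; the earlier row-major one must win.
        tpl = np.array([[0, 100], [100, 0]], dtype=np.uint16)
        img = np.full((40, 40), 50, dtype=np.uint16)
        img[2:4, 2:4] = tpl
        img[2:4, 20:22] = tpl
        m = match_template(Frame(img), NozzleTemplate(tpl, (0, 0)))
        assert m.top_left_rc == (2, 2)

    def test_template_larger_than_frame_rejected(self):
        frame = Frame(np.zeros((40, 40), dtype=np.uint16))
        with pytest.raises(DimensionError):
            match_template(frame, NozzleTemplate(np.zeros((50, 10)), (0, 0)))

    def test_translation_equivariance_on_synthetic_scene(self, template):
        p1 = SceneParams(nozzle_tip_rc=(45, 160))
        p2 = SceneParams(nozzle_tip_rc=(52, 171))
        m1 = match_template(render_scene(p1)[0], template)
        m2 = match_template(render_scene(p2)[0], template)
        assert m1.tip_rc == (45, 160) and m2.tip_rc == (52, 171)
        assert m1.score == pytest.approx(1.0, abs=1e-9)


class TestRoi:
    def test_clipping_arithmetic(self, cfg):
        c = cfg.replace(roi_length_px=300, roi_halfwidth_px=60)
        m = MatchResult(top_left_rc=(0, 0), score=1.0, tip_rc=(10, 50))
        roi = derive_roi(m, c, (512, 512))
        assert (roi.top, roi.left) == (10, 0)  # left clipped from -10
        assert roi.width == 110  # min(50+60, 512) - 0
        assert roi.height == 300

    def test_tip_at_top_edge(self, cfg):
        m = MatchResult((0, 0), 1.0, tip_rc=(0, 256))
        roi = derive_roi(m, cfg, (512, 512))
        assert roi.top == 0

    def test_roi_below_frame_is_location_error(self, cfg):
        m = MatchResult((0, 0), 1.0, tip_rc=(511, 511))
        with pytest.raises(LocationError):
            derive_roi(m, cfg, (512, 512))


class TestCrop:
    def test_crop_shape_and_pixels(self, rng):
        src = Frame(rng.integers(0, 65536, size=(64, 64), dtype=np.uint16), index=4, pixel_size_um=0.7)
        from jetvision import RegionOfInterest

        roi = RegionOfInterest(top=5, left=9, height=40, width=33)
        sub = crop(src, roi)
        assert sub.shape == (40, 33)
        assert sub.index == 4 and sub.pixel_size_um == 0.7
        # pixel (r, c) of the crop equals (top+r, left+c) of the source
        np.testing.assert_array_equal(sub.pixels, src.pixels[5:45, 9:42])

    def test_crop_of_crop_composes(self, rng):
        from jetvision import RegionOfInterest

        src = Frame(rng.integers(0, 65536, size=(100, 100), dtype=np.uint16))
        outer = RegionOfInterest(10, 20, 70, 60)
        inner = RegionOfInterest(5, 5, 40, 40)
        composed = RegionOfInterest(15, 25, 40, 40)
        np.testing.assert_array_equal(
            crop(crop(src, outer), inner).pixels, crop(src, composed).pixels
        )

    def test_crop_outside_frame_rejected(self, rng):
        from jetvision import RegionOfInterest

        src = Frame(rng.integers(0, 65536, size=(64, 64), dtype=np.uint16))
        with pytest.raises(LocationError):
            crop(src, RegionOfInterest(40, 40, 40, 40))


def test_default_template_matches_rendered_scene_exactly(template):
    frame, _ = render_scene(SceneParams())
    m = match_template(frame, template)
    assert m.score == pytest.approx(1.0, abs=1e-9)
    assert m.tip_rc == SceneParams().nozzle_tip_rc
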