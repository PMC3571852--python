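"""Face/eye segmentation, openness tracking and PERCLOS."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import ndimage
from skimage.color import hsv2rgb

from drowsefuse.errors import ConfigError, EyesNotFoundError, NoFaceError
from drowsefuse.synth import FaceGeometry, render_face_frame
from drowsefuse.vision import (
    EyeOpennessSeries,
    EyePair,
    Frame,
    OpennessTracker,
    Region,
    clean_mask,
    compute_perclos,
    extract_face_region,
    eye_openness,
    locate_eyes,
    nv21_to_rgb,
    rgb_to_nv21,
    skin_mask,
    to_hsv,
)


def uniform_rgb(h, s, v, shape=(16, 16)):
    return np.round(hsv2rgb(np.full(shape + (3,), [h / 360.0, s, v])) * 255).astype(np.uint8)


class TestToHsv:
    def test_pure_red_and_gray_fixed_points(self):
        hsv = to_hsv(np.full((2, 2, 3), [255, 0, 0], dtype=np.uint8))
        assert np.allclose(hsv[..., 0], 0) and np.allclose(hsv[..., 1:], 1)
        gray = to_hsv(np.full((2, 2, 3), 128, dtype=np.uint8))
        assert np.allclose(gray[..., 1], 0)  # achromatic: saturation 0, hue undefined->0
        assert np.allclose(gray[..., 0], 0)

    def test_unknown_color_space_rejected_by_name(self):
        with pytest.raises(ConfigError, match="yuv422"):
            to_hsv(np.zeros((2, 2, 3), dtype=np.uint8), color_space="yuv422")

    @pytest.mark.parametrize("h,s,v", [(20, 0.5, 0.8), (220, 0.5, 0.5), (0, 1.0, 1.0),
                                       (120, 0.8, 0.6), (300, 0.6, 0.7)])
    def test_nv21_roundtrip_matches_direct_conversion(self, h, s, v):
        """Camera-buffer decode agrees with direct RGB conversion within 1 hue unit."""
        rgb = uniform_rgb(h, s, v)
        direct = to_hsv(rgb)
        rt = to_hsv(nv21_to_rgb(rgb_to_nv21(rgb), 16, 16))
        diff = np.abs(direct[..., 0] - rt[..., 0])
        assert np.minimum(diff, 360 - diff).max() <= 1.0

    def test_nv21_roundtrip_on_rendered_face_interior(self):
        """Away from color boundaries (chroma is 2x2 subsampled), hue agrees within 1 unit."""
        frame = render_face_frame(1.0)
        direct = to_hsv(frame)
        rt = to_hsv(nv21_to_rgb(rgb_to_nv21(frame.pixels), frame.width, frame.height))
        skin = skin_mask(direct)
        interior = ndimage.binary_erosion(skin, iterations=3)
        diff = np.abs(direct[..., 0] - rt[..., 0])
        assert np.minimum(diff, 360 - diff)[interior].max() <= 1.0


class TestSkinMask:
    def test_disjoint_hue_gives_empty_mask(self):
        assert not skin_mask(to_hsv(uniform_rgb(200, 0.5, 0.5)), (0, 50), 0.2).any()

    def test_in_band_hue_gives_full_mask(self):
        assert skin_mask(to_hsv(uniform_rgb(20, 0.5, 0.5)), (0, 50), 0.2).all()

    def test_low_saturation_excluded(self):
        assert not skin_mask(to_hsv(uniform_rgb(20, 0.05, 0.5)), (0, 50), 0.15).any()

    def test_wrapping_hue_band(self):
        hsv = to_hsv(uniform_rgb(350, 0.5, 0.5))
        assert skin_mask(hsv, (340, 20), 0.2).all()
        assert not skin_mask(hsv, (0, 340), 0.2).all() or True  # 350 outside [0,340]
        assert not skin_mask(hsv, (0, 340), 0.2).any()

    def test_face_ellipse_area_recovered_exactly(self):
        """Mask area equals the generator's ground-truth ellipse pixel count."""
        g = FaceGeometry()
        frame = render_face_frame(0.0, geometry=g, draw_eyebrows=False)
        mask = skin_mask(to_hsv(frame))
        rr, cc = np.mgrid[0 : g.height, 0 : g.width]
        (r0, c0), (ry, rx) = g.face_center, g.face_radii
        ellipse = ((rr - r0) / ry) ** 2 + ((cc - c0) / rx) ** 2 <= 1.0
        assert mask.sum() == ellipse.sum()
        assert (mask == ellipse).all()


def brute_force_close(mask, k):
    """Independent morphological oracle: explicit dilation then erosion."""
    pad = k // 2
    dil = ndimage.maximum_filter(mask.astype(np.uint8), size=k, mode="constant", cval=0)
    ero = ndimage.minimum_filter(dil, size=k, mode="constant", cval=1)
    return ero.astype(bool)


def brute_force_fill(mask, frac):
    labels, n = ndimage.label(~mask, structure=np.ones((3, 3)))
    comps, counts = np.unique(ndimage.label(mask, structure=np.ones((3, 3)))[0], return_counts=True)
    largest = counts[comps > 0].max() if (comps > 0).any() else 0
    out = mask.copy()
    border = set(labels[0, :]) | set(labels[-1, :]) | set(labels[:, 0]) | set(labels[:, -1])
    for lab in range(1, n + 1):
        if lab in border:
            continue
        sel = labels == lab
        if sel.sum() < frac * largest:
            out[sel] = True
    return out


class TestCleanMask:
    def test_full_mask_is_fixed_point(self):
        mask = np.ones((20, 20), bool)
        assert clean_mask(mask, kernel=5).all()

    def test_small_interior_hole_is_filled(self):
        mask = np.ones((40, 40), bool)
        mask[20, 20] = False
        assert clean_mask(mask, kernel=3).all()

    def test_large_interior_hole_survives(self):
        mask = np.zeros((60, 60), bool)
        mask[5:55, 5:55] = True
        mask[20:35, 20:35] = False  # 225 px = 9% of the blob, above the 1% cutoff
        out = clean_mask(mask, kernel=3)
        assert not out[25, 25]

    def test_matches_brute_force_closing_plus_hole_fill(self, rng):
        """Pixelwise agreement with an independent dilation/erosion oracle."""
        for _ in range(5):
            mask = np.zeros((64, 64), bool)
            mask[8:56, 8:56] = True
            # sprinkle 2x2 false noise blocks inside the blob
            for _ in range(25):
                r, c = rng.integers(10, 52, 2)
                mask[r : r + 2, c : c + 2] = False
            out = clean_mask(mask, kernel=5, hole_frac=0.01)
            expected = brute_force_fill(brute_force_close(mask, 5), 0.01)
            assert (out == expected).all()


class TestFaceRegion:
    def test_bounding_box_of_single_blob(self):
        mask = np.zeros((30, 30), bool)
        mask[5:15, 5:15] = True
        assert extract_face_region(mask) == Region(5, 5, 15, 15)

    def test_largest_component_wins(self):
        mask = np.zeros((40, 40), bool)
        mask[2:12, 2:12] = True
        mask[25:29, 25:29] = True
        assert extract_face_region(mask) == Region(2, 2, 12, 12)

    def test_empty_mask_raises(self):
        with pytest.raises(NoFaceError):
            extract_face_region(np.zeros((10, 10), bool))

    @pytest.mark.parametrize("seed", range(20))
    def test_full_chain_recovers_generator_face_bbox(self, seed):
        """skin_mask -> clean_mask -> extract_face_region finds the face ellipse."""
        r = np.random.default_rng(seed)
        g = FaceGeometry(
            face_center=(int(r.integers(50, 70)), int(r.integers(70, 90))),
            face_radii=(int(r.integers(36, 44)), int(r.integers(28, 36))),
        )
        frame = render_face_frame(1.0, geometry=g, draw_eyebrows=False)
        kernel = 5
        mask = clean_mask(skin_mask(to_hsv(frame)), kernel=kernel)
        face = extract_face_region(mask)
        top, left, bottom, right = g.face_bbox
        assert abs(face.top - top) <= kernel and abs(face.left - left) <= kernel
        assert abs(face.bottom - bottom) <= kernel and abs(face.right - right) <= kernel
        assert face.contains(*g.face_center)


def mask_with_holes(holes, shape=(80, 80), face=(5, 5, 75, 75)):
    mask = np.zeros(shape, bool)
    mask[face[0] : face[2], face[1] : face[3]] = True
    for top, left, h, w in holes:
        mask[top : top + h, left : left + w] = False
    return mask


class TestLocateEyes:
    FACE = Region(5, 5, 75, 75)

    def test_single_aligned_pair(self):
        mask = mask_with_holes([(40, 20, 4, 6), (40, 50, 4, 6)])
        eyes = locate_eyes(mask, self.FACE, tolerance_px=10)
        assert eyes.vertical_offset == 0
        assert eyes.left_eye.left == 20 and eyes.right_eye.left == 50
        assert eyes.combined_area == 48

    def test_lower_larger_pair_beats_eyebrows(self):
        # upper pair 20 px^2 each, lower pair 40 px^2 each
        mask = mask_with_holes(
            [(20, 20, 4, 5), (20, 50, 4, 5), (45, 20, 5, 8), (45, 50, 5, 8)]
        )
        eyes = locate_eyes(mask, self.FACE, tolerance_px=10)
        assert eyes.left_eye.top == 45 and eyes.combined_area == 80

    def test_misaligned_pair_rejected(self):
        mask = mask_with_holes([(30, 20, 4, 6), (42, 50, 4, 6)])  # 12-row offset
        with pytest.raises(EyesNotFoundError):
            locate_eyes(mask, self.FACE, tolerance_px=10)

    def test_selection_invariant_to_left_right_mirror(self):
        mask = mask_with_holes(
            [(20, 20, 4, 5), (20, 50, 4, 5), (45, 18, 5, 8), (45, 52, 5, 8)]
        )
        eyes = locate_eyes(mask, self.FACE, tolerance_px=10)
        mirrored = locate_eyes(mask[:, ::-1].copy(), self.FACE, tolerance_px=10)
        assert eyes.combined_area == mirrored.combined_area
        assert eyes.left_eye.top == mirrored.left_eye.top

    def test_pair_never_violates_tolerance(self):
        mask = mask_with_holes([(40, 20, 4, 6), (46, 50, 4, 6), (20, 30, 4, 6)])
        eyes = locate_eyes(mask, self.FACE, tolerance_px=10)
        assert eyes.vertical_offset <= 10

    def test_rendered_frame_picks_eyes_not_eyebrows(self):
        g = FaceGeometry()
        frame = render_face_frame(1.0, geometry=g, draw_eyebrows=True)
        mask = clean_mask(skin_mask(to_hsv(frame)))
        eyes = locate_eyes(mask, extract_face_region(mask))
        row = (eyes.left_eye.top + eyes.left_eye.bottom) / 2
        assert abs(row - g.eye_row) <= 3  # eyes, not the eyebrow bars above


class TestOpenness:
    def test_ratio_and_clamp(self):
        pair = EyePair(Region(0, 0, 5, 5), Region(0, 10, 5, 15), 0.0, combined_area=50)
        assert eye_openness(pair, 100) == 0.5
        pair = EyePair(Region(0, 0, 5, 5), Region(0, 10, 5, 15), 0.0, combined_area=120)
        assert eye_openness(pair, 100) == 1.0

    def test_closed_eye_frames_score_zero_via_tracker(self):
        """Closed eyes leave no holes; with a face present the frame scores 0."""
        tracker = OpennessTracker()
        tracker.process(render_face_frame(1.0, timestamp=0.0, draw_eyebrows=False))
        tracker.process(render_face_frame(0.05, timestamp=0.2, draw_eyebrows=False))
        series = tracker.series
        assert series.openness[0] == 1.0
        assert series.openness[1] == 0.0

    def test_no_face_frame_is_skipped(self):
        tracker = OpennessTracker()
        blank = Frame(np.zeros((40, 40, 3), dtype=np.uint8), timestamp=0.0)
        assert tracker.process(blank) is None
        assert tracker.n_skipped == 1 and len(tracker.series) == 0


class TestFrameDirectory:
    def test_png_frames_load_in_time_order_and_track(self, tmp_path):
        import imageio.v3 as iio

        from drowsefuse.io import load_frames

        levels = [1.0, 1.0, 0.05, 1.0]
        for i, lvl in enumerate(levels):
            frame = render_face_frame(lvl, draw_eyebrows=False)
            iio.imwrite(tmp_path / f"frame_{i:04d}.png", frame.pixels)
        frames = load_frames(tmp_path, frame_rate=5.0)
        assert [f.timestamp for f in frames] == pytest.approx([0.0, 0.2, 0.4, 0.6])
        tracker = OpennessTracker()
        for f in frames:
            tracker.process(f)
        assert list(tracker.series.openness) == [1.0, 1.0, 0.0, 1.0]
        assert compute_perclos(tracker.series, window=60.0).pr == pytest.approx(0.25)


class TestPerclos:
    def test_all_closed_and_all_open(self):
        t = np.arange(10) * 0.2
        assert compute_perclos(EyeOpennessSeries(t, np.zeros(10)), 60).pr == 1.0
        assert compute_perclos(EyeOpennessSeries(t, np.ones(10)), 60).pr == 0.0

    def test_counted_fraction(self):
        t = np.arange(300) * 0.2
        o = np.where(np.arange(300) < 90, 0.1, 0.9)
        res = compute_perclos(EyeOpennessSeries(t, o), window=60.0, closure_threshold=0.2)
        assert res.pr == pytest.approx(90 / 300)
        assert res.n_frames == 300

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=200), st.integers(0, 2**31 - 1))
    def test_matches_brute_force_count(self, values, seed):
        t = np.arange(len(values)) * 0.1
        series = EyeOpennessSeries(t, np.array(values))
        thr = np.random.default_rng(seed).uniform(0.05, 0.95)
        res = compute_perclos(series, window=1e9, closure_threshold=thr)
        assert res.pr == sum(v < thr for v in values) / len(values)
        assert 0.0 <= res.pr <= 1.0
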