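import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from painface.video_io import (
    DecodeError,
    ColourSpaceError,
    Frame,
    StreamConfig,
    crop_sharpness,
    detect_and_crop_face,
    read_frames,
    rgb_to_ycbcr,
    shot_filter,
    ycbcr_to_rgb,
)


def _source(n, w=32, h=24, value=None):
    gen = np.random.default_rng(1)
    for i in range(n):
        img = (np.full((h, w, 3), value, np.uint8) if value is not None
               else gen.integers(0, 256, (h, w, 3), dtype=np.uint8))
        yield i, img


class TestReadFrames:
    def test_resampling_by_uniform_striding(self):
        frames = read_frames(_source(300), StreamConfig(max_frames=300, target_fps=15.0),
                             source_fps=30.0)
        assert len(frames) == 150
        assert [f.index for f in frames] == list(range(0, 300, 2))

    def test_budget_not_binding_keeps_all(self):
        frames = read_frames(_source(10), StreamConfig(max_frames=300),
                             source_fps=15.0)
        assert [f.index for f in frames] == list(range(10))

    def test_live_fifo_overwrite_keeps_newest(self):
        cfg = StreamConfig(max_frames=300, overwrite_buffer=True)
        frames = read_frames(_source(400), cfg, source_fps=15.0)
        assert len(frames) == 300
        assert frames[0].index == 100 and frames[-1].index == 399

    def test_indices_strictly_increasing_and_budget(self):
        frames = read_frames(_source(200), StreamConfig(max_frames=50), source_fps=30.0)
        idx = [f.index for f in frames]
        assert len(frames) <= 50
        assert all(a < b for a, b in zip(idx, idx[1:]))

    def test_resized_to_configured_resolution(self):
        frames = read_frames(_source(3), StreamConfig(resolution="QVGA"),
                             source_fps=15.0)
        assert frames[0].pixels.shape == (240, 320, 3)

    def test_empty_source_raises(self):
        with pytest.raises(DecodeError):
            read_frames(iter([]), StreamConfig())

    def test_missing_path_raises(self, tmp_path):
        with pytest.raises(DecodeError):
            read_frames(tmp_path / "nope.avi", StreamConfig())


class TestColourConversion:
    @pytest.mark.parametrize(
        "rgb,expected",
        [
            ((255, 255, 255), (255, 128, 128)),
            ((0, 0, 0), (0, 128, 128)),
            ((255, 0, 0), (76, 85, 255)),
        ],
    )
    def test_known_colours(self, rgb, expected):
        frame = Frame(index=0, pixels=np.full((2, 2, 3), rgb, np.uint8))
        out = rgb_to_ycbcr(frame)
        assert out.colour_space == "YCbCr"
        assert tuple(out.pixels[0, 0]) == expected

    def test_wrong_colour_space_rejected(self):
        frame = Frame(index=0, pixels=np.zeros((2, 2, 3), np.uint8),
                      colour_space="YCbCr")
        with pytest.raises(ColourSpaceError):
            rgb_to_ycbcr(frame)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 255), st.integers(0, 255), st.integers(0, 255))
    def test_roundtrip_within_one_level(self, r, g, b):
        frame = Frame(index=0, pixels=np.full((1, 1, 3), (r, g, b), np.uint8))
        back = ycbcr_to_rgb(rgb_to_ycbcr(frame)).pixels[0, 0].astype(int)
        assert np.abs(back - np.array([r, g, b])).max() <= 1


class TestFaceDetection:
    def test_override_bbox_forces_64x64_output(self, neutral_sequence):
        frame = neutral_sequence[0].frame
        crop = detect_and_crop_face(frame, bbox_override=(50, 40, 120, 130))
        assert crop is not None and crop.pixels.shape == (64, 64)

    def test_blank_frame_yields_none(self):
        frame = Frame(index=0, pixels=np.full((240, 320, 3), 90, np.uint8))
        assert detect_and_crop_face(frame) is None

    def test_largest_of_two_candidate_boxes_kept(self, neutral_sequence):
        frame = neutral_sequence[0].frame
        small, big = (10, 10, 30, 30), (100, 60, 120, 130)
        crop = detect_and_crop_face(frame, _all_bboxes=[small, big])
        assert crop.bbox == big

    def test_rendered_face_is_found_and_covers_landmarks(self, neutral_sequence):
        rec = neutral_sequence[0]
        crop = detect_and_crop_face(rgb_to_ycbcr(rec.frame))
        assert crop is not None
        x, y, w, h = crop.bbox
        cx, cy = rec.landmarks.points.mean(axis=0)
        assert x <= cx <= x + w and y <= cy <= y + h


class TestShotFilter:
    def _frames(self, n):
        return [Frame(index=i, pixels=np.zeros((8, 8, 3), np.uint8)) for i in range(n)]

    def _sharp_crop(self, i, rng):
        from painface.video_io import FaceCrop

        return FaceCrop(pixels=rng.integers(0, 256, (64, 64), dtype=np.uint8).astype(np.uint8),
                        bbox=(0, 0, 8, 8), frame_index=i)

    def _blurred_crop(self, i):
        from painface.video_io import FaceCrop

        return FaceCrop(pixels=np.full((64, 64), 100, np.uint8), bbox=(0, 0, 8, 8),
                        frame_index=i)

    def test_frames_without_detection_are_dropped(self, rng):
        crops = [self._sharp_crop(i, rng) if i % 3 else None for i in range(10)]
        kept = shot_filter(self._frames(10), crops, sharpness_threshold=10.0)
        assert len(kept) == sum(c is not None for c in crops)

    def test_all_blurred_filtered_out(self):
        crops = [self._blurred_crop(i) for i in range(5)]
        assert shot_filter(self._frames(5), crops, sharpness_threshold=10.0) == []

    def test_matches_independent_predicate_oracle_and_is_idempotent(self, rng):
        crops = []
        for i in range(20):
            r = i % 4
            crops.append(None if r == 0 else
                         self._blurred_crop(i) if r == 1 else self._sharp_crop(i, rng))
        frames = self._frames(20)
        kept = shot_filter(frames, crops, sharpness_threshold=10.0)
        oracle = [i for i, c in enumerate(crops)
                  if c is not None and crop_sharpness(c) >= 10.0]
        assert kept == oracle
        again = shot_filter([frames[i] for i in kept], [crops[i] for i in kept],
                            sharpness_threshold=10.0)
        assert [kept[i] for i in again] == kept
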