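import numpy as np
import pytest

from painface.synthetic import (
    ExpressionScript,
    MotionParams,
    Segment,
    generate_dataset,
    generate_expression_sequence,
    render_frame,
)
from painface.template import canonical_landmarks, expression_displacement
from painface.video_io import StreamConfig, read_frames


class TestTemplate:
    def test_zero_amplitude_is_exactly_zero_field_for_every_label(self):
        for label in ("neutral_face", "pain_face", "smile", "surprise", "angry"):
            assert (expression_displacement(label, 0.0) == 0).all()

    def test_displacements_scale_linearly_with_amplitude(self):
        d1 = expression_displacement("pain_face", 0.5)
        d2 = expression_displacement("pain_face", 1.0)
        assert np.allclose(2 * d1, d2)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            expression_displacement("bored", 0.5)


class TestSequenceGeneration:
    def test_zero_amplitude_frames_are_rigid_transforms_of_template(self):
        from painface.synthetic import project_landmarks

        script = ExpressionScript(segments=[Segment("neutral_face", 5, 0.0)],
                                  seed=3, noise_sigma=0.0)
        for rec in generate_expression_sequence(script):
            # the landmarks are exactly the template under the recorded
            # rigid pose: the expression deformation is identically zero
            expected = project_landmarks(rec.pose, np.zeros((66, 2)), "QVGA")
            assert np.allclose(rec.landmarks.points, expected)

    def test_same_seed_bit_identical(self):
        script = ExpressionScript(segments=[Segment("pain_face", 4, 0.9)], seed=12)
        a = generate_expression_sequence(script)
        b = generate_expression_sequence(script)
        for ra, rb in zip(a, b):
            assert (ra.frame.pixels == rb.frame.pixels).all()
            assert np.allclose(ra.landmarks.points, rb.landmarks.points)

    def test_scripted_segment_counts_and_label_order(self):
        script = ExpressionScript(
            segments=[Segment("neutral_face", 45, 0.9), Segment("smile", 45, 0.9),
                      Segment("pain_face", 45, 0.9)],
            seed=0,
        )
        records = generate_expression_sequence(script)
        assert len(records) == 135
        labels = [r.label for r in records]
        assert labels[:45] == ["neutral_face"] * 45
        assert labels[45:90] == ["not_pain_face"] * 45
        assert labels[90:] == ["pain_face"] * 45

    def test_landmarks_stay_inside_the_frame(self):
        script = ExpressionScript(segments=[Segment("surprise", 40, 1.0)], seed=77)
        for rec in generate_expression_sequence(script):
            pts = rec.landmarks.points
            H, W = rec.frame.pixels.shape[:2]
            assert pts[:, 0].min() >= 0 and pts[:, 0].max() < W
            assert pts[:, 1].min() >= 0 and pts[:, 1].max() < H


class TestRenderer:
    def test_illumination_gain_scales_mean_intensity(self):
        from painface.synthetic import project_landmarks

        pts = project_landmarks(dict(scale=1, roll=0, yaw=0, pitch=0,
                                     shift_x=0, shift_y=0), np.zeros((66, 2)), "QVGA")
        dim = render_frame(pts, illumination_gain=0.4).pixels.mean()
        bright = render_frame(pts, illumination_gain=1.0).pixels.mean()
        assert dim / bright == pytest.approx(0.4, abs=0.05)

    def test_noiseless_render_is_deterministic(self):
        from painface.synthetic import project_landmarks

        pts = project_landmarks(dict(scale=1, roll=0, yaw=0, pitch=0,
                                     shift_x=0, shift_y=0), np.zeros((66, 2)), "QVGA")
        a = render_frame(pts, noise_sigma=0.0)
        b = render_frame(pts, noise_sigma=0.0)
        assert (a.pixels == b.pixels).all()

    def test_rendered_face_detected(self, neutral_sequence):
        from painface.video_io import detect_and_crop_face, rgb_to_ycbcr

        crop = detect_and_crop_face(rgb_to_ycbcr(neutral_sequence[0].frame))
        assert crop is not None and crop.pixels.shape == (64, 64)


class TestDataset:
    def test_dataset_writes_manifest_and_roundtrips(self, tmp_path):
        out = generate_dataset(tmp_path / "db", n_videos=2, seed=1,
                               frames_per_segment=4)
        manifest = (out / "manifest.csv").read_text().strip().splitlines()
        assert len(manifest) == 1 + 2 * 3  # header + 3 segments per video
        frames = read_frames(out / "video_000",
                             StreamConfig(target_fps=15.0), source_fps=15.0)
        assert len(frames) == 12

    def test_fixed_seed_identical_manifest(self, tmp_path):
        a = generate_dataset(tmp_path / "a", n_videos=1, seed=9, frames_per_segment=3)
        b = generate_dataset(tmp_path / "b", n_videos=1, seed=9, frames_per_segment=3)
        assert (a / "manifest.csv").read_bytes() == (b / "manifest.csv").read_bytes()
        assert ((a / "video_000" / "frame_0000.png").read_bytes()
                == (b / "video_000" / "frame_0000.png").read_bytes())
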