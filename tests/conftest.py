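import logging

import numpy as np
import pytest

from painface.image_algebra import PointOpParams, enhance
from painface.landmark_model import (
    LandmarkSet,
    build_patch_model,
    build_shape_model,
    build_tree,
    procrustes_align,
)
from painface.pipeline import PipelineConfig, _landmarks_to_crop_coords, train_pipeline
from painface.synthetic import (
    ExpressionScript,
    Segment,
    default_video_script,
    generate_expression_sequence,
)
from painface.video_io import detect_and_crop_face, rgb_to_ycbcr

logging.getLogger("painface").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def neutral_sequence():
    """Thirty noiseless neutral frames with gentle rigid motion."""
    script = ExpressionScript(
        segments=[Segment("neutral_face", 30, 0.0)], seed=7, noise_sigma=0.0
    )
    return generate_expression_sequence(script)


@pytest.fixture(scope="session")
def crop_training_set():
    """Enhanced 64x64 crops with crop-coordinate annotations for model tests."""
    script = ExpressionScript(
        segments=[Segment("neutral_face", 18, 0.0), Segment("pain_face", 18, 0.9)],
        seed=5,
        noise_sigma=1.0,
    )
    records = generate_expression_sequence(script)
    crops, anns = [], []
    for rec in records:
        crop = detect_and_crop_face(rgb_to_ycbcr(rec.frame))
        assert crop is not None
        crops.append(enhance(crop.pixels, PointOpParams()).astype(float))
        anns.append(_landmarks_to_crop_coords(rec.landmarks.points, crop.bbox))
    return crops, anns


@pytest.fixture(scope="session")
def fitted_models(crop_training_set):
    """Shape + patch + tree models built from the crop training set."""
    crops, anns = crop_training_set
    aligned, _, _ = procrustes_align([LandmarkSet(points=a) for a in anns])
    shape_model = build_shape_model(aligned, 0.95)
    patch_model = build_patch_model(crops, anns, 11)
    crop_ref = np.mean(anns, axis=0)
    tree = build_tree(np.ones(66, bool), crop_ref)
    return shape_model, patch_model, tree, crop_ref


@pytest.fixture(scope="session")
def tiny_trained_model():
    """A pipeline model trained on three short synthetic videos."""
    videos = [
        generate_expression_sequence(
            default_video_script(v, seed=3, frames_per_segment=30)
        )
        for v in range(3)
    ]
    return train_pipeline(videos, PipelineConfig()), videos


@pytest.fixture(scope="session")
def separable_features():
    """Three collinear Gaussian clusters, 5 sigma apart, 100 per class."""
    gen = np.random.default_rng(5)
    direction = gen.standard_normal(15)
    direction /= np.linalg.norm(direction)
    X = np.vstack(
        [gen.standard_normal((100, 15)) + direction * k for k in (0.0, 5.0, 10.0)]
    )
    labels = ["neutral_face"] * 100 + ["pain_face"] * 100 + ["not_pain_face"] * 100
    return X, labels
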