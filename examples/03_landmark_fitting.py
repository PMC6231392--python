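"""Constrained local model landmark fitting on synthetic crops.

Builds the Procrustes+PCA shape model and per-landmark patch templates
from annotated frames, then fits the 66 landmarks on a crop starting
from a perturbed initialisation and reports the recovery error.
"""

import numpy as np

from painface import (
    ExpressionScript,
    LandmarkSet,
    Segment,
    build_patch_model,
    build_shape_model,
    build_tree,
    detect_and_crop_face,
    fit_landmarks,
    generate_expression_sequence,
    log_transform,
    procrustes_align,
    rgb_to_ycbcr,
)
from painface.pipeline import _landmarks_to_crop_coords

script = ExpressionScript(segments=[Segment("neutral_face", 20, 0.0)], seed=5,
                          noise_sigma=1.0)
records = generate_expression_sequence(script)
crops, annotations = [], []
for rec in records:
    crop = detect_and_crop_face(rgb_to_ycbcr(rec.frame))
    crops.append(log_transform(crop.pixels).astype(float))
    annotations.append(_landmarks_to_crop_coords(rec.landmarks.points, crop.bbox))

aligned, mean, _ = procrustes_align([LandmarkSet(points=a) for a in annotations])
shape_model = build_shape_model(aligned, variance_fraction=0.95)
patch_model = build_patch_model(crops, annotations, patch_size=11)
crop_reference = np.mean(annotations, axis=0)
tree = build_tree(np.ones(66, bool), crop_reference)
print(f"shape model retains {shape_model.k} mode(s); "
      f"tree has {len(tree.edges)} edges over 66 landmarks")

rng = np.random.default_rng(0)
errors = []
for crop, ann in zip(crops[:10], annotations[:10]):
    init = LandmarkSet(points=ann + rng.normal(0, 2.0, (66, 2)))
    fit = fit_landmarks(crop, init, shape_model, patch_model, tree,
                        reference_shape=crop_reference)
    errors.append(np.sqrt(np.mean(np.sum((fit.landmarks.points - ann) ** 2, axis=1))))
print(f"mean RMS landmark error after fitting from a 2 px-noise start: "
      f"{np.mean(errors):.2f} px")
print("Values near or below one pixel mean the patch responses and the")
print("3-sigma shape constraint pulled the points back onto the face.")
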