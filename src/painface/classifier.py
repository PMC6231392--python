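"""Histogram-technique training and Euclidean-distance soft-threshold
classification of frames into neutral_face / not_pain_face / pain_face.

Training z-normalises the 15-value frame descriptor (6 pose features +
9 LBP bins) over the training peak frames and stores each class's mean
descriptor as its template.  At test time a frame's Euclidean distance
``diff`` to the running neutral reference is thresholded:

    diff <  delta1            -> neutral_face
    delta1 <= diff < delta2   -> not_pain_face
    diff >= delta2            -> pain_face

delta1 < delta2 are the soft thresholds, calibrated on training
distances by a quantile grid search when not supplied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .features import FEATURE_DIM, FrameFeatures

logger = logging.getLogger(__name__)

NEUTRAL, PAIN, NOT_PAIN = "neutral_face", "pain_face", "not_pain_face"
CLASS_LABELS = (NEUTRAL, PAIN, NOT_PAIN)
CLASS_CODES = {NEUTRAL: 1, PAIN: 2, NOT_PAIN: 3}

STD_FLOOR = 1e-6


class TrainingError(RuntimeError):
    pass


@dataclass
class ClassTemplate:
    label: str
    feature_template: np.ndarray  # (15,), z-normalised space
    support: int

    def __post_init__(self) -> None:
        self.feature_template = np.asarray(self.feature_template, float)
        if self.feature_template.shape != (FEATURE_DIM,):
            raise ValueError(f"template must have dimension {FEATURE_DIM}")
        if self.support < 1:
            raise ValueError("template support must be >= 1")


@dataclass
class Normalisation:
    mean: np.ndarray
    std: np.ndarray

    def apply(self, vec: np.ndarray) -> np.ndarray:
        return (np.asarray(vec, float) - self.mean) / self.std


@dataclass
class ThresholdConfig:
    delta1: float
    delta2: float

    def __post_init__(self) -> None:
        if not 0 <= self.delta1 < self.delta2:
            raise ValueError("thresholds must satisfy 0 <= delta1 < delta2")


@dataclass
class ClassificationResult:
    frame_index: int
    diff: float
    label: str
    per_class_distance: np.ndarray = field(default_factory=lambda: np.zeros(3))


def _to_matrix(features) -> np.ndarray:
    rows = []
    for f in features:
        rows.append(f.vector if isinstance(f, FrameFeatures) else np.asarray(f, float))
    return np.array(rows, float)


def build_class_templates(features, labels):
    """Per-class mean templates in z-normalised feature space.

    Returns (dict label -> ClassTemplate, Normalisation).  The
    per-dimension mean/std are computed over all training peaks with a
    std floor of 1e-6.
    """
    X = _to_matrix(features)
    labels = list(labels)
    if len(X) != len(labels):
        raise ValueError("features and labels must be aligned")
    missing = [c for c in CLASS_LABELS if c not in labels]
    if missing:
        raise TrainingError(f"no training peak frames for class(es): {', '.join(missing)}")
    norm = Normalisation(mean=X.mean(axis=0), std=np.maximum(X.std(axis=0), STD_FLOOR))
    Z = (X - norm.mean) / norm.std
    templates = {}
    for c in CLASS_LABELS:
        idx = [i for i, lab in enumerate(labels) if lab == c]
        templates[c] = ClassTemplate(label=c, feature_template=Z[idx].mean(axis=0),
                                     support=len(idx))
    return templates, norm


def frame_distance(features, reference) -> float:
    """Euclidean distance between two descriptors in the same space."""
    a = features.vector if isinstance(features, FrameFeatures) else np.asarray(features, float)
    if isinstance(reference, ClassTemplate):
        b = reference.feature_template
    elif isinstance(reference, FrameFeatures):
        b = reference.vector
    else:
        b = np.asarray(reference, float)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(a - b))


def classify_frame(diff: float, thresholds: ThresholdConfig) -> str:
    """Soft-threshold rule; boundary equalities fall to the severer branch."""
    if diff < 0:
        raise ValueError("diff must be nonnegative")
    if diff < thresholds.delta1:
        return NEUTRAL
    if diff < thresholds.delta2:
        return NOT_PAIN
    return PAIN


def calibrate_thresholds(distances, labels, grid_step: float = 0.01) -> ThresholdConfig:
    """Grid-search (delta1, delta2) over pooled distance quantiles.

    Candidates are the pooled quantiles at ``grid_step`` spacing; the
    pair maximising macro-averaged per-class training accuracy wins,
    with ties broken by smaller delta1 then smaller delta2.  Each chosen
    threshold is then centred in the empty interval between the adjacent
    training distances, which leaves the training confusion unchanged
    but places the cut mid-gap instead of on a data point.  Degenerate
    (constant-distance) input falls back to quantile defaults with a
    warning.
    """
    d = np.asarray(distances, float)
    labels = np.asarray(labels)
    if len(d) != len(labels):
        raise ValueError("distances and labels must be aligned")
    for c in CLASS_LABELS:
        if not np.any(labels == c):
            raise TrainingError(f"no training distances for class {c}")
    if np.ptp(d) < 1e-12:
        logger.warning("all training distances identical; using quantile defaults")
        q1 = float(np.quantile(d, 0.33))
        return ThresholdConfig(delta1=q1, delta2=q1 + 1e-6)
    levels = np.arange(0.0, 1.0 + 1e-9, grid_step)
    masks = {c: labels == c for c in CLASS_LABELS}
    counts = {c: masks[c].sum() for c in CLASS_LABELS}
    # pooled plus per-class quantiles, so every class boundary is a candidate
    qs = [np.quantile(d, levels)] + [np.quantile(d[masks[c]], levels)
                                     for c in CLASS_LABELS]
    cand = np.unique(np.concatenate(qs))
    # boundary pulls equality into the severer class, so nudge candidates up
    cand = np.unique(np.concatenate([cand, cand + 1e-9]))
    best = (-1.0, None)
    # macro accuracy decomposes over classes given the two cut points
    order = {c: np.sort(d[masks[c]]) for c in CLASS_LABELS}
    lt = {c: np.searchsorted(order[c], cand, side="left") for c in CLASS_LABELS}
    for i1, d1 in enumerate(cand[:-1]):
        neu_acc = lt[NEUTRAL][i1] / counts[NEUTRAL]
        np_acc = (lt[NOT_PAIN][i1 + 1 :] - lt[NOT_PAIN][i1]) / counts[NOT_PAIN]
        pain_acc = (counts[PAIN] - lt[PAIN][i1 + 1 :]) / counts[PAIN]
        scores = (neu_acc + np_acc + pain_acc) / 3.0
        j = int(np.argmax(scores))  # first (smallest d2) among ties
        if scores[j] > best[0] + 1e-15:
            best = (float(scores[j]), (float(d1), float(cand[i1 + 1 + j])))
    if best[0] < 0.45:  # barely above the 1/3 chance level
        logger.warning("training classes are poorly separated "
                       "(best macro accuracy %.3f); thresholds are unreliable",
                       best[0])
    d1, d2 = best[1]
    pooled = np.sort(d)

    def _centre(t: float) -> float:
        # midpoint of the empty interval around t; points strictly below
        # t stay below, points at or above stay at or above
        i = int(np.searchsorted(pooled, t, side="left"))
        if i == 0 or i == len(pooled):
            return t
        lo, hi = pooled[i - 1], pooled[i]
        return 0.5 * (lo + hi) if hi > lo else t

    d1, d2 = _centre(d1), _centre(d2)
    if d2 <= d1:
        d2 = d1 + 1e-6
    logger.info("calibrated thresholds delta1=%.4f delta2=%.4f (macro acc %.4f)",
                d1, d2, best[0])
    return ThresholdConfig(delta1=d1, delta2=d2)


def classify_features(
    features,
    templates: dict,
    norm: Normalisation,
    thresholds: ThresholdConfig,
    gop: int = 15,
    adaptive_reference: bool = True,
):
    """Classify a sequence of FrameFeatures against the neutral reference.

    The reference is the neutral-class template evaluated at the current
    head pose: its six pose components track every frame, because global
    head pose is expression-independent nuisance that should never count
    as a deviation, while the nine texture (LBP) components — the pain
    carrier — always compare against the trained neutral texture, so the
    reference never adopts any expression.  With ``adaptive_reference``
    off the static neutral template is used unchanged.  Deterministic.
    """
    from .features import N_POSE_FEATURES

    template = templates[NEUTRAL].feature_template
    results = []
    for feat in features:
        z = norm.apply(feat.vector)
        reference = template.copy()
        if adaptive_reference:
            reference[:N_POSE_FEATURES] = z[:N_POSE_FEATURES]
        diff = float(np.linalg.norm(z - reference))
        label = classify_frame(diff, thresholds)
        per_class = np.array([
            float(np.linalg.norm(z - templates[c].feature_template))
            for c in CLASS_LABELS
        ])
        results.append(ClassificationResult(frame_index=feat.frame_index, diff=diff,
                                            label=label, per_class_distance=per_class))
    return results
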