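"""End-to-end orchestration: train, classify and evaluate.

``run_training`` executes the full training chain — decode, YCbCr
conversion, face localisation and 64x64 cropping, point-operation
enhancement, Procrustes + PCA shape model, appearance model, patch
templates, tree connectivity, landmark fitting/tracking, per-frame
features, peak-frame selection, class templates and threshold
calibration (or MLBPNN training) — and writes one versioned archive.
``run_classification`` replays the inference chain on new input and
evaluates against ground truth when available.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import archive as _archive
from .classifier import (
    CLASS_LABELS,
    NEUTRAL,
    ClassTemplate,
    Normalisation,
    ThresholdConfig,
    build_class_templates,
    calibrate_thresholds,
    classify_features,
    frame_distance,
)
from .evaluation import EvalReport, evaluate
from .features import (
    FrameFeatures,
    estimate_pose_features,
    lbp_histogram,
    select_training_peaks,
)
from .image_algebra import PointOpParams, enhance
from .landmark_model import (
    AppearanceModel,
    LandmarkSet,
    PatchModel,
    ShapeModel,
    TreeStructure,
    build_appearance_model,
    build_patch_model,
    build_shape_model,
    build_tree,
    fit_landmarks,
    procrustes_align,
)
from .neural import MLBPNN, MLBPNNConfig, predict_mlbpnn, train_mlbpnn
from .synthetic import SyntheticFrameRecord, read_landmarks_pts
from .video_io import (
    CROP_SIZE,
    Frame,
    StreamConfig,
    detect_and_crop_face,
    read_frames,
    rgb_to_ycbcr,
    shot_filter,
)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, with the printed defaults."""

    stream: StreamConfig = field(default_factory=StreamConfig)
    pointop: PointOpParams = field(default_factory=PointOpParams)
    sharpness_threshold: float = 10.0
    patch_size: int = 11
    search_window: int = 15
    fit_max_iter: int = 20
    fit_tol: float = 0.1
    clamp_sigma: float = 3.0
    variance_fraction: float = 0.95
    appearance_modes: int = 5
    appearance_max_samples: int = 60
    gop: int = 15
    classifier: str = "ed_histogram"  # or "mlbpnn"
    thresholds: ThresholdConfig | None = None  # None -> calibrate
    adaptive_reference: bool = True
    seed: int = 0

    def snapshot(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.snapshot(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class TrainedModel:
    shape_model: ShapeModel
    patch_model: PatchModel
    appearance_model: AppearanceModel | None
    tree: TreeStructure
    crop_reference: np.ndarray                 # (66, 2) mean shape in crop coords
    templates: dict[str, ClassTemplate]
    norm: Normalisation
    thresholds: ThresholdConfig
    config: PipelineConfig
    mlbpnn: MLBPNN | None = None
    training_accuracy: float | None = None


# ---------------------------------------------------------------------------
# shared per-frame processing


@dataclass
class ProcessedFrame:
    position: int
    frame_index: int
    crop: np.ndarray            # enhanced 64x64 float
    bbox: tuple[int, int, int, int]
    landmarks: LandmarkSet | None = None   # fitted, crop coords
    features: FrameFeatures | None = None


def _frame_to_crop(frame: Frame, config: PipelineConfig,
                   bbox_override=None):
    ycc = rgb_to_ycbcr(frame)
    return detect_and_crop_face(ycc, bbox_override=bbox_override)


def _landmarks_to_crop_coords(points: np.ndarray, bbox) -> np.ndarray:
    x, y, w, h = bbox
    return (np.asarray(points, float) - [x, y]) * [CROP_SIZE / w, CROP_SIZE / h]


def _bbox_from_landmarks(points: np.ndarray, frame_shape, pad: float = 0.15):
    pts = np.asarray(points, float)
    x0, y0 = pts.min(axis=0)
    x1, y1 = pts.max(axis=0)
    px, py = pad * (x1 - x0), pad * (y1 - y0)
    H, W = frame_shape[:2]
    x0, y0 = max(0, int(x0 - px)), max(0, int(y0 - py))
    x1, y1 = min(W, int(x1 + px) + 1), min(H, int(y1 + py) + 1)
    return (x0, y0, x1 - x0, y1 - y0)


def _process_video_frames(frames, config: PipelineConfig, annotations=None):
    """Decode -> YCbCr -> detect/crop -> shot filter -> enhance.

    ``annotations`` (frame-coordinate LandmarkSets) provide a bbox
    fallback when the localiser finds nothing in an annotated training
    frame.  Returns a list of ProcessedFrame for the retained frames.
    """
    crops = []
    for i, fr in enumerate(frames):
        crop = _frame_to_crop(fr, config)
        if crop is None and annotations is not None and annotations[i] is not None:
            bbox = _bbox_from_landmarks(annotations[i].points, fr.pixels.shape)
            crop = _frame_to_crop(fr, config, bbox_override=bbox)
        crops.append(crop)
    kept = shot_filter(frames, crops, config.sharpness_threshold)
    processed = []
    for i in kept:
        enhanced = enhance(crops[i].pixels, config.pointop).astype(np.float64)
        processed.append(ProcessedFrame(
            position=i, frame_index=frames[i].index, crop=enhanced,
            bbox=crops[i].bbox,
        ))
    return processed


def _fit_and_featurise(processed, model_parts, config: PipelineConfig):
    """Track landmarks through a video's processed frames and attach features."""
    shape_model, patch_model, tree, crop_ref = model_parts
    ref_set = LandmarkSet(points=crop_ref)
    prev = None
    for pf in processed:
        fit = fit_landmarks(
            pf.crop, prev, shape_model, patch_model, tree,
            reference_shape=crop_ref,
            search_window=config.search_window, max_iter=config.fit_max_iter,
            tol=config.fit_tol, clamp_sigma=config.clamp_sigma,
        )
        pf.landmarks = fit.landmarks
        prev = fit.landmarks
        pf.features = estimate_pose_features(
            fit.landmarks, ref_set, lbp_hist=lbp_histogram(pf.crop),
            frame_index=pf.frame_index,
        )
    return processed


# ---------------------------------------------------------------------------
# training


def _load_training_video(video, config: PipelineConfig):
    """Normalise a training input into (frames, annotations, labels, segments).

    Accepts a list of SyntheticFrameRecord or a directory written by
    ``synthetic.generate_dataset`` (PNG frames + .pts + labels.csv).
    """
    if isinstance(video, (list, tuple)) and video and isinstance(video[0], SyntheticFrameRecord):
        frames = [r.frame for r in video]
        anns = [r.landmarks for r in video]
        labels = [r.label for r in video]
        segments = [r.segment_index for r in video]
        return frames, anns, labels, segments
    path = Path(video)
    if not path.is_dir():
        raise StageError("decode", f"training video {path} is not a frame directory")
    frames = read_frames(path, config.stream, source_fps=config.stream.target_fps)
    import csv as _csv

    labels_by_frame, expr_by_frame = {}, {}
    with open(path / "labels.csv") as fh:
        for row in _csv.DictReader(fh):
            labels_by_frame[int(row["frame"])] = row["label"]
            expr_by_frame[int(row["frame"])] = row["expression"]
    anns, labels, segments = [], [], []
    seg_map = {}
    for fr in frames:
        pts_file = path / f"frame_{fr.index:04d}.pts"
        anns.append(read_landmarks_pts(pts_file, fr.index) if pts_file.exists() else None)
        labels.append(labels_by_frame.get(fr.index))
        expr = expr_by_frame.get(fr.index)
        seg_map.setdefault(expr, len(seg_map))
        segments.append(seg_map[expr])
    return frames, anns, labels, segments


def train_pipeline(videos, config: PipelineConfig | None = None) -> TrainedModel:
    """Train the full pipeline on labelled, landmark-annotated videos."""
    config = config or PipelineConfig()
    t0 = time.perf_counter()

    per_video = []
    for video in videos:
        frames, anns, labels, segments = _load_training_video(video, config)
        processed = _process_video_frames(frames, config, annotations=anns)
        if not processed:
            raise StageError("shot_filter", "a training video retained no frames")
        for pf in processed:
            pf.annotation = _landmarks_to_crop_coords(
                anns[pf.position].points, pf.bbox) if anns[pf.position] is not None else None
            pf.label = labels[pf.position]
            pf.segment = segments[pf.position]
        per_video.append(processed)
    logger.info("preprocessing done in %.1fs", time.perf_counter() - t0)

    # peak frames per expression segment (30-50 each)
    peak_frames = []
    for processed in per_video:
        seg_ids = sorted({pf.segment for pf in processed})
        for seg in seg_ids:
            seg_pfs = [pf for pf in processed if pf.segment == seg]
            peaks = select_training_peaks([pf.frame_index for pf in seg_pfs],
                                          gop=config.gop)
            chosen = set(peaks.indices.tolist())
            peak_frames += [pf for pf in seg_pfs if pf.frame_index in chosen]
    annotated_peaks = [pf for pf in peak_frames if pf.annotation is not None]
    if len(annotated_peaks) < 2:
        raise StageError("shape_model", "need >= 2 annotated peak frames")

    shapes = [LandmarkSet(points=pf.annotation) for pf in annotated_peaks]
    aligned, _, _ = procrustes_align(shapes)
    shape_model = build_shape_model(aligned, config.variance_fraction)
    crop_ref = np.mean([pf.annotation for pf in annotated_peaks], axis=0)
    patch_model = build_patch_model([pf.crop for pf in annotated_peaks],
                                    [pf.annotation for pf in annotated_peaks],
                                    config.patch_size)
    tree = build_tree(np.ones(len(crop_ref), bool), crop_ref)
    appearance = None
    if config.appearance_modes > 0:
        sub = annotated_peaks
        if len(sub) > config.appearance_max_samples:
            sel = np.linspace(0, len(sub) - 1, config.appearance_max_samples)
            sub = [sub[i] for i in np.unique(sel.round().astype(int))]
        appearance = build_appearance_model(
            [pf.crop for pf in sub], [pf.annotation for pf in sub],
            crop_ref, l=config.appearance_modes)
    logger.info("models built in %.1fs", time.perf_counter() - t0)

    model_parts = (shape_model, patch_model, tree, crop_ref)
    for processed in per_video:
        _fit_and_featurise(processed, model_parts, config)
    logger.info("landmark tracking done in %.1fs", time.perf_counter() - t0)

    peak_feats = [pf.features for pf in peak_frames]
    peak_labels = [pf.label for pf in peak_frames]
    templates, norm = build_class_templates(peak_feats, peak_labels)

    all_pfs = [pf for processed in per_video for pf in processed]
    all_labels = [pf.label for pf in all_pfs]
    dists = [frame_distance(norm.apply(pf.features.vector), templates[NEUTRAL])
             for pf in all_pfs]
    if config.thresholds is not None:
        thresholds = config.thresholds
    else:
        # two-pass calibration: a static-template pass seeds the
        # thresholds, then the streaming procedure (adaptive reference,
        # as used at test time) supplies the distances they are tuned on
        thresholds = calibrate_thresholds(dists, all_labels)
        stream_dists, stream_labels = [], []
        for processed in per_video:
            res = classify_features(
                [pf.features for pf in processed], templates, norm, thresholds,
                gop=config.gop, adaptive_reference=config.adaptive_reference,
            )
            stream_dists += [r.diff for r in res]
            stream_labels += [pf.label for pf in processed]
        thresholds = calibrate_thresholds(stream_dists, stream_labels)
        dists = stream_dists
        all_labels = stream_labels

    mlbpnn = None
    training_accuracy = None
    if config.classifier == "mlbpnn":
        mlbpnn = train_mlbpnn([pf.features for pf in all_pfs], all_labels,
                              MLBPNNConfig(seed=config.seed))
        preds = predict_mlbpnn(mlbpnn, [pf.features for pf in all_pfs])
        training_accuracy = float(np.mean([p == t for p, t in zip(preds, all_labels)]))
    else:
        from .classifier import classify_frame

        preds = [classify_frame(d, thresholds) for d in dists]
        training_accuracy = float(np.mean([p == t for p, t in zip(preds, all_labels)]))
    logger.info("training complete in %.1fs (training accuracy %.4f)",
                time.perf_counter() - t0, training_accuracy)

    return TrainedModel(
        shape_model=shape_model, patch_model=patch_model,
        appearance_model=appearance, tree=tree, crop_reference=crop_ref,
        templates=templates, norm=norm, thresholds=thresholds, config=config,
        mlbpnn=mlbpnn, training_accuracy=training_accuracy,
    )


# ---------------------------------------------------------------------------
# inference


@dataclass
class StreamRun:
    results: list
    diffs: np.ndarray
    retained_positions: list[int]
    skipped_positions: list[int]
    report: EvalReport | None = None


def run_stream(model: TrainedModel, frames, truth=None) -> StreamRun:
    """Classify a sequence of Frames (or SyntheticFrameRecords).

    ``truth`` are per-input-frame class labels; skipped frames (no
    usable face) are excluded from the metrics.
    """
    config = model.config
    if frames and isinstance(frames[0], SyntheticFrameRecord):
        if truth is None:
            truth = [r.label for r in frames]
        frames = [r.frame for r in frames]
    processed = _process_video_frames(frames, config)
    model_parts = (model.shape_model, model.patch_model, model.tree,
                   model.crop_reference)
    _fit_and_featurise(processed, model_parts, config)
    feats = [pf.features for pf in processed]
    if model.config.classifier == "mlbpnn" and model.mlbpnn is not None:
        labels = predict_mlbpnn(model.mlbpnn, feats) if feats else []
        ref = model.templates[NEUTRAL].feature_template
        diffs = [frame_distance(model.norm.apply(f.vector), ref) for f in feats]
        from .classifier import ClassificationResult

        results = [ClassificationResult(frame_index=f.frame_index, diff=d, label=lab)
                   for f, d, lab in zip(feats, diffs, labels)]
    else:
        results = classify_features(
            feats, model.templates, model.norm, model.thresholds,
            gop=config.gop, adaptive_reference=config.adaptive_reference,
        )
    retained = [pf.position for pf in processed]
    skipped = sorted(set(range(len(frames))) - set(retained))
    diffs = np.array([r.diff for r in results])
    report = None
    if truth is not None and results:
        kept_truth = [truth[i] for i in retained]
        report = evaluate(results, kept_truth, diffs=diffs, gop=config.gop)
    return StreamRun(results=results, diffs=diffs, retained_positions=retained,
                     skipped_positions=skipped, report=report)


def results_to_csv(run: StreamRun, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("frame_index,diff,label,d_neutral,d_pain,d_not_pain\n")
        for r in run.results:
            d = r.per_class_distance
            fh.write(f"{r.frame_index},{r.diff:.9f},{r.label},"
                     f"{d[0]:.9f},{d[1]:.9f},{d[2]:.9f}\n")
    return path


# ---------------------------------------------------------------------------
# archive round-trip


def save_model(model: TrainedModel, path) -> Path:
    arrays = {
        "shape_mean": model.shape_model.mean_shape,
        "shape_vectors": model.shape_model.shape_vectors,
        "shape_eigenvalues": model.shape_model.eigenvalues,
        "patches": model.patch_model.patches,
        "tree_vertices": model.tree.vertices,
        "tree_edges": np.array(model.tree.edges, dtype=np.int64),
        "crop_reference": model.crop_reference,
        "norm_mean": model.norm.mean,
        "norm_std": model.norm.std,
    }
    for c in CLASS_LABELS:
        arrays[f"template_{c}"] = model.templates[c].feature_template
    if model.appearance_model is not None:
        arrays["appearance_mean"] = model.appearance_model.base_appearance
        arrays["appearance_images"] = model.appearance_model.appearance_images
        arrays["appearance_eigenvalues"] = model.appearance_model.eigenvalues
        arrays["appearance_mask"] = model.appearance_model.domain_mask
    if model.mlbpnn is not None:
        for i, (W, b) in enumerate(zip(model.mlbpnn.weights, model.mlbpnn.biases)):
            arrays[f"nn_w{i}"] = W
            arrays[f"nn_b{i}"] = b
        arrays["nn_input_mean"] = model.mlbpnn.input_mean
        arrays["nn_input_std"] = model.mlbpnn.input_std
    meta = {
        "kind": "painface_model",
        "config": model.config.snapshot(),
        "config_hash": model.config.config_hash(),
        "patch_size": model.patch_model.patch_size,
        "thresholds": [model.thresholds.delta1, model.thresholds.delta2],
        "supports": {c: model.templates[c].support for c in CLASS_LABELS},
        "training_accuracy": model.training_accuracy,
        "has_mlbpnn": model.mlbpnn is not None,
    }
    return _archive.save_archive(path, meta, arrays)


def load_model(path) -> TrainedModel:
    meta, arrays = _archive.load_archive(path)
    if meta.get("kind") != "painface_model":
        raise _archive.ArchiveError("archive does not hold a trained model")
    cfg_d = meta["config"]
    config = PipelineConfig(
        stream=StreamConfig(**cfg_d["stream"]),
        pointop=PointOpParams(**cfg_d["pointop"]),
        **{k: v for k, v in cfg_d.items()
           if k not in ("stream", "pointop", "thresholds")},
    )
    shape_model = ShapeModel(mean_shape=arrays["shape_mean"],
                             shape_vectors=arrays["shape_vectors"],
                             eigenvalues=arrays["shape_eigenvalues"])
    patch_model = PatchModel(patches=arrays["patches"],
                             patch_size=int(meta["patch_size"]))
    tree = TreeStructure(vertices=arrays["tree_vertices"],
                         edges=[tuple(e) for e in arrays["tree_edges"]])
    templates = {
        c: ClassTemplate(label=c, feature_template=arrays[f"template_{c}"],
                         support=int(meta["supports"][c]))
        for c in CLASS_LABELS
    }
    norm = Normalisation(mean=arrays["norm_mean"], std=arrays["norm_std"])
    thresholds = ThresholdConfig(*meta["thresholds"])
    config.thresholds = thresholds
    appearance = None
    if "appearance_mean" in arrays:
        appearance = AppearanceModel(
            base_appearance=arrays["appearance_mean"],
            appearance_images=arrays["appearance_images"],
            eigenvalues=arrays["appearance_eigenvalues"],
            domain_mask=arrays["appearance_mask"].astype(bool),
        )
    mlbpnn = None
    if meta.get("has_mlbpnn"):
        mlbpnn = MLBPNN(config=MLBPNNConfig(seed=config.seed))
        i = 0
        while f"nn_w{i}" in arrays:
            mlbpnn.weights.append(arrays[f"nn_w{i}"])
            mlbpnn.biases.append(arrays[f"nn_b{i}"])
            i += 1
        mlbpnn.input_mean = arrays["nn_input_mean"]
        mlbpnn.input_std = arrays["nn_input_std"]
    return TrainedModel(
        shape_model=shape_model, patch_model=patch_model,
        appearance_model=appearance, tree=tree,
        crop_reference=arrays["crop_reference"], templates=templates,
        norm=norm, thresholds=thresholds, config=config, mlbpnn=mlbpnn,
        training_accuracy=meta.get("training_accuracy"),
    )
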