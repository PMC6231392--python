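"""Frame input, colour conversion, face localisation and shot filtering.

The front end of the pipeline: decode a video or frame stream, resample
it to a 5-15 fps working rate at QVGA/VGA resolution, convert RGB to
YCbCr, localise and crop the face to a 64x64 grayscale matrix, and drop
frames without a usable, sharp face.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from scipy.ndimage import laplace
from skimage import measure
from skimage.filters import threshold_otsu
from skimage.morphology import closing as _closing, disk as _disk
from skimage.transform import resize

logger = logging.getLogger(__name__)

CROP_SIZE = 64

RESOLUTIONS = {"QVGA": (320, 240), "VGA": (640, 480)}


class DecodeError(RuntimeError):
    """Raised when a video source cannot be opened or yields no frames."""


class ColourSpaceError(ValueError):
    """Raised when an operation receives a frame in the wrong colour space."""


@dataclass
class Frame:
    """A decoded video frame.

    pixels is H x W x 3 uint8; colour_space tags the pixel semantics
    (``RGB``, ``YCbCr`` or ``GRAY``).
    """

    index: int
    pixels: np.ndarray
    colour_space: str = "RGB"
    source_fps: float = 15.0

    def __post_init__(self) -> None:
        if self.index < 0:
            raise ValueError("frame index must be nonnegative")
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("frame pixels must be HxWx3")
        if self.colour_space not in ("RGB", "YCbCr", "GRAY"):
            raise ValueError(f"unknown colour space {self.colour_space!r}")


@dataclass
class FaceCrop:
    """A 64x64 grayscale face crop with its source bounding box."""

    pixels: np.ndarray
    bbox: tuple[int, int, int, int]  # (x, y, w, h) in source-frame pixels
    frame_index: int

    def __post_init__(self) -> None:
        if self.pixels.shape != (CROP_SIZE, CROP_SIZE):
            raise ValueError("face crop must be exactly 64x64")


@dataclass
class StreamConfig:
    """Frame-budget, rate and resolution settings for a stream."""

    max_frames: int = 300
    target_fps: float = 15.0
    resolution: str = "QVGA"
    overwrite_buffer: bool = False

    def __post_init__(self) -> None:
        if not 1 <= self.max_frames:
            raise ValueError("max_frames must be >= 1")
        if not 5.0 <= self.target_fps <= 15.0:
            raise ValueError("target_fps must lie in [5, 15]")
        if self.resolution not in RESOLUTIONS:
            raise ValueError("resolution must be 'QVGA' or 'VGA'")


def _as_uint8_rgb(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    if img.shape[2] == 4:
        img = img[:, :, :3]
    return np.ascontiguousarray(img.astype(np.uint8))


def _iter_source(source) -> Iterator[tuple[int, np.ndarray]]:
    """Normalise a source into an iterator of (index, RGB image) pairs."""
    if isinstance(source, (str, Path)):
        path = Path(source)
        if path.is_dir():
            files = sorted(
                p for p in path.iterdir() if p.suffix.lower() in (".png", ".jpg", ".jpeg")
            )
            if not files:
                raise DecodeError(f"no image frames found in {path}")
            import imageio.v3 as iio

            for i, f in enumerate(files):
                yield i, iio.imread(f)
            return
        if not path.exists():
            raise DecodeError(f"no such video source: {path}")
        try:
            import imageio.v3 as iio

            for i, img in enumerate(iio.imiter(path)):
                yield i, img
        except DecodeError:
            raise
        except Exception as exc:  # plugin missing or corrupt container
            raise DecodeError(f"cannot decode video container {path}: {exc}") from exc
        return
    for item in source:
        yield item


def read_frames(
    source,
    config: StreamConfig | None = None,
    source_fps: float = 30.0,
) -> list[Frame]:
    """Decode a source into at most ``max_frames`` RGB frames.

    ``source`` is a video file, a directory of numbered PNG/JPEG frames,
    or any iterable of (index, RGB image) pairs (the live-stream
    protocol).  Frames are resampled to ``config.target_fps`` by uniform
    index striding and resized to the configured resolution.  With
    ``overwrite_buffer`` the newest ``max_frames`` frames are kept (FIFO
    overwrite, live mode); otherwise reading stops at the budget.
    """
    config = config or StreamConfig()
    stride = max(1, int(round(source_fps / config.target_fps)))
    w, h = RESOLUTIONS[config.resolution]
    out: list[Frame] = []
    n_raw = 0
    for raw_index, image in _iter_source(source):
        n_raw += 1
        if raw_index % stride != 0:
            continue
        img = _as_uint8_rgb(image)
        if img.shape[0] != h or img.shape[1] != w:
            img = resize(img, (h, w), order=1, preserve_range=True, anti_aliasing=False)
            img = np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)
        out.append(
            Frame(index=raw_index, pixels=img, colour_space="RGB", source_fps=source_fps)
        )
        if len(out) > config.max_frames:
            if config.overwrite_buffer:
                out.pop(0)
            else:
                out.pop()
                break
    if n_raw == 0:
        raise DecodeError("source yielded no frames")
    return out


_RGB_TO_YCBCR = np.array(
    [
        [0.299, 0.587, 0.114],
        [-0.168736, -0.331264, 0.5],
        [0.5, -0.418688, -0.081312],
    ]
)
_YCBCR_OFFSET = np.array([0.0, 128.0, 128.0])


def rgb_to_ycbcr(frame: Frame) -> Frame:
    """Full-range (JFIF) RGB -> YCbCr conversion, rounded and clipped."""
    if frame.colour_space != "RGB":
        raise ColourSpaceError(f"expected RGB frame, got {frame.colour_space}")
    rgb = frame.pixels.astype(np.float64)
    ycc = rgb @ _RGB_TO_YCBCR.T + _YCBCR_OFFSET
    ycc = np.clip(np.floor(ycc + 0.5), 0, 255).astype(np.uint8)
    return Frame(
        index=frame.index, pixels=ycc, colour_space="YCbCr", source_fps=frame.source_fps
    )


def ycbcr_to_rgb(frame: Frame) -> Frame:
    """Inverse full-range conversion (round-trip within +/-1 per channel)."""
    if frame.colour_space != "YCbCr":
        raise ColourSpaceError(f"expected YCbCr frame, got {frame.colour_space}")
    ycc = frame.pixels.astype(np.float64) - _YCBCR_OFFSET
    rgb = ycc @ np.linalg.inv(_RGB_TO_YCBCR).T
    rgb = np.clip(np.floor(rgb + 0.5), 0, 255).astype(np.uint8)
    return Frame(
        index=frame.index, pixels=rgb, colour_space="RGB", source_fps=frame.source_fps
    )


def _frame_gray(frame: Frame) -> np.ndarray:
    """Luma plane of a frame in any tagged colour space, as float64."""
    px = frame.pixels.astype(np.float64)
    if frame.colour_space == "YCbCr":
        return px[:, :, 0]
    if frame.colour_space == "GRAY":
        return px[:, :, 0]
    return px @ _RGB_TO_YCBCR[0]


def _find_face_bbox(gray: np.ndarray) -> tuple[int, int, int, int] | None:
    """Locate the largest bright, face-plausible blob in a luma image.

    A deterministic localiser: Otsu-threshold the luma plane, label the
    connected foreground components, and keep the largest region whose
    bounding box has a plausible aspect ratio and area.  Returns (x, y,
    w, h) or None.
    """
    if gray.std() < 1.0:
        return None
    try:
        thr = threshold_otsu(gray)
    except ValueError:
        return None
    mask = gray > thr
    # bridge thin dark creases so one face stays one component
    mask = _closing(mask, _disk(2))
    labels = measure.label(mask, connectivity=2)
    best = None
    best_area = 0
    for region in measure.regionprops(labels):
        r0, c0, r1, c1 = region.bbox
        h, w = r1 - r0, c1 - c0
        if h < 16 or w < 16:
            continue
        aspect = h / w
        if not 0.6 <= aspect <= 2.2:
            continue
        if region.area < 0.35 * h * w:  # too sparse to be a face blob
            continue
        if region.area_bbox > best_area:
            best_area = region.area_bbox
            best = (c0, r0, w, h)
    return best


def detect_and_crop_face(
    frame: Frame,
    bbox_override: tuple[int, int, int, int] | None = None,
    _all_bboxes: Sequence[tuple[int, int, int, int]] | None = None,
) -> FaceCrop | None:
    """Localise the face and return a 64x64 grayscale crop, or None.

    ``bbox_override`` supplies an externally known bounding box (used for
    annotated fixtures); ``_all_bboxes`` injects candidate detections, of
    which the largest is kept.  Absence of a face is a valid None result.
    """
    H, W = frame.pixels.shape[:2]
    gray = _frame_gray(frame)
    if bbox_override is not None:
        bbox = bbox_override
    elif _all_bboxes is not None:
        if not _all_bboxes:
            return None
        if len(_all_bboxes) > 1:
            logger.warning("multiple faces detected; keeping the largest box")
        bbox = max(_all_bboxes, key=lambda b: b[2] * b[3])
    else:
        bbox = _find_face_bbox(gray)
        if bbox is None:
            return None
    x, y, w, h = (int(v) for v in bbox)
    x, y = max(0, x), max(0, y)
    w, h = min(w, W - x), min(h, H - y)
    if w < 2 or h < 2:
        return None
    patch = gray[y : y + h, x : x + w]
    crop = resize(patch, (CROP_SIZE, CROP_SIZE), order=1, preserve_range=True,
                  anti_aliasing=False)
    crop = np.clip(np.floor(crop + 0.5), 0, 255).astype(np.uint8)
    return FaceCrop(pixels=crop, bbox=(x, y, w, h), frame_index=frame.index)


def crop_sharpness(crop: FaceCrop) -> float:
    """Variance of the 3x3 Laplacian response of the crop."""
    return float(laplace(crop.pixels.astype(np.float64)).var())


def shot_filter(
    frames: Sequence[Frame],
    crops: Sequence[FaceCrop | None],
    sharpness_threshold: float = 10.0,
) -> list[int]:
    """Indices of frames that have a face crop and pass the sharpness test.

    Replaces shot detection with two predicates: a face was found, and
    the crop's Laplacian-variance sharpness is at least the threshold.
    Idempotent; returns positions (into ``frames``) in ascending order.
    """
    if len(frames) != len(crops):
        raise ValueError("frames and crops must be aligned")
    kept = []
    for i, crop in enumerate(crops):
        if crop is None:
            continue
        if crop_sharpness(crop) < sharpness_threshold:
            continue
        kept.append(i)
    return kept
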