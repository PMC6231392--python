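"""Point-operation image enhancement: logarithm and exponential transforms.

Each output pixel depends only on the corresponding input pixel.  The
log transform amplifies dark pixels and compresses bright ones; the
exponential (power-law) transform does the opposite, raising contrast
in bright regions.  Inputs are 8-bit single-channel matrices; internally
intensities are normalised to [0, 1], the curve s = c*log(1+r) or
s = c*r**gamma is applied, and the result is rescaled back to [0, 255]
(dividing by the curve's maximum, c*log 2 resp. c) and rounded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .video_io import FaceCrop


@dataclass
class PointOpParams:
    """Constants of the point operations (defaults are the best-found settings)."""

    c_log: float = 3.5
    c_exp: float = 3.0
    gamma: float = 2.0
    mode: str = "log"  # one of {"none", "log", "exp", "sharper"}

    def __post_init__(self) -> None:
        if self.c_log <= 0 or self.c_exp <= 0 or self.gamma <= 0:
            raise ValueError("point-operation constants must be strictly positive")
        if self.mode not in ("none", "log", "exp", "sharper"):
            raise ValueError(f"unknown point-operation mode {self.mode!r}")


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


def log_transform(image: np.ndarray, c: float = 3.5) -> np.ndarray:
    """Logarithmic enhancement s = c*log(1+r) on [0,1], rescaled to [0,255]."""
    if c <= 0:
        raise ValueError("c must be strictly positive")
    img = np.asarray(image, dtype=np.float64)
    if img.size == 0:
        raise ValueError("image must be non-empty")
    r = img / 255.0
    s = c * np.log1p(r)
    out = s / (c * np.log(2.0)) * 255.0
    return np.clip(_round_half_up(out), 0, 255).astype(np.uint8)


def exp_transform(image: np.ndarray, c: float = 3.0, gamma: float = 2.0) -> np.ndarray:
    """Power-law enhancement s = c*r**gamma on [0,1], rescaled to [0,255]."""
    if c <= 0 or gamma <= 0:
        raise ValueError("c and gamma must be strictly positive")
    img = np.asarray(image, dtype=np.float64)
    if img.size == 0:
        raise ValueError("image must be non-empty")
    r = img / 255.0
    s = c * np.power(r, gamma)
    out = s / c * 255.0
    return np.clip(_round_half_up(out), 0, 255).astype(np.uint8)


def enhance(image: np.ndarray, params: PointOpParams | None = None) -> np.ndarray:
    """Apply the configured point operation to a single-channel image.

    Mode ``sharper`` runs both transforms and keeps the one with the
    larger Laplacian-variance sharpness.
    """
    params = params or PointOpParams()
    if params.mode == "none":
        return np.asarray(image, dtype=np.uint8)
    if params.mode == "log":
        return log_transform(image, params.c_log)
    if params.mode == "exp":
        return exp_transform(image, params.c_exp, params.gamma)
    from scipy.ndimage import laplace

    a = log_transform(image, params.c_log)
    b = exp_transform(image, params.c_exp, params.gamma)
    va = laplace(a.astype(np.float64)).var()
    vb = laplace(b.astype(np.float64)).var()
    return a if va >= vb else b


@dataclass
class PackedFrame:
    """Compact integer-matrix storage of a processed 64x64 face crop."""

    data: np.ndarray  # flat uint8 vector, length 4096
    shape: tuple[int, int]
    frame_index: int
    bbox: tuple[int, int, int, int]


def pack_frame_matrix(crop: FaceCrop) -> PackedFrame:
    """Store a crop as a flat uint8 matrix record (lossless)."""
    return PackedFrame(
        data=np.ascontiguousarray(crop.pixels, dtype=np.uint8).ravel().copy(),
        shape=crop.pixels.shape,
        frame_index=crop.frame_index,
        bbox=crop.bbox,
    )


def unpack_frame_matrix(packed: PackedFrame) -> FaceCrop:
    """Reconstruct a bit-identical FaceCrop from a packed record."""
    return FaceCrop(
        pixels=packed.data.reshape(packed.shape).copy(),
        bbox=packed.bbox,
        frame_index=packed.frame_index,
    )
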