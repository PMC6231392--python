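"""Per-frame descriptors: six global pose features and the 9-bin LBP histogram.

Pose features — scale, pitch, yaw, roll (degrees) and the (x, y) shift
of the shape centroid from the reference shape — come from a
weak-perspective fit of the canonical 3-D landmark template to the
observed 2-D points.  Texture is summarised by a local-binary-pattern
histogram: each interior pixel's 8-neighbour code (neighbour >= centre
maps to 1) is binned by its number of set bits, giving 9 bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .landmark_model import AlignmentError, LandmarkSet
from .template import canonical_landmarks_3d

N_POSE_FEATURES = 6
N_LBP_BINS = 9
FEATURE_DIM = N_POSE_FEATURES + N_LBP_BINS

FEATURE_NAMES = (
    "scale", "pitch", "yaw", "roll", "shift_x", "shift_y",
    *[f"lbp_{i}" for i in range(N_LBP_BINS)],
)


@dataclass
class FrameFeatures:
    """The 15-value frame descriptor (6 pose features + 9 LBP bins)."""

    scale: float
    pitch: float
    yaw: float
    roll: float
    shift_x: float
    shift_y: float
    lbp_hist: np.ndarray
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.lbp_hist = np.asarray(self.lbp_hist, dtype=np.float64)
        if self.lbp_hist.shape != (N_LBP_BINS,):
            raise ValueError(f"LBP histogram must have {N_LBP_BINS} bins")

    @property
    def vector(self) -> np.ndarray:
        return np.concatenate([
            [self.scale, self.pitch, self.yaw, self.roll, self.shift_x, self.shift_y],
            self.lbp_hist,
        ])


@dataclass
class PeakFrameSet:
    """Periodically sampled reference-frame indices."""

    indices: np.ndarray
    gop: int = 15

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)


# ---------------------------------------------------------------------------
# head pose


def _weak_perspective_pose(points: np.ndarray, template3d: np.ndarray):
    """Fit points ~ s * (R @ X)_{xy} + t; return (s, R, t).

    The affine camera M (2x3) is the least-squares solution; its rows
    are orthonormalised through the SVD to extract the rotation.
    """
    P = np.asarray(points, float)
    Pc = P - P.mean(axis=0)
    X = template3d  # already centred
    # M minimising ||Pc - X M^T||
    M, *_ = np.linalg.lstsq(X, Pc, rcond=None)
    M = M.T  # 2x3
    norms = np.linalg.norm(M, axis=1)
    if np.any(norms < 1e-12):
        raise AlignmentError("degenerate landmark configuration for pose fit")
    s = float(norms.mean())
    U, _, Vt = np.linalg.svd(M / s)
    R2 = U @ np.eye(2, 3) @ Vt  # closest row-orthonormal 2x3
    r3 = np.cross(R2[0], R2[1])
    R = np.vstack([R2, r3])
    if np.linalg.det(R) < 0:
        R[2] *= -1.0
    t = P.mean(axis=0)
    return s, R, t


def _euler_zyx(R: np.ndarray) -> tuple[float, float, float]:
    """Decompose R = Rz(roll) @ Ry(yaw) @ Rx(pitch); angles in degrees."""
    yaw = float(np.degrees(-np.arcsin(np.clip(R[2, 0], -1.0, 1.0))))
    pitch = float(np.degrees(np.arctan2(R[2, 1], R[2, 2])))
    roll = float(np.degrees(np.arctan2(R[1, 0], R[0, 0])))
    return pitch, yaw, roll


def rotation_zyx(pitch: float, yaw: float, roll: float) -> np.ndarray:
    """Rz(roll) @ Ry(yaw) @ Rx(pitch), angles in degrees (image y down)."""
    a, b, g = np.radians([pitch, yaw, roll])
    Rx = np.array([[1, 0, 0], [0, np.cos(a), -np.sin(a)], [0, np.sin(a), np.cos(a)]])
    Ry = np.array([[np.cos(b), 0, np.sin(b)], [0, 1, 0], [-np.sin(b), 0, np.cos(b)]])
    Rz = np.array([[np.cos(g), -np.sin(g), 0], [np.sin(g), np.cos(g), 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def estimate_pose_features(
    landmarks: LandmarkSet,
    reference: LandmarkSet,
    lbp_hist: np.ndarray | None = None,
    frame_index: int = 0,
) -> FrameFeatures:
    """Six pose features of ``landmarks`` relative to ``reference``.

    Both shapes are fitted against the canonical 3-D template under weak
    perspective; scale is the ratio of fitted scales, the three angles
    are the observed-minus-reference Euler angles, and the shifts are
    centroid differences in pixels.
    """
    X = canonical_landmarks_3d()
    s_obs, R_obs, t_obs = _weak_perspective_pose(landmarks.points, X)
    s_ref, R_ref, t_ref = _weak_perspective_pose(reference.points, X)
    R_rel = R_obs @ R_ref.T
    pitch, yaw, roll = _euler_zyx(R_rel)
    if not (abs(pitch) < 90 and abs(yaw) < 90):
        raise AlignmentError("pose fit outside the frontal working range")
    hist = lbp_hist if lbp_hist is not None else np.full(N_LBP_BINS, 1.0 / N_LBP_BINS)
    return FrameFeatures(
        scale=s_obs / s_ref,
        pitch=pitch,
        yaw=yaw,
        roll=roll,
        shift_x=float(t_obs[0] - t_ref[0]),
        shift_y=float(t_obs[1] - t_ref[1]),
        lbp_hist=hist,
        frame_index=frame_index,
    )


# ---------------------------------------------------------------------------
# local binary patterns


def lbp_histogram(crop: np.ndarray) -> np.ndarray:
    """9-bin LBP histogram of a single-channel crop.

    For each interior pixel the 8 neighbours are compared to the centre
    (neighbour >= centre counts as 1) and the code is binned by its
    popcount (0-8 set bits).  Normalised to sum to 1.
    """
    img = np.asarray(crop, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("crop must be single-channel")
    if img.shape[0] < 3 or img.shape[1] < 3:
        raise ValueError("crop must be at least 3x3")
    c = img[1:-1, 1:-1]
    bits = np.zeros_like(c)
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            if dx == 0 and dy == 0:
                continue
            nb = img[1 + dy : img.shape[0] - 1 + dy, 1 + dx : img.shape[1] - 1 + dx]
            bits += (nb >= c)
    hist = np.bincount(bits.astype(np.int64).ravel(), minlength=N_LBP_BINS).astype(float)
    return hist / hist.sum()


# ---------------------------------------------------------------------------
# peak frames


def select_peak_frames(frame_indices, gop: int = 15) -> PeakFrameSet:
    """Every gop-th retained frame starting at the first."""
    if gop < 1:
        raise ValueError("gop must be >= 1")
    idx = np.asarray(sorted(frame_indices), dtype=np.int64)
    return PeakFrameSet(indices=idx[::gop], gop=gop)


def select_training_peaks(
    frame_indices, gop: int = 15, min_peaks: int = 30, max_peaks: int = 50
) -> PeakFrameSet:
    """Peak frames for one training expression segment, 30-50 per segment.

    Every gop-th frame is taken; if that yields fewer than ``min_peaks``
    but the segment is long enough, the stride is reduced (even
    subsample to ``min_peaks``); more than ``max_peaks`` peaks are evenly
    subsampled down to ``max_peaks``.  Deterministic.
    """
    idx = np.asarray(sorted(frame_indices), dtype=np.int64)
    if len(idx) == 0:
        return PeakFrameSet(indices=idx, gop=gop)
    peaks = idx[::gop]
    if len(peaks) < min_peaks and len(idx) >= min_peaks:
        sel = np.unique(np.linspace(0, len(idx) - 1, min_peaks).round().astype(int))
        peaks = idx[sel]
    elif len(peaks) < min_peaks:
        peaks = idx
    elif len(peaks) > max_peaks:
        sel = np.unique(np.linspace(0, len(peaks) - 1, max_peaks).round().astype(int))
        peaks = peaks[sel]
    return PeakFrameSet(indices=peaks, gop=gop)
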