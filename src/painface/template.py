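"""Canonical 66-point face template and expression deformation fields.

The landmark indexing follows the conventional 66-point layout used
throughout the package:

* jaw 0-16 (left ear to right ear along the jaw line)
* brows 17-21 (left), 22-26 (right)
* nose 27-30 (bridge, top to tip), 31-35 (nostril base, left to right)
* eyes 36-41 (left), 42-47 (right), six points each
* mouth 48-59 (outer lip, counter-clockwise from the left corner),
  60-65 (inner lip)

Coordinates live in a unit face frame: x in [-1, 1] (left to right),
y in [-1, 1.15] (up to down, image convention).  A coarse per-landmark
depth (z, toward the camera positive) turns the template into the
canonical 3-D shape used for weak-perspective head-pose estimation.
"""

from __future__ import annotations

import numpy as np

N_LANDMARKS = 66

JAW = slice(0, 17)
LEFT_BROW = slice(17, 22)
RIGHT_BROW = slice(22, 27)
NOSE_BRIDGE = slice(27, 31)
NOSE_BASE = slice(31, 36)
LEFT_EYE = slice(36, 42)
RIGHT_EYE = slice(42, 48)
OUTER_LIP = slice(48, 60)
INNER_LIP = slice(60, 66)


def canonical_landmarks() -> np.ndarray:
    """Return the neutral 66x2 template in unit-face coordinates."""
    pts = np.zeros((N_LANDMARKS, 2))

    # Jaw: lower half-ellipse, left ear (-0.95, 0.1) to right ear, chin at y=1.1.
    theta = np.linspace(np.pi, 0.0, 17)
    pts[JAW, 0] = 0.95 * np.cos(theta)
    pts[JAW, 1] = 0.10 + 1.00 * np.sin(theta)

    # Brows: gentle arches above the eyes.
    t = np.linspace(0.0, 1.0, 5)
    pts[LEFT_BROW, 0] = -0.65 + 0.50 * t
    pts[LEFT_BROW, 1] = -0.55 - 0.08 * np.sin(np.pi * t)
    pts[RIGHT_BROW, 0] = 0.15 + 0.50 * t
    pts[RIGHT_BROW, 1] = -0.55 - 0.08 * np.sin(np.pi * t)[::-1]

    # Nose bridge and base.
    pts[NOSE_BRIDGE, 0] = 0.0
    pts[NOSE_BRIDGE, 1] = np.linspace(-0.40, 0.08, 4)
    pts[NOSE_BASE, 0] = np.linspace(-0.18, 0.18, 5)
    pts[NOSE_BASE, 1] = [0.15, 0.19, 0.21, 0.19, 0.15]

    # Eyes: six points on small ellipses.
    ang = np.deg2rad([180.0, 120.0, 60.0, 0.0, -60.0, -120.0])
    pts[LEFT_EYE, 0] = -0.40 + 0.20 * np.cos(ang)
    pts[LEFT_EYE, 1] = -0.35 - 0.10 * np.sin(ang)
    pts[RIGHT_EYE, 0] = 0.40 + 0.20 * np.cos(ang)
    pts[RIGHT_EYE, 1] = -0.35 - 0.10 * np.sin(ang)

    # Mouth: outer lip (12 points) and inner lip (6 points).
    ang = np.deg2rad(np.arange(180.0, -180.0, -30.0))
    pts[OUTER_LIP, 0] = 0.32 * np.cos(ang)
    pts[OUTER_LIP, 1] = 0.55 - 0.13 * np.sin(ang)
    ang = np.deg2rad([180.0, 120.0, 60.0, 0.0, -60.0, -120.0])
    pts[INNER_LIP, 0] = 0.20 * np.cos(ang)
    pts[INNER_LIP, 1] = 0.55 - 0.05 * np.sin(ang)
    return pts


def canonical_depths() -> np.ndarray:
    """Coarse per-landmark depth (z toward the camera) for the 3-D template."""
    z = np.zeros(N_LANDMARKS)
    # Cheeks recede toward the ears; the chin sits mildly forward.
    t = np.abs(np.linspace(-1.0, 1.0, 17))
    z[JAW] = 0.05 - 0.50 * t**2
    z[LEFT_BROW] = 0.10
    z[RIGHT_BROW] = 0.10
    z[NOSE_BRIDGE] = np.linspace(0.15, 0.35, 4)
    z[NOSE_BASE] = [0.22, 0.30, 0.33, 0.30, 0.22]
    z[LEFT_EYE] = 0.05
    z[RIGHT_EYE] = 0.05
    z[OUTER_LIP] = 0.15
    z[INNER_LIP] = 0.15
    return z


def canonical_landmarks_3d() -> np.ndarray:
    """66x3 canonical shape, centred at the origin (mean removed per axis)."""
    xy = canonical_landmarks()
    xyz = np.column_stack([xy, canonical_depths()])
    return xyz - xyz.mean(axis=0)


def _squeeze_eyes(disp: np.ndarray, base: np.ndarray, factor: float) -> None:
    """Move eye contour points toward each eye's horizontal midline."""
    for eye in (LEFT_EYE, RIGHT_EYE):
        cy = base[eye, 1].mean()
        disp[eye, 1] += -factor * (base[eye, 1] - cy)


def expression_displacement(label: str, amplitude: float) -> np.ndarray:
    """66x2 displacement field for one expression at a given amplitude.

    Labels: ``neutral_face``, ``pain_face``, ``smile``, ``surprise``,
    ``angry`` (the latter three are the not-pain expressions).  Amplitude 0
    is exactly the zero field for every label.
    """
    base = canonical_landmarks()
    d = np.zeros_like(base)
    if label == "neutral_face" or amplitude == 0.0:
        return d
    a = float(amplitude)
    if label == "pain_face":
        # Brow lowering (inner ends more), eye narrowing, lip tightening.
        d[LEFT_BROW, 1] += a * np.linspace(0.06, 0.14, 5)
        d[RIGHT_BROW, 1] += a * np.linspace(0.14, 0.06, 5)
        d[LEFT_BROW, 0] += a * 0.04
        d[RIGHT_BROW, 0] -= a * 0.04
        _squeeze_eyes(d, base, 0.85 * a)
        cy = base[OUTER_LIP, 1].mean()
        d[OUTER_LIP, 1] += -0.55 * a * (base[OUTER_LIP, 1] - cy)
        d[INNER_LIP, 1] += -0.95 * a * (base[INNER_LIP, 1] - cy)
        d[[48, 54], 1] += a * 0.05
        d[48, 0] += a * 0.04
        d[54, 0] -= a * 0.04
    elif label == "smile":
        d[[48, 54], 1] -= a * 0.14
        d[48, 0] -= a * 0.07
        d[54, 0] += a * 0.07
        d[[49, 53, 59, 55], 1] -= a * 0.06
        _squeeze_eyes(d, base, 0.30 * a)
    elif label == "surprise":
        d[LEFT_BROW, 1] -= a * 0.10
        d[RIGHT_BROW, 1] -= a * 0.10
        _squeeze_eyes(d, base, -0.15 * a)  # widen
        lower_outer = [55, 56, 57, 58, 59]
        d[lower_outer, 1] += a * 0.14
        d[[63, 64, 62], 1] += a * 0.11
        d[[7, 8, 9], 1] += a * 0.08
    elif label == "angry":
        d[[20, 21], 1] += a * 0.10  # inner left brow down
        d[[22, 23], 1] += a * 0.10  # inner right brow down
        d[[20, 21], 0] += a * 0.05
        d[[22, 23], 0] -= a * 0.05
        _squeeze_eyes(d, base, 0.25 * a)
        d[[48, 54], 1] += a * 0.05
        cy = base[OUTER_LIP, 1].mean()
        d[OUTER_LIP, 1] += -0.20 * a * (base[OUTER_LIP, 1] - cy)
    else:
        raise ValueError(f"unknown expression label: {label!r}")
    return d
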