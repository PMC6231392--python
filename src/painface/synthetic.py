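"""Parametric synthetic face-video generator with ground truth.

Renders schematic (deliberately non-photorealistic) faces from the
canonical 66-point template: a bright skin polygon on a dark background
with dark strokes and fills at the brows, eyes, nose and mouth, all
drawn through the landmark positions so every landmark sits on usable
local structure.  Scripts compose labelled expression segments
(neutral / pain / smile / surprise / angry) with seeded smooth
random-walk rigid motion (scale, in-plane and out-of-plane rotation,
translation), illumination gain and additive Gaussian noise.  Each
frame carries its ground-truth landmarks, class label and pose, which
is what makes parameter-recovery and end-to-end tests possible without
any external data.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.draw import disk, polygon

from . import template as T
from .classifier import NEUTRAL, NOT_PAIN, PAIN
from .features import rotation_zyx
from .landmark_model import LandmarkSet
from .video_io import RESOLUTIONS, Frame

logger = logging.getLogger(__name__)

EXPRESSIONS = ("neutral_face", "pain_face", "smile", "surprise", "angry")

#: class label for each expression name
EXPRESSION_CLASS = {
    "neutral_face": NEUTRAL,
    "pain_face": PAIN,
    "smile": NOT_PAIN,
    "surprise": NOT_PAIN,
    "angry": NOT_PAIN,
}


@dataclass
class Segment:
    expression: str
    duration: int
    amplitude: float = 0.9

    def __post_init__(self) -> None:
        if self.expression not in EXPRESSIONS:
            raise ValueError(f"unknown expression {self.expression!r}")
        if self.duration < 1:
            raise ValueError("segment duration must be >= 1 frame")
        if not 0.0 <= self.amplitude <= 1.0:
            raise ValueError("amplitude must lie in [0, 1]")

    @property
    def label(self) -> str:
        return EXPRESSION_CLASS[self.expression]


@dataclass
class MotionParams:
    """Bounds and step sizes of the seeded rigid-motion random walk."""

    scale_range: tuple[float, float] = (0.8, 1.2)
    roll_range: tuple[float, float] = (-15.0, 15.0)
    yaw_range: tuple[float, float] = (-20.0, 20.0)
    pitch_range: tuple[float, float] = (-20.0, 20.0)
    shift_range: tuple[float, float] = (-20.0, 20.0)
    scale_step: float = 0.008
    angle_step: float = 0.8
    shift_step: float = 0.8
    enabled: bool = True


@dataclass
class ExpressionScript:
    """A scripted sequence of expression segments for one video."""

    segments: list[Segment]
    fps: int = 15
    resolution: str = "QVGA"
    seed: int = 0
    noise_sigma: float = 2.0
    illumination_range: tuple[float, float] = (0.4, 1.2)
    illumination_step: float = 0.01
    motion: MotionParams = field(default_factory=MotionParams)

    @property
    def n_frames(self) -> int:
        return sum(s.duration for s in self.segments)


@dataclass
class SyntheticFrameRecord:
    frame: Frame
    landmarks: LandmarkSet
    label: str
    expression: str
    pose: dict  # scale, pitch, yaw, roll, shift_x, shift_y (ground truth)
    segment_index: int


# ---------------------------------------------------------------------------
# rendering


def _stroke(canvas: np.ndarray, pts: np.ndarray, value: float, thickness: float,
            closed: bool = False) -> None:
    pts = np.asarray(pts, float)
    if closed:
        pts = np.vstack([pts, pts[:1]])
    H, W = canvas.shape
    for a, b in zip(pts[:-1], pts[1:]):
        n = max(2, int(np.hypot(*(b - a)) / 0.7) + 1)
        for t in np.linspace(0.0, 1.0, n):
            cx, cy = a + t * (b - a)
            rr, cc = disk((cy, cx), max(thickness, 0.8), shape=(H, W))
            canvas[rr, cc] = value


def _beaded_stroke(canvas: np.ndarray, pts: np.ndarray, value: float,
                   spacing: float = 4.0, radius: float = 2.2) -> None:
    """Chain of dark beads along a path: a crease rendered as a line of
    local intensity minima, the form in which deep skin folds read out
    as texture rather than as a smooth valley."""
    pts = np.asarray(pts, float)
    H, W = canvas.shape
    seglens = np.hypot(*(np.diff(pts, axis=0).T))
    total = seglens.sum()
    if total < 1e-6:
        return
    n = max(2, int(total / spacing) + 1)
    cum = np.concatenate([[0.0], np.cumsum(seglens)])
    for s in np.linspace(0.0, total, n):
        i = min(np.searchsorted(cum, s, side="right") - 1, len(seglens) - 1)
        t = (s - cum[i]) / max(seglens[i], 1e-9)
        cx, cy = pts[i] + t * (pts[i + 1] - pts[i])
        rr, cc = disk((cy, cx), radius, shape=(H, W))
        canvas[rr, cc] = value


def _fill(canvas: np.ndarray, pts: np.ndarray, value: float) -> None:
    pts = np.asarray(pts, float)
    rr, cc = polygon(pts[:, 1], pts[:, 0], shape=canvas.shape)
    canvas[rr, cc] = value


def _draw_wrinkles(canvas: np.ndarray, pts: np.ndarray, expression: str,
                   amplitude: float) -> None:
    """Expression-specific wrinkle and furrow strokes, scaled by amplitude.

    Facial expressions crease the skin over extended regions; these
    high-contrast strokes are what gives each expression a texture
    signature that survives sensor noise.  Pain carries the largest and
    darkest set (glabellar + brow furrows + nasolabial folds + tightened
    eye corners), the not-pain expressions distinct, lighter sets.
    """
    if amplitude <= 0 or expression == "neutral_face":
        return
    a = amplitude
    brow_in_l, brow_in_r = pts[21], pts[22]
    nose_top, nose_tip = pts[27], pts[30]
    gl = 0.5 * (brow_in_l + brow_in_r)
    brow_mid = 0.5 * (pts[19] + pts[24])
    ear_w = np.linalg.norm(pts[16] - pts[0])
    up = np.array([0.0, -1.0]) * 0.06 * ear_w

    def draw(path, value, width):
        _stroke(canvas, path, value, width)

    def nasolabial(value, width):
        for wing, corner in ((pts[31], pts[48]), (pts[35], pts[54])):
            mid = 0.5 * (wing + corner) + np.array([0.0, -0.02 * ear_w])
            draw(np.array([wing, mid, corner]), value, width)

    def crows_feet(value, width, length):
        for corner, sgn in ((pts[36], -1.0), (pts[45], 1.0)):
            for dy in (-0.4, 0.2, 0.8):
                p0 = corner + np.array([sgn * 0.01 * ear_w, dy * 0.02 * ear_w])
                p1 = p0 + np.array([sgn * length * ear_w, dy * 0.035 * ear_w])
                draw(np.array([p0, p1]), value, width)

    def glabellar(value, width):
        for dx in (-0.035, 0.035):
            p0 = gl + np.array([dx * ear_w, -0.02 * ear_w])
            p1 = nose_top + np.array([dx * ear_w * 0.7, 0.0])
            draw(np.array([p0, p1]), value, width)

    def forehead(value, width, n_lines, margin=0.08):
        span = pts[26, 0] - pts[17, 0]
        for i in range(n_lines):
            y = brow_mid[1] - (0.10 + 0.06 * i) * ear_w
            p0 = np.array([pts[17, 0] + margin * span, y])
            p2 = np.array([pts[26, 0] - margin * span, y])
            p1 = 0.5 * (p0 + p2) + np.array([0.0, -0.02 * ear_w])
            draw(np.array([p0, p1, p2]), value, width)

    if expression == "pain_face":
        # a grimace creases the whole face deeply: knitted glabella,
        # furrowed brow, crow's feet, nasolabial folds, cheek and chin
        # creases — the densest, darkest stroke set of any expression
        dark = 200.0 - a * 160.0
        glabellar(dark, 1.6)
        nasolabial(dark, 1.7)
        _stroke(canvas, pts[T.LEFT_BROW], dark, 3.0)
        _stroke(canvas, pts[T.RIGHT_BROW], dark, 3.0)
        crows_feet(dark, 1.4, 0.13)
        forehead(dark, 1.5, 3, margin=0.25)
        for eye, sgn in ((T.LEFT_EYE, -1.0), (T.RIGHT_EYE, 1.0)):
            lower = pts[eye].mean(axis=0) + np.array([0.0, 0.06 * ear_w])
            for k in (0.0, 0.5):
                p0 = lower + np.array([sgn * k * 0.05 * ear_w, k * 0.03 * ear_w])
                tip = p0 + np.array([sgn * 0.12 * ear_w, 0.14 * ear_w])
                draw(np.array([p0, tip]), dark, 1.5)
        chin = pts[8]
        for dy in (-0.10, -0.16):
            p0 = chin + np.array([-0.10 * ear_w, dy * ear_w])
            p1 = chin + np.array([0.10 * ear_w, dy * ear_w])
            draw(np.array([p0, 0.5 * (p0 + p1) + up * 0.2, p1]), dark, 1.3)
    elif expression == "smile":
        val = 200.0 - a * 70.0
        nasolabial(val, 1.2)
        crows_feet(val, 1.0, 0.07)
    elif expression == "surprise":
        pass  # raised brows, widened eyes and dropped jaw carry surprise
    elif expression == "angry":
        val = 200.0 - a * 80.0
        glabellar(val, 1.4)
        forehead(val, 1.0, 1)


def render_frame(
    landmarks: np.ndarray,
    illumination_gain: float = 1.0,
    noise_sigma: float = 0.0,
    resolution: str = "QVGA",
    rng: np.random.Generator | None = None,
    expression: str = "neutral_face",
    amplitude: float = 0.0,
    frame_index: int = 0,
    fps: float = 15.0,
) -> Frame:
    """Render one RGB frame from 66 landmark positions (pixel coords).

    ``expression``/``amplitude`` select the wrinkle strokes drawn on top
    of the landmark-driven geometry.  Deterministic given identical
    inputs (``rng`` drives only the additive noise).
    """
    W, H = RESOLUTIONS[resolution]
    pts = np.asarray(landmarks, float)
    # textured backdrop (a patterned wall): gives the corner regions of a
    # face crop stable local structure instead of noise-dominated flatness
    yy0, xx0 = np.mgrid[0:H, 0:W]
    canvas = 50.0 + 12.0 * np.sin(0.9 * xx0) * np.sin(0.9 * yy0)

    jaw = pts[T.JAW]
    ear_l, ear_r = jaw[0], jaw[-1]
    ear_mid = 0.5 * (ear_l + ear_r)
    # head outline: jaw arc plus a forehead arc mirrored across the ear line
    forehead = ear_mid + (ear_mid - jaw[::-1]) * 0.85
    outline = np.vstack([jaw, forehead])
    _fill(canvas, outline, 200.0)
    # gentle radial shading so the skin is not flat
    yy, xx = np.mgrid[0:H, 0:W]
    inside = np.abs(canvas - 200.0) < 1e-9
    r = np.hypot(xx - ear_mid[0], yy - ear_mid[1])
    r_norm = r / max(r[inside].max(), 1.0) if inside.any() else r
    canvas[inside] = 208.0 - 26.0 * r_norm[inside]
    # skin micro-texture, anchored to the face frame so it rides with the
    # head; its pixel-to-pixel gradients dominate sensor noise, keeping
    # flat-region LBP codes stable.  A pain grimace tenses the skin into
    # dense fine creasing, which reads out as a finer, stronger texture:
    # the density of local intensity extrema is what the LBP histogram
    # principally measures, so this is the texture correlate of pain.
    ear_w = np.linalg.norm(ear_r - ear_l)
    if ear_w > 1.0:
        e1 = (ear_r - ear_l) / ear_w
        e2 = np.array([-e1[1], e1[0]])
        dx, dy = xx - ear_mid[0], yy - ear_mid[1]
        u = (dx * e1[0] + dy * e1[1]) / ear_w
        v = (dx * e2[0] + dy * e2[1]) / ear_w
        if expression == "pain_face" and amplitude > 0:
            freq = 10.0 + 7.0 * amplitude
            amp = 18.0 + 30.0 * amplitude
        else:
            freq, amp = 10.0, 18.0
        tex = amp * np.sin(2 * np.pi * freq * u) * np.sin(2 * np.pi * freq * v)
        canvas[inside] += tex[inside]

    _stroke(canvas, outline, 130.0, 1.0, closed=True)
    _stroke(canvas, pts[T.LEFT_BROW], 70.0, 2.2)
    _stroke(canvas, pts[T.RIGHT_BROW], 70.0, 2.2)
    _stroke(canvas, pts[T.NOSE_BRIDGE], 150.0, 1.2)
    _stroke(canvas, pts[T.NOSE_BASE], 120.0, 1.4)

    # Eyes: open eyes show a bright sclera and a dark pupil; eyes squeezed
    # shut (orbit tightening) collapse to a dark lid line.
    for eye in (T.LEFT_EYE, T.RIGHT_EYE):
        ep = pts[eye]
        width = np.linalg.norm(ep[3] - ep[0])
        cy = ep[:, 1].mean()
        height = 2.0 * np.abs(ep[:, 1] - cy).max()
        if width > 0 and height / width >= 0.20:
            _fill(canvas, ep, 240.0)                      # sclera
            centre = ep.mean(axis=0)
            # iris striation: a speckle ring of strong local extrema that
            # disappears entirely when the orbit squeezes shut
            axis = (ep[3] - ep[0]) / max(width, 1e-9)
            for k, frac in enumerate(np.linspace(-0.42, 0.42, 7)):
                p = centre + axis * frac * width
                rr, cc = disk((p[1], p[0]), 2.0, shape=canvas.shape)
                canvas[rr, cc] = 25.0 if k % 2 == 0 else 250.0
            _stroke(canvas, ep, 60.0, 1.0, closed=True)   # lid contour
        else:
            # squeezed-shut orbit: a beaded lash line of strong minima
            _beaded_stroke(canvas, np.vstack([ep, ep[:1]]), 30.0,
                           spacing=3.5, radius=2.4)

    # Mouth: raised corners reveal a bright tooth band; a dropped jaw a
    # dark oral cavity; otherwise the lips are closed.
    lips = pts[T.OUTER_LIP]
    inner = pts[T.INNER_LIP]
    ear_w = np.linalg.norm(pts[16] - pts[0])
    _fill(canvas, lips, 115.0)
    _stroke(canvas, lips, 100.0, 1.0, closed=True)
    corner_raise = lips[:, 1].mean() - 0.5 * (lips[0, 1] + lips[6, 1])
    inner_h = inner[:, 1].max() - inner[:, 1].min()
    if inner_h > 0.12 * ear_w:      # jaw dropped: dark cavity
        _fill(canvas, inner, 35.0)
    elif corner_raise > 0.035 * ear_w:  # smiling: tooth band
        _fill(canvas, inner, 235.0)
    else:
        _fill(canvas, inner, 70.0)

    _draw_wrinkles(canvas, pts, expression, amplitude)

    canvas *= illumination_gain
    if noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        canvas = canvas + rng.normal(0.0, noise_sigma, canvas.shape)
    gray = np.clip(np.floor(canvas + 0.5), 0, 255).astype(np.uint8)
    return Frame(index=frame_index, pixels=np.stack([gray] * 3, axis=-1),
                 colour_space="RGB", source_fps=fps)


# ---------------------------------------------------------------------------
# sequence generation


def _reflect(value: float, lo: float, hi: float) -> float:
    if value < lo:
        return 2 * lo - value
    if value > hi:
        return 2 * hi - value
    return value


def base_scale(resolution: str) -> float:
    """Pixels per unit-face coordinate for a resolution."""
    W, H = RESOLUTIONS[resolution]
    return 0.2 * min(W, H)


def reference_placement(resolution: str) -> tuple[float, np.ndarray]:
    """(base scale, centre) at which the neutral template is staged."""
    W, H = RESOLUTIONS[resolution]
    return base_scale(resolution), np.array([W / 2.0, H / 2.0])


def project_landmarks(pose: dict, amplitude_field: np.ndarray,
                      resolution: str) -> np.ndarray:
    """Weak-perspective projection of the deformed 3-D template."""
    s0, centre = reference_placement(resolution)
    X = T.canonical_landmarks_3d().copy()
    X[:, :2] += amplitude_field
    R = rotation_zyx(pose["pitch"], pose["yaw"], pose["roll"])
    P = (s0 * pose["scale"]) * (X @ R.T)[:, :2]
    return P + centre + np.array([pose["shift_x"], pose["shift_y"]])


def generate_expression_sequence(script: ExpressionScript) -> list[SyntheticFrameRecord]:
    """Render a full scripted sequence with ground truth, reproducibly."""
    rng = np.random.default_rng(script.seed)
    W, H = RESOLUTIONS[script.resolution]
    m = script.motion
    pose = {"scale": 1.0, "roll": 0.0, "yaw": 0.0, "pitch": 0.0,
            "shift_x": 0.0, "shift_y": 0.0}
    gain = float(np.clip(rng.uniform(0.8, 1.1), *script.illumination_range))
    records: list[SyntheticFrameRecord] = []
    frame_index = 0
    for seg_i, seg in enumerate(script.segments):
        disp = T.expression_displacement(
            "neutral_face" if seg.expression == "neutral_face" else seg.expression,
            seg.amplitude,
        )
        for _ in range(seg.duration):
            if m.enabled:
                pose["scale"] = _reflect(pose["scale"] + rng.normal(0, m.scale_step),
                                         *m.scale_range)
                for key, rng_lim in (("roll", m.roll_range), ("yaw", m.yaw_range),
                                     ("pitch", m.pitch_range)):
                    pose[key] = _reflect(pose[key] + rng.normal(0, m.angle_step), *rng_lim)
                for key in ("shift_x", "shift_y"):
                    pose[key] = _reflect(pose[key] + rng.normal(0, m.shift_step),
                                         *m.shift_range)
            gain = _reflect(gain + rng.normal(0, script.illumination_step),
                            *script.illumination_range)
            pts = project_landmarks(pose, disp, script.resolution)
            margin = 2.0
            if (pts[:, 0].min() < margin or pts[:, 0].max() > W - margin
                    or pts[:, 1].min() < margin or pts[:, 1].max() > H - margin):
                logger.warning("landmarks left the frame; clamping translation")
                pose["shift_x"] = float(np.clip(pose["shift_x"], *m.shift_range) * 0.5)
                pose["shift_y"] = float(np.clip(pose["shift_y"], *m.shift_range) * 0.5)
                pts = project_landmarks(pose, disp, script.resolution)
            frame = render_frame(
                pts, illumination_gain=gain, noise_sigma=script.noise_sigma,
                resolution=script.resolution, rng=rng, expression=seg.expression,
                amplitude=seg.amplitude, frame_index=frame_index, fps=script.fps,
            )
            records.append(SyntheticFrameRecord(
                frame=frame,
                landmarks=LandmarkSet(points=pts, frame_index=frame_index),
                label=seg.label,
                expression=seg.expression,
                pose=dict(pose),
                segment_index=seg_i,
            ))
            frame_index += 1
    return records


def default_video_script(video_index: int, seed: int, frames_per_segment: int = 45,
                         amplitude: float = 0.9, noise_sigma: float = 2.0,
                         resolution: str = "QVGA") -> ExpressionScript:
    """The standard three-segment script used for dataset generation.

    Every video starts neutral; the pain segment and one rotating
    not-pain expression (smile / surprise / angry) fill the remaining
    two slots, alternating order across videos.
    """
    other = ("smile", "surprise", "angry")[video_index % 3]
    tail = [other, "pain_face"] if video_index % 2 == 0 else ["pain_face", other]
    segs = [Segment("neutral_face", frames_per_segment, amplitude)]
    segs += [Segment(e, frames_per_segment, amplitude) for e in tail]
    return ExpressionScript(segments=segs, seed=seed + 1000 * video_index,
                            noise_sigma=noise_sigma, resolution=resolution)


def write_landmarks_pts(path: Path, landmarks: LandmarkSet) -> None:
    with open(path, "w") as fh:
        for j, (x, y) in enumerate(landmarks.points):
            vis = int(landmarks.visibility[j])
            fh.write(f"{j} {x:.4f} {y:.4f} {vis}\n")


def read_landmarks_pts(path: Path, frame_index: int = 0) -> LandmarkSet:
    rows = np.loadtxt(path)
    return LandmarkSet(points=rows[:, 1:3], visibility=rows[:, 3] > 0,
                       frame_index=frame_index)


def generate_dataset(
    out_dir,
    n_videos: int = 22,
    seed: int = 0,
    frames_per_segment: int = 45,
    amplitude: float = 0.9,
    noise_sigma: float = 2.0,
    resolution: str = "QVGA",
) -> Path:
    """Write a full synthetic video database with ground-truth sidecars.

    Per video: a PNG frame folder, per-frame ``.pts`` landmark files and
    a ``labels.csv`` (frame, expression, label, pose).  A top-level
    ``manifest.csv`` lists (video, segment, expression, label, frames).
    """
    import imageio.v3 as iio

    if n_videos < 1:
        raise ValueError("n_videos must be >= 1")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    for v in range(n_videos):
        script = default_video_script(v, seed, frames_per_segment, amplitude,
                                      noise_sigma, resolution)
        records = generate_expression_sequence(script)
        vdir = out / f"video_{v:03d}"
        vdir.mkdir(exist_ok=True)
        with open(vdir / "labels.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["frame", "expression", "label", "scale", "pitch",
                             "yaw", "roll", "shift_x", "shift_y"])
            for rec in records:
                name = f"frame_{rec.frame.index:04d}"
                iio.imwrite(vdir / f"{name}.png", rec.frame.pixels)
                write_landmarks_pts(vdir / f"{name}.pts", rec.landmarks)
                writer.writerow([rec.frame.index, rec.expression, rec.label]
                                + [f"{rec.pose[k]:.5f}" for k in
                                   ("scale", "pitch", "yaw", "roll",
                                    "shift_x", "shift_y")])
        for seg_i, seg in enumerate(script.segments):
            manifest_rows.append([f"video_{v:03d}", seg_i, seg.expression,
                                  seg.label, seg.duration])
    with open(out / "manifest.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["video", "segment", "expression", "label", "frames"])
        writer.writerows(manifest_rows)
    return out
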