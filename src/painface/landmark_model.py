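"""Hybrid statistical landmark model: Procrustes + PCA shape model,
PCA appearance model, per-landmark patch templates, tree connectivity,
and constrained mean-shift landmark fitting.

The shape model expresses any 66-point face as the Procrustes mean plus
a linear combination of PCA eigen-shapes, s = s0 + sum_i q_i * s_i.
The appearance model does the same for shape-normalised face texture,
A(z) = A0(z) + sum_i lambda_i * A_i(z), on the pixel domain of the base
mesh.  Fitting alternates a local step (each landmark moves toward the
weighted centroid of its patch template's normalised cross-correlation
response in a search window) with a global step (projection onto the
shape subspace with per-mode coefficient clamping at 3 sigma), which
keeps every fitted shape statistically plausible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.spatial import Delaunay

from .template import N_LANDMARKS

logger = logging.getLogger(__name__)


class AlignmentError(RuntimeError):
    """Raised for degenerate point configurations."""


@dataclass
class LandmarkSet:
    """Ordered 66-point annotation of one frame.

    Indexing: jaw 0-16, brows 17-26, nose 27-35, eyes 36-47, mouth 48-65.
    """

    points: np.ndarray  # (66, 2) float
    visibility: np.ndarray | None = None  # (66,) bool
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.shape != (N_LANDMARKS, 2):
            raise ValueError(f"landmark set must be {N_LANDMARKS}x2")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("landmark coordinates must be finite")
        if self.visibility is None:
            self.visibility = np.ones(N_LANDMARKS, dtype=bool)
        else:
            self.visibility = np.asarray(self.visibility, dtype=bool)
            if self.visibility.shape != (N_LANDMARKS,):
                raise ValueError("visibility must have one flag per landmark")

    @property
    def vector(self) -> np.ndarray:
        """The shape as a flat 132-vector (x1, y1, ..., x66, y66)."""
        return self.points.ravel().copy()


@dataclass
class ShapeModel:
    """Mean shape plus PCA eigen-shapes of Procrustes-aligned training shapes."""

    mean_shape: np.ndarray          # (132,)
    shape_vectors: np.ndarray       # (132, k), orthonormal columns
    eigenvalues: np.ndarray         # (k,), descending
    k: int = field(init=False)

    def __post_init__(self) -> None:
        self.k = self.shape_vectors.shape[1]

    def project(self, shape_vec: np.ndarray, clamp_sigma: float | None = 3.0) -> np.ndarray:
        """Project a 132-vector onto the model subspace, clamping each
        coefficient to +/- clamp_sigma * sqrt(eigenvalue)."""
        q = self.shape_vectors.T @ (shape_vec - self.mean_shape)
        if clamp_sigma is not None and self.k:
            lim = clamp_sigma * np.sqrt(np.maximum(self.eigenvalues, 0.0))
            q = np.clip(q, -lim, lim)
        return self.mean_shape + self.shape_vectors @ q


@dataclass
class AppearanceModel:
    """Mean image plus eigen-images on the base-shape pixel domain."""

    base_appearance: np.ndarray     # (H, W)
    appearance_images: np.ndarray   # (l, H, W)
    eigenvalues: np.ndarray         # (l,)
    domain_mask: np.ndarray         # (H, W) bool, pixels inside the base mesh

    @property
    def l(self) -> int:
        return self.appearance_images.shape[0]


@dataclass
class PatchModel:
    """One normalised template patch per landmark, averaged over peak frames."""

    patches: np.ndarray  # (66, p, p)
    patch_size: int

    def __post_init__(self) -> None:
        if self.patches.shape[0] != N_LANDMARKS:
            raise ValueError(f"patch model must hold {N_LANDMARKS} templates")
        if self.patch_size % 2 != 1:
            raise ValueError("patch size must be odd")


@dataclass
class TreeStructure:
    """Spanning-tree connectivity over the visible landmarks."""

    vertices: np.ndarray            # visible landmark indices
    edges: list[tuple[int, int]]    # (i, j) with i < j
    n: int = field(init=False)

    def __post_init__(self) -> None:
        self.n = len(self.vertices)
        if len(self.edges) != self.n - 1:
            raise ValueError("a spanning tree on n vertices has n-1 edges")


# ---------------------------------------------------------------------------
# similarity transforms and Procrustes analysis


def similarity_fit(src: np.ndarray, dst: np.ndarray):
    """Least-squares similarity transform mapping src onto dst.

    Returns (scale, R, t) with dst ~ scale * src @ R.T + t.
    """
    src = np.asarray(src, float)
    dst = np.asarray(dst, float)
    src_c = src - src.mean(axis=0)
    dst_c = dst - dst.mean(axis=0)
    denom = (src_c**2).sum()
    if denom < 1e-12:
        raise AlignmentError("degenerate source shape (all points coincident)")
    H = src_c.T @ dst_c
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, d])
    R = Vt.T @ D @ U.T
    scale = (S @ np.diag([1.0, d]).diagonal()) / denom
    t = dst.mean(axis=0) - scale * src.mean(axis=0) @ R.T
    return float(scale), R, t


def apply_similarity(points: np.ndarray, scale: float, R: np.ndarray, t: np.ndarray):
    return scale * np.asarray(points, float) @ R.T + t


def invert_similarity(scale: float, R: np.ndarray, t: np.ndarray):
    s_inv = 1.0 / scale
    R_inv = R.T
    t_inv = -s_inv * t @ R_inv.T
    return s_inv, R_inv, t_inv


def procrustes_align(shapes: list[LandmarkSet], tol: float = 1e-8, max_iter: int = 100):
    """Generalised Procrustes alignment of a set of 66-point shapes.

    Each shape is centred, scaled to unit Frobenius norm and rotated to
    the evolving mean; iteration stops when the mean moves less than
    ``tol``.  Returns (aligned point arrays, mean shape points, list of
    (scale, R, t) transforms mapping each original shape to its aligned
    position).
    """
    if len(shapes) < 2:
        raise AlignmentError("need at least two shapes to align")
    pts = []
    for s in shapes:
        p = s.points
        if np.allclose(p, p[0]):
            raise AlignmentError("degenerate shape: all points coincident")
        pts.append(p)

    def _normalise(p):
        c = p - p.mean(axis=0)
        return c / np.linalg.norm(c)

    aligned = [_normalise(p) for p in pts]
    mean = _normalise(aligned[0])
    for _ in range(max_iter):
        new_aligned = []
        for p0, p in zip(pts, aligned):
            _, R, _ = similarity_fit(_normalise(p0), mean)
            new_aligned.append(_normalise(p0) @ R.T)
        new_mean = _normalise(np.mean(new_aligned, axis=0))
        aligned = new_aligned
        if np.linalg.norm(new_mean - mean) < tol:
            mean = new_mean
            break
        mean = new_mean
    transforms = [similarity_fit(p0, a) for p0, a in zip(pts, aligned)]
    return aligned, mean, transforms


# ---------------------------------------------------------------------------
# model building


def build_shape_model(aligned_shapes, variance_fraction: float = 0.95) -> ShapeModel:
    """PCA of aligned shapes; retain the smallest k modes reaching the
    requested fraction of total variance."""
    if len(aligned_shapes) < 2:
        raise AlignmentError("shape model requires at least two shapes")
    if not 0.0 < variance_fraction <= 1.0:
        raise ValueError("variance_fraction must lie in (0, 1]")
    X = np.array([np.asarray(s, float).ravel() for s in aligned_shapes])
    mean = X.mean(axis=0)
    Xc = X - mean
    # Eigendecomposition via SVD of the centred data matrix.
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigvals = S**2 / (len(X) - 1)
    total = eigvals.sum()
    if total < 1e-20:
        return ShapeModel(mean_shape=mean, shape_vectors=np.zeros((X.shape[1], 0)),
                          eigenvalues=np.zeros(0))
    cum = np.cumsum(eigvals) / total
    k = int(np.searchsorted(cum, variance_fraction - 1e-12) + 1)
    k = min(k, int((eigvals > 1e-12 * total).sum()))
    return ShapeModel(mean_shape=mean, shape_vectors=Vt[:k].T.copy(),
                      eigenvalues=eigvals[:k].copy())


def _rasterise_mask(points: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    tri = Delaunay(points)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    coords = np.column_stack([xx.ravel(), yy.ravel()])
    return (tri.find_simplex(coords) >= 0).reshape(shape)


def warp_to_base(image: np.ndarray, src_points: np.ndarray, base_points: np.ndarray,
                 out_shape: tuple[int, int]) -> np.ndarray:
    """Piecewise-affine warp of an image so its landmarks land on the base mesh."""
    from skimage.transform import PiecewiseAffineTransform, warp

    # skimage maps output coords through tform to input coords
    if hasattr(PiecewiseAffineTransform, "from_estimate"):
        tform = PiecewiseAffineTransform.from_estimate(base_points, src_points)
    else:  # older scikit-image
        tform = PiecewiseAffineTransform()
        tform.estimate(base_points, src_points)
    return warp(np.asarray(image, float), tform, output_shape=out_shape,
                order=1, mode="edge", preserve_range=True)


def build_appearance_model(crops, landmark_sets, base_points: np.ndarray,
                           l: int = 5, out_shape: tuple[int, int] = (64, 64)):
    """PCA appearance model on crops warped onto the base mesh.

    ``base_points`` are the base-shape landmarks in pixel coordinates of
    ``out_shape``.  ``l`` is clipped to the sample count with a warning.
    """
    if len(crops) < 2:
        raise AlignmentError("appearance model requires at least two crops")
    if l > len(crops):
        logger.warning("appearance mode count %d exceeds sample size %d; clipping",
                       l, len(crops))
        l = len(crops)
    mask = _rasterise_mask(base_points, out_shape)
    warped = np.array([
        warp_to_base(c, ls.points if isinstance(ls, LandmarkSet) else ls,
                     base_points, out_shape)
        for c, ls in zip(crops, landmark_sets)
    ])
    flat = warped.reshape(len(warped), -1)[:, mask.ravel()]
    mean = flat.mean(axis=0)
    Xc = flat - mean
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigvals = S**2 / max(len(flat) - 1, 1)
    l = min(l, len(eigvals))
    A0 = np.zeros(out_shape)
    A0[mask] = mean
    eigenimages = np.zeros((l,) + out_shape)
    for i in range(l):
        eigenimages[i][mask] = Vt[i]
    return AppearanceModel(base_appearance=A0, appearance_images=eigenimages,
                           eigenvalues=eigvals[:l].copy(), domain_mask=mask)


def _normalise_patch(patch: np.ndarray) -> np.ndarray:
    p = patch.astype(np.float64)
    p = p - p.mean()
    n = np.linalg.norm(p)
    return p / n * np.sqrt(p.size) if n > 1e-12 else p * 0.0


def extract_patch(image: np.ndarray, center: np.ndarray, size: int) -> np.ndarray:
    """size x size patch around a (x, y) centre, replicate-padded at borders."""
    half = size // 2
    img = np.asarray(image, float)
    # clamp so landmarks slightly outside the crop still yield a patch
    cx = int(round(min(max(center[0], 0), img.shape[1] - 1)))
    cy = int(round(min(max(center[1], 0), img.shape[0] - 1)))
    padded = np.pad(img, half + 1, mode="edge")
    cy_p, cx_p = cy + half + 1, cx + half + 1
    return padded[cy_p - half : cy_p + half + 1, cx_p - half : cx_p + half + 1]


def build_patch_model(images, landmark_sets, patch_size: int = 11) -> PatchModel:
    """Average the zero-mean/unit-variance patch around each landmark over
    the peak training frames."""
    if patch_size % 2 != 1:
        raise ValueError("patch size must be odd")
    acc = np.zeros((N_LANDMARKS, patch_size, patch_size))
    for img, ls in zip(images, landmark_sets):
        pts = ls.points if isinstance(ls, LandmarkSet) else np.asarray(ls, float)
        for j in range(N_LANDMARKS):
            acc[j] += _normalise_patch(extract_patch(img, pts[j], patch_size))
    acc /= max(len(images), 1)
    patches = np.array([_normalise_patch(acc[j]) for j in range(N_LANDMARKS)])
    return PatchModel(patches=patches, patch_size=patch_size)


def build_tree(visibility: np.ndarray, coordinates: np.ndarray) -> TreeStructure:
    """Euclidean minimum spanning tree over the visible landmarks.

    Kruskal's algorithm with edges ordered by (weight, i, j) gives the
    deterministic lower-index tie-break.
    """
    vis = np.flatnonzero(np.asarray(visibility, bool))
    if len(vis) < 2:
        raise AlignmentError("need at least two visible points for a tree")
    pts = np.asarray(coordinates, float).reshape(-1, 2)[vis]
    edges = []
    for a in range(len(vis)):
        for b in range(a + 1, len(vis)):
            w = float(np.hypot(*(pts[a] - pts[b])))
            edges.append((w, int(vis[a]), int(vis[b])))
    edges.sort()
    parent = {int(v): int(v) for v in vis}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    tree_edges = []
    for w, i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            tree_edges.append((i, j))
            if len(tree_edges) == len(vis) - 1:
                break
    return TreeStructure(vertices=vis, edges=tree_edges)


# ---------------------------------------------------------------------------
# constrained mean-shift fitting


@dataclass
class FitResult:
    landmarks: LandmarkSet
    pose: tuple[float, np.ndarray, np.ndarray]  # similarity (scale, R, t) vs mean shape
    visibility: np.ndarray
    converged: bool
    n_iter: int


def _ncc_responses(image: np.ndarray, points: np.ndarray, patches: np.ndarray,
                   window: int) -> tuple[np.ndarray, np.ndarray]:
    """Normalised cross-correlation response maps for all landmarks at once.

    Returns (responses (66, window, window), top-left corners (66, 2) of
    each response grid in image coordinates).
    """
    p = patches.shape[1]
    half_w, half_p = window // 2, p // 2
    reach = half_w + half_p
    img = np.asarray(image, float)
    padded = np.pad(img, reach + 1, mode="edge")
    centers = np.rint(points).astype(int)
    centers[:, 0] = np.clip(centers[:, 0], 0, img.shape[1] - 1)
    centers[:, 1] = np.clip(centers[:, 1], 0, img.shape[0] - 1)
    regions = np.empty((len(points), window + p - 1, window + p - 1))
    corners = np.empty((len(points), 2))
    for j, (cx, cy) in enumerate(centers):
        py, px = cy + reach + 1, cx + reach + 1
        regions[j] = padded[py - reach : py + reach + 1, px - reach : px + reach + 1]
        corners[j] = (cx - half_w, cy - half_w)
    win = sliding_window_view(regions, (p, p), axis=(1, 2))  # (66, W, W, p, p)
    n = p * p

    def _box_sums(arr):
        # integral-image windowed p x p sums, zero-padded cumulative sums
        S = np.zeros((arr.shape[0], arr.shape[1] + 1, arr.shape[2] + 1))
        S[:, 1:, 1:] = arr.cumsum(axis=1).cumsum(axis=2)
        return (S[:, p:, p:] - S[:, :-p, p:] - S[:, p:, :-p] + S[:, :-p, :-p])

    sums = _box_sums(regions)
    sumsq = _box_sums(regions**2)
    mean_w = sums / n
    var_w = np.maximum(sumsq / n - mean_w**2, 0.0)
    # patches are zero-mean with ||.||^2 = n, so NCC = cross / (n * std_w)
    cross = np.einsum("jabmn,jmn->jab", win, patches)
    denom = n * np.sqrt(var_w) + 1e-9
    resp = cross / denom
    return resp, corners


def fit_landmarks(
    crop: np.ndarray,
    init: LandmarkSet | None,
    shape_model: ShapeModel,
    patch_model: PatchModel,
    tree: TreeStructure | None = None,
    reference_shape: np.ndarray | None = None,
    search_window: int = 15,
    max_iter: int = 20,
    tol: float = 0.1,
    clamp_sigma: float = 3.0,
    visibility_floor: float = 0.3,
) -> FitResult:
    """Fit the 66 landmarks to an enhanced 64x64 crop.

    Alternates (a) a mean-shift step per landmark toward the
    response-weighted centroid of its NCC response map in a
    ``search_window`` square, and (b) projection onto the shape-model
    subspace with coefficients clamped at ``clamp_sigma`` standard
    deviations.  ``init`` defaults to ``reference_shape`` (the model
    mean placed in crop coordinates).  Deterministic throughout.
    """
    img = np.asarray(crop, float)
    if init is not None:
        points = init.points.copy()
    elif reference_shape is not None:
        points = np.asarray(reference_shape, float).reshape(N_LANDMARKS, 2).copy()
    else:
        raise ValueError("either init or reference_shape must be supplied")

    mean_pts = shape_model.mean_shape.reshape(N_LANDMARKS, 2)
    visibility = np.ones(N_LANDMARKS, dtype=bool)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        resp, corners = _ncc_responses(img, points, patch_model.patches, search_window)
        w = np.maximum(resp, 0.0) ** 2
        peak = resp.max(axis=(1, 2))
        visibility = peak >= visibility_floor
        wsum = w.sum(axis=(1, 2))
        grid = np.arange(search_window, dtype=float)
        gx = np.einsum("jab,b->j", w, grid)
        gy = np.einsum("jab,a->j", w, grid)
        new_points = points.copy()
        ok = wsum > 1e-12
        new_points[ok, 0] = corners[ok, 0] + gx[ok] / wsum[ok]
        new_points[ok, 1] = corners[ok, 1] + gy[ok] / wsum[ok]
        # global shape constraint in the model's normalised frame
        scale, R, t = similarity_fit(new_points, mean_pts)
        y = apply_similarity(new_points, scale, R, t).ravel()
        y_proj = shape_model.project(y, clamp_sigma=clamp_sigma)
        s_i, R_i, t_i = invert_similarity(scale, R, t)
        constrained = apply_similarity(y_proj.reshape(N_LANDMARKS, 2), s_i, R_i, t_i)
        disp = float(np.mean(np.linalg.norm(constrained - points, axis=1)))
        points = constrained
        if disp < tol:
            converged = True
            break
    if not converged:
        logger.debug("landmark fit did not converge in %d iterations", max_iter)
    scale, R, t = similarity_fit(mean_pts, points)
    return FitResult(
        landmarks=LandmarkSet(points=points, visibility=visibility),
        pose=(scale, R, t),
        visibility=visibility,
        converged=converged,
        n_iter=it,
    )
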