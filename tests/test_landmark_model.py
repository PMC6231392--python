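import numpy as np
import pytest

from painface.landmark_model import (
    AlignmentError,
    LandmarkSet,
    apply_similarity,
    build_patch_model,
    build_shape_model,
    build_tree,
    fit_landmarks,
    procrustes_align,
    similarity_fit,
)
from painface.template import canonical_landmarks


def _rot(deg):
    t = np.radians(deg)
    return np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])


def _random_shape(rng):
    return rng.standard_normal((66, 2)) * 10 + 50


class TestProcrustes:
    def test_self_alignment_zero_residual(self, rng):
        base = _random_shape(rng)
        shapes = [LandmarkSet(points=base.copy()) for _ in range(2)]
        aligned, mean, _ = procrustes_align(shapes)
        assert np.allclose(aligned[0], aligned[1], atol=1e-10)

    def test_similarity_transformed_copy_aligns_exactly(self, rng):
        base = _random_shape(rng)
        moved = 2.0 * base @ _rot(30.0).T + np.array([17.0, -4.0])
        aligned, _, _ = procrustes_align(
            [LandmarkSet(points=base), LandmarkSet(points=moved)]
        )
        assert np.linalg.norm(aligned[0] - aligned[1]) < 1e-8

    def test_optimal_rotation_matches_grid_search_oracle(self, rng):
        a, b = _random_shape(rng), _random_shape(rng)

        def norm(p):
            c = p - p.mean(axis=0)
            return c / np.linalg.norm(c)

        na, nb = norm(a), norm(b)
        grid = np.arange(-180.0, 180.0, 0.01)
        costs = [np.sum((na @ _rot(g).T - nb) ** 2) for g in grid]
        best = grid[int(np.argmin(costs))]
        _, R, _ = similarity_fit(na, nb)
        angle = np.degrees(np.arctan2(R[1, 0], R[0, 0]))
        assert abs((angle - best + 180) % 360 - 180) < 0.02

    def test_mean_invariant_to_similarity_transform_of_training_set(self, rng):
        shapes = [LandmarkSet(points=_random_shape(rng)) for _ in range(5)]
        _, mean1, _ = procrustes_align(shapes)
        moved = [
            LandmarkSet(points=1.7 * s.points @ _rot(25).T + [5.0, 9.0]) for s in shapes
        ]
        _, mean2, _ = procrustes_align(moved)
        _, R, _ = similarity_fit(mean2, mean1)
        assert np.linalg.norm(mean2 @ R.T - mean1) < 1e-6

    def test_degenerate_shape_rejected(self):
        flat = LandmarkSet(points=np.ones((66, 2)))
        with pytest.raises(AlignmentError):
            procrustes_align([flat, flat])


class TestShapeModel:
    def test_planted_single_mode_recovered(self, rng):
        mean = canonical_landmarks().ravel()
        d = rng.standard_normal(132)
        d /= np.linalg.norm(d)
        shapes = [(mean + t * d).reshape(66, 2) for t in np.linspace(-1, 1, 20)]
        model = build_shape_model(shapes, 0.95)
        assert model.k == 1
        cosine = abs(model.shape_vectors[:, 0] @ d)
        assert cosine >= 0.999

    def test_identical_shapes_degenerate_to_mean(self):
        shape = canonical_landmarks()
        model = build_shape_model([shape] * 5, 0.95)
        assert model.k == 0
        assert np.allclose(model.mean_shape, shape.ravel())

    def test_reconstruction_error_nonincreasing_in_k(self, rng):
        shapes = [canonical_landmarks() + 0.05 * rng.standard_normal((66, 2))
                  for _ in range(12)]
        model = build_shape_model(shapes, 1.0)
        target = shapes[3].ravel() - model.mean_shape
        errs = []
        for k in range(model.k + 1):
            W = model.shape_vectors[:, :k]
            errs.append(np.linalg.norm(target - W @ (W.T @ target)))
        assert all(a >= b - 1e-12 for a, b in zip(errs, errs[1:]))

    def test_too_few_shapes_rejected(self):
        with pytest.raises(AlignmentError):
            build_shape_model([canonical_landmarks()], 0.95)


class TestPatchModel:
    def test_single_frame_templates_equal_its_normalised_patches(self, rng):
        img = rng.integers(0, 256, (64, 64)).astype(float)
        pts = np.column_stack([rng.uniform(10, 54, 66), rng.uniform(10, 54, 66)])
        model = build_patch_model([img], [pts], 11)
        from painface.landmark_model import _normalise_patch, extract_patch

        for j in (0, 17, 65):
            expected = _normalise_patch(extract_patch(img, pts[j], 11))
            assert np.allclose(model.patches[j], expected)

    def test_always_66_templates(self, crop_training_set):
        crops, anns = crop_training_set
        model = build_patch_model(crops, anns, 11)
        assert model.patches.shape == (66, 11, 11)

    def test_mean_of_identical_patches_is_the_patch(self, rng):
        img = rng.integers(0, 256, (64, 64)).astype(float)
        pts = np.full((66, 2), 32.0)
        model = build_patch_model([img, img], [pts, pts], 11)
        single = build_patch_model([img], [pts], 11)
        assert np.allclose(model.patches, single.patches)


class TestTree:
    def test_three_collinear_points_join_neighbours(self):
        vis = np.zeros(66, bool)
        vis[[0, 1, 2]] = True
        coords = np.zeros((66, 2))
        coords[0], coords[1], coords[2] = (0, 0), (1, 0), (2, 0)
        tree = build_tree(vis, coords)
        assert sorted(tree.edges) == [(0, 1), (1, 2)]

    def test_full_visibility_gives_spanning_tree(self, fitted_models):
        _, _, tree, _ = fitted_models
        assert len(tree.edges) == 65
        # connectivity by union-find
        parent = list(range(66))

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        for i, j in tree.edges:
            parent[find(i)] = find(j)
        assert len({find(i) for i in range(66)}) == 1

    def test_two_visible_points_single_edge(self):
        vis = np.zeros(66, bool)
        vis[[4, 9]] = True
        tree = build_tree(vis, np.arange(132).reshape(66, 2).astype(float))
        assert tree.edges == [(4, 9)]


class TestFitLandmarks:
    def test_fixed_point_converges_fast(self, crop_training_set, fitted_models):
        crops, anns = crop_training_set
        sm, pm, tree, ref = fitted_models
        fit = fit_landmarks(crops[0], LandmarkSet(points=anns[0]), sm, pm, tree,
                            reference_shape=ref)
        assert fit.converged
        rms = np.sqrt(np.mean(np.sum((fit.landmarks.points - anns[0]) ** 2, axis=1)))
        assert rms < 1.5

    def test_recovers_from_perturbed_initialisation(self, crop_training_set,
                                                    fitted_models, rng):
        crops, anns = crop_training_set
        sm, pm, tree, ref = fitted_models
        errs = []
        for crop, ann in zip(crops[:12], anns[:12]):
            init = LandmarkSet(points=ann + rng.normal(0, 2.0, (66, 2)))
            fit = fit_landmarks(crop, init, sm, pm, tree, reference_shape=ref)
            errs.append(np.sqrt(np.mean(np.sum((fit.landmarks.points - ann) ** 2,
                                               axis=1))))
        assert np.mean(errs) < 1.5

    def test_projection_of_in_subspace_shape_is_idempotent(self, fitted_models):
        sm = fitted_models[0]
        q = 0.5 * np.sqrt(np.maximum(sm.eigenvalues, 0))
        inside = sm.mean_shape + sm.shape_vectors @ q
        assert np.linalg.norm(sm.project(inside) - inside) < 1e-9

    def test_coefficients_always_clamped_within_three_sigma(self, fitted_models, rng):
        sm = fitted_models[0]
        wild = sm.mean_shape + sm.shape_vectors @ (100.0 * np.ones(sm.k))
        proj = sm.project(wild, clamp_sigma=3.0)
        q = sm.shape_vectors.T @ (proj - sm.mean_shape)
        assert (np.abs(q) <= 3.0 * np.sqrt(sm.eigenvalues) + 1e-9).all()

    def test_fit_is_bit_reproducible(self, crop_training_set, fitted_models):
        crops, anns = crop_training_set
        sm, pm, tree, ref = fitted_models
        init = LandmarkSet(points=anns[4] + 1.0)
        a = fit_landmarks(crops[4], init, sm, pm, tree, reference_shape=ref)
        b = fit_landmarks(crops[4], init, sm, pm, tree, reference_shape=ref)
        assert (a.landmarks.points == b.landmarks.points).all()
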