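import numpy as np
import pytest

from painface.classifier import (
    CLASS_LABELS,
    NEUTRAL,
    NOT_PAIN,
    PAIN,
    ThresholdConfig,
    TrainingError,
    build_class_templates,
    calibrate_thresholds,
    classify_features,
    classify_frame,
    frame_distance,
)


def _labelled_vectors(rng, n_per_class=4, spread=0.0):
    X, labels = [], []
    for k, c in enumerate(CLASS_LABELS):
        for _ in range(n_per_class):
            X.append(np.full(15, float(k)) + spread * rng.standard_normal(15))
            labels.append(c)
    return X, labels


class TestTemplates:
    def test_single_vector_per_class_is_its_normalised_self(self, rng):
        X, labels = _labelled_vectors(rng, n_per_class=1, spread=0.5)
        templates, norm = build_class_templates(X, labels)
        for x, lab in zip(X, labels):
            assert np.allclose(templates[lab].feature_template, norm.apply(x))

    def test_duplicated_training_set_gives_identical_templates(self, rng):
        X, labels = _labelled_vectors(rng, spread=0.5)
        t1, _ = build_class_templates(X, labels)
        t2, _ = build_class_templates(X + X, labels + labels)
        for c in CLASS_LABELS:
            assert np.allclose(t1[c].feature_template, t2[c].feature_template)

    def test_planted_gaussian_cluster_means_recovered(self):
        gen = np.random.default_rng(11)
        n, sigma = 50, 1.0
        means = {NEUTRAL: np.zeros(15), PAIN: np.full(15, 6.0), NOT_PAIN: np.full(15, 3.0)}
        X, labels = [], []
        for c, m in means.items():
            X += list(m + sigma * gen.standard_normal((n, 15)))
            labels += [c] * n
        templates, norm = build_class_templates(X, labels)
        for c, m in means.items():
            recovered = templates[c].feature_template
            expected = norm.apply(m)
            tol = 3.0 * (sigma / norm.std) / np.sqrt(n)
            assert (np.abs(recovered - expected) <= tol).all()

    def test_missing_class_raises_naming_it(self, rng):
        X, labels = _labelled_vectors(rng)
        keep = [i for i, l in enumerate(labels) if l != PAIN]
        with pytest.raises(TrainingError, match="pain_face"):
            build_class_templates([X[i] for i in keep], [labels[i] for i in keep])


class TestFrameDistance:
    def test_identity_is_zero(self, rng):
        v = rng.standard_normal(15)
        assert frame_distance(v, v) == 0.0

    def test_three_four_five(self):
        a = np.zeros(15)
        b = np.zeros(15)
        b[0], b[1] = 3.0, 4.0
        assert frame_distance(a, b) == pytest.approx(5.0)

    def test_matches_sum_of_squares_oracle(self, rng):
        a, b = rng.standard_normal(15), rng.standard_normal(15)
        oracle = np.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)))
        assert frame_distance(a, b) == pytest.approx(oracle, abs=1e-12)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            frame_distance(np.zeros(15), np.zeros(14))


class TestThresholdRule:
    THR = ThresholdConfig(delta1=2.0, delta2=5.0)

    @pytest.mark.parametrize(
        "diff,expected",
        [(1.0, NEUTRAL), (3.5, NOT_PAIN), (10.0, PAIN), (2.0, NOT_PAIN), (5.0, PAIN)],
    )
    def test_branches_and_boundary_severity(self, diff, expected):
        assert classify_frame(diff, self.THR) == expected

    def test_matches_brute_force_conditional_on_dense_grid(self):
        grid = np.linspace(0.0, 10.0, 10_000)
        for diff in grid:
            expected = (NEUTRAL if diff < 2.0 else NOT_PAIN if diff < 5.0 else PAIN)
            assert classify_frame(float(diff), self.THR) == expected

    def test_monotone_in_diff(self):
        severity = {NEUTRAL: 0, NOT_PAIN: 1, PAIN: 2}
        labels = [severity[classify_frame(d, self.THR)]
                  for d in np.linspace(0, 10, 500)]
        assert all(a <= b for a, b in zip(labels, labels[1:]))

    def test_invalid_threshold_order_rejected(self):
        with pytest.raises(ValueError):
            ThresholdConfig(delta1=5.0, delta2=2.0)


class TestCalibration:
    def test_perfectly_separated_clusters(self, rng):
        d = np.concatenate([1 + 0.1 * rng.standard_normal(30),
                            5 + 0.1 * rng.standard_normal(30),
                            9 + 0.1 * rng.standard_normal(30)])
        labels = [NEUTRAL] * 30 + [NOT_PAIN] * 30 + [PAIN] * 30
        thr = calibrate_thresholds(d, labels)
        assert 1.0 < thr.delta1 < 5.0 and 5.0 < thr.delta2 < 9.0
        acc = np.mean([classify_frame(x, thr) == l for x, l in zip(d, labels)])
        assert acc == 1.0

    def test_degenerate_identical_distances_fall_back(self):
        d = np.ones(30)
        labels = ([NEUTRAL] * 10 + [NOT_PAIN] * 10 + [PAIN] * 10)
        thr = calibrate_thresholds(d, labels)
        assert thr.delta2 > thr.delta1

    def test_duplicated_training_set_gives_identical_thresholds(self, rng):
        d = list(rng.uniform(0, 10, 60))
        labels = [CLASS_LABELS[i % 3] for i in range(60)]
        t1 = calibrate_thresholds(d, labels)
        t2 = calibrate_thresholds(d + d, labels + labels)
        assert t1.delta1 == pytest.approx(t2.delta1)
        assert t1.delta2 == pytest.approx(t2.delta2)

    def test_inseparable_classes_trigger_a_warning(self, caplog):
        # label-independent distances: the collapsed-amplitude regime
        gen = np.random.default_rng(8)
        d = gen.normal(5.0, 0.5, 300)
        labels = [CLASS_LABELS[i % 3] for i in range(300)]
        import logging

        with caplog.at_level(logging.WARNING, logger="painface.classifier"):
            calibrate_thresholds(d, labels)
        assert any("poorly separated" in r.message for r in caplog.records)

    def test_never_returns_inverted_thresholds(self, rng):
        for seed in range(5):
            gen = np.random.default_rng(seed)
            d = gen.uniform(0, 1, 90)
            labels = [CLASS_LABELS[i % 3] for i in range(90)]
            thr = calibrate_thresholds(d, labels)
            assert thr.delta1 < thr.delta2


class TestClassifyStream:
    def test_empty_sequence_gives_empty_results(self, rng):
        X, labels = _labelled_vectors(rng, spread=0.1)
        templates, norm = build_class_templates(X, labels)
        out = classify_features([], templates, norm, ThresholdConfig(1.0, 2.0))
        assert out == []

    def test_deterministic(self, rng, tiny_trained_model):
        from painface.pipeline import run_stream

        model, videos = tiny_trained_model
        r1 = run_stream(model, videos[0])
        r2 = run_stream(model, videos[0])
        assert [a.label for a in r1.results] == [a.label for a in r2.results]
        assert np.allclose(r1.diffs, r2.diffs)
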