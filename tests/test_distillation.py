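"""Distillation loss against an independent brute-force oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from daita.distillation import (
    DistillationConfig,
    combine_teachers,
    ensemble_predict,
    kd_loss,
    kd_loss_grad,
    soften,
)
from daita.models import SoftmaxRegression


def brute_force_kd_loss(logits, labels, teacher, cfg):
    """Reference implementation: explicit per-sample loops, math.* only."""
    n, k = len(logits), len(logits[0])
    sw = [1.0] * n if cfg.sample_weights is None else list(cfg.sample_weights)
    cw = [1.0] * k if cfg.class_weights is None else list(cfg.class_weights)
    total = 0.0
    for i in range(n):
        exp = [math.exp(z - max(logits[i])) for z in logits[i]]
        p = [e / sum(exp) for e in exp]
        term = cfg.alpha * -math.log(max(p[labels[i]], 1e-12))
        if cfg.alpha < 1.0:
            t = cfg.temperature
            exp_t = [math.exp(z / t - max(logits[i]) / t) for z in logits[i]]
            p_t = [e / sum(exp_t) for e in exp_t]
            kl = sum(
                max(q, 1e-12) * (math.log(max(q, 1e-12)) - math.log(max(pt, 1e-12)))
                for q, pt in zip(teacher[i], p_t)
            )
            term += (1 - cfg.alpha) * t * t * kl
        total += sw[i] * cw[labels[i]] * cfg.node_weight * term
    return total / n


class TestSoften:
    def test_symmetric_logits_give_uniform(self):
        for t in (0.5, 1.0, 7.0):
            np.testing.assert_allclose(soften(np.zeros((3, 2)), t), 0.5)

    def test_unit_temperature_is_plain_softmax(self):
        out = soften(np.array([[2.0, 0.0]]), 1.0)
        np.testing.assert_allclose(out, [[0.8808, 0.1192]], atol=5e-5)

    def test_high_temperature_flattens(self):
        out = soften(np.array([[2.0, 0.0]]), 1e6)
        np.testing.assert_allclose(out, [[0.5, 0.5]], atol=1e-5)

    def test_nonfinite_logits_rejected(self):
        with pytest.raises(ValueError):
            soften(np.array([[np.inf, 0.0]]), 1.0)

    @given(st.integers(0, 2**31 - 1), st.floats(0.2, 20.0))
    @settings(max_examples=25, deadline=None)
    def test_rows_stay_stochastic(self, seed, temperature):
        logits = np.random.default_rng(seed).normal(size=(4, 3)) * 5
        out = soften(logits, temperature)
        assert np.all(out >= 0)
        np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-9)


class TestCombineTeachers:
    def test_single_teacher_identity(self, rng):
        q = soften(rng.normal(size=(5, 2)), 2.0)
        np.testing.assert_array_equal(combine_teachers([q], np.array([1.0])), q)

    def test_identical_teachers_idempotent(self, rng):
        q = soften(rng.normal(size=(5, 3)), 2.0)
        np.testing.assert_allclose(combine_teachers([q, q], np.array([0.3, 0.7])), q)

    def test_hand_arithmetic(self):
        a = np.array([[0.8, 0.2]])
        b = np.array([[0.4, 0.6]])
        np.testing.assert_allclose(
            combine_teachers([a, b], np.array([0.5, 0.5])), [[0.6, 0.4]]
        )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            combine_teachers([np.ones((2, 2)) / 2, np.ones((3, 2)) / 2])

    @given(st.integers(0, 2**31 - 1), st.integers(1, 5))
    @settings(max_examples=25, deadline=None)
    def test_row_stochasticity_preserved(self, seed, n_teachers):
        r = np.random.default_rng(seed)
        mats = [soften(r.normal(size=(4, 3)), 2.0) for _ in range(n_teachers)]
        w = r.uniform(0.1, 1.0, n_teachers)
        out = combine_teachers(mats, w)
        np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-9)


class TestKDLoss:
    def test_matched_distributions_alpha_zero_gives_zero(self):
        logits = np.array([[1.0, -0.5], [0.2, 0.9]])
        cfg = DistillationConfig(temperature=2.0, alpha=0.0)
        teacher = soften(logits, 2.0)
        assert kd_loss(logits, np.array([0, 1]), teacher, cfg) <= 1e-8

    def test_alpha_one_is_weighted_cross_entropy(self, rng):
        logits = rng.normal(size=(6, 2))
        labels = rng.integers(0, 2, 6)
        cfg = DistillationConfig(alpha=1.0, class_weights=np.array([2.0, 0.5]))
        got = kd_loss(logits, labels, None, cfg)
        expected = brute_force_kd_loss(logits.tolist(), labels.tolist(), None, cfg)
        assert got == pytest.approx(expected, rel=1e-12)

    @given(st.integers(0, 2**31 - 1), st.floats(0.0, 1.0), st.floats(0.5, 5.0))
    @settings(max_examples=40, deadline=None)
    def test_matches_brute_force_oracle(self, seed, alpha, temperature):
        r = np.random.default_rng(seed)
        n, k = 5, 3
        logits = r.normal(size=(n, k)) * 3
        labels = r.integers(0, k, n)
        teacher = soften(r.normal(size=(n, k)), temperature)
        cfg = DistillationConfig(
            temperature=temperature,
            alpha=alpha,
            class_weights=r.uniform(0.5, 2.0, k),
            node_weight=float(r.uniform(0.5, 2.0)),
            sample_weights=r.uniform(0.5, 2.0, n),
        )
        got = kd_loss(logits, labels, teacher, cfg)
        expected = brute_force_kd_loss(logits.tolist(), labels.tolist(), teacher.tolist(), cfg)
        assert got >= 0
        assert got == pytest.approx(expected, rel=1e-8)

    def test_continuous_in_alpha(self, rng):
        logits = rng.normal(size=(4, 2))
        labels = rng.integers(0, 2, 4)
        teacher = soften(rng.normal(size=(4, 2)), 2.0)
        values = [
            kd_loss(logits, labels, teacher, DistillationConfig(alpha=a))
            for a in np.linspace(0, 1, 21)
        ]
        deltas = np.abs(np.diff(values))
        assert deltas.max() < 1.0  # no jumps on a fine alpha grid

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            kd_loss(np.empty((0, 2)), np.empty(0, dtype=int), None, DistillationConfig(alpha=1.0))

    def test_gradient_matches_finite_differences(self, rng):
        logits = rng.normal(size=(3, 2))
        labels = np.array([0, 1, 0])
        teacher = soften(rng.normal(size=(3, 2)), 2.0)
        cfg = DistillationConfig(temperature=2.0, alpha=0.3)
        grad = kd_loss_grad(logits, labels, teacher, cfg)
        eps = 1e-6
        for i in range(3):
            for j in range(2):
                up, down = logits.copy(), logits.copy()
                up[i, j] += eps
                down[i, j] -= eps
                fd = (
                    kd_loss(up, labels, teacher, cfg) - kd_loss(down, labels, teacher, cfg)
                ) / (2 * eps)
                assert grad[i, j] == pytest.approx(fd, abs=1e-6)

    def test_temperature_squared_keeps_gradient_scale(self, rng):
        # finite-difference KL-term gradients at T ∈ {1,2,5} agree in scale
        logits = rng.normal(size=(8, 2))
        labels = rng.integers(0, 2, 8)
        teacher_logits = rng.normal(size=(8, 2))
        norms = []
        for t in (1.0, 2.0, 5.0):
            cfg = DistillationConfig(temperature=t, alpha=0.0)
            g = kd_loss_grad(logits, labels, soften(teacher_logits, t), cfg)
            norms.append(np.linalg.norm(g))
        assert max(norms) / min(norms) < 3.0


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"temperature": 0.0},
            {"temperature": -1.0},
            {"alpha": 1.5},
            {"alpha": -0.1},
            {"node_weight": 0.0},
            {"teacher_weights": np.array([-0.2, 1.2])},
            {"class_weights": np.array([0.0, 1.0])},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            DistillationConfig(**kwargs)

    def test_teacher_weights_normalized(self):
        cfg = DistillationConfig(teacher_weights=np.array([1.0, 3.0]))
        np.testing.assert_allclose(cfg.teacher_weights, [0.25, 0.75])

    def test_dict_roundtrip(self):
        cfg = DistillationConfig(
            temperature=3.0, alpha=0.2, teacher_weights=np.array([0.5, 0.5])
        )
        back = DistillationConfig.from_dict(cfg.to_dict())
        assert back.temperature == cfg.temperature
        np.testing.assert_allclose(back.teacher_weights, cfg.teacher_weights)


class TestEnsemble:
    def test_single_model_identity(self, rng):
        model = SoftmaxRegression(2, 2, seed=1)
        x = rng.normal(size=(4, 2))
        np.testing.assert_allclose(ensemble_predict([model], x), model.predict_proba(x))

    def test_mean_of_three_members(self, rng):
        models = [SoftmaxRegression(2, 2, seed=s) for s in (1, 2, 3)]
        x = rng.normal(size=(5, 2))
        expected = sum(m.predict_proba(x) for m in models) / 3
        np.testing.assert_allclose(ensemble_predict(models, x), expected)
        np.testing.assert_allclose(ensemble_predict(models, x).sum(axis=1), 1.0, atol=1e-9)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            ensemble_predict([], np.zeros((1, 2)))
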