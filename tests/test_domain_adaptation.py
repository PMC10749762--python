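import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from microgda.domain_adaptation import (
    DANConfig,
    DANModel,
    DomainPair,
    _mmd_and_grad,
    extract_latent,
    mk_mmd,
    train_classifier,
    train_dan,
)


@pytest.fixture(scope="module")
def gaussian_pair():
    rng = np.random.default_rng(7)
    a = rng.normal(size=(200, 5))
    b = rng.normal(size=(200, 5))
    shifted = rng.normal(loc=3.0, size=(200, 5))
    return a, b, shifted


def _permutation_null(a, b, n_perm=200, seed=0):
    rng = np.random.default_rng(seed)
    pooled = np.vstack([a, b])
    n = a.shape[0]
    null = []
    for _ in range(n_perm):
        idx = rng.permutation(pooled.shape[0])
        null.append(mk_mmd(pooled[idx[:n]], pooled[idx[n:]]))
    return np.array(null)


class TestMkMmd:
    def test_identical_inputs_give_zero(self):
        a = np.random.default_rng(0).normal(size=(30, 4))
        assert mk_mmd(a, a) <= 1e-9

    def test_symmetry_and_permutation_invariance(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=(12, 3)), rng.normal(size=(9, 3))
        assert mk_mmd(a, b) == mk_mmd(b, a)
        perm = rng.permutation(12)
        assert mk_mmd(a[perm], b) == pytest.approx(mk_mmd(a, b), abs=1e-12)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        a=arrays(
            np.float64,
            st.tuples(st.integers(2, 8), st.just(3)),
            elements=st.floats(-10, 10, allow_nan=False),
        ),
        b=arrays(
            np.float64,
            st.tuples(st.integers(2, 8), st.just(3)),
            elements=st.floats(-10, 10, allow_nan=False),
        ),
    )
    def test_nonnegative_and_symmetric_for_arbitrary_inputs(self, a, b):
        v = mk_mmd(a, b)
        assert v >= 0.0
        assert v == mk_mmd(b, a)

    def test_invalid_inputs_rejected(self):
        a = np.zeros((3, 2))
        with pytest.raises(ValueError):
            mk_mmd(a, np.zeros((3, 5)))
        with pytest.raises(ValueError):
            mk_mmd(a, np.zeros((0, 2)))

    def test_same_distribution_below_null_quantile(self, gaussian_pair):
        a, b, _ = gaussian_pair
        null = _permutation_null(a, b, seed=3)
        assert mk_mmd(a, b) < np.quantile(null, 0.95)

    def test_shifted_distribution_above_null_quantile(self, gaussian_pair):
        a, _, shifted = gaussian_pair
        null = _permutation_null(a, shifted, seed=4)
        assert mk_mmd(a, shifted) > np.quantile(null, 0.99)

    def test_gradient_matches_finite_differences(self):
        # fixed bandwidth so the analytic gradient is exact
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=(6, 3)), rng.normal(0.4, 1.0, size=(5, 3))
        mult = (0.5, 1.0, 2.0)
        _, ga, gb = _mmd_and_grad(a, b, mult, base_bandwidth=1.5)
        eps = 1e-6
        for target, grad in ((a, ga), (b, gb)):
            num = np.zeros_like(target)
            for i in range(target.shape[0]):
                for j in range(target.shape[1]):
                    up, dn = target.copy(), target.copy()
                    up[i, j] += eps
                    dn[i, j] -= eps
                    args_up = (up, b) if target is a else (a, up)
                    args_dn = (dn, b) if target is a else (a, dn)
                    vu = _mmd_and_grad(*args_up, mult, base_bandwidth=1.5)[0]
                    vd = _mmd_and_grad(*args_dn, mult, base_bandwidth=1.5)[0]
                    num[i, j] = (vu - vd) / (2 * eps)
            np.testing.assert_allclose(num, grad, atol=1e-7)


def _toy_pair(seed=0, n=40, shift=0.0):
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    x = rng.normal(size=(n, 6)) + y[:, None] * 2.0
    xt = rng.normal(size=(n, 6)) + rng.integers(0, 2, n)[:, None] * 2.0 + shift
    return DomainPair(x, y, xt), x, y, xt


SMALL = DANConfig(layer_sizes=(16, 8, 4), epochs=60, seed=3)


class TestTrainDan:
    def test_lambda_zero_equals_plain_classifier_bitwise(self):
        pair, x, y, _ = _toy_pair()
        cfg = dataclasses.replace(SMALL, lambda_penalty=0.0)
        dan = train_dan(pair, cfg)
        plain = train_classifier(x, y, cfg)
        for w1, w2 in zip(dan.weights, plain.weights):
            np.testing.assert_array_equal(w1, w2)
        for b1, b2 in zip(dan.biases, plain.biases):
            np.testing.assert_array_equal(b1, b2)

    def test_lambda_zero_ignores_target_data(self):
        pair1, x, y, _ = _toy_pair(seed=1)
        cfg = dataclasses.replace(SMALL, lambda_penalty=0.0)
        other_target = np.random.default_rng(99).normal(5.0, 2.0, size=(25, 6))
        pair2 = DomainPair(x, y, other_target)
        m1, m2 = train_dan(pair1, cfg), train_dan(pair2, cfg)
        for w1, w2 in zip(m1.weights, m2.weights):
            np.testing.assert_array_equal(w1, w2)

    def test_separable_source_reaches_perfect_accuracy(self):
        pair, x, y, _ = _toy_pair(seed=2)
        cfg = dataclasses.replace(SMALL, epochs=300, weight_decay=0.0)
        model = train_dan(pair, cfg)
        pred = model.logits(x).argmax(axis=1)
        assert np.mean(pred == y) == 1.0

    def test_adaptation_reduces_latent_discrepancy(self):
        pair, x, y, xt = _toy_pair(seed=4, shift=3.0)
        cfg = dataclasses.replace(SMALL, epochs=200, lambda_penalty=1.0)
        model = train_dan(pair, cfg)
        raw = mk_mmd(x, xt)
        latent = mk_mmd(extract_latent(model, x), extract_latent(model, xt))
        assert latent < raw

    def test_seeded_retraining_is_identical(self):
        pair, *_ = _toy_pair(seed=5)
        m1, m2 = train_dan(pair, SMALL), train_dan(pair, SMALL)
        for w1, w2 in zip(m1.weights, m2.weights):
            np.testing.assert_array_equal(w1, w2)

    def test_training_log_records_both_components(self):
        pair, *_ = _toy_pair(seed=6)
        model = train_dan(pair, SMALL)
        assert len(model.training_log) == SMALL.epochs
        assert {"classification_loss", "mmd"} <= set(model.training_log[0])
        assert all(e["mmd"] >= 0.0 for e in model.training_log)

    def test_single_class_source_rejected(self):
        x = np.zeros((10, 3))
        with pytest.raises(ValueError):
            DomainPair(x, np.zeros(10, dtype=int), x)
        with pytest.raises(ValueError):
            train_classifier(x, np.ones(10, dtype=int), SMALL)

    def test_checkpoint_round_trip(self, tmp_path):
        pair, x, *_ = _toy_pair(seed=7)
        model = train_dan(pair, SMALL)
        path = tmp_path / "dan.npz"
        model.save(path)
        back = DANModel.load(path, SMALL)
        np.testing.assert_array_equal(back.logits(x), model.logits(x))


class TestExtractLatent:
    def _manual_model(self, weights, biases, n_hidden_sizes):
        cfg = DANConfig(layer_sizes=n_hidden_sizes, epochs=1)
        return DANModel(weights=weights, biases=biases, config=cfg)

    def test_zero_weights_give_zero_latent(self):
        m = self._manual_model(
            [np.zeros((3, 2)), np.zeros((2, 2))], [np.zeros(2), np.zeros(2)], (2,)
        )
        np.testing.assert_array_equal(
            extract_latent(m, np.ones((4, 3)), 1), np.zeros((4, 2))
        )

    def test_hand_computed_single_unit(self):
        # w = [[1], [-1]], b = [0], x = (2, 3): ReLU(2 - 3) = 0
        m = self._manual_model(
            [np.array([[1.0], [-1.0]]), np.zeros((1, 2))],
            [np.zeros(1), np.zeros(2)],
            (1,),
        )
        np.testing.assert_array_equal(
            extract_latent(m, np.array([[2.0, 3.0]]), 1), [[0.0]]
        )

    def test_identity_weights_pass_nonnegative_input_through(self):
        m = self._manual_model(
            [np.eye(3), np.zeros((3, 2))], [np.zeros(3), np.zeros(2)], (3,)
        )
        x = np.abs(np.random.default_rng(0).normal(size=(5, 3)))
        np.testing.assert_array_equal(extract_latent(m, x, 1), x)

    def test_latent_is_nonnegative_and_pure(self):
        pair, x, *_ = _toy_pair(seed=8)
        model = train_dan(pair, SMALL)
        h1 = extract_latent(model, x, 2)
        h2 = extract_latent(model, x, 2)
        assert (h1 >= 0).all()
        np.testing.assert_array_equal(h1, h2)

    def test_invalid_layer_rejected(self):
        pair, x, *_ = _toy_pair(seed=9)
        model = train_dan(pair, SMALL)
        with pytest.raises(ValueError):
            extract_latent(model, x, 4)
        with pytest.raises(ValueError):
            extract_latent(model, x[:, :3], 1)
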