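import numpy as np
import pytest

from harpipe.classifier import (
    TrainConfig,
    _loss_and_grads,
    forward,
    init_network,
    predict,
    train,
)


def _toy_separable(rng, n_per_class=10, dim=6):
    X = np.vstack(
        [rng.normal(-2, 0.5, size=(n_per_class, dim)),
         rng.normal(2, 0.5, size=(n_per_class, dim))]
    )
    y = np.repeat([0, 1], n_per_class)
    return X, y


class TestInit:
    def test_identical_seed_gives_identical_parameters(self):
        a = init_network(10, 3, seed=5)
        b = init_network(10, 3, seed=5)
        np.testing.assert_array_equal(a.lego_filters, b.lego_filters)
        for ma, mb in zip(a.masks, b.masks):
            np.testing.assert_array_equal(ma, mb)

    def test_single_lego_filter_degenerate_sharing(self):
        m = init_network(8, 2, n_lego=1)
        for mask in m.masks:
            assert not mask.any()  # every slot selects filter 0

    def test_round_robin_assignment_is_balanced(self):
        m = init_network(24, 3, n_lego=5, fragment_dim=4)
        for mask in m.masks:
            _, counts = np.unique(mask, return_counts=True)
            assert counts.max() - counts.min() <= 1

    def test_parameter_count_independent_of_fragment_count(self):
        small = init_network(8, 2, n_lego=4, fragment_dim=4, kernel_len=3)
        large = init_network(80, 2, n_lego=4, fragment_dim=4, kernel_len=3)
        assert small.n_conv_params == large.n_conv_params == 4 * 4 * 3

    def test_input_smaller_than_fragment_rejected(self):
        with pytest.raises(ValueError, match="fragment_dim"):
            init_network(2, 2, fragment_dim=4)


class TestForward:
    def test_zero_head_yields_uniform_probabilities(self, rng):
        m = init_network(12, 5, seed=0)
        p = forward(m, rng.standard_normal((7, 12))).probabilities
        np.testing.assert_allclose(p, 0.2, atol=1e-12)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)

    def test_duplicated_sample_gives_duplicated_rows(self, rng):
        m = init_network(12, 3, seed=1)
        m.head_weights = rng.standard_normal(m.head_weights.shape)
        x = rng.standard_normal(12)
        p = forward(m, np.stack([x, x])).probabilities
        np.testing.assert_array_equal(p[0], p[1])

    def test_masked_sum_matches_hand_computation(self):
        # input_dim 4, fragment_dim 2, kernel_len 1, n_lego = n_fragments = 2
        m = init_network(
            4, 2, n_lego=2, fragment_dim=2, kernel_len=1, n_layers=1, seed=0
        )
        m.lego_filters = np.array([[[1.0], [2.0]], [[3.0], [4.0]]])  # (2, 2, 1)
        x = np.array([[1.0, 2.0, 3.0, 4.0]])  # fragments (1,2) and (3,4)
        # masks: slot 0 -> filters (0, 1), slot 1 -> filters (0, 1)
        np.testing.assert_array_equal(m.masks[0], [[0, 1], [0, 1]])
        logits, caches = (lambda r: (r[0], r[1]))(
            __import__("harpipe.classifier", fromlist=["_forward_cached"])
            ._forward_cached(m, x)
        )
        # gamma_0 = frag1 . eps0 + frag2 . eps1 = (1+4) + (9+16) = 30
        # gamma_1 identical by construction of the masks
        (pooled,) = caches[-1]
        np.testing.assert_allclose(pooled, [[30.0, 30.0]])


class TestTrain:
    def test_zero_learning_rate_freezes_parameters(self, rng):
        X, y = _toy_separable(rng)
        m = init_network(6, 2, seed=0)
        before = m.lego_filters.copy()
        train(m, X, y, TrainConfig(learning_rate=0.0, epochs=5, seed=0))
        np.testing.assert_array_equal(m.lego_filters, before)
        tr = m.loss_trace["train"]
        np.testing.assert_allclose(tr, tr[0])

    def test_separable_toy_set_reaches_full_train_accuracy(self, rng):
        # logistic-regression oracle certifies separability of this set
        from sklearn.linear_model import LogisticRegression

        X, y = _toy_separable(rng)
        assert LogisticRegression().fit(X, y).score(X, y) == 1.0
        m = init_network(6, 2, seed=0)
        train(m, X, y, TrainConfig(learning_rate=0.05, epochs=200, batch_size=20, seed=0))
        assert (predict(m, X).labels == y).mean() == 1.0

    def test_loss_trace_settles_monotone(self, rng):
        X, y = _toy_separable(rng)
        m = init_network(6, 2, seed=0)
        train(m, X, y, TrainConfig(learning_rate=0.01, epochs=100, batch_size=20, seed=0))
        upticks = int((np.diff(m.loss_trace["train"][5:]) > 1e-12).sum())
        assert upticks <= 3

    def test_gradients_match_central_differences(self, rng):
        m = init_network(7, 3, n_lego=2, fragment_dim=2, kernel_len=2, n_layers=2, seed=1)
        m.head_weights = rng.standard_normal(m.head_weights.shape)
        m.head_bias = rng.standard_normal(m.head_bias.shape)
        X = rng.standard_normal((5, 7))
        y = np.array([0, 1, 2, 0, 1])
        _, grads = _loss_and_grads(m, X, y)
        eps = 1e-6
        for name in ("lego_filters", "head_weights", "head_bias"):
            arr = getattr(m, name)
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                i = it.multi_index
                old = arr[i]
                arr[i] = old + eps
                lp, _ = _loss_and_grads(m, X, y)
                arr[i] = old - eps
                lm, _ = _loss_and_grads(m, X, y)
                arr[i] = old
                num = (lp - lm) / (2 * eps)
                assert grads[name][i] == pytest.approx(num, rel=1e-5, abs=1e-8)

    def test_determinism_of_loss_traces(self, rng):
        X, y = _toy_separable(rng)
        cfg = TrainConfig(learning_rate=0.05, epochs=20, seed=3)
        m1 = train(init_network(6, 2, seed=3), X, y, cfg)
        m2 = train(init_network(6, 2, seed=3), X, y, cfg)
        np.testing.assert_array_equal(m1.loss_trace["train"], m2.loss_trace["train"])

    def test_single_class_labels_rejected(self):
        m = init_network(6, 2, seed=0)
        with pytest.raises(ValueError, match="two classes"):
            train(m, np.zeros((5, 6)), np.zeros(5, dtype=int))


class TestPredict:
    def test_argmax_and_smallest_id_tie_rule(self, rng):
        m = init_network(6, 2, seed=0)
        X, y = _toy_separable(rng)
        train(m, X, y, TrainConfig(epochs=5, seed=0))
        p = predict(m, X)
        np.testing.assert_array_equal(
            p.labels, p.class_ids[np.argmax(p.probabilities, axis=1)]
        )

    def test_unfitted_model_raises_state_error(self, rng):
        m = init_network(6, 2, seed=0)
        with pytest.raises(RuntimeError, match="not fitted"):
            predict(m, rng.standard_normal((2, 6)))

    def test_confusion_accounting_identity(self, rng):
        from harpipe.metrics import confusion_counts

        X, y = _toy_separable(rng)
        m = train(init_network(6, 2, seed=0), X, y, TrainConfig(epochs=30, seed=0))
        pred = predict(m, X).labels
        for cc in confusion_counts(y, pred).values():
            assert cc.n == len(y)
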