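"""Sparse-autoencoder math: closed forms, gradients, training behavior."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from cardiossae import sae
from cardiossae.sae import (
    SAEHyper,
    SAELayer,
    attach_and_finetune,
    classify,
    classify_batch,
    encode,
    greedy_pretrain,
    kl_penalty,
    layer_gradients,
    mean_activation,
    reconstruction_loss,
    train_layer,
)


def make_layer(d_in, d_hidden, hyper=None, seed=0):
    rng = np.random.default_rng(seed)
    return SAELayer(
        W_enc=rng.normal(size=(d_hidden, d_in)),
        b_enc=rng.normal(size=d_hidden),
        W_dec=rng.normal(size=(d_in, d_hidden)),
        b_dec=rng.normal(size=d_in),
        hyper=hyper or SAEHyper(),
    )


def zero_layer(d_in, d_hidden, hyper=None):
    return SAELayer(
        np.zeros((d_hidden, d_in)),
        np.zeros(d_hidden),
        np.zeros((d_in, d_hidden)),
        np.zeros(d_in),
        hyper or SAEHyper(),
    )


class TestEncode:
    def test_zero_weights_give_half(self):
        lay = zero_layer(4, 3)
        H = encode(lay, np.random.default_rng(0).random((5, 4)))
        np.testing.assert_array_equal(H, np.full((5, 3), 0.5))

    def test_single_unit_at_zero_input(self):
        lay = SAELayer(np.array([[1.0]]), np.zeros(1), np.array([[1.0]]), np.zeros(1))
        assert encode(lay, np.array([[0.0]]))[0, 0] == 0.5

    def test_matches_hand_coded_oracle(self):
        lay = make_layer(4, 3, seed=2)
        X = np.random.default_rng(3).random((5, 4))
        oracle = 1.0 / (1.0 + np.exp(-(X @ lay.W_enc.T + lay.b_enc)))
        np.testing.assert_allclose(encode(lay, X), oracle, atol=1e-12)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(sae.DimensionMismatchError):
            encode(make_layer(4, 3), np.ones((2, 5)))


class TestReconstructionLoss:
    def test_zero_weights_zero_input_closed_form(self):
        # decoded output is logistic(0)=0.5 per entry -> loss = d_in * 0.125
        d_in = 6
        lay = zero_layer(d_in, 3, SAEHyper(lambda_decay=0.7))
        X = np.zeros((4, d_in))
        assert reconstruction_loss(lay, X) == pytest.approx(d_in * 0.125, abs=1e-12)

    def test_perfect_reconstruction_zero_loss(self):
        # inject an identity reconstruction by evaluating the data term alone
        lay = make_layer(3, 2, SAEHyper(lambda_decay=0.0), seed=1)
        X = expit(np.random.default_rng(0).normal(size=(4, 3)))
        Y = sae.decode(lay, encode(lay, X))
        manual = np.sum((X - Y) ** 2) / (2 * 4)
        assert reconstruction_loss(lay, X) == pytest.approx(manual, rel=1e-12)

    def test_linear_in_lambda(self):
        X = np.random.default_rng(4).random((5, 4))
        l1 = make_layer(4, 3, SAEHyper(lambda_decay=0.3), seed=6)
        l2 = SAELayer(l1.W_enc, l1.b_enc, l1.W_dec, l1.b_dec, SAEHyper(lambda_decay=0.6))
        w2 = np.sum(l1.W_enc**2) + np.sum(l1.W_dec**2)
        assert reconstruction_loss(l2, X) - reconstruction_loss(l1, X) == pytest.approx(
            0.15 * w2, rel=1e-10
        )

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            reconstruction_loss(make_layer(3, 2), np.zeros((0, 3)))


class TestMeanActivation:
    def test_single_sample_equals_activation(self):
        lay = make_layer(4, 3, seed=5)
        x = np.random.default_rng(6).random((1, 4))
        np.testing.assert_allclose(mean_activation(lay, x), encode(lay, x)[0], atol=1e-15)

    def test_zero_layer_gives_half(self):
        np.testing.assert_array_equal(
            mean_activation(zero_layer(4, 3), np.ones((7, 4))), np.full(3, 0.5)
        )

    def test_matches_arithmetic_mean_oracle(self):
        lay = make_layer(5, 4, seed=7)
        X = np.random.default_rng(8).random((9, 5))
        H = encode(lay, X)
        np.testing.assert_allclose(mean_activation(lay, X), H.sum(axis=0) / 9, atol=1e-12)


class TestKLPenalty:
    def test_zero_at_target(self):
        assert kl_penalty(0.3, np.full(5, 0.3)) == pytest.approx(0.0, abs=1e-12)

    def test_reference_value(self):
        # 0.5 ln(0.5/0.25) + 0.5 ln(0.5/0.75), evaluated independently
        expected = 0.5 * np.log(2.0) + 0.5 * np.log(2.0 / 3.0)
        assert kl_penalty(0.5, np.array([0.25])) == pytest.approx(expected, abs=1e-12)
        assert kl_penalty(0.5, np.array([0.25])) == pytest.approx(0.14384, abs=1e-5)

    def test_convex_in_rho_hat(self):
        lo, hi, rho = 0.1, 0.4, 0.2
        mid = kl_penalty(rho, np.array([(lo + hi) / 2]))
        avg = 0.5 * (kl_penalty(rho, np.array([lo])) + kl_penalty(rho, np.array([hi])))
        assert mid < avg

    def test_rho_out_of_range_rejected(self):
        for bad in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                kl_penalty(bad, np.array([0.5]))

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        rho=st.floats(0.01, 0.99),
        rho_hat=st.lists(st.floats(1e-6, 1 - 1e-6), min_size=1, max_size=8),
    )
    def test_nonnegative_everywhere(self, rho, rho_hat):
        assert kl_penalty(rho, np.array(rho_hat)) >= 0.0


class TestGradients:
    @pytest.mark.parametrize("seed", range(6))
    def test_finite_difference_agreement(self, seed):
        rng = np.random.default_rng(seed)
        hyp = SAEHyper(
            lambda_decay=float(rng.uniform(0, 1e-2)),
            beta_sparsity=float(rng.uniform(0, 4)),
            rho_target=float(rng.uniform(0.02, 0.3)),
        )
        lay = sae._init_layer(6, 4, hyp, seed=seed)
        X = rng.random((5, 6))
        g = layer_gradients(lay, X)
        ana = np.concatenate([g["W_enc"].ravel(), g["b_enc"], g["W_dec"].ravel(), g["b_dec"]])
        theta = sae._pack(lay)
        num = np.empty_like(theta)
        h = 1e-5
        for i in range(len(theta)):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += h
            tm[i] -= h
            num[i] = (
                sae.sae_objective(sae._unpack(tp, 6, 4, hyp), X)
                - sae.sae_objective(sae._unpack(tm, 6, 4, hyp), X)
            ) / (2 * h)
        denom = np.maximum(np.abs(ana) + np.abs(num), 1e-8)
        assert np.max(np.abs(ana - num) / denom) <= 1e-6

    def test_decay_gradient_is_lambda_w(self):
        hyp = SAEHyper(lambda_decay=0.5, beta_sparsity=0.0)
        lay = make_layer(4, 3, hyp, seed=9)
        g = layer_gradients(lay, np.random.default_rng(1).random((6, 4)))
        hyp0 = SAEHyper(lambda_decay=0.0, beta_sparsity=0.0)
        lay0 = SAELayer(lay.W_enc, lay.b_enc, lay.W_dec, lay.b_dec, hyp0)
        g0 = layer_gradients(lay0, np.random.default_rng(1).random((6, 4)))
        np.testing.assert_allclose(g["W_enc"] - g0["W_enc"], 0.5 * lay.W_enc, atol=1e-12)
        np.testing.assert_allclose(g["W_dec"] - g0["W_dec"], 0.5 * lay.W_dec, atol=1e-12)


class TestTrainLayer:
    def test_max_iter_zero_returns_init(self):
        X = np.random.default_rng(0).random((20, 8))
        hyp = SAEHyper(max_iter=0, seed=3)
        lay, rep = train_layer(X, 4, hyp)
        ref = sae._init_layer(8, 4, hyp)
        np.testing.assert_array_equal(lay.W_enc, ref.W_enc)
        assert rep.objectives == [] and rep.iterations == 0

    def test_deterministic(self):
        X = np.random.default_rng(1).random((30, 8))
        hyp = SAEHyper(max_iter=50, seed=4)
        l1, _ = train_layer(X, 5, hyp)
        l2, _ = train_layer(X, 5, hyp)
        np.testing.assert_array_equal(l1.W_enc, l2.W_enc)
        np.testing.assert_array_equal(l1.W_dec, l2.W_dec)

    def test_objective_decreases_and_sparsity_targets(self):
        # 200 noiseless normal beats; strong sparsity pressure drives the
        # mean activation to the target
        from cardiossae import synthgen

        X = np.vstack([synthgen.gen_beat("N", jitter=0.0) for _ in range(200)])
        X = X + 0.001 * np.random.default_rng(0).standard_normal(X.shape)
        X = (X - X.min()) / (X.max() - X.min())
        hyp = SAEHyper(lambda_decay=1e-4, beta_sparsity=3.0, rho_target=0.05, max_iter=150, seed=1)
        lay, rep = train_layer(X, 10, hyp)
        init = sae._init_layer(X.shape[1], 10, hyp)
        assert rep.final_objective < sae.sae_objective(init, X)
        rho_hat = mean_activation(lay, X)
        assert np.all(np.abs(rho_hat.mean() - 0.05) <= 0.05)

    def test_accepted_iterates_non_increasing(self):
        X = np.random.default_rng(5).random((40, 10))
        _, rep = train_layer(X, 6, SAEHyper(max_iter=80, seed=2))
        assert all(b <= a + 1e-10 for a, b in zip(rep.objectives, rep.objectives[1:]))


class TestGreedyPretrain:
    def test_single_layer_degenerates_to_train_layer(self):
        X = np.random.default_rng(2).random((25, 8))
        hyp = SAEHyper(max_iter=30, seed=6)
        stack = greedy_pretrain(X, (4,), hyp)
        lay, _ = train_layer(X, 4, hyp, seed=[hyp.seed, 0])
        np.testing.assert_array_equal(stack.layers[0].W_enc, lay.W_enc)

    def test_feature_dims_chain(self):
        X = np.random.default_rng(3).random((30, 40))
        stack = greedy_pretrain(X, (16, 8, 4), SAEHyper(max_iter=5, seed=1))
        assert [l.d_hidden for l in stack.layers] == [16, 8, 4]
        assert sae.features(stack, X).shape == (30, 4)

    def test_nondecreasing_dims_warn(self):
        X = np.random.default_rng(4).random((10, 5))
        with pytest.warns(UserWarning, match="not strictly decreasing"):
            greedy_pretrain(X, (4, 6), SAEHyper(max_iter=2, seed=1))

    def test_sample_order_invariance(self):
        X = np.random.default_rng(5).random((30, 10))
        hyp = SAEHyper(max_iter=40, seed=8)
        s1 = greedy_pretrain(X, (5,), hyp)
        perm = np.random.default_rng(9).permutation(30)
        s2 = greedy_pretrain(X[perm], (5,), hyp)
        np.testing.assert_allclose(s1.layers[0].W_enc, s2.layers[0].W_enc, atol=1e-7)


class TestHeadAndClassify:
    def test_zero_head_uniform_probabilities(self, tiny_trained_stack):
        import copy

        stack = copy.deepcopy(tiny_trained_stack)
        stack.softmax_W = np.zeros_like(stack.softmax_W)
        stack.softmax_b = np.zeros_like(stack.softmax_b)
        label, P = classify(stack, np.random.default_rng(0).random(stack.d_in))
        np.testing.assert_allclose(P, np.full(6, 1 / 6), atol=1e-12)
        assert label == stack.class_names[0]  # lowest-index tie-break

    def test_probabilities_sum_to_one(self, tiny_trained_stack):
        X = np.random.default_rng(1).random((20, tiny_trained_stack.d_in))
        _, P = classify_batch(tiny_trained_stack, X)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(P >= 0)

    def test_matches_hand_coded_forward_oracle(self, tiny_trained_stack):
        x = np.random.default_rng(2).random(tiny_trained_stack.d_in)
        h = x
        for lay in tiny_trained_stack.layers:
            h = 1.0 / (1.0 + np.exp(-(lay.W_enc @ h + lay.b_enc)))
        z = tiny_trained_stack.softmax_W @ h + tiny_trained_stack.softmax_b
        p = np.exp(z) / np.exp(z).sum()
        _, P = classify(tiny_trained_stack, x)
        np.testing.assert_allclose(P, p, atol=1e-12)

    def test_single_class_labels_rejected(self, small_beat_batch):
        X, _ = small_beat_batch
        stack = greedy_pretrain(X[:10], (6,), SAEHyper(max_iter=2, seed=1))
        with pytest.raises(ValueError, match="2 classes"):
            attach_and_finetune(stack, X[:10], ["N"] * 10)

    def test_finetune_improves_or_preserves_train_accuracy(self, small_beat_batch):
        from cardiossae.pipelines import train_beat_classifier

        X, y = small_beat_batch
        _, info = train_beat_classifier(X, y, SAEHyper(max_iter=60, seed=2), (16, 8))
        assert info["finetuned_train_accuracy"] >= info["head_only_train_accuracy"]

    def test_untrained_head_rejected(self, small_beat_batch):
        X, _ = small_beat_batch
        stack = greedy_pretrain(X[:10], (6,), SAEHyper(max_iter=2, seed=1))
        with pytest.raises(sae.SAEError):
            classify(stack, X[0])

    def test_wrong_input_length_rejected(self, tiny_trained_stack):
        with pytest.raises(sae.DimensionMismatchError):
            classify(tiny_trained_stack, np.zeros(7))


class TestSerialization:
    def test_round_trip_bit_exact(self, tiny_trained_stack, tmp_path):
        path = tmp_path / "stack.npz"
        sae.save_stack(tiny_trained_stack, path)
        loaded = sae.load_stack(path)
        assert loaded.class_names == tiny_trained_stack.class_names
        for a, b in zip(tiny_trained_stack.layers, loaded.layers):
            np.testing.assert_array_equal(a.W_enc, b.W_enc)
            np.testing.assert_array_equal(a.W_dec, b.W_dec)
            assert a.hyper == b.hyper
        np.testing.assert_array_equal(tiny_trained_stack.softmax_W, loaded.softmax_W)
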