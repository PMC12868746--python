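"""Attention layers, LSTM/FC heads, generators, discriminator, gradients."""

import numpy as np
import pytest

from topoeeg import (Discriminator, GATLayer, GatOnlyGenerator, Generator,
                     LstmOnlyGenerator, pi_to_graph)
from topoeeg.io import load_checkpoint, save_checkpoint
from topoeeg.pigat_gan import bce_grad_logits, bce_loss, sigmoid


def seg_sums(alpha, graph):
    return np.add.reduceat(alpha, graph.seg_ptr[:-1], axis=-1)


class TestAttention:
    def test_isolated_node_attends_to_itself(self):
        g = pi_to_graph(np.array([[0.3]]))
        layer = GATLayer(1, 4, n_heads=2, rng=np.random.default_rng(0))
        alpha = layer.attention(g, g.node_features[None])
        assert np.allclose(alpha, 1.0)

    def test_identical_neighbors_share_attention_equally(self):
        g = pi_to_graph(np.full((1, 2), 0.8))  # two mutually adjacent nodes
        layer = GATLayer(1, 4, n_heads=3, rng=np.random.default_rng(1))
        alpha = layer.attention(g, g.node_features[None])
        assert np.allclose(alpha, 0.5)

    @pytest.mark.parametrize("heads,f_out", [(8, 8), (1, 1), (4, 2)])
    def test_coefficients_sum_to_one(self, heads, f_out, rng):
        g = pi_to_graph(rng.random((6, 5)))
        layer = GATLayer(1, f_out, n_heads=heads, rng=rng)
        alpha = layer.attention(g, rng.random((2, 30, 1)))
        assert np.abs(seg_sums(alpha, g) - 1.0).max() < 1e-6

    def test_sums_hold_after_forward_in_both_layers(self, rng):
        gen = Generator(6, seed=4)
        x = rng.random((2, 6, 6))
        gen.forward(x)
        for layer in (gen.gat1, gen.gat2):
            alpha = layer._cache[4]
            assert np.abs(seg_sums(alpha, gen.graph) - 1.0).max() < 1e-6


class TestGatForward:
    def test_identity_fixed_point_on_single_node(self):
        g = pi_to_graph(np.array([[0.37]]))
        layer = GATLayer(1, 1, n_heads=1, activation="linear",
                         rng=np.random.default_rng(0))
        layer.params["W"][...] = 1.0
        out = layer.forward(g, g.node_features[None])
        assert out[0, 0, 0] == pytest.approx(0.37)

    def test_matches_per_node_oracle(self, rng):
        """Head-averaged aggregation equals an explicit per-node loop."""
        img = rng.random((3, 3))
        g = pi_to_graph(img)
        layer = GATLayer(1, 2, n_heads=4, rng=rng)
        h = img.reshape(-1, 1)
        out = layer.forward(g, h[None])[0]

        W = layer.params["W"]
        a_src, a_dst = layer.params["a_src"], layer.params["a_dst"]
        nbrs = {i: [int(s) for s, d in zip(g.src, g.dst) if d == i]
                for i in range(9)}
        expected = np.zeros((9, 2))
        for i in range(9):
            acc = np.zeros(2)
            for k in range(4):
                z = {j: W[k].T @ h[j] for j in nbrs[i]}
                e = {j: float(a_src[k] @ z[j] + a_dst[k] @ z[i])
                     for j in nbrs[i]}
                l = {j: v if v > 0 else 0.2 * v for j, v in e.items()}
                m = max(l.values())
                w = {j: np.exp(v - m) for j, v in l.items()}
                tot = sum(w.values())
                acc += sum((w[j] / tot) * z[j] for j in nbrs[i])
            pre = acc / 4
            expected[i] = np.where(pre > 0, pre, np.expm1(pre))
        assert np.allclose(out, expected)

    def test_grid_shape_preserved_through_both_layers(self, rng):
        gen = Generator(10, seed=0)
        x = rng.random((3, 10, 10))
        h = x.reshape(3, 100, 1)
        h1 = gen.gat1.forward(gen.graph, h)
        h2 = gen.gat2.forward(gen.graph, h1)
        assert h1.shape == (3, 100, 8)
        assert h2.shape == (3, 100, 1)


class TestGenerator:
    def test_output_in_unit_interval(self, rng):
        gen = Generator(8, seed=1)
        out = gen.forward(rng.random((4, 8, 8)))
        assert out.shape == (4, 8, 8)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_zero_head_gives_half_everywhere(self, rng):
        gen = Generator(6, seed=1)
        gen.fc.params["W"][...] = 0.0
        gen.fc.params["b"][...] = 0.0
        out = gen.forward(rng.random((2, 6, 6)))
        assert np.allclose(out, 0.5)

    def test_eval_mode_is_deterministic(self, rng):
        gen = Generator(8, dropout=0.6, seed=2)
        x = rng.random((2, 8, 8))
        assert np.array_equal(gen.forward(x), gen.forward(x))

    def test_training_dropout_perturbs_output(self, rng):
        gen = Generator(8, dropout=0.6, seed=2)
        x = rng.random((2, 8, 8))
        a = gen.forward(x, training=True, rng=np.random.default_rng(0))
        b = gen.forward(x, training=True, rng=np.random.default_rng(99))
        assert not np.array_equal(a, b)

    def test_shape_mismatch_rejected(self, rng):
        gen = Generator(8, seed=0)
        with pytest.raises(ValueError):
            gen.forward(rng.random((2, 9, 9)))


class TestDiscriminator:
    def test_zero_parameters_give_half(self):
        disc = Discriminator(4, seed=0)
        for p in disc.params.values():
            p[...] = 0.0
        out = disc.forward(np.random.default_rng(0).random((3, 4, 4)))
        assert np.allclose(out, 0.5)

    def test_output_strictly_monotone_in_final_logit(self):
        disc = Discriminator(2, hidden=2, seed=0)
        logits = np.linspace(-3, 3, 7)
        assert np.all(np.diff(sigmoid(logits)) > 0)

    def test_hand_computed_two_pixel_example(self):
        # two input pixels -> 1 hidden unit (ReLU) -> sigmoid output
        from topoeeg.pigat_gan import Dense
        x = np.array([0.2, 0.6])
        fc1 = Dense(2, 1)
        fc1.params["W"][...] = np.array([[1.0], [2.0]])
        fc1.params["b"][...] = 0.1
        fc2 = Dense(1, 1)
        fc2.params["W"][...] = 3.0
        fc2.params["b"][...] = -0.5
        z1 = fc1.forward(x[None])
        y = sigmoid(fc2.forward(np.maximum(z1, 0.0)))
        expected = 1.0 / (1.0 + np.exp(-(3.0 * (0.2 + 1.2 + 0.1) - 0.5)))
        assert y[0, 0] == pytest.approx(expected)


class TestAblationHeads:
    def test_all_variants_emit_valid_images(self, rng):
        x = rng.random((3, 8, 8))
        for cls in (Generator, GatOnlyGenerator, LstmOnlyGenerator):
            out = cls(8, seed=0).forward(x)
            assert out.shape == (3, 8, 8)
            assert out.min() >= 0.0 and out.max() <= 1.0

    def test_parameter_count_ordering(self):
        full = Generator(12, seed=0).n_params()
        gat_only = GatOnlyGenerator(12, seed=0).n_params()
        lstm_only = LstmOnlyGenerator(12, seed=0).n_params()
        assert gat_only < full
        assert lstm_only < full


class TestGradients:
    @pytest.mark.parametrize("cls", [Generator, GatOnlyGenerator,
                                     LstmOnlyGenerator])
    def test_backprop_matches_finite_differences(self, cls, rng):
        """BCE gradient vs centred differences on a tiny R=4 instance."""
        R = 4
        x = rng.random((3, R, R))
        t = rng.random((3, R, R))
        model = cls(R, seed=3)
        model.zero_grads()
        p = model.forward(x)
        model.backward(bce_grad_logits(p, t).reshape(3, -1))
        grads = {k: v.copy() for k, v in model.grads.items()}
        prng = np.random.default_rng(1)
        for key, param in model.params.items():
            flat = param.ravel()
            for _ in range(min(4, flat.size)):
                i = int(prng.integers(flat.size))
                h = 1e-5
                orig = flat[i]
                flat[i] = orig + h
                lp = bce_loss(model.forward(x), t)
                flat[i] = orig - h
                lm = bce_loss(model.forward(x), t)
                flat[i] = orig
                fd = (lp - lm) / (2 * h)
                an = grads[key].ravel()[i]
                # relative check with an absolute floor for ~0 gradients,
                # where the finite difference itself loses all precision
                assert abs(fd - an) <= 1e-4 * max(abs(fd) + abs(an), 1e-3), key

    def test_discriminator_input_gradient(self, rng):
        R = 4
        disc = Discriminator(R, hidden=3, seed=2)
        x = rng.random((2, R, R))
        labels = np.array([1.0, 0.0])
        p = disc.forward(x)
        disc.zero_grads()
        dx = disc.backward(bce_grad_logits(p, labels))
        i, j, k = 1, 2, 3
        h = 1e-6
        xp = x.copy(); xp[i, j, k] += h
        xm = x.copy(); xm[i, j, k] -= h
        fd = (bce_loss(disc.forward(xp), labels)
              - bce_loss(disc.forward(xm), labels)) / (2 * h)
        assert dx[i, j, k] == pytest.approx(fd, rel=1e-5, abs=1e-10)


class TestCheckpoints:
    def test_round_trip_reproduces_outputs(self, tmp_path, rng):
        gen = Generator(6, seed=5)
        probe = rng.random((2, 6, 6))
        expected = gen.forward(probe)
        path = tmp_path / "gen.npz"
        save_checkpoint(path, gen, {"resolution": 6})
        fresh = Generator(6, seed=99)
        assert not np.allclose(fresh.forward(probe), expected)
        load_checkpoint(path, fresh)
        assert np.array_equal(fresh.forward(probe), expected)

    def test_wrong_model_class_rejected(self, tmp_path):
        gen = Generator(6, seed=0)
        path = tmp_path / "gen.npz"
        save_checkpoint(path, gen, {})
        with pytest.raises(ValueError):
            load_checkpoint(path, Discriminator(6, seed=0))
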