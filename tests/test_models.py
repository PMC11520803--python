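import math

import numpy as np
import pytest

from ctibench.models import (
    E3FP_TOWER_SPECS,
    PHYGRATT_TARGET_SPECS,
    ConvPoolSpec,
    Dense,
    GATv2Params,
    ReLU,
    Sequential,
    TrainConfig,
    build_fp_mlp_tower,
    conv_pool_output_shape,
    conv_pool_tower,
    cross_entropy,
    deepconv_target_tower,
    fp2d_pair_model,
    fp_mlp_tower,
    gatv2_layer,
    init_gatv2_params,
    phys_init_embeddings,
    random_embeddings,
    train,
)
from ctibench.io_data import AMINO_ACIDS


def _elu(x):
    return np.where(x > 0, x, np.expm1(x))


def gatv2_scalar_oracle(features, adjacency, params, edge_weights=None):
    """Literal loop evaluation of the attention equations, one pair at a time."""
    n = len(features)
    out = np.zeros((n, params.d_out))
    for i in range(n):
        neigh = [j for j in range(n) if adjacency[i, j]]
        if not neigh:
            neigh = [i]
        scores = []
        for j in neigh:
            pre = features[i] @ params.W_left + features[j] @ params.W_right
            act = np.where(pre > 0, pre, params.leaky_slope * pre)
            e = float(params.a @ act)
            if edge_weights is not None and adjacency[i, j]:
                e *= edge_weights[i, j]
            scores.append(e)
        scores = np.array(scores)
        alpha = np.exp(scores - scores.max())
        alpha /= alpha.sum()
        msg = sum(a * (features[j] @ params.W_right) for a, j in zip(alpha, neigh))
        out[i] = _elu(msg)
    return out


class TestGATv2:
    def test_single_neighbor_attention_is_one(self):
        rng = np.random.default_rng(0)
        params = init_gatv2_params(4, 3, rng)
        f = rng.normal(size=(2, 4))
        adj = np.array([[0, 1], [1, 0]])
        out = gatv2_layer(f, adj, params)
        expected0 = _elu(f[1] @ params.W_right)
        assert np.allclose(out[0], expected0, atol=1e-10)

    def test_matches_scalar_oracle_on_random_graphs(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = int(rng.integers(2, 7))
            d_in = int(rng.integers(2, 6))
            d_out = int(rng.integers(1, 5))
            params = init_gatv2_params(d_in, d_out, rng)
            f = rng.normal(size=(n, d_in))
            adj = np.triu((rng.random((n, n)) < 0.5).astype(int), 1)
            adj = adj + adj.T
            ours = gatv2_layer(f, adj, params)
            oracle = gatv2_scalar_oracle(f, adj, params)
            assert np.allclose(ours, oracle, atol=1e-6)

    def test_weighted_graph_matches_oracle(self):
        rng = np.random.default_rng(2)
        params = init_gatv2_params(3, 2, rng)
        f = rng.normal(size=(4, 3))
        adj = np.array(
            [[0, 1, 1, 0], [1, 0, 0, 1], [1, 0, 0, 1], [0, 1, 1, 0]]
        )
        w = adj * rng.uniform(1, 20, size=(4, 4))
        w = np.triu(w) + np.triu(w, 1).T
        ours = gatv2_layer(f, adj, params, edge_weights=w)
        oracle = gatv2_scalar_oracle(f, adj, params, edge_weights=w)
        assert np.allclose(ours, oracle, atol=1e-6)

    def test_isolated_node_gets_self_loop(self):
        rng = np.random.default_rng(3)
        params = init_gatv2_params(3, 2, rng)
        f = rng.normal(size=(3, 3))
        adj = np.zeros((3, 3), dtype=int)
        adj[0, 1] = adj[1, 0] = 1  # node 2 isolated
        out = gatv2_layer(f, adj, params)
        assert np.isfinite(out).all()
        assert np.allclose(out[2], _elu(f[2] @ params.W_right), atol=1e-10)

    def test_dim_mismatch_errors(self):
        params = init_gatv2_params(4, 2)
        with pytest.raises(ValueError, match="feature dim"):
            gatv2_layer(np.zeros((3, 5)), np.eye(3), params)


class TestConvPoolTower:
    def test_physchem_target_tower_stage_shapes(self):
        # (1400,20) -> conv(603,8) p1 -> (800,15) -> pool(201,4) s1 -> (600,12)
        #           -> conv(303,7) p1 -> (300,8)  -> pool(101,4) s1 -> (200,5)
        first = conv_pool_output_shape((1400, 20), PHYGRATT_TARGET_SPECS[:1])
        assert first == (600, 12)
        assert conv_pool_output_shape((1400, 20), PHYGRATT_TARGET_SPECS) == (200, 5)

    def test_conformer_tower_stage_shape(self):
        assert conv_pool_output_shape((3, 2048), E3FP_TOWER_SPECS) == (1, 310)

    def test_forward_pass_lengths(self):
        rng = np.random.default_rng(0)
        out = conv_pool_tower(rng.normal(size=(1400, 20)), PHYGRATT_TARGET_SPECS)
        assert out.shape == (1000,)
        out = conv_pool_tower(rng.normal(size=(3, 2048)), E3FP_TOWER_SPECS)
        assert out.shape == (310,)

    def test_identity_spec_flattens_input(self):
        spec = [ConvPoolSpec(conv_kernel=(1, 1), pool_kernel=(1, 1), conv_padding=0)]
        x = np.arange(12.0).reshape(3, 4)
        out = conv_pool_tower(x, spec, seed=0)
        # 1x1 conv is a scalar multiple; flattening preserves proportions
        assert out.shape == (12,)
        nz = x.ravel() != 0
        assert np.allclose(out[nz] / x.ravel()[nz], out[nz][0] / x.ravel()[nz][0])

    def test_oversized_kernel_errors_with_shapes(self):
        spec = [ConvPoolSpec(conv_kernel=(10, 10), pool_kernel=(1, 1), conv_padding=0)]
        with pytest.raises(ValueError, match="larger than padded input"):
            conv_pool_tower(np.zeros((4, 4)), spec)


class TestFpMlpTower:
    def test_output_always_128(self):
        tower = build_fp_mlp_tower(seed=0)
        out = fp_mlp_tower(np.zeros(3239), tower)
        assert out.shape == (128,)

    def test_zero_input_propagates_biases(self):
        tower = build_fp_mlp_tower(seed=1)
        d1, _, d2, _, d3 = tower.layers
        expected = (
            np.maximum(np.maximum(d1.b, 0) @ d2.W + d2.b, 0) @ d3.W + d3.b
        )
        assert np.allclose(fp_mlp_tower(np.zeros(3239), tower), expected, atol=1e-6)

    def test_matches_matrix_arithmetic_oracle(self):
        rng = np.random.default_rng(7)
        tower = build_fp_mlp_tower(seed=7)
        x = rng.random(3239).astype(np.float32)
        d1, _, d2, _, d3 = tower.layers
        h1 = np.maximum(x @ d1.W + d1.b, 0)
        h2 = np.maximum(h1 @ d2.W + d2.b, 0)
        expected = h2 @ d3.W + d3.b
        assert np.allclose(fp_mlp_tower(x, tower), expected, atol=1e-5)

    def test_wrong_length_errors(self):
        with pytest.raises(ValueError, match="3239"):
            fp_mlp_tower(np.zeros(100))


class TestDeepConvTower:
    def test_output_width_is_windows_times_filters(self):
        emb = random_embeddings(8, seed=0)
        seq = "ACDEFGHIKLMNPQRSTVWY" * 3
        out = deepconv_target_tower(seq, emb, window_sizes=(4, 8), filters_per_window=5)
        assert out.shape == (10,)

    def test_constant_sequence_single_response(self):
        emb = random_embeddings(8, seed=1)
        out = deepconv_target_tower("A" * 50, emb, window_sizes=(4,), filters_per_window=3)
        # every window sees the same content: max equals the repeated response
        windows = deepconv_target_tower("A" * 30, emb, window_sizes=(4,), filters_per_window=3)
        assert np.allclose(out, windows, atol=1e-10)

    def test_padding_never_wins_the_max(self):
        emb = random_embeddings(8, seed=2)
        emb_spiked = emb.copy()
        emb_spiked[0] = 100.0  # corrupt the pad row
        seq = "ACDEFGHIKL" * 4
        a = deepconv_target_tower(seq, emb, window_sizes=(5,), filters_per_window=4)
        b = deepconv_target_tower(seq, emb_spiked, window_sizes=(5,), filters_per_window=4)
        assert np.allclose(a, b)

    def test_window_longer_than_max_errors(self):
        emb = random_embeddings(8)
        with pytest.raises(ValueError, match="longer than max"):
            deepconv_target_tower("ACDEF", emb, window_sizes=(2000,))


class TestPhysInitEmbeddings:
    def test_lookup_matches_projection(self, projection):
        table = phys_init_embeddings(projection)
        vec = projection.aa_vectors["A"]
        assert np.allclose(table[1 + AMINO_ACIDS.index("A")], vec / np.linalg.norm(vec))

    def test_pad_row_zero_and_rows_unit_norm(self, projection):
        table = phys_init_embeddings(projection)
        assert table[0].sum() == 0
        assert np.allclose(np.linalg.norm(table[1:], axis=1), 1.0)

    def test_dim_mismatch_errors(self, projection):
        with pytest.raises(ValueError, match="width"):
            phys_init_embeddings(projection, dim=64)

    def test_random_table_reproducible(self):
        assert np.array_equal(random_embeddings(16, seed=4), random_embeddings(16, seed=4))


class TestCrossEntropy:
    def test_perfect_prediction_near_zero(self):
        assert cross_entropy(np.array([1]), np.array([1 - 1e-7])) < 1e-5

    def test_half_confidence_is_ln2_both_classes(self):
        assert cross_entropy(np.array([1]), np.array([0.5])) == pytest.approx(math.log(2))
        assert cross_entropy(np.array([0]), np.array([0.5])) == pytest.approx(math.log(2))

    def test_clipping_keeps_loss_finite(self):
        assert np.isfinite(cross_entropy(np.array([1]), np.array([0.0])))


class TestTraining:
    def test_zero_epochs_leaves_parameters_unchanged(self):
        model = fp2d_pair_model(8, seed=0)
        before = model.state()
        rng = np.random.default_rng(0)
        train(model, rng.random((10, 3239)), rng.random((10, 8)),
              np.array([0, 1] * 5), TrainConfig(epochs=0))
        after = model.state()
        assert all(np.array_equal(a, b) for a, b in zip(before, after))

    def test_same_seed_identical_parameters(self):
        rng = np.random.default_rng(1)
        xc = rng.random((16, 3239)).astype(np.float32)
        xt = rng.random((16, 8)).astype(np.float32)
        y = np.array([0, 1] * 8)
        results = []
        for _ in range(2):
            model = fp2d_pair_model(8, seed=5)
            train(model, xc, xt, y, TrainConfig(epochs=2, seed=5))
            results.append(model.state())
        assert all(np.array_equal(a, b) for a, b in zip(*results))

    def test_gradients_match_finite_differences(self):
        """Backward pass of the dense stack agrees with numerical gradients."""
        rng = np.random.default_rng(0)
        net = Sequential(Dense(5, 4, rng), ReLU(), Dense(4, 2, rng))
        x = rng.normal(size=(3, 5))
        y = np.array([0, 1, 1])
        onehot = np.eye(2)[y]

        def loss_at():
            from ctibench.models import softmax

            probs = softmax(net.forward(x))
            return cross_entropy(y, probs[:, 1])

        from ctibench.models import softmax

        probs = softmax(net.forward(x))
        for _, g in net.parameters():
            g[...] = 0.0
        net.backward((probs - onehot) / len(y))
        eps = 1e-5
        for p, g in net.parameters():
            flat_p = p.ravel()
            flat_g = g.ravel()
            for idx in range(0, flat_p.size, max(1, flat_p.size // 5)):
                orig = flat_p[idx]
                flat_p[idx] = orig + eps
                up = loss_at()
                flat_p[idx] = orig - eps
                down = loss_at()
                flat_p[idx] = orig
                # float32 parameters limit finite-difference accuracy
                assert (up - down) / (2 * eps) == pytest.approx(
                    flat_g[idx], rel=2e-2, abs=1e-3
                )
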