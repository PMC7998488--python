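import math

import numpy as np
import pytest

from ggat import (
    LayerConfig,
    ModelConfig,
    default_model_config,
    dense_oracle_forward,
    fixture_path_graph,
    ggat_forward,
    init_params,
    load_model,
    save_model,
)
from ggat.errors import ConfigError, ValidationError
from ggat.ggat_core import (
    aggregate,
    compute_gates,
    gate_combine,
    multi_head_combine,
    new_information,
    normalize_attention,
    raw_attention,
)
from helpers import random_instance


class TestRawAttention:
    def test_zero_attention_vector_gives_zero_scores(self):
        A = np.ones((2, 2))
        H = np.array([[1.0], [2.0]])
        head = {"W": np.array([[1.0]]), "a": np.zeros(2)}
        B = raw_attention(H, head, A)
        assert np.allclose(B, 0.0)

    def test_hand_computed_pair_score(self):
        # W = [[1]], a = (1, 1), h = (1, 2): b_12 = LeakyReLU(1*1 + 1*2) = 3
        A = np.ones((2, 2))
        H = np.array([[1.0], [2.0]])
        head = {"W": np.array([[1.0]]), "a": np.array([1.0, 1.0])}
        B = raw_attention(H, head, A)
        assert B[0, 1] == pytest.approx(3.0)

    def test_negative_preactivation_uses_leaky_slope(self):
        A = np.ones((2, 2))
        H = np.array([[1.0], [2.0]])
        head = {"W": np.array([[1.0]]), "a": np.array([-1.0, -1.0])}
        B = raw_attention(H, head, A, leaky_slope=0.2)
        assert B[0, 1] == pytest.approx(0.2 * -3.0)

    def test_non_neighbours_masked_regardless_of_features(self, rng):
        A = np.eye(3)
        A[0, 1] = A[1, 0] = 1.0
        H = rng.normal(size=(3, 2))
        head = {"W": rng.normal(size=(2, 2)), "a": rng.normal(size=4)}
        B = raw_attention(H, head, A)
        assert B[0, 2] < -1e29 and B[2, 0] < -1e29

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            raw_attention(np.ones((2, 3)), {"W": np.ones((2, 1)), "a": np.ones(2)},
                          np.ones((2, 2)))


class TestNormalizeAttention:
    def test_single_neighbour_gets_weight_one(self):
        A = np.eye(2)  # only self-loops
        B = raw_attention(np.ones((2, 1)), {"W": np.ones((1, 1)), "a": np.ones(2)}, A)
        alpha = normalize_attention(B, A)
        assert np.allclose(np.diag(alpha), 1.0)
        assert alpha[0, 1] == 0.0

    def test_equal_scores_give_uniform_weights(self):
        A = np.ones((4, 4))
        alpha = normalize_attention(np.where(A > 0, 1.7, -1e30), A)
        assert np.allclose(alpha, 0.25)

    def test_matches_unstabilized_softmax_oracle(self, rng):
        n = 5
        A = (rng.random((n, n)) < 0.6).astype(float)
        A = np.maximum(A, A.T)
        np.fill_diagonal(A, 1.0)
        B = np.where(A > 0, rng.normal(size=(n, n)), -1e30)
        alpha = normalize_attention(B, A)
        for i in range(n):
            neigh = np.flatnonzero(A[i])
            raw = [math.exp(B[i, j]) for j in neigh]
            for j, r in zip(neigh, raw):
                assert alpha[i, j] == pytest.approx(r / sum(raw), abs=1e-10)

    def test_rows_sum_to_one_over_neighbourhood(self, rng):
        for seed in range(5):
            X, A, params, config = random_instance(seed)
            for head in params["layers"][0]["heads"]:
                alpha = normalize_attention(raw_attention(X, head, A), A)
                assert np.allclose(alpha.sum(axis=1), 1.0, atol=1e-8)
                assert np.all(alpha[A == 0] == 0.0)


class TestAggregateAndCombine:
    def test_one_hot_attention_copies_neighbour(self, rng):
        H = rng.normal(size=(3, 2))
        W = rng.normal(size=(2, 2))
        alpha = np.zeros((3, 3))
        alpha[:, 1] = 1.0  # everyone attends only to node 1
        out = aggregate(alpha, H, {"W": W}, activation="identity")
        assert np.allclose(out, np.tile(H[1] @ W, (3, 1)))

    def test_zero_features_give_sigma_of_zero(self):
        alpha = np.full((2, 2), 0.5)
        out = aggregate(alpha, np.zeros((2, 3)), {"W": np.ones((3, 2))},
                        activation="softmax")
        assert np.allclose(out, 0.5)  # softmax of a zero 2-vector

    def test_three_node_loop_oracle(self, rng):
        H = rng.normal(size=(3, 2))
        W = rng.normal(size=(2, 2))
        alpha = rng.dirichlet(np.ones(3), size=3)
        out = aggregate(alpha, H, {"W": W}, activation="identity")
        for i in range(3):
            expect = sum(alpha[i, j] * (H[j] @ W) for j in range(3))
            assert np.allclose(out[i], expect)

    def test_concat_shape(self, rng):
        parts = [rng.normal(size=(4, 3)) for _ in range(2)]
        assert multi_head_combine(parts, "concat").shape == (4, 6)

    def test_paper_default_concat_width(self, rng):
        # 8 heads x 8 hidden units -> 64 concatenated columns
        parts = [rng.normal(size=(5, 8)) for _ in range(8)]
        assert multi_head_combine(parts, "concat").shape == (5, 64)

    def test_average_of_identical_heads_is_identity(self, rng):
        m = rng.normal(size=(4, 3))
        assert np.allclose(multi_head_combine([m, m, m], "average"), m)

    def test_mixed_shapes_rejected(self, rng):
        with pytest.raises(ValidationError):
            multi_head_combine([rng.normal(size=(4, 3)), rng.normal(size=(4, 2))],
                               "concat")


class TestGates:
    def _gp(self, rng, m=2, f=2):
        return {
            "Wz": rng.normal(size=(m, m)), "Uz": rng.normal(size=(f, m)),
            "Wr": rng.normal(size=(m, f)), "Ur": rng.normal(size=(f, f)),
            "Wn": rng.normal(size=(m, m)), "Un": rng.normal(size=(f, m)),
        }

    def test_zero_weights_give_half_gates(self, rng):
        gp = {k: np.zeros_like(v) for k, v in self._gp(rng).items()}
        z, r = compute_gates(rng.normal(size=(3, 2)), rng.normal(size=(3, 2)), gp)
        assert np.allclose(z, 0.5) and np.allclose(r, 0.5)

    def test_gates_strictly_inside_unit_interval(self, rng):
        gp = self._gp(rng)
        z, r = compute_gates(rng.normal(size=(6, 2)) * 5, rng.normal(size=(6, 2)) * 5, gp)
        for g in (z, r):
            assert np.all(g > 0.0) and np.all(g < 1.0)

    def test_scalar_hand_oracle(self):
        gp = {
            "Wz": np.array([[0.5]]), "Uz": np.array([[-0.25]]),
            "Wr": np.array([[1.0]]), "Ur": np.array([[2.0]]),
            "Wn": np.array([[1.5]]), "Un": np.array([[-1.0]]),
        }
        m = np.array([[2.0]])
        h = np.array([[4.0]])
        z, r = compute_gates(m, h, gp)
        assert z[0, 0] == pytest.approx(1 / (1 + math.exp(-(0.5 * 2 - 0.25 * 4))))
        assert r[0, 0] == pytest.approx(1 / (1 + math.exp(-(1.0 * 2 + 2.0 * 4))))
        n = new_information(m, h, r, gp)
        assert n[0, 0] == pytest.approx(math.tanh(1.5 * 2 - 1.0 * r[0, 0] * 4.0))

    def test_new_information_zero_weights(self, rng):
        gp = {k: np.zeros_like(v) for k, v in self._gp(rng).items()}
        n = new_information(rng.normal(size=(3, 2)), rng.normal(size=(3, 2)),
                            np.full((3, 2), 0.5), gp)
        assert np.allclose(n, 0.0)

    def test_full_reset_drops_the_input(self, rng):
        gp = self._gp(rng)
        m = rng.normal(size=(3, 2))
        h = rng.normal(size=(3, 2))
        n = new_information(m, h, np.zeros((3, 2)), gp)
        assert np.allclose(n, np.tanh(m @ gp["Wn"]))

    @pytest.mark.parametrize(
        "z,expect", [(0.0, 1.0), (1.0, 0.0), (0.5, 0.5)]
    )
    def test_gate_combine_limits(self, z, expect):
        # h = 1, n = 0: z=0 keeps h, z=1 takes n, z=0.5 is the midpoint
        out = gate_combine(np.ones((1, 1)), np.zeros((1, 1)), np.full((1, 1), z))
        assert out[0, 0] == pytest.approx(expect)

    def test_output_between_input_and_new_information(self, rng):
        h = rng.normal(size=(5, 3))
        n = rng.normal(size=(5, 3))
        z = rng.random((5, 3))
        out = gate_combine(h, n, z)
        assert np.all(out >= np.minimum(h, n) - 1e-12)
        assert np.all(out <= np.maximum(h, n) + 1e-12)


class TestLayerAndForward:
    def test_gated_layer_same_width_uses_identity_projection(self):
        config = default_model_config(2, hidden=3, heads=2, n_layers=3)
        params = init_params(config, 4, seed=0)
        assert "P" not in params["layers"][1]["gates"]   # 6 -> 6: no projection
        assert "P" in params["layers"][2]["gates"]       # 6 -> 2: projection

    def test_log_probabilities_normalized(self, rng):
        X, A, params, config = random_instance(3)
        logp = ggat_forward(X, A, params, config)
        from scipy.special import logsumexp

        assert np.allclose(logsumexp(logp, axis=1), 0.0, atol=1e-8)

    def test_permutation_equivariance(self, rng):
        X, A, params, config = random_instance(4, n_max=8)
        logp = ggat_forward(X, A, params, config)
        for seed in range(10):
            perm = np.random.default_rng(seed).permutation(X.shape[0])
            logp_p = ggat_forward(X[perm], A[np.ix_(perm, perm)], params, config)
            assert np.allclose(logp_p, logp[perm], atol=1e-6)

    @pytest.mark.parametrize("seed", range(20))
    def test_oracle_equivalence_on_random_instances(self, seed):
        X, A, params, config = random_instance(seed)
        fast = ggat_forward(X, A, params, config)
        slow = dense_oracle_forward(X, A, params, config)
        assert np.max(np.abs(fast - slow)) < 1e-6

    def test_oracle_equivalence_with_elu_variants(self):
        X, A, params, config = random_instance(31)
        config = ModelConfig(
            [LayerConfig(c.heads, c.out_dim, c.combine, c.gated, "elu")
             for c in config.layers],
            interlayer="elu",
        )
        fast = ggat_forward(X, A, params, config)
        slow = dense_oracle_forward(X, A, params, config)
        assert np.max(np.abs(fast - slow)) < 1e-6

    def test_receptive_field_on_path_graph(self):
        # Table-style propagation: after three layers node 0 holds information
        # from <= 3 hops; a 4-hop perturbation leaves its output bit-identical
        for seed in range(10):
            G = fixture_path_graph(6, n_features=4, seed=seed)
            config = default_model_config(2, hidden=3, heads=2, n_layers=3)
            params = init_params(config, 4, seed=seed + 100)
            base = ggat_forward(G.features, G.adjacency, params, config)
            far = G.features.copy()
            far[4] += 1.0  # 4 hops from node 0
            far[5] -= 1.0
            out_far = ggat_forward(far, G.adjacency, params, config)
            assert np.array_equal(base[0], out_far[0])
            near = G.features.copy()
            near[3] += 1.0  # 3 hops: inside the receptive field
            out_near = ggat_forward(near, G.adjacency, params, config)
            assert not np.array_equal(base[0], out_near[0])

    def test_single_node_graph_oracle(self):
        config = default_model_config(2, hidden=2, heads=1, n_layers=3)
        params = init_params(config, 3, seed=0)
        X = np.array([[0.3, -1.2, 0.7]])
        A = np.ones((1, 1))
        fast = ggat_forward(X, A, params, config)
        slow = dense_oracle_forward(X, A, params, config)
        assert np.allclose(fast, slow, atol=1e-10)

    def test_zero_weight_model_gives_uniform_log_probabilities(self):
        config = default_model_config(3, hidden=2, heads=2, n_layers=3)
        params = init_params(config, 4, seed=0)
        for lp in params["layers"]:
            for head in lp["heads"]:
                head["W"] *= 0.0
                head["a"] *= 0.0
            if "gates" in lp:
                for k in lp["gates"]:
                    lp["gates"][k] *= 0.0
        logp = dense_oracle_forward(np.random.default_rng(0).normal(size=(4, 4)),
                                    np.ones((4, 4)), params, config)
        assert np.allclose(logp, -math.log(3))

    def test_gradient_matches_finite_differences(self):
        from autograd import grad
        from autograd.misc.flatten import flatten

        X, A, params, config = random_instance(9, n_max=5, f_max=3, k_max=1)
        y = np.arange(X.shape[0]) % 2
        flat, unflatten = flatten(params)

        def loss(theta):
            logp = ggat_forward(X, A, unflatten(theta), config)
            import autograd.numpy as anp

            idx = np.arange(X.shape[0])
            return -anp.sum(logp[idx, y]) / len(idx)

        g = grad(loss)(flat)
        rng = np.random.default_rng(0)
        for _ in range(10):
            i = int(rng.integers(flat.size))
            eps = 1e-6
            e = np.zeros_like(flat)
            e[i] = eps
            fd = (loss(flat + e) - loss(flat - e)) / (2 * eps)
            assert g[i] == pytest.approx(fd, rel=1e-4, abs=1e-8)


class TestConfigAndSerialization:
    def test_endmost_layer_must_average(self):
        with pytest.raises(ConfigError):
            ModelConfig([LayerConfig(2, 2, "concat")])

    def test_too_few_classes_rejected(self):
        with pytest.raises(ConfigError):
            default_model_config(1)

    def test_unknown_activation_rejected(self):
        with pytest.raises(ConfigError):
            LayerConfig(activation="relu6")

    def test_save_load_round_trip(self, tmp_path):
        X, A, params, config = random_instance(5)
        path = save_model(params, config, tmp_path / "model.json")
        params2, config2 = load_model(path)
        assert np.allclose(
            ggat_forward(X, A, params, config), ggat_forward(X, A, params2, config2)
        )

    def test_load_rejects_foreign_json(self, tmp_path):
        p = tmp_path / "x.json"
        p.write_text('{"hello": 1}')
        with pytest.raises(ValidationError):
            load_model(p)
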