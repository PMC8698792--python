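"""Forward-pass contracts, gradient correctness, and training behaviour."""

import numpy as np
import pytest

from embeddti.chem_graphs import build_atom_graph, parse_smiles
from embeddti.data_pipeline import AffinityRecord
from embeddti.neural_model import (
    ModelConfig,
    Tensor,
    attention_scores,
    featurize_record,
    fuse_and_predict,
    gcn_layer_forward,
    graph_branch_forward,
    init_model_params,
    load_checkpoint,
    node_attention,
    normalize_adjacency,
    predict,
    protein_branch_forward,
    save_checkpoint,
    t_square,
    t_sub,
    train_model,
    _forward_t,
    _init_graph_branch,
)
from embeddti.protein_embedding import encode_protein


class TestNormalizeAdjacency:
    def test_single_node(self):
        assert normalize_adjacency(np.array([[0.0]])) == pytest.approx(np.array([[1.0]]))

    def test_single_edge(self):
        out = normalize_adjacency(np.array([[0.0, 1.0], [1.0, 0.0]]))
        assert out == pytest.approx(np.full((2, 2), 0.5))

    def test_triangle(self):
        K3 = np.ones((3, 3)) - np.eye(3)
        assert normalize_adjacency(K3) == pytest.approx(np.full((3, 3), 1 / 3))

    @pytest.mark.parametrize(
        "bad",
        [np.array([[0.0, 1.0], [0.0, 0.0]]), np.array([[1.0]]),
         np.zeros((2, 3))],
    )
    def test_invalid_input_rejected(self, bad):
        with pytest.raises(ValueError):
            normalize_adjacency(bad)


class TestNodeAttention:
    def test_single_node_is_identity(self, small_config, small_params):
        X = np.random.default_rng(0).normal(size=(1, 101))
        out = node_attention(X, small_params.atom, d_k=small_config.d_k)
        assert out == pytest.approx(X)

    def test_zero_projections_give_column_means(self, small_config):
        params = _init_graph_branch(101, small_config, np.random.default_rng(0))
        params.W_Q.data[:] = 0.0
        params.W_K.data[:] = 0.0
        X = np.random.default_rng(1).normal(size=(5, 101))
        out = node_attention(X, params, d_k=small_config.d_k)
        assert out == pytest.approx(np.tile(X.mean(axis=0), (5, 1)))

    def test_rows_are_convex_combinations(self, small_params, small_config):
        # uniform-sign input stays inside its own bounding box under alpha X
        X = np.abs(np.random.default_rng(2).normal(size=(4, 101)))
        out = node_attention(X, small_params.atom, d_k=small_config.d_k)
        assert np.all(out <= X.max(axis=0) + 1e-12)
        assert np.all(out >= X.min(axis=0) - 1e-12)


class TestGcnLayer:
    def test_identity_weights_no_activation(self):
        A_norm = normalize_adjacency(np.array([[0.0, 1.0], [1.0, 0.0]]))
        H = np.random.default_rng(0).normal(size=(2, 3))
        out = gcn_layer_forward(H, A_norm, np.eye(3), activation="identity")
        assert out == pytest.approx(A_norm @ H)

    def test_single_node(self):
        H = np.array([[1.0, -2.0]])
        W = np.array([[1.0, 0.0], [0.0, 1.0]])
        out = gcn_layer_forward(H, np.array([[1.0]]), W)
        assert out == pytest.approx(np.array([[1.0, 0.0]]))  # ReLU clips the negative

    def test_matches_per_node_aggregation_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            n = int(rng.integers(2, 11))
            A = np.triu(rng.integers(0, 2, size=(n, n)), 1)
            A = A + A.T
            A_norm = normalize_adjacency(A.astype(float))
            H = rng.normal(size=(n, 4))
            W = rng.normal(size=(4, 6))
            out = gcn_layer_forward(H, A_norm, W)
            HW = H @ W
            for i in range(n):
                acc = sum(A_norm[i, j] * HW[j] for j in range(n))
                assert out[i] == pytest.approx(np.maximum(acc, 0.0))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            gcn_layer_forward(np.zeros((2, 3)), np.eye(2), np.zeros((4, 5)))


class TestGraphBranch:
    def test_output_width(self, small_config, small_params):
        graph = build_atom_graph(parse_smiles("CC(=O)Oc1ccccc1"))
        out = graph_branch_forward(graph, small_params.atom, small_config)
        assert out.shape == (small_config.branch_dim,)
        assert np.isfinite(out).all()

    def test_permutation_invariance(self, small_config, small_params):
        graph = build_atom_graph(parse_smiles("CC(=O)Oc1ccccc1C(=O)O"))
        base = graph_branch_forward(graph, small_params.atom, small_config)
        rng = np.random.default_rng(4)
        perm = rng.permutation(graph.n_atoms)
        permuted = type(graph)(
            n_atoms=graph.n_atoms,
            adjacency=graph.adjacency[np.ix_(perm, perm)],
            features=graph.features[perm],
        )
        out = graph_branch_forward(permuted, small_params.atom, small_config)
        assert out == pytest.approx(base, abs=1e-9)

    def test_single_node_graph(self, small_config, small_params):
        graph = build_atom_graph(parse_smiles("C"))
        out = graph_branch_forward(graph, small_params.atom, small_config)
        assert np.isfinite(out).all()


class TestProteinBranch:
    def test_output_width_and_determinism(self, small_config, small_params):
        enc = encode_protein("MKVLAAGG" * 5, L=small_config.protein_len)
        out1 = protein_branch_forward(enc, small_params.protein, small_config)
        out2 = protein_branch_forward(enc, small_params.protein, small_config)
        assert out1.shape == (small_config.branch_dim,)
        assert np.array_equal(out1, out2)

    def test_all_pad_input_finite(self, small_config, small_params):
        enc = encode_protein("B", L=small_config.protein_len)  # B -> X, rest PAD
        enc.indices[:] = 0
        out = protein_branch_forward(enc, small_params.protein, small_config)
        assert np.isfinite(out).all()

    def test_wrong_length_rejected(self, small_config, small_params):
        enc = encode_protein("MKV", L=32)
        with pytest.raises(ValueError):
            protein_branch_forward(enc, small_params.protein, small_config)


class TestFusionHead:
    def test_input_width_is_three_branches(self, small_config, small_params):
        d = small_config.branch_dim
        assert small_params.fusion.W1.data.shape[0] == 3 * d
        out = fuse_and_predict(np.ones(d), np.ones(d), np.ones(d),
                               small_params.fusion, small_config)
        assert np.isfinite(out)

    def test_zero_weights_output_final_bias(self, small_config):
        params = init_model_params(small_config, seed=0)
        for t in params.fusion.named().values():
            t.data[:] = 0.0
        params.fusion.b3.data[:] = 2.5
        d = small_config.branch_dim
        out = fuse_and_predict(np.ones(d), np.ones(d), np.ones(d),
                               params.fusion, small_config)
        assert out == pytest.approx(2.5)

    def test_dimension_mismatch_rejected(self, small_config, small_params):
        d = small_config.branch_dim
        with pytest.raises(ValueError):
            fuse_and_predict(np.ones(d + 1), np.ones(d), np.ones(d),
                             small_params.fusion, small_config)


class TestGradients:
    def test_analytic_gradients_match_finite_differences(self, small_config):
        params = init_model_params(small_config, seed=2)
        record = AffinityRecord("CCO", "ACDEFGHIKLMNPQRSTVWY" * 3, 5.0)
        feat = featurize_record(record, small_config)

        def loss_value():
            pred = _forward_t(feat, params, small_config, train=False, rng=None)
            return float((pred.data[0, 0] - 5.0) ** 2)

        named = params.named()
        pred = _forward_t(feat, params, small_config, train=False, rng=None)
        loss = t_square(t_sub(pred, Tensor([[5.0]])))
        loss.backward()
        rng = np.random.default_rng(0)
        for name in ["atom.W_Q", "sub.gcn1_W", "protein.conv0_W",
                     "protein.embedding", "fusion.W2", "fusion.b3",
                     "atom.fc1_W", "sub.W_K"]:
            tensor = named[name]
            assert tensor.grad is not None, name
            for _ in range(3):
                idx = tuple(rng.integers(s) for s in tensor.data.shape)
                h = 1e-6
                orig = tensor.data[idx]
                tensor.data[idx] = orig + h
                up = loss_value()
                tensor.data[idx] = orig - h
                down = loss_value()
                tensor.data[idx] = orig
                fd = (up - down) / (2 * h)
                analytic = tensor.grad[idx]
                assert analytic == pytest.approx(fd, rel=1e-4, abs=1e-7), name


class TestTraining:
    def test_loss_decreases(self, tiny_dataset):
        config = ModelConfig.small(epochs=20, batch_size=10, learning_rate=0.005)
        state = train_model(tiny_dataset, config, seed=1)
        assert state.train_losses[-1] < state.train_losses[0]

    def test_seeded_determinism(self, tiny_dataset):
        config = ModelConfig.small(epochs=3, batch_size=5, learning_rate=0.005,
                                   dropout=0.2)
        s1 = train_model(tiny_dataset, config, seed=9)
        s2 = train_model(tiny_dataset, config, seed=9)
        assert s1.train_losses == s2.train_losses

    def test_memorizes_ten_records(self, tiny_dataset, memorized_state):
        assert memorized_state.train_losses[-1] < 0.01
        for record in tiny_dataset:
            pred = predict(record.drug_smiles, record.protein_sequence,
                           memorized_state)
            assert abs(pred - record.affinity) < 0.2

    def test_validation_tracking(self, tiny_dataset):
        config = ModelConfig.small(epochs=4, batch_size=5, learning_rate=0.005)
        state = train_model(tiny_dataset[:7], config, seed=2,
                            validation=tiny_dataset[7:])
        assert len(state.val_losses) == 4
        assert state.best_val_loss == pytest.approx(min(state.val_losses))
        assert state.best_params_arrays is not None

    def test_unfeaturizable_record_named(self, small_config):
        bad = AffinityRecord("zz((", "MKVA", 5.0, drug_id="bad-drug")
        with pytest.raises(ValueError, match="bad-drug"):
            train_model([bad], ModelConfig.small(epochs=1), seed=0)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train_model([], ModelConfig.small(), seed=0)


class TestPredict:
    def test_repeated_calls_identical(self, memorized_state):
        a = predict("CCO", "MKVAG" * 10, memorized_state)
        b = predict("CCO", "MKVAG" * 10, memorized_state)
        assert a == b and np.isfinite(a)

    def test_parse_failure_propagates(self, memorized_state):
        with pytest.raises(ValueError):
            predict("((", "MKVA", memorized_state)


class TestAttentionScores:
    def test_range_and_max(self, small_config, small_params):
        graph = build_atom_graph(parse_smiles("CC(=O)Oc1ccccc1"))
        scores = attention_scores(graph, small_params.atom, small_config)
        assert scores.shape == (graph.n_atoms,)
        assert scores.max() == pytest.approx(1.0)
        assert scores.min() == pytest.approx(0.0)
        assert np.all((scores >= 0) & (scores <= 1))

    def test_single_node_scores_one(self, small_config, small_params):
        graph = build_atom_graph(parse_smiles("C"))
        scores = attention_scores(graph, small_params.atom, small_config)
        assert scores == pytest.approx([1.0])

    def test_uniform_attention_degenerates_to_ones(self, small_config):
        params = _init_graph_branch(101, small_config, np.random.default_rng(0))
        params.W_Q.data[:] = 0.0
        params.W_K.data[:] = 0.0
        graph = build_atom_graph(parse_smiles("CCCC"))
        scores = attention_scores(graph, params, small_config)
        assert scores == pytest.approx(np.ones(graph.n_atoms))


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, memorized_state, tmp_path):
        path = tmp_path / "model.ckpt"
        save_checkpoint(memorized_state, path)
        loaded = load_checkpoint(path)
        assert loaded.config == memorized_state.config
        assert loaded.train_losses == memorized_state.train_losses
        pair = ("CCO", "MKVAG" * 10)
        assert predict(*pair, loaded) == predict(*pair, memorized_state)
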