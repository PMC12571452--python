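import numpy as np
import pytest

from cgsda.autodiff import Tensor
from cgsda.data import TrainSplit, build_block_adjacency
from cgsda.model import (
    CGSDAModel,
    ModelConfig,
    bce_loss,
    decode_scores,
    train,
)


def small_config(**overrides):
    base = dict(cheb_layers=2, cheb_orders=(2, 2), gated_layers=2,
                hidden_dim=8, epochs=5, seed=0)
    base.update(overrides)
    return ModelConfig(**base)


class TestConfig:
    def test_defaults_are_the_tuned_operating_point(self):
        cfg = ModelConfig()
        assert cfg.cheb_orders == (3, 5)
        assert (cfg.cheb_layers, cfg.gated_layers, cfg.gated_seq_len) == (2, 3, 1)
        assert (cfg.hidden_dim, cfg.epochs) == (64, 600)
        assert (cfg.learning_rate, cfg.weight_decay, cfg.dropout) == (5e-4, 1e-4, 0.01)

    def test_validation(self):
        with pytest.raises(ValueError, match="variant"):
            ModelConfig(variant="nope")
        with pytest.raises(ValueError, match="orders"):
            ModelConfig(cheb_layers=3, cheb_orders=(3, 5))

    def test_round_trip(self):
        cfg = ModelConfig(epochs=100, variant="no-cheb")
        assert ModelConfig.from_dict(cfg.to_dict()) == cfg


class TestEncoder:
    def test_zero_weights_give_zero(self, tiny_dataset):
        model = CGSDAModel(3, 3, small_config())
        model.W_s.data[:] = model.W_d.data[:] = 0.0
        out = model.encode(np.ones((2, 3)), np.ones((2, 3)))
        assert not out.data.any()

    def test_stacked_shape_snornas_first(self):
        model = CGSDAModel(4, 6, small_config())
        out = model.encode(np.ones((2, 4)), np.ones((1, 6)))
        assert out.data.shape == (3, 8)

    def test_identity_passthrough_on_nonnegative_input(self):
        cfg = small_config(hidden_dim=4)
        model = CGSDAModel(4, 4, cfg)
        model.W_s.data = np.eye(4)
        model.W_d.data = np.eye(4)
        model.b_s.data[:] = model.b_d.data[:] = 0.0
        F_s = np.abs(np.random.default_rng(0).standard_normal((3, 4)))
        F_d = np.abs(np.random.default_rng(1).standard_normal((2, 4)))
        out = model.encode(F_s, F_d)
        assert np.allclose(out.data, np.vstack([F_s, F_d]))

    def test_width_mismatch_rejected(self):
        model = CGSDAModel(4, 4, small_config())
        with pytest.raises(ValueError, match="width"):
            model.encode(np.ones((2, 5)), np.ones((2, 4)))


class TestForward:
    @pytest.mark.parametrize("variant,width", [
        ("full", 16), ("no-cheb", 8), ("no-gated", 8), ("no-residual", 16),
    ])
    def test_fusion_width_by_variant(self, tiny_dataset, variant, width):
        cfg = small_config(variant=variant)
        model = CGSDAModel(3, 3, cfg)
        graph = build_block_adjacency(tiny_dataset, TrainSplit.full(tiny_dataset))
        rng = np.random.default_rng(0)
        out = model.forward(graph, rng.standard_normal((2, 3)),
                            rng.standard_normal((2, 3)))
        assert out.data.shape == (4, width)

    def test_permutation_consistency_of_scores(self, tiny_dataset):
        """Relabeling snoRNAs permutes score rows identically."""
        cfg = small_config()
        rng = np.random.default_rng(0)
        F_s = rng.standard_normal((2, 3))
        F_d = rng.standard_normal((2, 3))
        graph = build_block_adjacency(tiny_dataset, TrainSplit.full(tiny_dataset))
        model = CGSDAModel(3, 3, cfg)
        base = decode_scores(model.forward(graph, F_s, F_d))

        perm = np.array([1, 0])
        from cgsda.data import AssociationDataset
        ds2 = AssociationDataset(["s2", "s1"], ["d1", "d2"],
                                 tiny_dataset.A[perm])
        graph2 = build_block_adjacency(ds2, TrainSplit.full(ds2))
        out2 = decode_scores(model.forward(graph2, F_s[perm], F_d))
        full_perm = np.array([1, 0, 2, 3])
        assert np.allclose(out2.data, base.data[np.ix_(full_perm, full_perm)],
                           atol=1e-10)


class TestDecoder:
    def test_zero_embedding_gives_uniform_half(self):
        out = decode_scores(np.zeros((4, 3)))
        assert np.allclose(out, 0.5)

    def test_orthonormal_rows(self):
        out = decode_scores(np.eye(3))
        expect = np.full((3, 3), 0.5)
        np.fill_diagonal(expect, 1 / (1 + np.exp(-1)))
        assert np.allclose(out, expect, atol=1e-12)

    def test_symmetric_and_in_unit_interval(self):
        F = np.random.default_rng(0).standard_normal((6, 4))
        out = decode_scores(F)
        assert np.allclose(out, out.T, atol=1e-12)
        assert np.all((out > 0) & (out < 1))


class TestBceLoss:
    def test_half_scores_give_log2(self):
        loss = bce_loss(np.full(4, 0.5), np.array([0, 1, 0, 1.0]))
        assert loss.data.item() == pytest.approx(np.log(2), abs=1e-12)

    def test_confident_correct(self):
        loss = bce_loss(np.array([0.9]), np.array([1.0]))
        assert loss.data.item() == pytest.approx(-np.log(0.9), abs=1e-9)

    def test_perfect_prediction_limit(self):
        loss = bce_loss(np.array([1.0, 0.0]), np.array([1.0, 0.0]))
        assert loss.data.item() == pytest.approx(0.0, abs=1e-9)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            bce_loss(np.array([0.5]), np.array([1.0, 0.0]))


class TestTraining:
    def test_loss_descends_on_planted_fixture(self, small_planted):
        dataset, F_s, F_d, _ = small_planted
        cfg = small_config(epochs=100, seed=1, hidden_dim=16)
        fitted = train(dataset, TrainSplit.full(dataset), F_s, F_d, cfg)
        assert fitted.loss_history[-1] < fitted.loss_history[0]

    def test_same_seed_identical_trajectory(self, small_planted):
        dataset, F_s, F_d, _ = small_planted
        cfg = small_config(epochs=8, seed=3)
        a = train(dataset, TrainSplit.full(dataset), F_s, F_d, cfg)
        b = train(dataset, TrainSplit.full(dataset), F_s, F_d, cfg)
        assert a.loss_history == b.loss_history
        assert np.array_equal(a.score_matrix(), b.score_matrix())

    def test_ablation_wiring(self, small_planted):
        dataset, F_s, F_d, _ = small_planted
        no_gated = train(dataset, TrainSplit.full(dataset), F_s, F_d,
                         small_config(epochs=2, variant="no-gated"))
        assert no_gated.model.gated is None and no_gated.model.cheb is not None
        no_cheb = train(dataset, TrainSplit.full(dataset), F_s, F_d,
                        small_config(epochs=2, variant="no-cheb"))
        assert no_cheb.model.cheb is None and no_cheb.model.gated is not None

    def test_no_training_positives_rejected(self, tiny_dataset):
        pos = [tuple(p) for p in tiny_dataset.positive_pairs()]
        split = TrainSplit.holding_out(tiny_dataset, pos)
        with pytest.raises(ValueError, match="positives"):
            train(tiny_dataset, split, np.ones((2, 3)), np.ones((2, 3)),
                  small_config())

    def test_held_out_positives_never_sampled_as_negatives(self, small_planted):
        from cgsda.model import _negative_pool
        dataset, *_ = small_planted
        pool = _negative_pool(dataset, set())
        pos_flat = {i * dataset.n_disease + j for i, j in dataset.positive_pairs()}
        assert not pos_flat & set(pool.tolist())


@pytest.fixture(scope="module")
def fitted(small_planted):
    dataset, F_s, F_d, _ = small_planted
    return train(dataset, TrainSplit.full(dataset), F_s, F_d,
                 small_config(epochs=3, seed=2))


class TestPredict:

    def test_full_block_shape_and_range(self, fitted):
        block = fitted.score_matrix()
        assert block.shape == (fitted.dataset.n_snorna, fitted.dataset.n_disease)
        assert np.all((block > 0) & (block < 1))

    def test_single_pair_and_order_invariance(self, fitted):
        ds = fitted.dataset
        pairs = [(ds.snorna_ids[3], ds.disease_ids[1]),
                 (ds.snorna_ids[0], ds.disease_ids[4])]
        fwd = fitted.predict(pairs)
        rev = fitted.predict(pairs[::-1])
        assert np.allclose(fwd, rev[::-1])
        assert 0 < fwd[0] < 1

    def test_unknown_id_rejected(self, fitted):
        with pytest.raises(ValueError):
            fitted.predict([("not-a-snorna", fitted.dataset.disease_ids[0])])
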