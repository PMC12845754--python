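"""AES channel attention, MBE blocks, ranking, and pre-training."""

import numpy as np
import pytest

from aesmbe import nn
from aesmbe.backbone import (
    AESLayer,
    BackboneNet,
    IntentBackbone,
    MBEBlock,
    aes_forward,
    backbone_forward,
    channel_importance,
    init_fc_weights,
    mbe_block_forward,
    rank_and_select,
)


class TestAESForward:
    def test_zero_weights_halve_the_signal(self):
        x = np.random.default_rng(0).standard_normal((6, 160))
        out, alpha = aes_forward(x, np.zeros((6, 6)))
        np.testing.assert_allclose(alpha, 0.5)
        np.testing.assert_allclose(out, x / 2)

    def test_shape_preserved_64x160(self):
        x = np.random.default_rng(1).standard_normal((64, 160))
        out, alpha = aes_forward(x, init_fc_weights(64, 0))
        assert out.shape == (64, 160)
        assert alpha.shape == (64,)
        assert ((alpha >= 0) & (alpha <= 1)).all()

    def test_hand_case_scalar_sigmoid(self):
        # constant channels give z = [1, 0]; identity weights route them
        # straight through the sigmoid
        x = np.stack([np.ones(4), np.zeros(4)])
        _, alpha = aes_forward(x, np.eye(2), descriptor="mean")
        np.testing.assert_allclose(alpha, [1 / (1 + np.exp(-1)), 0.5], atol=1e-9)
        np.testing.assert_allclose(alpha, [0.7311, 0.5], atol=1e-4)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            aes_forward(np.zeros((4, 10)), np.zeros((3, 3)))


class TestInit:
    def test_bounds_and_determinism(self):
        w = init_fc_weights(64, seed=3)
        assert w.shape == (64, 64)
        assert np.abs(w).max() <= 0.125
        np.testing.assert_array_equal(w, init_fc_weights(64, seed=3))

    def test_mean_is_centered(self):
        draws = np.concatenate(
            [init_fc_weights(4, seed=s).ravel() for s in range(625)]
        )  # 10^4 values
        bound = 1 / 2.0
        se = bound / np.sqrt(3) / np.sqrt(draws.size)
        assert abs(draws.mean()) < 3 * se


class TestMBEBlock:
    def test_shape_preserved_through_block(self):
        rng = np.random.default_rng(0)
        block = MBEBlock(8, rng)
        x = rng.standard_normal((2, 8, 160))
        assert mbe_block_forward(x, block).shape == (2, 8, 160)
        assert mbe_block_forward(x[0], block).shape == (8, 160)

    def test_zero_weights_propagate_zero(self):
        block = MBEBlock(4, np.random.default_rng(0))
        for branch in (block.fwd, block.bwd):
            for layer in (branch.conv_local, branch.conv_global):
                layer.weight.data[:] = 0
                layer.bias.data[:] = 0
            branch.proj.weight.data[:] = 0
            branch.proj.bias.data[:] = 0
        block.gate_fc.weight.data[:] = 0
        block.gate_fc.bias.data[:] = 0
        out = mbe_block_forward(np.random.default_rng(1).standard_normal((4, 32)), block)
        np.testing.assert_allclose(out, 0.0, atol=1e-15)

    def test_time_reversal_identity_with_tied_weights(self):
        """With backward weights tied to forward ones, the backward branch
        equals reverse(forward(reverse(x))) exactly."""
        rng = np.random.default_rng(2)
        block = MBEBlock(5, rng)
        block.bwd.load_state_dict(block.fwd.state_dict())
        x = rng.standard_normal((3, 5, 64))
        xt = nn.Tensor(x)
        fwd_of_reversed = block.fwd(xt.flip(2)).data[:, :, ::-1]
        bwd = block.bwd(xt.flip(2)).flip(2).data
        np.testing.assert_allclose(bwd, fwd_of_reversed, atol=1e-6)

    def test_window_shorter_than_global_kernel_rejected(self):
        block = MBEBlock(4, np.random.default_rng(0), k_global=7)
        with pytest.raises(ValueError, match="shorter"):
            block(nn.Tensor(np.zeros((1, 4, 5))))


class TestBackboneShapes:
    def test_logits_and_probabilities(self):
        net = BackboneNet(16, n_blocks=1, seed=0)
        net.eval()
        x = np.random.default_rng(0).standard_normal((8, 16, 160))
        logits, probs = backbone_forward(x, net)
        assert logits.shape == (8, 4)
        assert np.abs(probs.sum(axis=1) - 1).max() < 1e-6
        assert (probs >= 0).all()

    def test_batch_order_permutes_outputs(self):
        net = BackboneNet(6, n_blocks=1, seed=1)
        net.eval()
        x = np.random.default_rng(1).standard_normal((10, 6, 160))
        _, p = backbone_forward(x, net)
        perm = np.random.default_rng(2).permutation(10)
        _, p_perm = backbone_forward(x[perm], net)
        np.testing.assert_allclose(p_perm, p[perm], atol=1e-12)

    def test_channel_mismatch_rejected(self):
        net = BackboneNet(6, seed=0)
        with pytest.raises(ValueError):
            backbone_forward(np.zeros((2, 5, 160)), net)


class TestChannelImportance:
    def test_hand_column_sums(self):
        np.testing.assert_array_equal(
            channel_importance(np.array([[1.0, -2.0], [0.0, 3.0]])), [1.0, 5.0]
        )

    def test_identity_and_homogeneity(self):
        w = np.eye(4)
        np.testing.assert_array_equal(channel_importance(w), np.ones(4))
        r = np.random.default_rng(0).standard_normal((5, 5))
        np.testing.assert_allclose(
            channel_importance(2 * r), 2 * channel_importance(r)
        )

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            channel_importance(np.zeros((3, 4)))


class TestRankAndSelect:
    def test_tie_break_and_ascending_output(self):
        ranking, selected = rank_and_select(np.array([0.5, 0.9, 0.9, 0.1]), 2)
        assert selected == [1, 2]
        assert ranking.order == (1, 2, 0, 3)

    def test_full_budget_and_argmax(self):
        scores = np.array([0.3, 0.1, 0.9, 0.2])
        _, all_ch = rank_and_select(scores, 4)
        assert all_ch == [0, 1, 2, 3]
        _, top1 = rank_and_select(scores, 1)
        assert top1 == [2]

    def test_out_of_range_budget(self):
        with pytest.raises(ValueError):
            rank_and_select(np.ones(4), 0)
        with pytest.raises(ValueError):
            rank_and_select(np.ones(4), 5)


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(0)
    # micro task: class 0 = strong 10 Hz wave on channel 1, class 1 = noise
    t = np.arange(160) / 160
    X, y = [], []
    for i in range(40):
        w = rng.standard_normal((4, 160))
        if i % 2 == 0:
            w[1] += 6 * np.sin(2 * np.pi * 10 * t + rng.uniform(0, 6))
            y.append("rest")
        else:
            y.append("other_subject")
        w = (w - w.mean(axis=1, keepdims=True)) / w.std(axis=1, keepdims=True)
        X.append(w)
    est = IntentBackbone(
        n_blocks=1, lr=0.02, batch_size=20, max_epochs=12, patience=12, seed=0
    )
    return est.fit(np.stack(X), np.array(y, dtype=object)), np.stack(X), np.array(y)


class TestPretraining:
    def test_loss_decreases_and_history_bounded(self, fitted):
        est, _, _ = fitted
        assert est.loss_history_[-1] < est.loss_history_[0]
        assert len(est.loss_history_) <= 12

    def test_refit_same_seed_identical(self, fitted):
        est, X, y = fitted
        est2 = IntentBackbone(
            n_blocks=1, lr=0.02, batch_size=20, max_epochs=12, patience=12, seed=0
        ).fit(X, y)
        for (n1, p1), (n2, p2) in zip(
            est.net_.named_parameters(), est2.net_.named_parameters()
        ):
            assert n1 == n2
            np.testing.assert_array_equal(p1.data, p2.data)

    def test_ranking_is_weights_only(self, fitted):
        est, X, _ = fitted
        r1 = est.channel_ranking(0)
        est.predict(X[:5])  # running more data must not move the ranking
        assert est.channel_ranking(0) == r1
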